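"""Shared phantom fixtures.

Phantom generation is cheap (<1 s) but metric extraction is a few seconds,
so the default phantom and its extracted record are session-scoped and
shared across test modules.
"""

from __future__ import annotations

import warnings

import pytest

from orbitmorph.morphometrics import extract_all_metrics
from orbitmorph.phantom import PhantomSpec, generate_orbit_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Straight-nerve phantom at the package's default anatomy."""
    return generate_orbit_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_record(default_phantom):
    labels, _, landmarks, _ = default_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_all_metrics(labels, landmarks)


@pytest.fixture(scope="session")
def flattened_phantom():
    """Posteriorly flattened globe (f=0.9, R=12) for deformation mapping."""
    return generate_orbit_phantom(
        PhantomSpec(globe_radius=12.0, flattening=0.9, seed=3)
    )


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory, default_phantom):
    """Default phantom written to disk in its external formats."""
    from orbitmorph.io_formats import write_landmarks, write_volume

    labels, intensity, landmarks, truth = default_phantom
    d = tmp_path_factory.mktemp("phantom")
    write_volume(labels, d / "labels.nii.gz")
    write_volume(intensity, d / "image.nii.gz")
    write_landmarks(landmarks, d / "landmarks.mrk.json")
    truth.to_json(d / "truth.json")
    import json

    with open(d / "label_table.json", "w") as fh:
        json.dump(
            {f"{s}|{side}": c for (s, side), c in labels.label_table.items()}, fh
        )
    return d


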