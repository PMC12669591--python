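"""Shared helpers for the phantom-recovery checks (also used by the
acceptance suite)."""

from __future__ import annotations

import numpy as np

from orbitmorph.phantom import PhantomSpec

#: Metrics computed purely from landmark coordinates: recovered exactly.
LANDMARK_METRICS = frozenset(
    {
        "dist_lens_globe_centre",
        "dist_globe_centre_on_tip",
        "globe_length",
        "dist_globe_centre_rim",
        "dist_lens_rim",
        "onsh_width",
        "globe_width",
        "retro_width_muscle",
        "retro_width_bone",
        "optic_canal_area",
    }
)


def metric_tolerance(metric: str, truth: float) -> float:
    """Absolute tolerance for a raster-derived metric vs analytic truth:
    5% relative, with floors where the truth is (near) zero — 0.1 mm^-1 for
    torsion (ill-conditioned on near-straight paths, and empirically the
    least reliable nerve metric), 0.005 for curvature and tortuosity
    (half-voxel path-length quantisation over a ~25 mm nerve)."""
    if metric == "on_torsion":
        floor = 0.1
    elif metric in ("on_curvature", "on_tortuosity"):
        floor = 0.005
    else:
        floor = 0.05
    return max(0.05 * abs(truth), floor)


def random_phantom_spec(rng: np.random.Generator) -> PhantomSpec:
    """A random but anatomically compatible phantom: the draw ranges keep
    the two sheath tubes separated at the midline."""
    curv = float(rng.choice([0.0, 0.01, 0.02]))
    return PhantomSpec(
        globe_radius=float(rng.uniform(10.5, 12.5)),
        on_radius=float(rng.uniform(1.2, 1.8)),
        ons_radius=float(rng.uniform(2.8, 3.6)),
        on_length=float(rng.uniform(22.0, 26.0)),
        on_path="arc" if curv > 0 else "straight",
        on_curvature=curv,
        on_tilt_medial=float(rng.uniform(8.0, 14.0)),
        on_tilt_superior=float(rng.uniform(2.0, 8.0)),
        lens_semiaxes=(4.5, float(rng.uniform(3.5, 4.5)), 4.5),
        seed=int(rng.integers(0, 2**31)),
    )
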