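"""Readers and writers for every external format the pipeline touches.

Conventions enforced here and assumed everywhere else in the package:

* world coordinates are RAS millimetres;
* voxel indices are 0-based and a voxel's world position is its centre;
* label volumes carry a ``label_table`` mapping ``(structure, side)`` to the
  integer code used in the array, with 0 reserved for background.

Supported formats: NIfTI-1/2 (via nibabel) for label and intensity volumes,
3D Slicer markups in both the ``.fcsv`` and ``.mrk.json`` dialects for
landmarks, and CSV/JSON for metric records.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import nibabel as nib
import numpy as np

SIDES = ("right", "left")

#: The 21 per-side landmark names the pipeline understands (42 bilateral).
#: Midline landmarks are permitted but none are required.
LANDMARK_REGISTRY: tuple[str, ...] = (
    "lens_centre",
    "globe_centre",
    "globe_back",
    "on_tip",
    "optic_canal_start",
    "orbital_rim_superior",
    "orbital_rim_inferior",
    "orbital_rim_medial",
    "orbital_rim_lateral",
    "optic_canal_major_a",
    "optic_canal_major_b",
    "optic_canal_minor_a",
    "optic_canal_minor_b",
    "retroorbital_muscle_medial",
    "retroorbital_muscle_lateral",
    "retroorbital_bone_medial",
    "retroorbital_bone_lateral",
    "onsh_a",
    "onsh_b",
    "globe_width_nasal",
    "globe_width_temporal",
)

#: Structures a full label table provides per side.
CORE_STRUCTURES = ("globe", "lens", "optic_nerve", "optic_nerve_sheath")

#: Default integer codes: right eye 1-4, left eye 5-8.
DEFAULT_LABEL_TABLE: dict[tuple[str, str], int] = {
    (s, side): i + 1 + 4 * j
    for j, side in enumerate(SIDES)
    for i, s in enumerate(CORE_STRUCTURES)
}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class LabelVolume:
    """3D integer label grid plus a voxel-to-world (RAS mm) affine."""

    data: np.ndarray
    affine: np.ndarray
    label_table: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_TABLE)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if np.max(np.abs(self.data - rounded)) > 1e-6:
                raise FormatError("label data is not integer within 1e-6")
            self.data = rounded.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("label codes must be non-negative")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm, derived from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def has(self, structure: str, side: str) -> bool:
        return (structure, side) in self.label_table

    def code(self, structure: str, side: str) -> int:
        try:
            return self.label_table[(structure, side)]
        except KeyError:
            raise KeyError(f"no label code for ({structure}, {side})") from None

    def mask(self, structure: str, side: str) -> np.ndarray:
        """Boolean mask of one labelled structure."""
        return self.data == self.code(structure, side)

    def any_label_mask(self) -> np.ndarray:
        return self.data > 0

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (...,3) voxel indices to world RAS mm (voxel centres)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (...,3) world RAS mm positions to continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class IntensityVolume:
    """Real-valued 3D image on the same conventions as :class:`LabelVolume`."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    def check_paired(self, labels: LabelVolume) -> None:
        """Verify this image shares the grid of ``labels`` (shape + affine)."""
        if self.data.shape != labels.data.shape:
            raise ValueError(
                f"grid mismatch: image {self.data.shape} vs labels {labels.data.shape}"
            )
        if not np.allclose(self.affine, labels.affine, atol=1e-6):
            raise ValueError("affine mismatch between image and labels")


@dataclass(frozen=True)
class Landmark:
    """A named, sided anatomical point in world RAS mm."""

    name: str
    side: str  # right | left | midline
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.side not in ("right", "left", "midline"):
            raise ValueError(f"bad side {self.side!r}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for {self.name}")
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


class LandmarkSet:
    """A collection of landmarks, unique per (name, side)."""

    def __init__(self, landmarks: Iterable[Landmark] = (), provenance: str = ""):
        self.provenance = provenance
        self._points: dict[tuple[str, str], Landmark] = {}
        for lm in landmarks:
            self.add(lm)

    def add(self, lm: Landmark, overwrite: bool = False) -> None:
        key = (lm.name, lm.side)
        if key in self._points and not overwrite:
            raise ValueError(f"duplicate landmark {key}")
        self._points[key] = lm

    def get(self, name: str, side: str) -> np.ndarray | None:
        """Position of a landmark, or None when absent."""
        lm = self._points.get((name, side))
        return None if lm is None else lm.xyz

    def require(self, name: str, side: str) -> np.ndarray:
        pos = self.get(name, side)
        if pos is None:
            raise KeyError(f"missing landmark ({name}, {side})")
        return pos

    def __len__(self) -> int:
        return len(self._points)

    def __iter__(self) -> Iterator[Landmark]:
        return iter(self._points.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._points

    def count(self, side: str) -> int:
        return sum(1 for lm in self if lm.side == side)

    def is_complete(self) -> bool:
        """True when all 21 registry landmarks are present on both sides."""
        return all(
            (name, side) in self._points
            for name in LANDMARK_REGISTRY
            for side in SIDES
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Rigidly transformed copy (positions -> R p + t)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return LandmarkSet(
            (
                Landmark(lm.name, lm.side, tuple(rotation @ lm.xyz + translation))
                for lm in self
            ),
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# NIfTI volumes


def _load_canonical(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)  # reorient grid axes to RAS
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, np.asarray(img.affine, dtype=float)


def read_label_volume(
    path: str | Path, label_table: Mapping[tuple[str, str], int] | None = None
) -> LabelVolume:
    """Read a NIfTI segmentation, reoriented so the affine is RAS.

    No resampling is performed: reorientation only permutes/flips grid axes.
    Data must be integer after rounding within 1e-6.
    """
    data, affine = _load_canonical(path)
    table = dict(label_table) if label_table is not None else dict(DEFAULT_LABEL_TABLE)
    return LabelVolume(data=data, affine=affine, label_table=table)


def read_intensity_volume(path: str | Path) -> IntensityVolume:
    """Read a NIfTI intensity image, reoriented so the affine is RAS."""
    data, affine = _load_canonical(path)
    return IntensityVolume(data=data.astype(float), affine=affine)


def write_volume(
    volume: LabelVolume | IntensityVolume, path: str | Path
) -> None:
    """Write a volume as NIfTI-1 (labels as int16, intensities as float32)."""
    if isinstance(volume, LabelVolume):
        data = volume.data.astype(np.int16)
    else:
        data = volume.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))


# ---------------------------------------------------------------------------
# Slicer markups (.fcsv and .mrk.json)

_SIDE_SUFFIXES = {
    "_r": "right",
    "_right": "right",
    "-r": "right",
    "_l": "left",
    "_left": "left",
    "-l": "left",
    "_m": "midline",
    "_mid": "midline",
    "_midline": "midline",
}


def _parse_label(
    raw: str, aliases: Mapping[str, str]
) -> tuple[str, str]:
    """Split a markup label into (registry name, side).

    Accepts ``name_R``, ``name_left`` etc.; the remaining stem is passed
    through the alias table.  Labels without a side suffix are midline.
    """
    stem, side = raw, "midline"
    low = raw.lower()
    for suffix, s in _SIDE_SUFFIXES.items():
        if low.endswith(suffix):
            stem, side = raw[: -len(suffix)], s
            break
    name = aliases.get(stem, aliases.get(stem.lower(), stem.lower()))
    return name, side


def read_landmarks(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    strict: bool = False,
) -> LandmarkSet:
    """Read a Slicer markups file (FCSV or .mrk.json) into world RAS mm.

    FCSV files declaring ``# CoordinateSystem = LPS`` (or ``0``) have their
    x and y coordinates negated.  ``strict`` rejects names that are not in
    :data:`LANDMARK_REGISTRY` after alias mapping; otherwise they are kept.
    """
    path = Path(path)
    aliases = dict(aliases or {})
    if path.suffix.lower() == ".fcsv":
        entries = _read_fcsv(path)
    elif path.name.lower().endswith((".mrk.json", ".json")):
        entries = _read_mrk_json(path)
    else:
        raise FormatError(f"unknown markups dialect: {path.name}")

    lms = LandmarkSet(provenance=str(path))
    for raw_label, pos in entries:
        name, side = _parse_label(raw_label, aliases)
        if name not in LANDMARK_REGISTRY and strict:
            raise FormatError(f"unknown landmark name {raw_label!r} -> {name!r}")
        lms.add(Landmark(name, side, tuple(pos)))
    return lms


def _read_fcsv(path: Path) -> list[tuple[str, np.ndarray]]:
    lps = False
    columns: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("coordinatesystem"):
                    value = body.split("=", 1)[1].strip().lower()
                    lps = value in ("lps", "0")
                elif body.lower().startswith("columns"):
                    columns = [c.strip() for c in body.split("=", 1)[1].split(",")]
                continue
            rows.append(next(csv.reader([line])))
    if columns is None:
        # Slicer's fixed legacy layout
        columns = "id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID".split(",")
    try:
        ix, iy, iz = columns.index("x"), columns.index("y"), columns.index("z")
        ilabel = columns.index("label")
    except ValueError as exc:
        raise FormatError(f"{path}: missing x/y/z/label columns") from exc
    out = []
    for row in rows:
        pos = np.array([float(row[ix]), float(row[iy]), float(row[iz])])
        if lps:
            pos[0], pos[1] = -pos[0], -pos[1]
        out.append((row[ilabel], pos))
    return out


def _read_mrk_json(path: Path) -> list[tuple[str, np.ndarray]]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for markup in doc.get("markups", []):
        lps = str(markup.get("coordinateSystem", "LPS")).upper() == "LPS"
        for cp in markup.get("controlPoints", []):
            pos = np.asarray(cp["position"], dtype=float)
            if lps:
                pos[0], pos[1] = -pos[0], -pos[1]
            out.append((cp["label"], pos))
    return out


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set as a Slicer ``.mrk.json`` markups file (RAS)."""
    control_points = [
        {
            "id": str(i + 1),
            "label": f"{lm.name}_{lm.side}",
            "position": list(lm.position),
        }
        for i, lm in enumerate(sorted(iter(lms), key=lambda l: (l.name, l.side)))
    ]
    doc = {
        "@schema": "https://raw.githubusercontent.com/Slicer/Slicer/main/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json#",
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": "RAS",
                "controlPoints": control_points,
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Metric records (CSV long format / JSON)


def write_metrics(record, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`~orbitmorph.morphometrics.MetricsRecord`.

    CSV is long format with columns ``metric,side,value,units`` in the fixed
    registry order; JSON mirrors the same rows.  NaN marks unavailable
    metrics; the row count is always 38.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = record.to_rows()
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "side", "value", "units"])
            for metric, side, value, units in rows:
                writer.writerow([metric, side, repr(float(value)), units])
    elif fmt == "json":
        payload = [
            {"metric": m, "side": s, "value": None if np.isnan(v) else float(v), "units": u}
            for m, s, v, u in rows
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown metrics format {fmt!r}")


def read_metrics(path: str | Path):
    """Read a metrics file written by :func:`write_metrics`."""
    from .morphometrics import MetricsRecord  # deferred: avoids import cycle

    path = Path(path)
    values: dict[tuple[str, str], float] = {}
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            for row in json.load(fh):
                v = row["value"]
                values[(row["metric"], row["side"])] = float("nan") if v is None else float(v)
    else:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                values[(row["metric"], row["side"])] = float(row["value"])
    return MetricsRecord(values)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
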