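"""Posterior-globe deformation map.

The scleral surface is expressed in a bespoke spherical frame: origin at
the globe centre, zenith pointing from the globe centre to the nerve tip
(i.e. posteriorly), azimuth reference derived from the world left-right
axis.  Every surface point becomes (r, theta, phi); anterior points
(theta > 90 deg) are discarded, the polar angle is normalised by 90 deg,
and the mean radius is accumulated on a fixed (theta_norm x phi) polar
grid.  Posterior flattening (raised intracranial pressure, spaceflight-
associated neuro-ocular syndrome) shows up as a depressed radius around
the map centre while the equatorial rim stays at the globe radius.

Maps on a shared grid aggregate across subjects into per-bin mean and
sample-variance maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.measure import marching_cubes

from .io_formats import LabelVolume, LandmarkSet


@dataclass(frozen=True)
class SphericalFrame:
    """Globe-centred frame: zenith toward the nerve tip, azimuth reference
    orthogonalised from the world +x (left-to-right) axis."""

    origin: np.ndarray
    zenith: np.ndarray
    azimuth_ref: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "zenith", "azimuth_ref"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if abs(np.linalg.norm(self.zenith) - 1) > 1e-9:
            raise ValueError("zenith must be unit length")
        if abs(float(self.zenith @ self.azimuth_ref)) > 1e-9:
            raise ValueError("azimuth_ref must be orthogonal to zenith")

    def to_spherical(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(r mm, theta deg from zenith, phi deg in [0, 360)) per point."""
        d = np.asarray(points, dtype=float) - self.origin
        r = np.linalg.norm(d, axis=-1)
        z = d @ self.zenith
        theta = np.degrees(np.arccos(np.clip(z / np.maximum(r, 1e-12), -1.0, 1.0)))
        y_axis = np.cross(self.zenith, self.azimuth_ref)
        phi = np.degrees(np.arctan2(d @ y_axis, d @ self.azimuth_ref)) % 360.0
        return r, theta, phi


def build_frame(globe_centre: np.ndarray, on_tip: np.ndarray) -> SphericalFrame:
    """Frame from the two landmarks; falls back to the world +y axis for
    the azimuth reference when the zenith is (near) parallel to +x."""
    globe_centre = np.asarray(globe_centre, dtype=float)
    on_tip = np.asarray(on_tip, dtype=float)
    d = on_tip - globe_centre
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ValueError("globe centre and nerve tip coincide")
    zenith = d / norm
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ zenith) > 0.999:
        ref = np.array([0.0, 1.0, 0.0])
    az = ref - (ref @ zenith) * zenith
    az /= np.linalg.norm(az)
    return SphericalFrame(origin=globe_centre, zenith=zenith, azimuth_ref=az)


def globe_surface_points(labels: LabelVolume, side: str, iso: float = 0.5) -> np.ndarray:
    """Vertices of the globe mask's iso-surface, in world RAS mm.

    The surface is extracted by marching cubes in voxel space and mapped
    through the affine, so rotated grids are handled exactly.  The lens,
    when labelled separately, is counted as globe interior so the anterior
    surface is the sclera, not the lens carve-out.
    """
    mask = labels.mask("globe", side)
    if labels.has("lens", side):
        mask = mask | labels.mask("lens", side)
    if not mask.any():
        raise ValueError(f"globe label empty on side {side}")
    padded = np.pad(mask.astype(float), 1)
    verts, _, _, _ = marching_cubes(padded, level=iso)
    verts -= 1.0  # undo padding offset
    return labels.voxel_to_world(verts)


@dataclass
class DeformationMap:
    """Mean scleral radius on a (theta_norm x phi) polar grid.

    ``grid[i, j]`` is the mean radius (mm) of surface points falling in the
    i-th normalised-polar-angle bin (theta/90 in [0, 1]) and j-th azimuth
    bin (phi in [0, 360)); NaN where no point fell.  ``counts`` and
    ``variance`` follow the same layout.
    """

    grid: np.ndarray
    counts: np.ndarray
    variance: np.ndarray | None = None
    side: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_theta(self) -> int:
        return self.grid.shape[0]

    @property
    def n_phi(self) -> int:
        return self.grid.shape[1]

    def central_radius(self, n_rings: int = 2) -> float:
        """Mean radius over the innermost polar rings (around the posterior
        pole, where flattening is maximal)."""
        block = self.grid[:n_rings]
        return float(np.nanmean(block))

    def rim_radius(self, n_rings: int = 2) -> float:
        """Mean radius over the outermost rings (theta_norm ~ 1)."""
        return float(np.nanmean(self.grid[-n_rings:]))

    def to_csv(self, path: str | Path) -> None:
        """Grid as CSV plus a sidecar JSON header (bins, side, frame)."""
        path = Path(path)
        np.savetxt(path, self.grid, delimiter=",", fmt="%.6f")
        header = {
            "n_theta": self.n_theta,
            "n_phi": self.n_phi,
            "side": self.side,
            **{k: v for k, v in self.meta.items()},
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(header, fh, indent=1)
        np.savetxt(
            path.with_name(path.stem + "_counts" + path.suffix),
            self.counts, delimiter=",", fmt="%d",
        )


def to_deformation_map(
    points: np.ndarray,
    frame: SphericalFrame,
    n_theta: int = 30,
    n_phi: int = 72,
    side: str | None = None,
) -> DeformationMap:
    """Bin surface points into the polar deformation grid.

    Points on the anterior hemisphere (theta > 90 deg) are discarded; theta
    bins are uniform in theta (matching the direct theta/90 normalisation),
    phi bins uniform over [0, 360).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 100:
        raise ValueError("need at least 100 surface points")
    r, theta, phi = frame.to_spherical(points)
    posterior = theta <= 90.0
    if not posterior.any():
        raise ValueError("all surface points are anterior to the equator")
    r, theta, phi = r[posterior], theta[posterior], phi[posterior]
    t_idx = np.clip((theta / 90.0 * n_theta).astype(int), 0, n_theta - 1)
    p_idx = np.clip((phi / 360.0 * n_phi).astype(int), 0, n_phi - 1)
    flat = t_idx * n_phi + p_idx
    counts = np.bincount(flat, minlength=n_theta * n_phi)
    sums = np.bincount(flat, weights=r, minlength=n_theta * n_phi)
    sq = np.bincount(flat, weights=r**2, minlength=n_theta * n_phi)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = sq / counts - mean**2
    grid = mean.reshape(n_theta, n_phi)
    meta = {
        "origin": list(frame.origin),
        "zenith": list(frame.zenith),
        "azimuth_ref": list(frame.azimuth_ref),
        "n_anterior_discarded": int(np.sum(~posterior)),
    }
    return DeformationMap(
        grid=grid,
        counts=counts.reshape(n_theta, n_phi),
        variance=np.where(counts > 0, var, np.nan).reshape(n_theta, n_phi),
        side=side,
        meta=meta,
    )


def subject_deformation_map(
    labels: LabelVolume,
    landmarks: LandmarkSet,
    side: str,
    n_theta: int = 30,
    n_phi: int = 72,
) -> DeformationMap:
    """Convenience: surface extraction + frame + binning for one eye."""
    frame = build_frame(
        landmarks.require("globe_centre", side), landmarks.require("on_tip", side)
    )
    points = globe_surface_points(labels, side)
    return to_deformation_map(points, frame, n_theta=n_theta, n_phi=n_phi, side=side)


def aggregate_maps(maps: Sequence[DeformationMap]) -> tuple[DeformationMap, DeformationMap]:
    """Across-subject per-bin mean and sample variance (ddof=1).

    Bins missing (empty) in any subject are flagged NaN in both outputs;
    the returned maps record how many subjects entered each bin.
    """
    if not maps:
        raise ValueError("no maps to aggregate")
    shape = maps[0].grid.shape
    for m in maps:
        if m.grid.shape != shape:
            raise ValueError("deformation maps have mismatched grid shapes")
    stack = np.stack([m.grid for m in maps])
    present = np.stack([m.counts > 0 for m in maps])
    all_present = present.all(axis=0)
    n = len(maps)
    mean = np.where(all_present, np.nanmean(stack, axis=0), np.nan)
    if n > 1:
        var = np.where(all_present, np.nanvar(stack, axis=0, ddof=1), np.nan)
    else:
        var = np.full(shape, np.nan)
    n_present = present.sum(axis=0)
    meta = {"n_subjects": n}
    return (
        DeformationMap(grid=mean, counts=n_present, side=maps[0].side, meta=meta),
        DeformationMap(grid=var, counts=n_present, side=maps[0].side, meta=meta),
    )
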