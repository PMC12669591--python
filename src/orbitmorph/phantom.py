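"""Synthetic orbit phantom with closed-form ground truth.

The phantom emulates, per side: a spherical ocular globe (optionally
flattened at the posterior pole), an ellipsoidal lens tangent to the
anterior globe interior, a curved coaxial optic-nerve / nerve-sheath tube
pair swept posteriorly from the back of the globe, and the full 21-landmark
constellation (orbital rim ring, optic-canal axis pairs, retroorbital width
pairs, sheath-head pair).  Intensities are per-tissue means plus Gaussian
noise; everything is reproducible from the seed.

Every metric the pipeline measures has an analytic truth value recorded in
:class:`PhantomTruth`, so the whole measurement chain can be validated
without any real MRI.

Geometry conventions: world RAS mm; the zenith (globe centre -> nerve tip)
axis points posteriorly, i.e. along -A = (0,-1,0); eyes are mirror images
across the mid-sagittal plane x=0 unless per-side overrides are given.
"""

from __future__ import annotations

import json
import math
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from .io_formats import (
    IntensityVolume,
    LabelVolume,
    Landmark,
    LandmarkSet,
    SIDES,
)

POSTERIOR = np.array([0.0, -1.0, 0.0])  # zenith direction in RAS
SUPERIOR = np.array([0.0, 0.0, 1.0])


@dataclass
class PhantomSpec:
    """Parameters of the synthetic orbit.

    Defaults are sized to the adult orbit: an 11.3 mm globe radius gives a
    6.04 cm^3 globe, the 1.5 / 3.2 mm nerve and sheath radii give an
    ~1 mm^2-scale nerve and a ~32 mm^2 sheath cross-section 3 mm behind the
    globe, and the 25 mm nerve length, 21.4 / 31.2 mm retroorbital widths
    and 4.56 x 4.09 mm canal axes sit at normative adult values.
    """

    voxel_size: float = 0.5  # mm, isotropic
    globe_radius: float = 11.3  # mm
    globe_centre_x: float = 20.0  # mm lateral offset of each eye from midline
    lens_semiaxes: tuple[float, float, float] = (4.5, 4.0, 4.5)  # (x, zenith, z) mm
    on_radius: float = 1.5  # mm
    ons_radius: float = 3.2  # mm
    on_path: Literal["straight", "arc"] = "straight"
    on_curvature: float = 0.0  # mm^-1, used when on_path == "arc"
    on_length: float = 25.0  # mm along the centerline
    on_tilt_medial: float = 15.0  # deg, nerve axis tilt toward the nose
    on_tilt_superior: float = 6.0  # deg, nerve axis tilt upward
    flattening: float = 1.0  # posterior-pole scale f in (0, 1]
    noise_sigma: float = 10.0  # intensity units
    tissue_intensities: dict[str, float] = field(
        default_factory=lambda: {
            "globe": 200.0,
            "lens": 230.0,
            "optic_nerve": 150.0,
            "optic_nerve_sheath": 180.0,
            "orbit": 120.0,
            "air": 0.0,
        }
    )
    rim_offset: float = 6.2  # mm, rim plane anterior to the globe centre
    rim_radius: float = 17.0  # mm, rim landmark ring radius
    retro_width_muscle: float = 21.4  # mm
    retro_width_bone: float = 31.2  # mm
    canal_major: float = 4.56  # mm, optic canal major axis
    canal_minor: float = 4.09  # mm
    orbit_margin: float = 4.0  # mm of soft tissue surrounding the structures
    air_margin: float = 5.0  # mm of air beyond the soft-tissue band
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.ons_radius > self.on_radius > 0):
            raise ValueError("require ons_radius > on_radius > 0")
        if self.globe_radius <= 0:
            raise ValueError("globe_radius must be positive")
        if not (0 < self.flattening <= 1):
            raise ValueError("flattening must be in (0, 1]")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.on_path == "arc" and self.on_curvature <= 0:
            raise ValueError("arc path requires on_curvature > 0")
        if self.on_path == "straight":
            self.on_curvature = 0.0


@dataclass
class PhantomTruth:
    """Analytic ground truth for every pipeline output.

    ``metrics[(name, side)]`` holds the 19 morphometric parameters per side;
    ``snr``/``cnr`` the quality-metric ratios per structure; the flattening
    rule parameters allow the deformation map to be checked bin by bin.
    """

    metrics: dict[tuple[str, str], float]
    snr: dict[str, float]
    cnr: dict[str, float]
    noise_sigma: float
    globe_radius: float
    flattening: float
    globe_centres: dict[str, tuple[float, float, float]]

    def scleral_radius(self, theta_deg: np.ndarray | float) -> np.ndarray:
        """Posterior scleral radius r(theta) = R * (1 - (1-f) cos^2 theta)."""
        theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return self.globe_radius * (1.0 - (1.0 - self.flattening) * np.cos(theta) ** 2)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "metrics": {f"{m}|{s}": v for (m, s), v in self.metrics.items()},
            "snr": self.snr,
            "cnr": self.cnr,
            "noise_sigma": self.noise_sigma,
            "globe_radius": self.globe_radius,
            "flattening": self.flattening,
            "globe_centres": self.globe_centres,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def flattened_sphere_volume(radius: float, f: float) -> float:
    """Volume (mm^3) of a sphere whose posterior hemisphere follows
    r(theta) = R(1 - (1-f) cos^2 theta).

    Closed form: the posterior half integrates to
    (2 pi R^3 / 3) * (1 - e + 3 e^2/5 - e^3/7) with e = 1 - f, the anterior
    half is an exact hemisphere.
    """
    e = 1.0 - f
    posterior = 1.0 - e + 3.0 * e**2 / 5.0 - e**3 / 7.0
    return (2.0 * math.pi * radius**3 / 3.0) * (1.0 + posterior)


def arc_tortuosity(curvature: float, length: float) -> float:
    """arc/chord - 1 for a circular arc of given curvature and arc length."""
    if curvature == 0:
        return 0.0
    half = curvature * length / 2.0
    return half / math.sin(half) - 1.0


# ---------------------------------------------------------------------------
# analytic inside tests


def _inside_sphere(
    pts: np.ndarray, centre: np.ndarray, radius: float, zenith: np.ndarray, f: float
) -> np.ndarray:
    """Flattened-sphere membership: radius fR at the posterior pole,
    interpolating to R at the equator, exact sphere on the anterior half."""
    d = pts - centre
    r = np.linalg.norm(d, axis=-1)
    if f >= 1.0:
        return r <= radius
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(r > 0, (d @ zenith) / np.maximum(r, 1e-12), 0.0)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    limit = np.where(
        cos_t > 0, radius * (1.0 - (1.0 - f) * cos_t**2), radius
    )
    return r <= limit


def _inside_ellipsoid(
    pts: np.ndarray, centre: np.ndarray, semiaxes: tuple[float, float, float]
) -> np.ndarray:
    d = (pts - centre) / np.asarray(semiaxes, dtype=float)
    return np.einsum("...i,...i->...", d, d) <= 1.0


def _tube_distance(
    pts: np.ndarray,
    start: np.ndarray,
    direction: np.ndarray,
    bend: np.ndarray,
    curvature: float,
    length: float,
) -> np.ndarray:
    """Distance from points to a finite straight segment or circular arc.

    The arc starts at ``start`` with tangent ``direction`` and bends toward
    ``bend`` with constant ``curvature``; points whose projection falls
    outside the arc span get +inf (no end caps, so tube volume is exactly
    pi r^2 L)."""
    if curvature == 0.0:
        t = (pts - start) @ direction
        radial = pts - start - t[..., None] * direction
        dist = np.linalg.norm(radial, axis=-1)
        return np.where((t >= 0) & (t <= length), dist, np.inf)
    rho0 = 1.0 / curvature
    centre = start + rho0 * bend
    axis = np.cross(direction, bend)
    d = pts - centre
    w = d @ axis
    d_ip = d - w[..., None] * axis
    u1 = d_ip @ (-bend)
    u2 = d_ip @ direction
    phi = np.arctan2(u2, u1)
    rho = np.linalg.norm(d_ip, axis=-1)
    dist = np.sqrt((rho - rho0) ** 2 + w**2)
    inside_span = (phi >= 0) & (phi <= curvature * length)
    return np.where(inside_span, dist, np.inf)


def _path_point(
    s: float,
    start: np.ndarray,
    direction: np.ndarray,
    bend: np.ndarray,
    curvature: float,
) -> np.ndarray:
    if curvature == 0.0:
        return start + s * direction
    k = curvature
    return start + (math.sin(k * s) / k) * direction + ((1 - math.cos(k * s)) / k) * bend


def _path_tangent(
    s: float, direction: np.ndarray, bend: np.ndarray, curvature: float
) -> np.ndarray:
    if curvature == 0.0:
        return direction
    k = curvature
    return math.cos(k * s) * direction + math.sin(k * s) * bend


# ---------------------------------------------------------------------------
# generator


def _perp_unit(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Component of v orthogonal to the unit vector axis, normalised."""
    w = v - (v @ axis) * axis
    return w / np.linalg.norm(w)


def _side_geometry(spec: PhantomSpec, side: str) -> dict:
    sgn = 1.0 if side == "right" else -1.0
    centre = np.array([sgn * spec.globe_centre_x, 0.0, 0.0])
    medial = np.array([-sgn, 0.0, 0.0])  # toward the nose
    # the nerve runs posteromedially (and slightly upward) toward the
    # orbital apex; the zenith axis of the phantom follows it
    zenith = (
        POSTERIOR
        + math.tan(math.radians(spec.on_tilt_medial)) * medial
        + math.tan(math.radians(spec.on_tilt_superior)) * SUPERIOR
    )
    zenith = zenith / np.linalg.norm(zenith)
    pole = centre + spec.flattening * spec.globe_radius * zenith
    lens_centre = centre - (spec.globe_radius - spec.lens_semiaxes[1]) * zenith
    return {
        "sgn": sgn,
        "centre": centre,
        "zenith": zenith,
        "medial": medial,
        "pole": pole,
        "lens_centre": lens_centre,
        # arcs bend medially, staying in the (tilted) axial plane
        "bend": _perp_unit(medial, zenith),
    }


def _build_landmarks(spec: PhantomSpec) -> LandmarkSet:
    lms = LandmarkSet(provenance="orbit phantom")
    for side in SIDES:
        g = _side_geometry(spec, side)
        c, zen, sgn = g["centre"], g["zenith"], g["sgn"]
        lateral = np.array([sgn, 0.0, 0.0])
        p_end = _path_point(spec.on_length, g["pole"], zen, g["bend"], spec.on_curvature)
        t_end = _path_tangent(spec.on_length, zen, g["bend"], spec.on_curvature)
        # canal ellipse axes in the plane perpendicular to the exit tangent
        u = _perp_unit(SUPERIOR, t_end)
        v = np.cross(t_end, u)
        if v @ g["medial"] < 0:  # keep the minor axis nasally oriented
            v = -v
        onsh_centre = _path_point(1.5, g["pole"], zen, g["bend"], spec.on_curvature)
        onsh_u = _perp_unit(
            SUPERIOR, _path_tangent(1.5, zen, g["bend"], spec.on_curvature)
        )
        rim_c = c - spec.rim_offset * zen  # anterior of the globe centre
        rim_u = _perp_unit(SUPERIOR, zen)
        rim_v = np.cross(zen, rim_u)
        if rim_v @ g["medial"] < 0:
            rim_v = -rim_v
        width_dir = _perp_unit(g["medial"], zen)  # equatorial nasal direction
        y_m = c[1] - spec.globe_radius - 2.0  # retroorbital width planes
        y_b = c[1] - spec.globe_radius - 5.0
        points = {
            "lens_centre": g["lens_centre"],
            "globe_centre": c,
            "globe_back": g["pole"],
            "on_tip": g["pole"],
            "optic_canal_start": p_end,
            "orbital_rim_superior": rim_c + spec.rim_radius * rim_u,
            "orbital_rim_inferior": rim_c - spec.rim_radius * rim_u,
            "orbital_rim_medial": rim_c + spec.rim_radius * rim_v,
            "orbital_rim_lateral": rim_c - spec.rim_radius * rim_v,
            "optic_canal_major_a": p_end + 0.5 * spec.canal_major * u,
            "optic_canal_major_b": p_end - 0.5 * spec.canal_major * u,
            "optic_canal_minor_a": p_end + 0.5 * spec.canal_minor * v,
            "optic_canal_minor_b": p_end - 0.5 * spec.canal_minor * v,
            "retroorbital_muscle_medial": np.array(
                [c[0] - sgn * spec.retro_width_muscle / 2, y_m, 0.0]
            ),
            "retroorbital_muscle_lateral": np.array(
                [c[0] + sgn * spec.retro_width_muscle / 2, y_m, 0.0]
            ),
            "retroorbital_bone_medial": np.array(
                [c[0] - sgn * spec.retro_width_bone / 2, y_b, 0.0]
            ),
            "retroorbital_bone_lateral": np.array(
                [c[0] + sgn * spec.retro_width_bone / 2, y_b, 0.0]
            ),
            "onsh_a": onsh_centre + spec.ons_radius * onsh_u,
            "onsh_b": onsh_centre - spec.ons_radius * onsh_u,
            "globe_width_nasal": c + spec.globe_radius * width_dir,
            "globe_width_temporal": c - spec.globe_radius * width_dir,
        }
        for name, pos in points.items():
            lms.add(Landmark(name, side, tuple(pos)))
    return lms


def _truth(spec: PhantomSpec) -> PhantomTruth:
    lens_axial = spec.lens_semiaxes[1]
    lens_volume = (
        4.0 / 3.0 * math.pi * spec.lens_semiaxes[0] * lens_axial * spec.lens_semiaxes[2]
    )
    globe_mm3 = flattened_sphere_volume(spec.globe_radius, spec.flattening)
    per_side = {
        "dist_lens_globe_centre": spec.globe_radius - lens_axial,
        "dist_globe_centre_on_tip": spec.flattening * spec.globe_radius,
        "globe_length": (spec.globe_radius - lens_axial)
        + spec.flattening * spec.globe_radius,
        "dist_globe_centre_rim": spec.rim_offset,
        "dist_lens_rim": spec.rim_offset - (spec.globe_radius - lens_axial),
        "onsh_width": 2.0 * spec.ons_radius,
        "globe_width": 2.0 * spec.globe_radius,
        "retro_width_muscle": spec.retro_width_muscle,
        "retro_width_bone": spec.retro_width_bone,
        "optic_canal_area": math.pi * spec.canal_major * spec.canal_minor / 4.0,
        "ons_3mm_area": math.pi * spec.ons_radius**2,
        "ons_3mm_optimal_area": math.pi * spec.ons_radius**2,
        "on_radius": spec.on_radius,
        "on_length": spec.on_length,
        "on_curvature": spec.on_curvature,
        "on_torsion": 0.0,  # planar nerve path
        "on_tortuosity": arc_tortuosity(spec.on_curvature, spec.on_length),
        # the lens is carved out of the globe label, so the labelled globe
        # volume is the (flattened) sphere minus the lens ellipsoid
        "globe_volume": (globe_mm3 - lens_volume) / 1000.0,
        "ons_volume": math.pi
        * (spec.ons_radius**2 - spec.on_radius**2)
        * spec.on_length
        / 1000.0,
    }
    ti = spec.tissue_intensities
    snr = {s: ti[s] / spec.noise_sigma for s in ("globe", "optic_nerve")}
    cnr = {s: (ti[s] - ti["orbit"]) / spec.noise_sigma for s in ("globe", "optic_nerve")}
    centres = {
        side: tuple(_side_geometry(spec, side)["centre"]) for side in SIDES
    }
    return PhantomTruth(
        metrics={(m, side): v for side in SIDES for m, v in per_side.items()},
        snr=snr,
        cnr=cnr,
        noise_sigma=spec.noise_sigma,
        globe_radius=spec.globe_radius,
        flattening=spec.flattening,
        globe_centres=centres,
    )


def _grid(spec: PhantomSpec) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Affine and shape of a grid containing all structures plus the
    soft-tissue band and an air margin on every face."""
    pad = spec.orbit_margin + spec.air_margin
    pts = []
    for side in SIDES:
        g = _side_geometry(spec, side)
        pts.append(g["centre"] - spec.globe_radius)
        pts.append(g["centre"] + spec.globe_radius)
        for s in np.linspace(0, spec.on_length, 64):
            p = _path_point(s, g["pole"], g["zenith"], g["bend"], spec.on_curvature)
            pts.append(p - spec.ons_radius)
            pts.append(p + spec.ons_radius)
    pts = np.asarray(pts)
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    h = spec.voxel_size
    shape = tuple(int(math.ceil((hi[i] - lo[i]) / h)) + 1 for i in range(3))
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = lo
    return affine, shape


def _box_slices(
    affine: np.ndarray, shape: tuple[int, ...], lo: np.ndarray, hi: np.ndarray
) -> tuple[slice, slice, slice]:
    """Voxel slices covering a world-space axis-aligned box."""
    inv = np.linalg.inv(affine)
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    vox = corners @ inv[:3, :3].T + inv[:3, 3]
    lo_i = np.clip(np.floor(vox.min(axis=0)).astype(int) - 1, 0, np.array(shape) - 1)
    hi_i = np.clip(np.ceil(vox.max(axis=0)).astype(int) + 2, 1, np.array(shape))
    return tuple(slice(int(lo_i[i]), int(hi_i[i])) for i in range(3))


def _world_points(affine: np.ndarray, slices: tuple[slice, slice, slice]) -> np.ndarray:
    """(ni, nj, nk, 3) world coordinates of voxel centres in a sub-box."""
    axes = [np.arange(s.start, s.stop, dtype=float) for s in slices]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1)
    return pts @ affine[:3, :3].T + affine[:3, 3]


def generate_orbit_phantom(
    spec: PhantomSpec,
) -> tuple[LabelVolume, IntensityVolume, LandmarkSet, PhantomTruth]:
    """Rasterise the phantom and return labels, intensities, landmarks, truth.

    Labels are assigned by analytic inside-tests at voxel centres with
    priority lens > globe > nerve > sheath (the lens sits inside the globe;
    nerve and sheath never overwrite ocular tissue).  The intensity image is
    per-tissue means plus N(0, sigma^2) noise from ``spec.seed``.
    """
    affine, shape = _grid(spec)
    labels = np.zeros(shape, dtype=np.int16)
    side_union = {side: np.zeros(shape, dtype=bool) for side in SIDES}

    table: dict[tuple[str, str], int] = {}
    code = 0
    for side in SIDES:
        g = _side_geometry(spec, side)
        # ocular box: globe + lens
        pad = 2 * spec.voxel_size
        sl_eye = _box_slices(
            affine, shape,
            g["centre"] - spec.globe_radius - pad,
            g["centre"] + spec.globe_radius + pad,
        )
        pts_eye = _world_points(affine, sl_eye)
        in_globe = _inside_sphere(
            pts_eye, g["centre"], spec.globe_radius, g["zenith"], spec.flattening
        )
        in_lens = _inside_ellipsoid(pts_eye, g["lens_centre"], spec.lens_semiaxes)
        # nerve box: swept tube
        dense = np.array(
            [
                _path_point(s, g["pole"], g["zenith"], g["bend"], spec.on_curvature)
                for s in np.linspace(0, spec.on_length, 64)
            ]
        )
        sl_tube = _box_slices(
            affine, shape,
            dense.min(axis=0) - spec.ons_radius - pad,
            dense.max(axis=0) + spec.ons_radius + pad,
        )
        pts_tube = _world_points(affine, sl_tube)
        tube_d = _tube_distance(
            pts_tube, g["pole"], g["zenith"], g["bend"], spec.on_curvature, spec.on_length
        )
        tube_globe = _inside_sphere(
            pts_tube, g["centre"], spec.globe_radius, g["zenith"], spec.flattening
        )
        in_on = (tube_d <= spec.on_radius) & ~tube_globe
        in_ons = (tube_d <= spec.ons_radius) & ~tube_globe & ~in_on
        for structure, mask, sl in (
            ("globe", in_globe & ~in_lens, sl_eye),
            ("lens", in_lens, sl_eye),
            ("optic_nerve", in_on, sl_tube),
            ("optic_nerve_sheath", in_ons, sl_tube),
        ):
            code += 1
            table[(structure, side)] = code
            region = labels[sl]
            region[mask & (region == 0)] = code
            side_union[side][sl] |= mask
    if (side_union["right"] & side_union["left"]).any():
        raise ValueError(
            "left and right structures overlap; increase globe_centre_x or "
            "reduce the nerve curvature/tilt"
        )

    label_volume = LabelVolume(data=labels, affine=affine, label_table=table)

    # soft-tissue band around the structures; everything beyond it is air
    tissue = labels > 0
    dist_out = ndimage.distance_transform_edt(
        ~tissue, sampling=label_volume.spacing
    )
    orbit_band = (dist_out <= spec.orbit_margin) & ~tissue

    ti = spec.tissue_intensities
    intensity = np.full(shape, ti["air"], dtype=float)
    intensity[orbit_band] = ti["orbit"]
    for (structure, side), c in table.items():
        intensity[labels == c] = ti[structure]
    rng = np.random.default_rng(spec.seed)
    intensity += rng.normal(0.0, spec.noise_sigma, size=shape)

    return (
        label_volume,
        IntensityVolume(data=intensity, affine=affine),
        _build_landmarks(spec),
        _truth(spec),
    )


def flatten_posterior(spec: PhantomSpec, f: float) -> PhantomSpec:
    """Copy of ``spec`` with posterior flattening factor ``f`` in (0, 1).

    The flattened phantom's scleral radius at polar angle theta from the
    zenith is r(theta) = R * (1 - (1-f) cos^2 theta): f*R at the posterior
    pole, smoothly back to R at the equator.
    """
    if not (0 < f < 1):
        raise ValueError("flattening factor must be in (0, 1)")
    return dataclasses.replace(spec, flattening=f)


def true_air_mask(labels: LabelVolume, orbit_margin: float = 4.0) -> np.ndarray:
    """Ground-truth air region: farther than ``orbit_margin`` mm from any
    labelled structure (matches the generator's soft-tissue band)."""
    tissue = labels.any_label_mask()
    dist_out = ndimage.distance_transform_edt(~tissue, sampling=labels.spacing)
    return dist_out > orbit_margin


def generate_tube_phantom(
    radius: float = 1.5,
    length: float = 25.0,
    curvature: float = 0.0,
    voxel_size: float = 0.5,
    margin: float = 5.0,
) -> tuple[LabelVolume, np.ndarray, np.ndarray]:
    """A single nerve-like tube mask for centerline validation.

    Returns the label volume (code 1 = ("optic_nerve", "right")) and the
    exact world start/end points of the tube axis.  The tube starts at the
    origin with tangent (0,-1,0) and bends toward (-1,0,0) when curved.
    """
    start = np.zeros(3)
    direction = POSTERIOR.copy()
    bend = np.array([-1.0, 0.0, 0.0])
    dense = np.array(
        [_path_point(s, start, direction, bend, curvature) for s in np.linspace(0, length, 128)]
    )
    lo = dense.min(axis=0) - radius - margin
    hi = dense.max(axis=0) + radius + margin
    shape = tuple(int(math.ceil((hi[i] - lo[i]) / voxel_size)) + 1 for i in range(3))
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = lo
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).astype(float) @ affine[:3, :3].T + affine[:3, 3]
    d = _tube_distance(pts, start, direction, bend, curvature, length)
    labels = (d <= radius).astype(np.int16)
    vol = LabelVolume(
        data=labels, affine=affine, label_table={("optic_nerve", "right"): 1}
    )
    end = _path_point(length, start, direction, bend, curvature)
    return vol, start, end
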