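"""Region-specific image-quality metrics for the globe and optic nerve.

Three metrics are computed on the intensities inside each segmented
structure:

* **EFC** (entropy focus criterion): the Shannon entropy of the intensity
  distribution normalised by the ROI's intensity energy,
  ``E = -sum (x_j/x_max) ln(x_j/x_max)`` with ``x_max = sqrt(sum x_j^2)``,
  reported as ``E / (sqrt(n) ln sqrt(n))`` so a uniform ROI scores 1 and a
  one-hot ROI scores 0.  Motion (ghosting, blurring) spreads energy and
  raises entropy, so within a cohort unusually extreme values flag
  motion-corrupted scans.
* **SNR**: ROI mean over the standard deviation of an air mask.
* **CNR**: (ROI mean - comparison-region mean) over the air-mask standard
  deviation, the comparison region being a thin shell of surrounding tissue.

Cohort screening uses the mean +/- 2 SD rule; flagged scans are reported,
never removed automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io_formats import IntensityVolume, LabelVolume


@dataclass
class IQMRecord:
    """Quality metrics for one (structure, side)."""

    structure: str
    side: str
    efc: float
    snr: float
    cnr: float
    n_roi_voxels: int
    outlier_flags: dict[str, bool] | None = None


def efc(roi_intensities: np.ndarray) -> float:
    """Entropy focus criterion of a vector of non-negative intensities.

    Zero intensities contribute nothing (0 ln 0 := 0).  Scale-invariant;
    bounded in [0, 1] with 1 for a uniform ROI, 0 for a single bright voxel.
    """
    x = np.asarray(roi_intensities, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("EFC needs at least 2 voxels")
    if np.any(x < 0):
        raise ValueError("EFC expects non-negative intensities")
    x_max = np.sqrt(np.sum(x**2))
    if x_max == 0:
        raise ValueError("EFC undefined for all-zero input")
    p = x / x_max
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))
    n = x.size
    e_max = np.sqrt(n) * np.log(np.sqrt(n))
    return float(entropy / e_max)


def snr(
    intensity: IntensityVolume, roi: np.ndarray, background: np.ndarray
) -> float:
    """ROI mean / air-mask standard deviation (population SD)."""
    _check_masks(roi=roi, background=background)
    sigma = float(np.std(intensity.data[background]))
    if sigma == 0:
        raise ValueError("degenerate background: sigma = 0")
    return float(np.mean(intensity.data[roi]) / sigma)


def cnr(
    intensity: IntensityVolume,
    roi: np.ndarray,
    comparison: np.ndarray,
    background: np.ndarray,
) -> float:
    """(ROI mean - comparison mean) / air-mask standard deviation."""
    _check_masks(roi=roi, comparison=comparison, background=background)
    sigma = float(np.std(intensity.data[background]))
    if sigma == 0:
        raise ValueError("degenerate background: sigma = 0")
    mu_roi = float(np.mean(intensity.data[roi]))
    mu_comp = float(np.mean(intensity.data[comparison]))
    return (mu_roi - mu_comp) / sigma


def _check_masks(**masks: np.ndarray) -> None:
    items = list(masks.items())
    for name, m in items:
        if not m.any():
            raise ValueError(f"empty {name} mask")
    for i, (na, a) in enumerate(items):
        for nb, b in items[i + 1 :]:
            if np.any(a & b):
                raise ValueError(f"masks {na} and {nb} overlap")


def make_masks(
    labels: LabelVolume,
    structure: str,
    side: str,
    shell_width: int = 3,
    air_margin: int = 5,
    intensity: IntensityVolume | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROI, comparison-shell and air-background masks for one structure.

    * roi: the structure's voxels;
    * comparison: morphological dilation of the ROI by ``shell_width``
      voxels, minus the ROI and minus every labelled tissue, so surrounding
      unlabelled tissue only;
    * background: voxels within ``air_margin`` voxels of the volume faces;
      when an intensity image is supplied, restricted to intensities below
      an Otsu threshold computed over that margin (air is the dark class).
    """
    roi = labels.mask(structure, side)
    if not roi.any():
        raise ValueError(f"structure ({structure}, {side}) absent from labels")
    struct = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    dilated = ndimage.binary_dilation(roi, structure=struct, iterations=shell_width)
    comparison = dilated & ~roi & ~labels.any_label_mask()
    if not comparison.any():
        raise ValueError("empty comparison shell after excluding labelled tissue")

    face = np.zeros(labels.data.shape, dtype=bool)
    m = air_margin
    for axis in range(3):
        sl = [slice(None)] * 3
        sl[axis] = slice(0, m)
        face[tuple(sl)] = True
        sl[axis] = slice(-m, None)
        face[tuple(sl)] = True
    face &= ~labels.any_label_mask()
    if intensity is not None:
        background = face & _air_by_threshold(intensity.data, face)
    else:
        background = face
    background &= ~dilated
    if not background.any():
        raise ValueError("empty background mask")
    return roi, comparison, background


def _air_by_threshold(data: np.ndarray, face: np.ndarray) -> np.ndarray:
    """Dark-class (air) selection over the face margin.

    Otsu's threshold is only applied when it actually separates two classes
    (inter-class distance > 3x the pooled within-class SD); a margin that is
    pure air is unimodal noise, and thresholding it would truncate the
    distribution and bias the noise estimate low.
    """
    vals = data[face]
    if vals.max() <= vals.min():
        return np.ones(data.shape, dtype=bool)
    thr = threshold_otsu(vals)
    lo, hi = vals[vals < thr], vals[vals >= thr]
    if len(lo) < 2 or len(hi) < 2:
        return np.ones(data.shape, dtype=bool)
    pooled_sd = np.sqrt((lo.var() * len(lo) + hi.var() * len(hi)) / len(vals))
    if hi.mean() - lo.mean() <= 3.0 * pooled_sd:
        return np.ones(data.shape, dtype=bool)  # unimodal: all air
    return data < thr


def flag_outliers(values: np.ndarray) -> np.ndarray:
    """Mean +/- 2 SD screening over a cohort vector.

    Uses the population SD (ddof=0) and an inclusive threshold: with the
    sample SD the largest attainable deviation in a cohort of n is
    (n-1)/sqrt(n) SDs, so a single extreme scan among five could never be
    flagged.  Flagged scans are reported, never removed automatically.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("outlier screening needs at least 3 values")
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros(v.shape, dtype=bool)
    return np.abs(v - v.mean()) >= 2.0 * sd * (1.0 - 1e-12)


def qc_structure(
    intensity: IntensityVolume,
    labels: LabelVolume,
    structure: str,
    side: str,
    shell_width: int = 3,
    air_margin: int = 5,
) -> IQMRecord:
    """EFC/SNR/CNR for one structure; intensities are clipped at 0 for the
    EFC, which is defined on non-negative data."""
    intensity.check_paired(labels)
    roi, comparison, background = make_masks(
        labels, structure, side, shell_width, air_margin, intensity=intensity
    )
    roi_vals = np.clip(intensity.data[roi], 0.0, None)
    return IQMRecord(
        structure=structure,
        side=side,
        efc=efc(roi_vals),
        snr=snr(intensity, roi, background),
        cnr=cnr(intensity, roi, comparison, background),
        n_roi_voxels=int(roi.sum()),
    )
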