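"""Test-retest reliability via the intraclass correlation coefficient.

ICC(2,1) — two-way random effects, absolute agreement, single measures —
from the standard two-way ANOVA decomposition of an n-subject x k-session
matrix (McGraw & Wong's ICC(A,1)):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

where MSR, MSC, MSE are the subject, session and residual mean squares.
Absolute agreement charges systematic session offsets against reliability,
unlike the consistency form.  The significance test is F = MSR/MSE with
(n-1, (n-1)(k-1)) degrees of freedom.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_formats import SIDES
from .morphometrics import METRIC_NAMES


class ICCResult(NamedTuple):
    icc: float
    p_value: float
    n_subjects: int
    n_sessions: int


def icc_2_1(values: np.ndarray) -> ICCResult:
    """ICC(2,1) of a subjects x sessions matrix.

    Rows containing any missing value are dropped listwise (with a
    warning).  A matrix with zero variance everywhere has an undefined ICC,
    reported as NaN.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2D subjects x sessions matrix")
    keep = ~np.isnan(m).any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} subject rows with missing cells")
        m = m[keep]
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = m - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.allclose(m, grand):
        return ICCResult(float("nan"), float("nan"), n, k)
    icc = (msr - mse) / denom
    if mse == 0:
        p = 0.0
    else:
        f = msr / mse
        p = float(sstats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return ICCResult(float(icc), p, n, k)


def icc_consistency(values: np.ndarray) -> float:
    """ICC(C,1) (consistency form), for comparison: systematic session
    offsets are not penalised."""
    m = np.asarray(values, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    resid = m - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse))


#: Conventional interpretation bands for single-measure ICCs.
DEFAULT_BANDS: tuple[tuple[float, str], ...] = (
    (0.9, "excellent"),
    (0.75, "good"),
    (0.5, "moderate"),
    (-np.inf, "poor"),
)


def _band(icc: float, bands=DEFAULT_BANDS) -> str:
    if np.isnan(icc):
        return "undefined"
    for lo, name in bands:
        if icc >= lo:
            return name
    return "poor"


def replicability_report(
    session_a: pd.DataFrame,
    session_b: pd.DataFrame,
    bands=DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-(metric, side) ICC(2,1) across two measurement sessions.

    Inputs are long-format cohort tables with columns
    ``subject, metric, side, value``; subjects are matched by identifier.
    Returns up to 38 rows (19 metrics x 2 sides) with icc, p, n and a
    qualitative band; metrics with no usable paired data are NaN rows.
    """
    for name, df in (("session_a", session_a), ("session_b", session_b)):
        missing = {"subject", "metric", "side", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} lacks columns {sorted(missing)}")
    a = session_a.set_index(["metric", "side", "subject"])["value"]
    b = session_b.set_index(["metric", "side", "subject"])["value"]
    subjects = sorted(
        set(session_a["subject"].unique()) & set(session_b["subject"].unique())
    )
    if not subjects:
        raise ValueError("no matched subjects between sessions")

    rows = []
    for metric in METRIC_NAMES:
        for side in SIDES:
            pairs = []
            for subj in subjects:
                try:
                    pairs.append([a.loc[(metric, side, subj)], b.loc[(metric, side, subj)]])
                except KeyError:
                    continue
            mat = np.asarray(pairs, dtype=float)
            if len(mat) >= 2 and np.isfinite(mat).all(axis=1).sum() >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = icc_2_1(mat)
                rows.append(
                    {
                        "metric": metric,
                        "side": side,
                        "icc": res.icc,
                        "p_value": res.p_value,
                        "n_subjects": res.n_subjects,
                        "band": _band(res.icc, bands),
                    }
                )
            else:
                rows.append(
                    {
                        "metric": metric,
                        "side": side,
                        "icc": float("nan"),
                        "p_value": float("nan"),
                        "n_subjects": len(mat),
                        "band": "undefined",
                    }
                )
    return pd.DataFrame(rows)
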