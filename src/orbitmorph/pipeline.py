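"""Subject- and cohort-level orchestration.

``run_subject`` ties the modules together for one co-registered dataset
(labels + landmarks, optionally an intensity image): quality control,
the 38 metric values, and per-eye deformation maps, all written under an
output directory together with a machine-readable run log.  ``run_cohort``
stacks subjects, screens the quality metrics with the mean +/- 2 SD rule
and aggregates deformation maps into mean/variance maps.

Upstream template building and registration are performed with external
tooling; the expected hand-off per subject is a warped label volume and
warped landmarks on the subject grid.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deformation import DeformationMap, aggregate_maps, subject_deformation_map
from .io_formats import (
    SIDES,
    read_intensity_volume,
    read_label_volume,
    read_landmarks,
    write_metrics,
)
from .morphometrics import MetricsRecord, extract_all_metrics
from .qc import IQMRecord, flag_outliers, qc_structure

QC_STRUCTURES = ("globe", "optic_nerve")


@dataclass
class RunConfig:
    """Everything one subject run needs."""

    labels: str
    landmarks: str
    out_dir: str
    image: str | None = None
    subject: str = "subject"
    label_table: dict | None = None  # {"structure|side": code}
    grid_step: float = 0.1  # mm, cross-section sampling
    max_tilt: float = 30.0  # deg, optimal-plane search
    centerline_step: float = 1.0  # mm
    n_theta: int = 30
    n_phi: int = 72
    globe_width_mode: str = "landmarks"
    centres: str = "file"
    seed: int = 0

    def parsed_label_table(self) -> dict | None:
        if self.label_table is None:
            return None
        return {
            tuple(key.split("|")): int(code) for key, code in self.label_table.items()
        }


@dataclass
class SubjectResult:
    subject: str
    metrics: MetricsRecord
    qc: list[IQMRecord]
    deformation: dict[str, DeformationMap] = field(default_factory=dict)


def run_subject(cfg: RunConfig) -> SubjectResult:
    """Full single-subject run; outputs are deterministic given the config."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = read_label_volume(cfg.labels, cfg.parsed_label_table())
    landmarks = read_landmarks(cfg.landmarks)
    intensity = read_intensity_volume(cfg.image) if cfg.image else None

    qc_records: list[IQMRecord] = []
    if intensity is not None:
        for side in SIDES:
            for structure in QC_STRUCTURES:
                try:
                    qc_records.append(
                        qc_structure(intensity, labels, structure, side)
                    )
                except (ValueError, KeyError) as exc:
                    warnings.warn(f"QC failed for ({structure}, {side}): {exc}")

    metrics = extract_all_metrics(
        labels,
        landmarks,
        intensity=intensity,
        centerline_step=cfg.centerline_step,
        grid_step=cfg.grid_step,
        max_tilt=cfg.max_tilt,
        centres=cfg.centres,
    )

    deformation: dict[str, DeformationMap] = {}
    for side in SIDES:
        try:
            deformation[side] = subject_deformation_map(
                labels, landmarks, side, n_theta=cfg.n_theta, n_phi=cfg.n_phi
            )
        except (ValueError, KeyError) as exc:
            warnings.warn(f"deformation map failed ({side}): {exc}")

    write_metrics(metrics, out / "metrics.csv")
    _write_qc_csv(qc_records, out / "qc.csv")
    for side, dmap in deformation.items():
        dmap.to_csv(out / f"deformation_{side}.csv")
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "package_version": __version__,
                "config": dataclasses.asdict(cfg),
                "n_metric_values": len(metrics),
                "qc_rows": len(qc_records),
            },
            fh,
            indent=1,
        )
    return SubjectResult(cfg.subject, metrics, qc_records, deformation)


def _write_qc_csv(records: list[IQMRecord], path: Path) -> None:
    rows = [
        {
            "structure": r.structure,
            "side": r.side,
            "efc": r.efc,
            "snr": r.snr,
            "cnr": r.cnr,
            "n_roi_voxels": r.n_roi_voxels,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["structure", "side", "efc", "snr", "cnr", "n_roi_voxels"]
    ).to_csv(path, index=False)


@dataclass
class CohortResult:
    metrics: pd.DataFrame  # long format: subject, metric, side, value, units
    qc: pd.DataFrame  # per (subject, structure, side) with outlier flags
    mean_maps: dict[str, DeformationMap]
    variance_maps: dict[str, DeformationMap]
    failed_subjects: list[str]


def run_cohort(configs: list[RunConfig]) -> CohortResult:
    """Run every subject, then screen QC metrics (mean +/- 2 SD within each
    structure/side/metric group) and aggregate deformation maps.  Failed
    subjects are reported and skipped, never fatal."""
    if not configs:
        raise ValueError("empty cohort")
    results: list[SubjectResult] = []
    failed: list[str] = []
    for cfg in configs:
        try:
            results.append(run_subject(cfg))
        except Exception as exc:  # noqa: BLE001 - cohort runs must survive
            warnings.warn(f"subject {cfg.subject} failed: {exc}")
            failed.append(cfg.subject)

    metric_rows = []
    for res in sorted(results, key=lambda r: r.subject):
        for metric, side, value, units in res.metrics.to_rows():
            metric_rows.append(
                {
                    "subject": res.subject,
                    "metric": metric,
                    "side": side,
                    "value": value,
                    "units": units,
                }
            )
    metrics_df = pd.DataFrame(
        metric_rows, columns=["subject", "metric", "side", "value", "units"]
    )

    qc_rows = []
    for res in results:
        for r in res.qc:
            qc_rows.append(
                {
                    "subject": res.subject,
                    "structure": r.structure,
                    "side": r.side,
                    "efc": r.efc,
                    "snr": r.snr,
                    "cnr": r.cnr,
                }
            )
    qc_df = pd.DataFrame(
        qc_rows, columns=["subject", "structure", "side", "efc", "snr", "cnr"]
    ).sort_values(["structure", "side", "subject"], ignore_index=True)
    for col in ("efc", "snr", "cnr"):
        flag_col = np.zeros(len(qc_df), dtype=bool)
        if len(qc_df):
            for _, idx in qc_df.groupby(["structure", "side"]).groups.items():
                vals = qc_df.loc[idx, col].to_numpy()
                if len(vals) >= 3:
                    flag_col[qc_df.index.get_indexer(idx)] = flag_outliers(vals)
        qc_df[f"{col}_outlier"] = flag_col

    mean_maps: dict[str, DeformationMap] = {}
    var_maps: dict[str, DeformationMap] = {}
    for side in SIDES:
        maps = [r.deformation[side] for r in results if side in r.deformation]
        if maps:
            mean_maps[side], var_maps[side] = aggregate_maps(maps)

    return CohortResult(metrics_df, qc_df, mean_maps, var_maps, failed)
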