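"""Table I/O for count streams, labels, verdicts and reports.

All tables are plain comma-separated text with a mandatory header, UTF-8,
"." decimal separator — hand-editable at the scale of a surgical study.

Count-stream table, one row per 1 s bin::

    patient_id,district_id,sample_id,acquisition_id,role,t_seconds,counts

``sample_id`` is empty on background rows. Labels table::

    sample_id,pathology_label        # positive | negative | unknown
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .count_model import (
    Acquisition,
    Cohort,
    District,
    GA68_HALF_LIFE_S,
    Patient,
    Sample,
)
from .discrimination import SampleVerdict

__all__ = [
    "COUNT_COLUMNS",
    "ParseError",
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "apply_labels",
    "write_verdicts",
    "load_run_config",
    "write_report_json",
    "render_report",
    "plot_roc_family",
]

COUNT_COLUMNS = (
    "patient_id", "district_id", "sample_id", "acquisition_id",
    "role", "t_seconds", "counts",
)


class ParseError(ValueError):
    """Malformed input table; the message names the column/rows at fault."""


def write_counts(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as the one-row-per-bin count-stream table.

    Integer-valued counts are written without a decimal point so the table
    round-trips bit-exactly through :func:`read_counts`.
    """
    rows = []
    for patient in cohort.patients:
        for district in patient.districts:
            acqs = [(None, a) for a in district.background_acquisitions]
            acqs += [(s, a) for s in district.samples for a in s.measurements]
            for sample, acq in acqs:
                for i, c in enumerate(acq.counts):
                    rows.append({
                        "patient_id": patient.patient_id,
                        "district_id": district.district_id,
                        "sample_id": "" if sample is None else sample.sample_id,
                        "acquisition_id": acq.acquisition_id,
                        "role": acq.role,
                        "t_seconds": acq.start_time + i,
                        "counts": int(c) if float(c).is_integer() else float(c),
                    })
    pd.DataFrame(rows, columns=list(COUNT_COLUMNS)).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_counts(path: str | Path) -> Cohort:
    """Assemble a cohort from a count-stream table.

    Raw counts must be non-negative integers; rows claiming the measurement
    role without a sample id (or vice versa) are rejected with their line
    numbers. Pathology labels start ``unknown``; see :func:`apply_labels`.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str,
                                  "district_id": str, "acquisition_id": str},
                     keep_default_na=False, float_precision="round_trip")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    # +2: 1-based line numbers plus the header row
    counts_num = pd.to_numeric(df["counts"], errors="coerce")
    bad = df.index[counts_num.isna() | (counts_num < 0)
                   | (counts_num != counts_num.round())]
    if len(bad):
        raise ParseError(
            f"{path}: non-integer or negative counts on line(s) "
            f"{', '.join(str(i + 2) for i in bad[:10])}"
        )
    bad_role = df.index[~df["role"].isin(["background", "sample_measurement"])]
    if len(bad_role):
        raise ParseError(
            f"{path}: unknown role on line(s) "
            f"{', '.join(str(i + 2) for i in bad_role[:10])}"
        )
    orphan = df.index[(df["role"] == "sample_measurement") & (df["sample_id"] == "")]
    if len(orphan):
        raise ParseError(
            f"{path}: measurement rows without sample_id on line(s) "
            f"{', '.join(str(i + 2) for i in orphan[:10])}"
        )
    df["counts"] = counts_num
    df["t_seconds"] = pd.to_numeric(df["t_seconds"])

    patients: list[Patient] = []
    for patient_id, pdf in df.groupby("patient_id", sort=False):
        districts: list[District] = []
        for district_id, ddf in pdf.groupby("district_id", sort=False):
            backgrounds: list[Acquisition] = []
            samples: dict[str, list[Acquisition]] = {}
            for (role, sample_id, acq_id), adf in ddf.groupby(
                ["role", "sample_id", "acquisition_id"], sort=False
            ):
                adf = adf.sort_values("t_seconds")
                acq = Acquisition(
                    counts=adf["counts"].to_numpy(dtype=float),
                    start_time=float(adf["t_seconds"].iloc[0]),
                    role=role,
                    acquisition_id=str(acq_id),
                )
                if role == "background":
                    backgrounds.append(acq)
                else:
                    samples.setdefault(str(sample_id), []).append(acq)
            districts.append(District(
                district_id=str(district_id),
                background_acquisitions=tuple(
                    sorted(backgrounds, key=lambda a: a.start_time)
                ),
                samples=tuple(
                    Sample(sample_id=sid,
                           measurements=tuple(sorted(m, key=lambda a: a.start_time)))
                    for sid, m in samples.items()
                ),
            ))
        patients.append(Patient(
            patient_id=str(patient_id),
            injected_activity_MBq=float("nan"),
            districts=tuple(districts),
        ))
    return Cohort(patients=tuple(patients))


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("sample_id", "pathology_label"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column(s) {col}")
    bad = df.index[~df["pathology_label"].isin(["positive", "negative", "unknown"])]
    if len(bad):
        raise ParseError(
            f"{path}: invalid pathology_label on line(s) "
            f"{', '.join(str(i + 2) for i in bad[:10])}"
        )
    return dict(zip(df["sample_id"], df["pathology_label"]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "pathology_label": list(labels.values())}
    ).to_csv(path, index=False, encoding="utf-8")


def apply_labels(
    cohort: Cohort, labels: Mapping[str, str]
) -> tuple[Cohort, list[str]]:
    """Attach pathology labels to a cohort's samples.

    Returns the labelled cohort and a list of warnings: label-file entries
    with no matching sample, and samples left ``unknown`` for lack of a label.
    """
    warnings: list[str] = []
    known = {s.sample_id for s in cohort.samples()}
    for sid in labels:
        if sid not in known:
            warnings.append(f"label for unknown sample {sid!r} ignored")
    from dataclasses import replace

    patients = []
    for patient in cohort.patients:
        districts = []
        for district in patient.districts:
            new_samples = []
            for sample in district.samples:
                label = labels.get(sample.sample_id)
                if label is None:
                    warnings.append(
                        f"sample {sample.sample_id!r} has no label; left unknown"
                    )
                    label = "unknown"
                new_samples.append(sample.with_label(label))
            districts.append(replace(district, samples=tuple(new_samples)))
        patients.append(replace(patient, districts=tuple(districts)))
    return Cohort(patients=tuple(patients)), warnings


def write_verdicts(verdicts: Iterable[SampleVerdict], path: str | Path) -> None:
    pd.DataFrame([
        {
            "sample_id": v.sample_id,
            "probe_label": v.probe_label,
            "cutoff_cps": v.cutoff_cps,
            "frac_value": v.frac_value,
            "longest_run": v.longest_run,
            "triggered_by": v.triggered_by,
            "algorithm": v.algorithm,
        }
        for v in verdicts
    ]).to_csv(path, index=False, encoding="utf-8")


def load_run_config(path: str | Path) -> dict:
    """Read a YAML run configuration (half_life_s, reference_policy, grid)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    cfg.setdefault("half_life_s", GA68_HALF_LIFE_S)
    cfg.setdefault("reference_policy", "district_background")
    return cfg


def write_report_json(report_dict: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")


def render_report(report_dict: dict) -> str:
    """Human-readable summary of a pipeline report."""
    best = report_dict["best_config"]
    split = report_dict["split"]
    lines = [
        "Signal-to-background discrimination report",
        f"  seed: {report_dict['seed']}",
        f"  grid: {report_dict['grid']['n_configs']} configurations "
        f"({len(report_dict['grid']['n_sigma_values'])} N_sigma x "
        f"{len(report_dict['grid']['eps_frac_values'])} eps_frac x "
        f"{len(report_dict['grid']['eps_num_values'])} eps_num)",
        f"  split: {len(split['train_district_ids'])} train / "
        f"{len(split['test_district_ids'])} test districts "
        f"(train {split['train_pos']}+/{split['train_neg']}-, "
        f"test {split['test_pos']}+/{split['test_neg']}-)",
        f"  train AUC: median {report_dict['train_auc']['median']:.3f} "
        f"(IQR {report_dict['train_auc']['iqr'][0]:.3f}-"
        f"{report_dict['train_auc']['iqr'][1]:.3f})",
        f"  best config: N_sigma={best['n_sigma']:g}, "
        f"eps_frac={best['eps_frac']:g}, eps_num={best['eps_num']}",
        "",
        f"  {'dataset':<10}{'sens %':>8}{'spec %':>8}"
        f"{'TP':>5}{'TN':>5}{'FP':>5}{'FN':>5}",
    ]
    for name, c in report_dict["confusion"].items():
        sens = c.get("sensitivity_pct")
        spec = c.get("specificity_pct")
        sens_s = f"{sens:>8.1f}" if sens is not None else f"{'n/a':>8}"
        spec_s = f"{spec:>8.1f}" if spec is not None else f"{'n/a':>8}"
        lines.append(
            f"  {name:<10}{sens_s}{spec_s}"
            f"{c['tp']:>5}{c['tn']:>5}{c['fp']:>5}{c['fn']:>5}"
        )
    return "\n".join(lines)


def plot_roc_family(curves, path: str | Path, best=None) -> None:
    """Save a ROC-family figure (one line per (eps_frac, eps_num) pair)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for curve in curves:
        ax.plot(100.0 - curve.specificities, curve.sensitivities,
                marker="o", markersize=2, linewidth=0.8, alpha=0.6,
                label=f"f={curve.eps_frac:g}, n={curve.eps_num}")
    if best is not None:
        ax.plot(100.0 - best.specificity, best.sensitivity, "r*", markersize=14,
                label="best")
    ax.plot([0, 100], [0, 100], "k:", linewidth=0.8)
    ax.set_xlabel("100 - specificity (%)")
    ax.set_ylabel("sensitivity (%)")
    ax.legend(fontsize=5, ncol=2)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
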