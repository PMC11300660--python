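"""Grid-search optimization of the discrimination algorithm.

The three parameters (N_sigma, eps_frac, eps_num) are enumerated over a fixed
grid (504 configurations by default). For every (eps_frac, eps_num) pair a ROC
curve is traced by varying N_sigma, sensitivity and specificity being computed
against pathology labels. The operating point chosen is the one nearest, in
the (sensitivity, specificity) percent plane, to the ideal 100-100 corner.

Evaluation is honest out-of-sample: districts (not samples) are randomly
partitioned into train and test halves with similar numbers of diseased and
healthy samples, the grid search runs on the train half only, and the chosen
configuration is then scored on the held-out districts, on the whole cohort,
and against fixed-SBR comparators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .count_model import Cohort, District, correct_cohort, GA68_HALF_LIFE_S
from .discrimination import (
    AlgorithmConfig,
    classify_fixed_sbr,
    classify_sample,
    compute_cutoff,
    estimate_district_background,
    fraction_condition,
    run_condition,
)

__all__ = [
    "DEFAULT_N_SIGMA",
    "DEFAULT_EPS_FRAC",
    "DEFAULT_EPS_NUM",
    "GridSpec",
    "ConfusionCounts",
    "RocCurve",
    "SplitAssignment",
    "BestPoint",
    "PipelineReport",
    "UndefinedMetricError",
    "sensitivity_specificity",
    "enumerate_grid",
    "evaluate_config",
    "evaluate_fixed_sbr",
    "build_roc_family",
    "auc",
    "select_best",
    "district_split",
    "run_full_pipeline",
]

DEFAULT_N_SIGMA: tuple[float, ...] = (
    0.5, 1, 1.5, 2, 2.25, 2.5, 2.75, 3, 3.25, 3.5, 3.75, 4, 4.5, 5, 6, 8, 10, 30,
)
DEFAULT_EPS_FRAC: tuple[float, ...] = (0.05, 0.10, 0.20, 0.50)
DEFAULT_EPS_NUM: tuple[int, ...] = (2, 3, 4, 6, 8, 10, 20)


class UndefinedMetricError(ValueError):
    """Sensitivity or specificity requested on an empty stratum."""


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid for the discrimination algorithm."""

    n_sigma_values: tuple[float, ...] = DEFAULT_N_SIGMA
    eps_frac_values: tuple[float, ...] = DEFAULT_EPS_FRAC
    eps_num_values: tuple[int, ...] = DEFAULT_EPS_NUM

    def __post_init__(self) -> None:
        for name in ("n_sigma_values", "eps_frac_values", "eps_num_values"):
            vals = tuple(getattr(self, name))
            object.__setattr__(self, name, vals)
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def size(self) -> int:
        return (len(self.n_sigma_values) * len(self.eps_frac_values)
                * len(self.eps_num_values))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally of probe verdicts against pathology.

    ``n_unknown`` counts samples excluded for lack of a pathology label; it is
    not part of the 2x2 total.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    n_unknown: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn, self.n_unknown) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity and specificity in percent.

    sens = 100*TP/(TP+FN), spec = 100*TN/(TN+FP). An empty stratum (no
    positives, or no negatives) raises :class:`UndefinedMetricError` rather
    than silently returning NaN.
    """
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no pathology-positive samples: sensitivity undefined")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no pathology-negative samples: specificity undefined")
    return 100.0 * c.tp / (c.tp + c.fn), 100.0 * c.tn / (c.tn + c.fp)


def enumerate_grid(grid: GridSpec) -> list[AlgorithmConfig]:
    """Cartesian product of the grid, in deterministic order.

    n_sigma is the outer (slowest) axis, then eps_frac, then eps_num, so
    tie-breaks downstream are reproducible.
    """
    return [
        AlgorithmConfig(n_sigma=ns, eps_frac=ef, eps_num=en)
        for ns, ef, en in product(
            grid.n_sigma_values, grid.eps_frac_values, grid.eps_num_values
        )
    ]


def _tally(pred_positive: Iterable[bool], truth_positive: Iterable[bool],
           n_unknown: int = 0) -> ConfusionCounts:
    tp = tn = fp = fn = 0
    for pred, truth in zip(pred_positive, truth_positive):
        if truth:
            tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, n_unknown=n_unknown)


def evaluate_config(
    districts: Iterable[District], config: AlgorithmConfig
) -> ConfusionCounts:
    """Classify every labelled sample of the given districts under one config.

    Per district: flat background estimate, cutoff, per-sample verdict; tallied
    against pathology. Samples labelled ``unknown`` are excluded from the 2x2
    table and reported in ``n_unknown``. Districts must be decay-corrected.
    """
    preds: list[bool] = []
    truths: list[bool] = []
    n_unknown = 0
    for district in districts:
        est = estimate_district_background(district)
        for sample in district.samples:
            if sample.pathology_label == "unknown":
                n_unknown += 1
                continue
            verdict = classify_sample(sample, est, config)
            preds.append(verdict.probe_label == "positive")
            truths.append(sample.pathology_label == "positive")
    return _tally(preds, truths, n_unknown)


def evaluate_fixed_sbr(
    districts: Iterable[District], sbr_cutoff: float
) -> ConfusionCounts:
    """Confusion counts of the fixed-SBR comparator over labelled samples."""
    preds: list[bool] = []
    truths: list[bool] = []
    n_unknown = 0
    for district in districts:
        est = estimate_district_background(district)
        for sample in district.samples:
            if sample.pathology_label == "unknown":
                n_unknown += 1
                continue
            verdict = classify_fixed_sbr(sample, est, sbr_cutoff)
            preds.append(verdict.probe_label == "positive")
            truths.append(sample.pathology_label == "positive")
    return _tally(preds, truths, n_unknown)


@dataclass(frozen=True)
class RocCurve:
    """Sensitivity/specificity trace over N_sigma at fixed (eps_frac, eps_num).

    Points are ordered by increasing n_sigma; sensitivity must be
    non-increasing and specificity non-decreasing along the curve (raising the
    cutoff can only turn positives into negatives).
    """

    eps_frac: float
    eps_num: int
    points: tuple[tuple[float, float, float], ...]  # (n_sigma, sens %, spec %)
    auc: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(tuple(p) for p in self.points))
        if not self.points:
            raise ValueError("a ROC curve needs >= 1 point")
        tol = 1e-9
        for (n0, s0, p0), (n1, s1, p1) in zip(self.points, self.points[1:]):
            if n1 <= n0:
                raise ValueError("ROC points must be ordered by increasing n_sigma")
            if s1 > s0 + tol or p1 < p0 - tol:
                raise ValueError(
                    "ROC monotonicity violated: sensitivity must be "
                    "non-increasing and specificity non-decreasing in n_sigma"
                )
        if math.isnan(self.auc):
            object.__setattr__(self, "auc", auc(self))

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def specificities(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under sensitivity vs (100 - specificity), as fractions.

    Anchor points (0,0) and (1,1) are appended because the sampled N_sigma
    values need not span the full ROC range.
    """
    x = (100.0 - curve.specificities) / 100.0  # false-positive rate
    y = curve.sensitivities / 100.0
    x = np.concatenate(([0.0], x, [1.0]))
    y = np.concatenate(([0.0], y, [1.0]))
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def _sample_condition_stats(
    districts: Sequence[District], n_sigma_values: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per labelled sample and per n_sigma: max fraction and max run length.

    Because a sample is positive when ANY measurement satisfies EITHER
    condition, the maxima over measurements are sufficient statistics: the
    sample is positive under (n_sigma, eps_frac, eps_num) iff
    max_frac >= eps_frac or max_run >= eps_num. This lets the 504-config grid
    reuse one pass over the count streams per n_sigma value.
    """
    max_frac_rows: list[list[float]] = []
    max_run_rows: list[list[int]] = []
    truth: list[bool] = []
    for district in districts:
        est = estimate_district_background(district)
        cutoffs = [compute_cutoff(est, ns) for ns in n_sigma_values]
        for sample in district.samples:
            if sample.pathology_label == "unknown":
                continue
            fr_row: list[float] = []
            run_row: list[int] = []
            for cutoff in cutoffs:
                mf = 0.0
                mr = 0
                for acq in sample.measurements:
                    _, frac = fraction_condition(acq.counts, cutoff, 1.0)
                    _, run = run_condition(acq.counts, cutoff, 1)
                    mf = max(mf, frac)
                    mr = max(mr, run)
                fr_row.append(mf)
                run_row.append(mr)
            max_frac_rows.append(fr_row)
            max_run_rows.append(run_row)
            truth.append(sample.pathology_label == "positive")
    return (
        np.asarray(max_frac_rows, dtype=float),
        np.asarray(max_run_rows, dtype=int),
        np.asarray(truth, dtype=bool),
    )


def build_roc_family(
    districts: Sequence[District] | Cohort, grid: GridSpec | None = None
) -> list[RocCurve]:
    """One ROC curve per (eps_frac, eps_num) pair, one point per N_sigma.

    With the default grid this yields 28 curves of 18 points each. Metric
    errors on degenerate label strata propagate with curve context.
    """
    if isinstance(districts, Cohort):
        districts = list(districts.districts())
    grid = grid or GridSpec()
    max_frac, max_run, truth = _sample_condition_stats(
        districts, grid.n_sigma_values
    )
    if truth.size == 0:
        raise UndefinedMetricError("no labelled samples to build ROC curves from")
    curves: list[RocCurve] = []
    for ef, en in product(grid.eps_frac_values, grid.eps_num_values):
        points: list[tuple[float, float, float]] = []
        for j, ns in enumerate(grid.n_sigma_values):
            pred = (max_frac[:, j] >= ef) | (max_run[:, j] >= en)
            counts = _tally(pred, truth)
            try:
                sens, spec = sensitivity_specificity(counts)
            except UndefinedMetricError as exc:
                raise UndefinedMetricError(
                    f"curve eps_frac={ef}, eps_num={en}, n_sigma={ns}: {exc}"
                ) from exc
            points.append((float(ns), sens, spec))
        curves.append(RocCurve(eps_frac=ef, eps_num=en, points=tuple(points)))
    return curves


@dataclass(frozen=True)
class BestPoint:
    config: AlgorithmConfig
    sensitivity: float
    specificity: float
    distance: float


def select_best(roc_family: Sequence[RocCurve]) -> BestPoint:
    """Operating point nearest to the ideal (100, 100) corner.

    Distance is Euclidean in the (sensitivity, specificity) percent plane.
    Ties prefer higher specificity (a false positive costs an unnecessary
    resection). Residual ties — typically a plateau of N_sigma values with
    identical empirical performance on a small training set — are resolved by
    the N_sigma nearest the median of the tied values: the centre of the
    plateau keeps the largest margin against both noise-driven false
    positives (low N_sigma) and lesion-missing false negatives (high
    N_sigma). Any remainder falls back to the deterministic grid order.
    """
    if not roc_family:
        raise ValueError("empty ROC family")
    candidates: list[BestPoint] = []
    for curve in roc_family:
        for ns, sens, spec in curve.points:
            candidates.append(BestPoint(
                config=AlgorithmConfig(n_sigma=ns, eps_frac=curve.eps_frac,
                                       eps_num=curve.eps_num),
                sensitivity=sens,
                specificity=spec,
                distance=math.hypot(100.0 - sens, 100.0 - spec),
            ))
    best_key = min((c.distance, -c.specificity) for c in candidates)
    tied = [c for c in candidates
            if (c.distance, -c.specificity) == best_key]
    ns_median = float(np.median([c.config.n_sigma for c in tied]))
    return min(
        tied,
        key=lambda c: (abs(c.config.n_sigma - ns_median), c.config.n_sigma,
                       c.config.eps_frac, c.config.eps_num),
    )


@dataclass(frozen=True)
class SplitAssignment:
    """District-level train/test partition with its class balance."""

    train_district_ids: tuple[str, ...]
    test_district_ids: tuple[str, ...]
    train_pos: int
    train_neg: int
    test_pos: int
    test_neg: int
    seed: int

    @property
    def imbalance(self) -> int:
        return abs(self.train_pos - self.test_pos) + abs(self.train_neg - self.test_neg)


def _district_class_counts(district: District) -> tuple[int, int]:
    pos = sum(1 for s in district.samples if s.pathology_label == "positive")
    neg = sum(1 for s in district.samples if s.pathology_label == "negative")
    return pos, neg


def district_split(
    cohort: Cohort, seed: int, n_candidates: int = 1000
) -> SplitAssignment:
    """Random district-level partition balancing diseased/healthy samples.

    Districts (never individual samples) are assigned to train or test, so no
    background estimate is shared across the split. ``n_candidates`` random
    partitions are drawn and the one minimizing
    ``|train_pos - test_pos| + |train_neg - test_neg|`` is kept, with
    ``|train_n - test_n|`` (total samples) as tie-break. Deterministic given
    the seed.
    """
    districts = list(cohort.districts())
    if len(districts) < 2:
        raise ValueError("cannot split a cohort with fewer than 2 districts")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    class_counts = np.array([_district_class_counts(d) for d in districts])
    totals = class_counts.sum(axis=1)
    best_key: tuple[int, int] | None = None
    best_mask: np.ndarray | None = None
    for _ in range(n_candidates):
        mask = rng.random(len(districts)) < 0.5
        if mask.all() or not mask.any():
            continue
        train = class_counts[mask].sum(axis=0)
        test = class_counts[~mask].sum(axis=0)
        imbalance = int(abs(train[0] - test[0]) + abs(train[1] - test[1]))
        size_gap = int(abs(totals[mask].sum() - totals[~mask].sum()))
        key = (imbalance, size_gap)
        if best_key is None or key < best_key:
            best_key, best_mask = key, mask
    if best_mask is None:
        raise ValueError("no valid partition drawn; increase n_candidates")
    train_ids = tuple(d.district_id for d, m in zip(districts, best_mask) if m)
    test_ids = tuple(d.district_id for d, m in zip(districts, best_mask) if not m)
    train = class_counts[best_mask].sum(axis=0)
    test = class_counts[~best_mask].sum(axis=0)
    return SplitAssignment(
        train_district_ids=train_ids,
        test_district_ids=test_ids,
        train_pos=int(train[0]), train_neg=int(train[1]),
        test_pos=int(test[0]), test_neg=int(test[1]),
        seed=seed,
    )


def _confusion_dict(c: ConfusionCounts) -> dict:
    out = {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
           "n_unknown": c.n_unknown}
    try:
        sens, spec = sensitivity_specificity(c)
        out["sensitivity_pct"] = round(sens, 6)
        out["specificity_pct"] = round(spec, 6)
    except UndefinedMetricError:
        pass
    return out


@dataclass(frozen=True)
class PipelineReport:
    """Full train/test evaluation of the discrimination algorithm."""

    seed: int
    grid: GridSpec
    split: SplitAssignment
    best: BestPoint
    auc_median: float
    auc_iqr: tuple[float, float]
    train_counts: ConfusionCounts
    test_counts: ConfusionCounts
    full_counts: ConfusionCounts
    sbr_counts: dict[float, ConfusionCounts]

    def to_dict(self) -> dict:
        def metrics(c: ConfusionCounts) -> dict:
            return _confusion_dict(c)

        return {
            "seed": self.seed,
            "grid": {
                "n_sigma_values": list(self.grid.n_sigma_values),
                "eps_frac_values": list(self.grid.eps_frac_values),
                "eps_num_values": list(self.grid.eps_num_values),
                "n_configs": self.grid.size,
            },
            "split": {
                "train_district_ids": list(self.split.train_district_ids),
                "test_district_ids": list(self.split.test_district_ids),
                "train_pos": self.split.train_pos,
                "train_neg": self.split.train_neg,
                "test_pos": self.split.test_pos,
                "test_neg": self.split.test_neg,
            },
            "best_config": {
                "n_sigma": self.best.config.n_sigma,
                "eps_frac": self.best.config.eps_frac,
                "eps_num": self.best.config.eps_num,
                "train_sensitivity_pct": round(self.best.sensitivity, 6),
                "train_specificity_pct": round(self.best.specificity, 6),
            },
            "train_auc": {
                "median": round(self.auc_median, 6),
                "iqr": [round(self.auc_iqr[0], 6), round(self.auc_iqr[1], 6)],
            },
            "confusion": {
                "train": metrics(self.train_counts),
                "test": metrics(self.test_counts),
                "full": metrics(self.full_counts),
                **{f"sbr{c:g}": metrics(cc) for c, cc in self.sbr_counts.items()},
            },
        }


def run_full_pipeline(
    cohort: Cohort,
    grid: GridSpec | None = None,
    seed: int = 0,
    half_life_s: float = GA68_HALF_LIFE_S,
    reference_policy: str = "district_background",
    sbr_cutoffs: Sequence[float] = (1.5, 2.0),
    n_candidates: int = 1000,
    decay_correct: bool = True,
) -> PipelineReport:
    """End-to-end evaluation on a labelled cohort.

    Decay-corrects the cohort, splits districts into balanced train/test
    halves, builds the ROC family on the train half, selects the best operating
    point, and scores it on the test half, on the whole cohort, and against the
    fixed-SBR comparators. Fully deterministic given the seed.
    """
    grid = grid or GridSpec()
    if decay_correct:
        cohort = correct_cohort(cohort, half_life_s, reference_policy)
    split = district_split(cohort, seed=seed, n_candidates=n_candidates)
    by_id = {d.district_id: d for d in cohort.districts()}
    train = [by_id[i] for i in split.train_district_ids]
    test = [by_id[i] for i in split.test_district_ids]

    family = build_roc_family(train, grid)
    best = select_best(family)
    aucs = np.array([c.auc for c in family])

    return PipelineReport(
        seed=seed,
        grid=grid,
        split=split,
        best=best,
        auc_median=float(np.median(aucs)),
        auc_iqr=(float(np.percentile(aucs, 25)), float(np.percentile(aucs, 75))),
        train_counts=evaluate_config(train, best.config),
        test_counts=evaluate_config(test, best.config),
        full_counts=evaluate_config(list(cohort.districts()), best.config),
        sbr_counts={
            float(c): evaluate_fixed_sbr(list(cohort.districts()), c)
            for c in sbr_cutoffs
        },
    )
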