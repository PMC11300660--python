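"""Signal-to-background discrimination of probe count streams.

The cutoff is referenced to the district background, whose counts are modelled
as a flat (uniform) distribution spanning the observed min-max range:

    <R_bkg> = (R_max + R_min) / 2,     sigma_flat = (R_max - R_min) / sqrt(12),
    R_cutoff = <R_bkg> + N_sigma * sigma_flat.

A measurement flags its sample Probe-Positive when either detection condition
holds:

* fraction condition - at least a fraction ``eps_frac`` of its 1 s counts lie
  strictly above the cutoff;
* run condition - the longest contiguous run of counts strictly above the
  cutoff has length >= ``eps_num``.

The two conditions capture different lesion topologies: a hot node held
briefly (high fraction, short stream) and a sustained dwell over a lesion
(long run inside a longer sweep). ``classify_fixed_sbr`` implements the
conventional comparator, a fixed signal-to-background ratio threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .count_model import District, Sample

__all__ = [
    "BackgroundEstimate",
    "AlgorithmConfig",
    "SampleVerdict",
    "InsufficientBackgroundError",
    "UndefinedSBRError",
    "estimate_background",
    "estimate_district_background",
    "compute_cutoff",
    "fraction_condition",
    "run_condition",
    "longest_true_run",
    "classify_sample",
    "classify_fixed_sbr",
]

SQRT12 = math.sqrt(12.0)


class InsufficientBackgroundError(ValueError):
    """Background stream too short to estimate a flat distribution."""


class UndefinedSBRError(ZeroDivisionError):
    """Signal-to-background ratio requested against a zero-mean background."""


@dataclass(frozen=True)
class BackgroundEstimate:
    """Flat-distribution summary of a district's background stream."""

    r_max: float
    r_min: float
    mean_flat: float
    sigma_flat: float
    n_counts: int

    def __post_init__(self) -> None:
        if not (self.r_min <= self.mean_flat <= self.r_max):
            raise ValueError("mean_flat must lie within [r_min, r_max]")
        if self.sigma_flat < 0:
            raise ValueError("sigma_flat must be >= 0")


@dataclass(frozen=True)
class AlgorithmConfig:
    """The three tunable parameters of the statistical discrimination algorithm.

    ``n_sigma`` sets the cutoff height in background sigmas, ``eps_frac`` the
    minimum fraction of counts above cutoff, ``eps_num`` the minimum contiguous
    run length above cutoff.
    """

    n_sigma: float
    eps_frac: float
    eps_num: int

    def __post_init__(self) -> None:
        if self.n_sigma < 0:
            raise ValueError("n_sigma must be >= 0")
        if not (0 < self.eps_frac <= 1):
            raise ValueError("eps_frac must be in (0, 1]")
        if int(self.eps_num) != self.eps_num or self.eps_num < 1:
            raise ValueError("eps_num must be a positive integer")


@dataclass(frozen=True)
class SampleVerdict:
    """Per-sample classification outcome.

    ``frac_value`` and ``longest_run`` are the maxima over the sample's
    measurements; ``triggered_by`` records which condition(s) fired anywhere.
    """

    sample_id: str
    probe_label: str  # "positive" | "negative"
    cutoff_cps: float
    frac_value: float
    longest_run: int
    triggered_by: str  # "frac" | "run" | "both" | "none"
    algorithm: str = "statistical"

    def __post_init__(self) -> None:
        positive = self.triggered_by != "none"
        if positive != (self.probe_label == "positive"):
            raise ValueError("probe_label inconsistent with triggered_by")


def estimate_background(bkg_counts: Sequence[float] | np.ndarray) -> BackgroundEstimate:
    """Flat-distribution estimate from a (decay-corrected) background stream."""
    arr = np.asarray(bkg_counts, dtype=float)
    if arr.size < 2:
        raise InsufficientBackgroundError(
            f"need >= 2 background counts, got {arr.size}"
        )
    r_max = float(arr.max())
    r_min = float(arr.min())
    return BackgroundEstimate(
        r_max=r_max,
        r_min=r_min,
        mean_flat=(r_max + r_min) / 2.0,
        sigma_flat=(r_max - r_min) / SQRT12,
        n_counts=int(arr.size),
    )


def estimate_district_background(district: District) -> BackgroundEstimate:
    """Single estimate per district: all background acquisitions concatenated."""
    if not district.background_acquisitions:
        raise InsufficientBackgroundError(
            f"district {district.district_id!r} has no background acquisition"
        )
    return estimate_background(district.background_counts)


def compute_cutoff(est: BackgroundEstimate, n_sigma: float) -> float:
    """Cutoff rate in CPS: flat mean plus ``n_sigma`` flat sigmas."""
    return est.mean_flat + n_sigma * est.sigma_flat


def fraction_condition(
    counts: np.ndarray, cutoff: float, eps_frac: float
) -> tuple[bool, float]:
    """Fraction of counts strictly above the cutoff, tested against eps_frac (>=)."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty count stream")
    frac = float(np.count_nonzero(arr > cutoff)) / arr.size
    return frac >= eps_frac, frac


def longest_true_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values in a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max())


def run_condition(
    counts: np.ndarray, cutoff: float, eps_num: int
) -> tuple[bool, int]:
    """Longest contiguous run strictly above the cutoff, tested against eps_num (>=).

    Runs are computed within a single acquisition; callers must not concatenate
    acquisitions, which are temporally disjoint probe placements.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty count stream")
    run = longest_true_run(arr > cutoff)
    return run >= eps_num, run


def classify_sample(
    sample: Sample, est: BackgroundEstimate, config: AlgorithmConfig
) -> SampleVerdict:
    """Rate a sample Probe-Positive/Negative under the statistical algorithm.

    Each measurement is evaluated independently against the district cutoff;
    the sample is positive as soon as any measurement satisfies the fraction
    OR the run condition. Measurements are never bridged: a run cannot span
    two probe placements.
    """
    cutoff = compute_cutoff(est, config.n_sigma)
    frac_hit = run_hit = False
    max_frac = 0.0
    max_run = 0
    for acq in sample.measurements:
        f_ok, frac = fraction_condition(acq.counts, cutoff, config.eps_frac)
        r_ok, run = run_condition(acq.counts, cutoff, config.eps_num)
        frac_hit |= f_ok
        run_hit |= r_ok
        max_frac = max(max_frac, frac)
        max_run = max(max_run, run)
    triggered = {
        (True, True): "both",
        (True, False): "frac",
        (False, True): "run",
        (False, False): "none",
    }[(frac_hit, run_hit)]
    return SampleVerdict(
        sample_id=sample.sample_id,
        probe_label="positive" if triggered != "none" else "negative",
        cutoff_cps=cutoff,
        frac_value=max_frac,
        longest_run=max_run,
        triggered_by=triggered,
    )


def classify_fixed_sbr(
    sample: Sample, est: BackgroundEstimate, sbr_cutoff: float
) -> SampleVerdict:
    """Conventional fixed signal-to-background-ratio comparator.

    Per measurement, SBR = mean measurement rate / flat background mean; the
    sample is positive when any measurement reaches ``sbr_cutoff`` (boundary
    inclusive). The verdict reuses the frac/run slots to report the best SBR
    (as ``frac_value``) for table output.
    """
    if est.mean_flat == 0:
        raise UndefinedSBRError(
            "background mean is zero; signal-to-background ratio undefined"
        )
    best_sbr = max(acq.mean_rate / est.mean_flat for acq in sample.measurements)
    positive = best_sbr >= sbr_cutoff
    return SampleVerdict(
        sample_id=sample.sample_id,
        probe_label="positive" if positive else "negative",
        cutoff_cps=sbr_cutoff * est.mean_flat,
        frac_value=best_sbr,
        longest_run=0,
        triggered_by="frac" if positive else "none",
        algorithm=f"sbr{sbr_cutoff:g}",
    )
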