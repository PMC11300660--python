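"""Synthetic cohorts with the statistical structure of an intraoperative study.

Counting statistics make the emission model Poisson by physics: each 1 s bin
of an acquisition is an independent Poisson draw whose mean is the district
background rate, multiplied by a lesion-specific uplift (tumor samples) or a
near-unity jitter (healthy samples), and attenuated by exponential tracer
decay across the procedure.

The default parameters mirror the structure of a first-in-human prostate
cancer series: 7 patients, about 25 districts and 66 lymph-node samples, 47%
pathology-positive, background acquisitions of 5-10 s, measurements of 5-20 s,
all within a 20-152 min post-injection window with the Ga-68 half-life. True
clinical distributions of background rates and lesion uplift are not
published; the defaults here (log-normal background around 100 CPS, uniform
1.2-5x uplift) are order-of-magnitude placeholders chosen to exercise the
analysis, not calibrated clinical values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .count_model import (
    Acquisition,
    Cohort,
    District,
    GA68_HALF_LIFE_S,
    Patient,
    Sample,
)

__all__ = ["CohortParams", "generate_cohort", "make_separable_cohort"]


@dataclass(frozen=True)
class CohortParams:
    """Knobs of the synthetic cohort generator.

    Durations are in seconds, rates in CPS. ``lesion_uplift`` and
    ``healthy_jitter`` are multiplicative factors applied to the district
    background rate; ``gamma_floor_cps`` is an optional additive rate shared
    by all acquisitions of a district (a crude shine-through stand-in for
    robustness tests, off by default).
    """

    n_patients: int = 7
    districts_per_patient: tuple[int, int] = (3, 4)  # min, max (uniform)
    mean_extra_samples_per_district: float = 1.64  # samples = 1 + Poisson(mean)
    prevalence: float = 0.47
    background_rate_median_cps: float = 100.0
    background_rate_log_sigma: float = 0.4
    lesion_uplift: tuple[float, float] = (1.2, 5.0)  # uniform range
    healthy_jitter_log_sigma: float = 0.05
    background_duration_s: tuple[int, int] = (5, 10)
    measurement_duration_s: tuple[int, int] = (5, 20)
    repeat_measurement_prob: float = 0.2
    time_after_injection_window_s: tuple[float, float] = (20 * 60.0, 152 * 60.0)
    half_life_s: float = GA68_HALF_LIFE_S
    decay: bool = True
    gamma_floor_cps: float = 0.0
    injected_activity_MBq: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if self.background_rate_median_cps <= 0:
            raise ValueError("background rate must be > 0")
        if self.lesion_uplift[0] <= 0 or self.lesion_uplift[1] < self.lesion_uplift[0]:
            raise ValueError("lesion_uplift must be a positive (low, high) range")
        if self.background_duration_s[0] < 1 or self.measurement_duration_s[0] < 1:
            raise ValueError("durations must be >= 1 s")
        if self.half_life_s <= 0:
            raise ValueError("half_life_s must be > 0")
        if self.gamma_floor_cps < 0:
            raise ValueError("gamma_floor_cps must be >= 0")


def _poisson_stream(
    rng: np.random.Generator,
    rate_cps: float,
    start_time: float,
    duration_s: int,
    half_life_s: float,
    decay: bool,
) -> np.ndarray:
    t = start_time + np.arange(duration_s, dtype=float)
    mean = np.full(duration_s, rate_cps)
    if decay:
        mean = mean * 2.0 ** (-t / half_life_s)
    return rng.poisson(mean).astype(float)


def generate_cohort(params: CohortParams) -> tuple[Cohort, pd.DataFrame]:
    """Draw a full cohort plus its ground-truth table, reproducible from seed.

    Districts are independent. Within a district, the background acquisition
    comes first, then the sample measurements follow sequentially with short
    gaps; all acquisitions inherit the district's background rate (times the
    per-sample multiplier and the decay factor at each bin).

    Returns the cohort (with pathology labels already attached) and a truth
    table with one row per sample: ids, label, the multiplier actually drawn,
    and the district background rate.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.time_after_injection_window_s
    truth_rows: list[dict] = []
    patients: list[Patient] = []
    district_counter = 0
    sample_counter = 0
    for p_idx in range(params.n_patients):
        patient_id = f"P{p_idx + 1:02d}"
        n_districts = int(rng.integers(params.districts_per_patient[0],
                                       params.districts_per_patient[1] + 1))
        districts: list[District] = []
        for _ in range(n_districts):
            district_counter += 1
            district_id = f"D{district_counter:03d}"
            bkg_rate = params.background_rate_median_cps * float(
                np.exp(rng.normal(0.0, params.background_rate_log_sigma))
            )
            t_cursor = float(rng.uniform(lo, hi))
            bkg_dur = int(rng.integers(params.background_duration_s[0],
                                       params.background_duration_s[1] + 1))
            bkg = Acquisition(
                counts=_poisson_stream(
                    rng, bkg_rate + params.gamma_floor_cps, t_cursor, bkg_dur,
                    params.half_life_s, params.decay,
                ),
                start_time=t_cursor,
                role="background",
                acquisition_id=f"{district_id}-bkg",
            )
            t_cursor += bkg_dur + float(rng.integers(2, 6))
            n_samples = 1 + int(rng.poisson(params.mean_extra_samples_per_district))
            samples: list[Sample] = []
            for _ in range(n_samples):
                sample_counter += 1
                sample_id = f"S{sample_counter:03d}"
                is_tumor = bool(rng.random() < params.prevalence)
                if is_tumor:
                    mult = float(rng.uniform(*params.lesion_uplift))
                else:
                    mult = float(np.exp(rng.normal(0.0, params.healthy_jitter_log_sigma)))
                n_meas = 1 + int(rng.random() < params.repeat_measurement_prob)
                measurements: list[Acquisition] = []
                for m_idx in range(n_meas):
                    dur = int(rng.integers(params.measurement_duration_s[0],
                                           params.measurement_duration_s[1] + 1))
                    measurements.append(Acquisition(
                        counts=_poisson_stream(
                            rng, bkg_rate * mult + params.gamma_floor_cps,
                            t_cursor, dur, params.half_life_s, params.decay,
                        ),
                        start_time=t_cursor,
                        role="sample_measurement",
                        acquisition_id=f"{sample_id}-m{m_idx + 1}",
                    ))
                    t_cursor += dur + float(rng.integers(2, 6))
                samples.append(Sample(
                    sample_id=sample_id,
                    measurements=tuple(measurements),
                    pathology_label="positive" if is_tumor else "negative",
                ))
                truth_rows.append({
                    "patient_id": patient_id,
                    "district_id": district_id,
                    "sample_id": sample_id,
                    "pathology_label": "positive" if is_tumor else "negative",
                    "rate_multiplier": mult,
                    "background_rate_cps": bkg_rate,
                })
            districts.append(District(
                district_id=district_id,
                background_acquisitions=(bkg,),
                samples=tuple(samples),
            ))
        patients.append(Patient(
            patient_id=patient_id,
            injected_activity_MBq=params.injected_activity_MBq,
            districts=tuple(districts),
        ))
    return Cohort(patients=tuple(patients)), pd.DataFrame(truth_rows)


def make_separable_cohort(
    params: CohortParams | None = None,
    masked_tumor_ids: Sequence[str] = (),
) -> Cohort:
    """Deterministic, perfectly separable cohort for end-to-end checks.

    The cohort copies the structural draw of :func:`generate_cohort` (same
    patient/district/sample layout and labels for the same seed) but replaces
    every count stream with noise-free values on a common scale:

    * background: a 12 s ramp cycling over 95..105 CPS, so every district has
      flat mean 100 and flat sigma 10/sqrt(12) ~ 2.89;
    * tumor measurements: constant 200 CPS, more than 10 flat sigmas above the
      cutoff for every grid N_sigma (including 30);
    * healthy measurements: constant 95 CPS, strictly below the flat mean.

    Decay is disabled. ``masked_tumor_ids`` forces the named tumor samples
    down to the healthy level, producing exactly that many false negatives
    under any discriminating cutoff.
    """
    params = params or CohortParams()
    structure, _ = generate_cohort(params)
    masked = set(masked_tumor_ids)
    bkg_counts = 95.0 + np.arange(12) % 11

    def flat_acq(acq: Acquisition, level: float, duration: int) -> Acquisition:
        return Acquisition(
            counts=np.full(duration, level),
            start_time=acq.start_time,
            role=acq.role,
            acquisition_id=acq.acquisition_id,
        )

    patients = []
    for patient in structure.patients:
        districts = []
        for district in patient.districts:
            bkg = district.background_acquisitions[0]
            new_bkg = Acquisition(
                counts=bkg_counts.copy(),
                start_time=bkg.start_time,
                role="background",
                acquisition_id=bkg.acquisition_id,
            )
            samples = []
            for sample in district.samples:
                tumor = sample.pathology_label == "positive"
                level = 95.0 if (not tumor or sample.sample_id in masked) else 200.0
                samples.append(Sample(
                    sample_id=sample.sample_id,
                    measurements=tuple(
                        flat_acq(m, level, 20) for m in sample.measurements
                    ),
                    pathology_label=sample.pathology_label,
                ))
            districts.append(District(
                district_id=district.district_id,
                background_acquisitions=(new_bkg,),
                samples=tuple(samples),
            ))
        patients.append(Patient(
            patient_id=patient.patient_id,
            injected_activity_MBq=patient.injected_activity_MBq,
            districts=tuple(districts),
        ))
    return Cohort(patients=tuple(patients))
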