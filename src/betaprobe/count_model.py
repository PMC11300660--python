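"""Domain model for intraoperative probe count streams.

The probe emits one reading per 1 s exposure (counts per second, CPS).
Readings are grouped into *acquisitions* (a contiguous series with a single
probe placement), acquisitions into *samples* (lymph nodes, the unit of
classification), samples into *districts* (surgical regions sharing one
background definition, the unit over which a single cutoff applies), and
districts into *patients*.

Because the tracer isotope decays on the timescale of a procedure, counts
acquired at different times are not directly comparable; :func:`decay_correct`
rescales every 1 s bin to a common reference time so that one background
estimate and cutoff serve a whole district.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "GA68_HALF_LIFE_S",
    "MIN_BACKGROUND_DURATION_S",
    "Acquisition",
    "Sample",
    "District",
    "Patient",
    "Cohort",
    "DecayModel",
    "ValidationReport",
    "InvalidDecayModelError",
    "decay_correct",
    "correct_district",
    "correct_cohort",
    "validate_cohort",
]

#: Physical half-life of Ga-68 (67.71 min), the standard nuclear-data value.
GA68_HALF_LIFE_S: float = 67.71 * 60.0

#: Background acquisitions shorter than this draw a validation warning: the
#: surgical protocol asks for at least 5-10 s of background contact.
MIN_BACKGROUND_DURATION_S: int = 5

Role = Literal["background", "sample_measurement"]
PathologyLabel = Literal["positive", "negative", "unknown"]


class InvalidDecayModelError(ValueError):
    """Raised for a decay model with a non-positive half-life."""


@dataclass(frozen=True, eq=False)
class Acquisition:
    """One contiguous series of per-second probe counts.

    Parameters
    ----------
    counts
        Counts per 1 s bin. Non-negative; integer-valued as read from the
        probe, real-valued after decay correction.
    start_time
        Seconds since tracer injection of the first bin.
    role
        ``"background"`` or ``"sample_measurement"``.
    acquisition_id
        Optional identifier, used by the table I/O.
    """

    counts: np.ndarray
    start_time: float
    role: Role
    acquisition_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("an acquisition needs a 1-D stream of >= 1 counts")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite and >= 0")
        if self.role not in ("background", "sample_measurement"):
            raise ValueError(f"unknown acquisition role {self.role!r}")
        arr.flags.writeable = False
        object.__setattr__(self, "counts", arr)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Acquisition):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.start_time == other.start_time
            and self.role == other.role
            and self.acquisition_id == other.acquisition_id
        )

    __hash__ = None  # type: ignore[assignment]

    @property
    def duration_s(self) -> int:
        return int(self.counts.size)

    @property
    def times(self) -> np.ndarray:
        """Absolute time (s since injection) of each 1 s bin."""
        return self.start_time + np.arange(self.counts.size, dtype=float)

    @property
    def mean_rate(self) -> float:
        return float(self.counts.mean())


@dataclass(frozen=True)
class Sample:
    """A lymph node: >= 1 measurement acquisitions plus a pathology label."""

    sample_id: str
    measurements: tuple[Acquisition, ...]
    pathology_label: PathologyLabel = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if not self.measurements:
            raise ValueError(f"sample {self.sample_id!r} has no measurements")
        if self.pathology_label not in ("positive", "negative", "unknown"):
            raise ValueError(f"bad pathology label {self.pathology_label!r}")
        for acq in self.measurements:
            if acq.role != "sample_measurement":
                raise ValueError(
                    f"sample {self.sample_id!r} holds a non-measurement acquisition"
                )

    def with_label(self, label: PathologyLabel) -> "Sample":
        return replace(self, pathology_label=label)


@dataclass(frozen=True)
class District:
    """A surgical region sharing one background definition."""

    district_id: str
    background_acquisitions: tuple[Acquisition, ...]
    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "background_acquisitions", tuple(self.background_acquisitions)
        )
        object.__setattr__(self, "samples", tuple(self.samples))
        for acq in self.background_acquisitions:
            if acq.role != "background":
                raise ValueError(
                    f"district {self.district_id!r} holds a non-background "
                    "acquisition among its backgrounds"
                )

    @property
    def background_counts(self) -> np.ndarray:
        """All background bins of the district, concatenated in time order."""
        acqs = sorted(self.background_acquisitions, key=lambda a: a.start_time)
        return np.concatenate([a.counts for a in acqs])

    @property
    def background_start_time(self) -> float:
        if not self.background_acquisitions:
            raise ValueError(f"district {self.district_id!r} has no background")
        return min(a.start_time for a in self.background_acquisitions)


@dataclass(frozen=True)
class Patient:
    patient_id: str
    injected_activity_MBq: float
    districts: tuple[District, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "districts", tuple(self.districts))


@dataclass(frozen=True)
class Cohort:
    """All patients of a study; district ids are globally unique."""

    patients: tuple[Patient, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))

    def districts(self) -> Iterator[District]:
        for patient in self.patients:
            yield from patient.districts

    def samples(self) -> Iterator[Sample]:
        for district in self.districts():
            yield from district.samples

    def n_samples(self) -> int:
        return sum(1 for _ in self.samples())

    def n_districts(self) -> int:
        return sum(1 for _ in self.districts())

    def labels(self) -> dict[str, PathologyLabel]:
        return {s.sample_id: s.pathology_label for s in self.samples()}


@dataclass(frozen=True)
class DecayModel:
    """Exponential decay correction towards a reference time.

    A count ``c`` observed at ``t`` seconds after injection is rescaled to
    ``c * 2**((t - reference_time_s) / half_life_s)``: counts observed later
    than the reference are inflated to undo the physical decay.
    """

    half_life_s: float = GA68_HALF_LIFE_S
    reference_time_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.half_life_s > 0):
            raise InvalidDecayModelError(
                f"half-life must be positive, got {self.half_life_s}"
            )

    def factor(self, t: np.ndarray | float) -> np.ndarray | float:
        return 2.0 ** ((np.asarray(t, dtype=float) - self.reference_time_s)
                       / self.half_life_s)


def decay_correct(acq: Acquisition, model: DecayModel) -> Acquisition:
    """Rescale each 1 s bin to the model's reference time.

    Role and start time are preserved; corrected counts are real-valued.
    """
    corrected = acq.counts * model.factor(acq.times)
    return replace(acq, counts=corrected)


def _district_reference_time(
    district: District, policy: str
) -> float:
    if policy == "district_background":
        return district.background_start_time
    if policy == "injection":
        return 0.0
    raise ValueError(f"unknown reference-time policy {policy!r}")


def correct_district(
    district: District,
    half_life_s: float = GA68_HALF_LIFE_S,
    reference_policy: str = "district_background",
) -> District:
    """Decay-correct every acquisition of a district onto one rate scale.

    The default reference is the start of the district's first background
    acquisition, so the cutoff and the sample rates live on the same scale;
    ``"injection"`` references everything to t = 0 instead.
    """
    model = DecayModel(
        half_life_s=half_life_s,
        reference_time_s=_district_reference_time(district, reference_policy),
    )
    return replace(
        district,
        background_acquisitions=tuple(
            decay_correct(a, model) for a in district.background_acquisitions
        ),
        samples=tuple(
            replace(s, measurements=tuple(decay_correct(a, model)
                                          for a in s.measurements))
            for s in district.samples
        ),
    )


def correct_cohort(
    cohort: Cohort,
    half_life_s: float = GA68_HALF_LIFE_S,
    reference_policy: str = "district_background",
) -> Cohort:
    """Apply :func:`correct_district` to every district of a cohort."""
    return replace(
        cohort,
        patients=tuple(
            replace(
                p,
                districts=tuple(
                    correct_district(d, half_life_s, reference_policy)
                    for d in p.districts
                ),
            )
            for p in cohort.patients
        ),
    )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_cohort`: errors block analysis, warnings don't."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check structural invariants of a cohort without mutating it.

    Errors: districts without background acquisitions, duplicate district or
    sample ids, negative counts. Warnings: background acquisitions shorter
    than the 5 s protocol minimum, degenerate (constant) backgrounds.
    """
    report = ValidationReport()
    seen_districts: set[str] = set()
    for district in cohort.districts():
        did = district.district_id
        if did in seen_districts:
            report.errors.append(f"duplicate district id {did!r}")
        seen_districts.add(did)
        if not district.background_acquisitions:
            report.errors.append(f"district {did!r} has no background acquisition")
        for acq in district.background_acquisitions:
            if acq.duration_s < MIN_BACKGROUND_DURATION_S:
                report.warnings.append(
                    f"district {did!r}: background acquisition of "
                    f"{acq.duration_s} s is below the {MIN_BACKGROUND_DURATION_S} s "
                    "protocol minimum"
                )
        if district.background_acquisitions:
            bkg = district.background_counts
            if bkg.size >= 2 and bkg.max() == bkg.min():
                report.warnings.append(
                    f"district {did!r}: degenerate background (all counts equal); "
                    "the flat-distribution sigma is 0 and the cutoff ignores N_sigma"
                )
        seen_samples: set[str] = set()
        for sample in district.samples:
            if sample.sample_id in seen_samples:
                report.errors.append(
                    f"duplicate sample id {sample.sample_id!r} in district {did!r}"
                )
            seen_samples.add(sample.sample_id)
            for acq in sample.measurements:
                if np.any(acq.counts < 0):
                    report.errors.append(
                        f"sample {sample.sample_id!r}: negative counts"
                    )
    return report
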