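import numpy as np
import pytest
from hypothesis import settings

from betaprobe.count_model import Acquisition, Cohort, District, Patient, Sample
from betaprobe.synthetic import CohortParams, generate_cohort, make_separable_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def measurement(values, start=100.0, acq_id="m1"):
    return Acquisition(
        counts=np.asarray(values, dtype=float),
        start_time=start,
        role="sample_measurement",
        acquisition_id=acq_id,
    )


def background(values, start=0.0, acq_id="bkg"):
    return Acquisition(
        counts=np.asarray(values, dtype=float),
        start_time=start,
        role="background",
        acquisition_id=acq_id,
    )


@pytest.fixture
def toy_district():
    """10-sample district with a known background and hand-designed streams.

    Background spans 90..110 -> flat mean 100, flat sigma 20/sqrt(12) ~ 5.77.
    """
    bkg = background([90, 95, 100, 105, 110, 100, 98, 102])
    streams = {
        # sample_id: (counts, pathology)
        "T1": ([200] * 10, "positive"),          # far above any cutoff
        "T2": ([150] * 12, "positive"),          # above moderate cutoffs
        "T3": ([100] * 5 + [140] * 5, "positive"),
        "T4": ([95] * 10, "positive"),           # tumor at background: miss
        "T5": ([90, 130, 90, 130, 90, 130], "positive"),  # alternating
        "H1": ([95] * 10, "negative"),
        "H2": ([100] * 8, "negative"),
        "H3": ([105] * 10, "negative"),          # just under 1-sigma cutoff?
        "H4": ([90] * 15, "negative"),
        "H5": ([130] * 10, "negative"),          # hot healthy node: false pos
    }
    samples = tuple(
        Sample(sample_id=sid, measurements=(measurement(vals, acq_id=f"{sid}-m1"),),
               pathology_label=label)
        for sid, (vals, label) in streams.items()
    )
    return District(district_id="D1", background_acquisitions=(bkg,),
                    samples=samples)


@pytest.fixture
def toy_cohort(toy_district):
    return Cohort(patients=(Patient("P1", 100.0, (toy_district,)),))


@pytest.fixture
def default_cohort():
    cohort, truth = generate_cohort(CohortParams(seed=11))
    return cohort


@pytest.fixture
def separable_cohort():
    return make_separable_cohort(CohortParams(seed=5))
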