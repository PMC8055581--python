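import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from adipometry import AthleteRecord, Cohort  # noqa: E402


def make_record(record_id="a1", sex="F", **overrides):
    """A complete, physiologically plausible record for one athlete."""
    base = dict(
        id=record_id,
        sex=sex,
        age=14.8,
        body_mass=50.9,
        stature=160.5,
        sitting_height=84.0,
        skinfolds={
            "triceps": 14.0,
            "biceps": 7.0,
            "subscapular": 10.0,
            "suprailiac": 12.0,
            "supraspinale": 8.0,
            "abdominal": 14.0,
            "front_thigh": 22.0,
            "medial_calf": 12.0,
        },
        girths={
            "head": 54.0,
            "relaxed_arm": 25.0,
            "forearm": 22.5,
            "thigh": 50.0,
            "calf": 33.5,
            "chest": 80.0,
            "waist": 66.0,
        },
        breadths={
            "biacromial": 35.0,
            "biiliocristal": 27.0,
            "humerus": 6.0,
            "femur": 8.9,
            "ap_chest": 16.0,
            "transverse_chest": 24.5,
        },
        dexa_fp=27.3,
    )
    base.update(overrides)
    return AthleteRecord(**base)


@pytest.fixture
def complete_record():
    return make_record()


@pytest.fixture
def small_cohort():
    return Cohort(
        records=tuple(
            make_record(f"a{i}", sex=s, dexa_fp=fp)
            for i, (s, fp) in enumerate(
                [("F", 27.3), ("F", 24.1), ("M", 19.2), ("M", 16.8), ("F", 30.6), ("M", 22.0)]
            )
        ),
        provenance="fixture",
    )


def icc_anova_oracle(criterion, predicted):
    """Independent brute-force ICC(A,1) from the explicit ANOVA table.

    Written with plain loops over the subjects x methods cells so it shares
    no code path with the package implementation.
    """
    y = np.column_stack([np.asarray(criterion, float), np.asarray(predicted, float)])
    n, k = y.shape
    grand = y.mean()
    ssr = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum(
        (y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
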