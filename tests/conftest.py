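import numpy as np
import pytest

from phantomech import BilinearTruth, StressStrainCurve, SyntheticSpec


@pytest.fixture
def four_point_curve():
    return StressStrainCurve(
        strain=[0.0, 0.1, 0.2, 0.3],
        stress=[0.0, 2.0, 6.0, 14.0],
        material="ECOFLEX-0010",
        dilution_pct=5.0,
        replicate_id="r1",
    )


@pytest.fixture
def linear_heel_truth():
    return BilinearTruth(E1=20.0, E2=500.0, heel_start=0.20, heel_end=0.40,
                         heel="linear")


@pytest.fixture
def bilinear_spec(linear_heel_truth):
    return SyntheticSpec(
        kind="bilinear",
        truth=linear_heel_truth,
        noise_rel=0.0,
        noise_abs=0.0,
        truth_jitter=0.0,
        n_replicates=3,
        seed=7,
    )


def piecewise_linear(x, slopes, psi):
    """Continuous piecewise-linear ground truth through the origin."""
    x = np.asarray(x, dtype=float)
    y = slopes[0] * x
    for k, p in enumerate(psi):
        y = y + (slopes[k + 1] - slopes[k]) * np.clip(x - p, 0.0, None)
    return y


@pytest.fixture
def four_segment_data():
    x = np.linspace(0.0, 0.7, 200)
    psi = np.array([0.20, 0.35, 0.60])
    slopes = np.array([20.0, 150.0, 500.0, 800.0])
    return x, piecewise_linear(x, slopes, psi), psi, slopes
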