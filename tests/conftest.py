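import numpy as np
import pytest

from itseg import NoiseParams, ScenarioSpec, SegmentedMeanParams, simulate_dataset


def make_spec(
    N=1,
    n=100,
    tau=50,
    beta0=10.0,
    beta1=0.05,
    delta=0.0,
    Delta=0.0,
    phi1=0.3,
    phi2=0.3,
    s2_1=1.0,
    s2_2=1.0,
    structure="ar1",
    seed=0,
    start=None,
    **kw,
):
    """One-line scenario builder with identical parameters across units."""
    if structure == "independent":
        phi1 = phi2 = 0.0
    mean = SegmentedMeanParams(beta0, beta1, delta, Delta)
    noise = NoiseParams(structure, phi1, phi2, s2_1, s2_2)
    return ScenarioSpec(
        N=N,
        n=n,
        tau=tau,
        mean_params=(mean,) * N,
        noise_params=(noise,) * N,
        seed=seed,
        start=start,
        **kw,
    )


@pytest.fixture
def ar1_dataset():
    """Small AR(1) panel with a clear level change at tau=50."""
    spec = make_spec(N=3, delta=3.0, Delta=-0.03, phi1=0.3, phi2=0.5, s2_2=0.8, seed=42)
    return simulate_dataset(spec), spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
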