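import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,  # stateless factory fixtures
    ],
)
settings.load_profile("ci")


@pytest.fixture
def make_curve():
    """Factory for hand-built ThT curves."""
    from tauseed import ThTCurve

    def _make(times, fluor, well_id="A1", sample_id="s1", dilution=0.1):
        return ThTCurve(
            well_id=well_id,
            sample_id=sample_id,
            dilution=dilution,
            times_h=np.asarray(times, float),
            fluorescence_au=np.asarray(fluor, float),
        )

    return _make


@pytest.fixture
def logistic_curve(make_curve):
    """Noise-free logistic curve sampled on the 15-min grid out to 60 h."""
    from tauseed.synthetic import AggregationKineticsParams, simulate_tht_curve

    def _make(f0=100.0, amplitude=2000.0, rate_k=0.6, t_half=20.0,
              read_interval_h=0.25, duration_h=60.0, noise_sd=0.0, rng_seed=0):
        params = AggregationKineticsParams(
            f0=f0, amplitude=amplitude, rate_k=rate_k, t_half=t_half,
            noise_sd=noise_sd, read_interval_h=read_interval_h,
            duration_h=duration_h, rng_seed=rng_seed,
        )
        return simulate_tht_curve(params)

    return _make
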