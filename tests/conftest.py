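import numpy as np
import pytest

from opsinkit import (
    ExtractConfig,
    FeatureSet,
    SynthConfig,
    extract_features,
    fixture,
    generate_clamp_traces,
    generate_two_pulse_series,
    recovery_time,
)


@pytest.fixture(scope="session")
def rsrs_final():
    return fixture("rsrs_final")


@pytest.fixture(scope="session")
def mm_final():
    return fixture("mm_final")


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free synthetic study at the default grid: traces, truth, recovery."""
    cfg = SynthConfig(noise_sigma_rel=0.0)
    traces, truth = generate_clamp_traces(cfg)
    two_pulse = generate_two_pulse_series(cfg)
    return cfg, traces, truth, two_pulse


@pytest.fixture(scope="session")
def noiseless_features(noiseless_dataset):
    """Stage-1 output: features extracted from the noise-free traces."""
    _, traces, _, two_pulse = noiseless_dataset
    fs = FeatureSet()
    ec = ExtractConfig(n_starts=10, seed=0)
    for (I, V), tr in traces.items():
        try:
            f = extract_features(tr, tr.protocol, ec)
        except Exception:
            continue
        for name, val in f.items():
            if val is not None:
                fs.add(I, V, name, val)
    for (I, V), (intervals, ratios) in two_pulse.items():
        fs.add(I, V, "tau_recov", recovery_time(intervals, ratios))
    return fs


def random_params_in_bounds(rng):
    """A well-conditioned random draw inside the published search box."""
    from opsinkit import OpsinParams

    sgn = lambda: rng.choice([-1.0, 1.0])
    return OpsinParams(
        g=1.0,
        E=0.0,
        tauO_I=(rng.uniform(-3, 3), rng.uniform(0.3, 5), rng.uniform(0.005, 0.5)),
        tauO_V=(rng.uniform(0.1, 50), rng.uniform(-80, 80), sgn() * rng.uniform(5, 200)),
        tauR_I=(rng.uniform(0.5, 10), rng.uniform(0, 1),
                rng.uniform(-3, 3), rng.uniform(0.1, 5),
                rng.uniform(-3, 3), rng.uniform(0.1, 5)),
        tauR_V=(rng.uniform(1, 100), rng.uniform(-80, 80), sgn() * rng.uniform(5, 200)),
        Oinf=(rng.uniform(1, 4), rng.uniform(0.3, 3)),
        Rinf=(rng.uniform(1, 4), rng.uniform(0.3, 3), rng.uniform(0, 1)),
        Grect=(rng.uniform(0.5, 20), rng.uniform(1.1, 10), rng.uniform(20, 200)),
        combine_O=rng.choice(["product", "reciprocal_sum"]),
        combine_R=rng.choice(["product", "reciprocal_sum"]),
    )
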