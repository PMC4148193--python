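import numpy as np
import pytest

import insulator_bridge as ib


@pytest.fixture(scope="session")
def fcs_run():
    """One 50 s Brownian-dynamics FCS measurement of a single species.

    Shared between the diffusion-time round trip and the amplitude
    invariant so the (expensive) simulation runs once per session.
    """
    cfg = ib.FccsSimConfig(
        seed=7,
        n_molecules=30,
        bridged_fraction=0.0,
        mix_fraction_green=1.0,
        label_eff_green=1.0,
        duration=50.0,
    )
    trace = ib.simulate_intensity_traces(cfg)
    curve = ib.correlate_traces(trace.green, trace.green, dt=cfg.dt,
                                channel_pair="green_auto")
    fit = ib.fit_acf(curve)
    return cfg, trace, curve, fit


def make_cosine_trace(n=10_000, p1=1700, p2=2900, phase=0.7):
    """Deterministic band-limited trace for correlator oracle checks."""
    k = np.arange(n)
    return (100.0
            + 5.0 * np.cos(2 * np.pi * k / p1)
            + 3.0 * np.cos(2 * np.pi * k / p2 + phase))


def direct_correlation(a, b, k):
    """Brute-force correlation estimate at a single integer lag."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0 = a[: a.size - k] if k else a
    bk = b[k:]
    return (a0 * bk).mean() / (a0.mean() * bk.mean()) - 1.0
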