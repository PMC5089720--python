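import numpy as np
import pytest

import clamptrace as ct


@pytest.fixture(scope="session")
def matched_constants():
    """Steele constants that make the single-pool simulator exact."""
    return ct.KineticConstants(p=1.0, V=2.2)


@pytest.fixture(scope="session")
def noise_free_lean():
    """One noise-free lean-conscious clamp with ground truth."""
    cfg = ct.preset_config("lean_conscious", cv_G=0.0, cv_I=0.0,
                           tracer_count_sd=0.0, seed=1)
    rec, truth = ct.simulate_clamp(cfg)
    return cfg, rec, truth


def constant_record(n=13, G=100.0, Gstar=4000.0, I=50.0, GINF=0.0,
                    Fstar=20000.0, SA_inf=0.0, insulin_start=60.0):
    """A perfectly steady clamp record (all series constant)."""
    t = np.arange(n) * 10.0
    return ct.ClampRecord(
        time=t,
        G=np.full(n, G),
        Gstar=np.full(n, Gstar),
        I=np.full(n, I),
        GINF=np.full(n, GINF),
        Fstar=np.full(n, Fstar),
        SA_inf=SA_inf,
        weight=28.5,
        insulin_rate=1.0,
        insulin_start=insulin_start,
    )
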