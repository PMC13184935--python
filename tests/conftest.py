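import numpy as np
import pytest

from washkin import KineticParams, Protocol, Trace


@pytest.fixture
def scenario2_params() -> KineticParams:
    """Fast-rebinding regime: k_a*P_t = 10 >> k_lw = 1."""
    return KineticParams(k_a=10.0, k_minus_a=1.0, k_lw=1.0, k_wl=1.0, P_t=1.0)


@pytest.fixture
def scenario1_params() -> KineticParams:
    """Fast membrane exit: k_lw = 100 >> k_a*P_t = 0.1."""
    return KineticParams(k_a=0.1, k_minus_a=0.5, k_lw=100.0, k_wl=100.0, P_t=1.0)


def make_exp_trace(
    tau: float = 12.0,
    amplitude: float = 2.0,
    offset: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = 100.0,
    baseline_s: float = 5.0,
    drug_s: float = 5.0,
    washout_s: float = 80.0,
) -> Trace:
    """Trace whose washout is an exact single exponential (plus optional noise)."""
    n_b, n_d, n_w = (round(s * fs) for s in (baseline_s, drug_s, washout_s))
    t_w = np.arange(n_w) / fs
    current = np.concatenate(
        [
            np.full(n_b, offset),
            np.full(n_d, offset + amplitude),
            offset + amplitude * np.exp(-t_w / tau),
        ]
    )
    if noise_sd > 0:
        current = current + np.random.default_rng(seed).normal(
            0.0, noise_sd, current.size
        )
    segment = np.concatenate(
        [
            np.full(n_b, "baseline", dtype="U8"),
            np.full(n_d, "drug", dtype="U8"),
            np.full(n_w, "washout", dtype="U8"),
        ]
    )
    times = np.arange(current.size) / fs
    return Trace(times, current, segment, meta={"tau": tau})
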