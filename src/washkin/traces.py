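"""Synthetic inside-out patch-clamp traces for potentiator washout protocols.

A trace mimics the experimental protocol: PKA/ATP-activated baseline current,
drug application to a potentiated steady state, then washout with drug-free
solution.  Current is a linear readout of protein-site occupancy,

    I(t) = I_baseline * (1 + (fold - 1) * bound(t)),

plus additive white Gaussian noise; the recording chain's anti-alias filter
can optionally be approximated by a two-pass moving average.  Packaged
analog presets carry the measured fold-potentiation values (ABBV-974 and its
isobutyl analog 2.94, hexyl 1.74, decyl 2.52) and membrane-exit rates ordered
by chain length through the R-group logP scaling law.

Time is in seconds; currents are in arbitrary units (absolute patch currents
are not modelled); the default sampling rate is 500 Hz.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    KineticParams,
    OccupancyTrajectory,
    clamped_water_trajectory,
    scenario2_tau,
)
from .lipophilicity import klw_ratio

__all__ = [
    "Protocol",
    "AnalogPreset",
    "Trace",
    "PRESETS",
    "ANALOG_ORDER",
    "occupancy_to_current",
    "simulate_loading",
    "generate_trace",
    "default_protocol",
    "klw_from_logp",
]

SEGMENTS = ("baseline", "drug", "washout")


@dataclass(frozen=True)
class Protocol:
    """Timing and bath composition of the three-segment recording protocol."""

    sample_rate: float = 500.0
    baseline_s: float = 10.0
    drug_s: float = 30.0
    washout_s: float = 60.0
    bath_conc: float = 250.0

    def __post_init__(self) -> None:
        for name in ("sample_rate", "baseline_s", "drug_s", "washout_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.bath_conc < 0:
            raise ValueError("bath_conc must be >= 0")


@dataclass(frozen=True)
class AnalogPreset:
    """Per-analog fold-potentiation, kinetics and R-group lipophilicity."""

    name: str
    fold_potentiation: float
    kinetics: KineticParams
    rgroup_logP: float

    def __post_init__(self) -> None:
        if self.fold_potentiation < 1:
            raise ValueError("fold_potentiation must be >= 1")


# Kinetic constants shared across analogs: protein-ligand affinity is taken to
# be R-group independent, so only the membrane exit rate k_lw varies.
_SHARED = dict(k_a=10.0, k_minus_a=1.0, k_wl=1.0, P_t=1.0)

#: Anchor for the logP -> k_lw map: the isobutyl R group (logP ~2) exits the
#: membrane at 1/s.  Fragment-estimate logP defaults rise ~0.5 per CH2.
REFERENCE_LOGP = 2.0
REFERENCE_KLW = 1.0


def klw_from_logp(
    logP: float, ref_logp: float = REFERENCE_LOGP, ref_klw: float = REFERENCE_KLW
) -> float:
    """Membrane exit rate from R-group logP via the square-root-of-P scaling."""
    return ref_klw * klw_ratio(logP, ref_logp)


def _preset(name: str, fold: float, logp: float) -> AnalogPreset:
    return AnalogPreset(
        name=name,
        fold_potentiation=fold,
        kinetics=KineticParams(k_lw=klw_from_logp(logp), **_SHARED),
        rgroup_logP=logp,
    )


#: Packaged analog presets.  Fold values are the measured potentiations
#: (mean over patches); the NBD-labelled analog washes out on the same time
#: scale as the parent compound and shares its preset kinetics.
PRESETS: dict[str, AnalogPreset] = {
    "ABBV-974": _preset("ABBV-974", 2.94, 2.0),
    "CFTRi-C3": _preset("CFTRi-C3", 2.94, 2.0),
    "CFTRi-C6": _preset("CFTRi-C6", 1.74, 3.0),
    "CFTRi-C10": _preset("CFTRi-C10", 2.52, 5.0),
    "CFTRi-NBD": _preset("CFTRi-NBD", 2.94, 2.0),
}

#: Alkyl-chain ordering used by monotonicity checks.
ANALOG_ORDER = ("CFTRi-C3", "CFTRi-C6", "CFTRi-C10")


@dataclass
class Trace:
    """A sampled current record with per-sample protocol segment labels."""

    times: np.ndarray
    current: np.ndarray
    segment: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.segment = np.asarray(self.segment, dtype="U8")
        if not (self.times.shape == self.current.shape == self.segment.shape):
            raise ValueError("times, current, segment must have equal shapes")
        labels = [s for s in SEGMENTS if np.any(self.segment == s)]
        order = [self.segment.tolist().index(s) for s in labels]
        if order != sorted(order) or set(np.unique(self.segment)) - set(SEGMENTS):
            raise ValueError("segment labels must be contiguous and in protocol order")

    def segment_indices(self, name: str) -> np.ndarray:
        idx = np.nonzero(self.segment == name)[0]
        if idx.size == 0:
            raise ValueError(f"trace has no {name!r} segment")
        return idx

    def segment_duration(self, name: str) -> float:
        idx = self.segment_indices(name)
        dt = self.times[1] - self.times[0]
        return float(idx.size * dt)

    def to_csv(self, path) -> None:
        """Write the trace as CSV with a JSON metadata sidecar."""
        pd.DataFrame(
            {"time_s": self.times, "current": self.current, "segment": self.segment}
        ).to_csv(path, index=False)
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        meta = {}
        try:
            with open(f"{path}.meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(
            df["time_s"].to_numpy(),
            df["current"].to_numpy(),
            df["segment"].to_numpy(dtype="U8"),
            meta=meta,
        )


def occupancy_to_current(bound, baseline_current: float, fold: float):
    """Linear potentiation map ``I = I0 * (1 + (fold - 1) * bound)``."""
    bound = np.asarray(bound, dtype=float)
    if np.any(bound < 0) or np.any(bound > 1):
        raise ValueError("bound must lie in [0, 1]")
    if fold < 1:
        raise ValueError(f"fold must be >= 1, got {fold}")
    return baseline_current * (1.0 + (fold - 1.0) * bound)


def simulate_loading(
    params: KineticParams,
    bath_conc: float,
    times: np.ndarray,
    b0: float = 0.0,
    m0: float = 0.0,
) -> OccupancyTrajectory:
    """Drug-application phase: full kinetics with the bath clamped at ``bath_conc``.

    Occupancy rises monotonically to its steady state; the steady-state
    membrane concentration is ``bath_conc * k_wl / k_lw`` (binding flux
    vanishes at equilibrium, so protein buffering does not shift it).
    """
    if bath_conc < 0:
        raise ValueError("bath_conc must be >= 0")
    if params.k_wl == 0 and bath_conc > 0:
        warnings.warn(
            "k_wl is zero: drug never enters the membrane and occupancy stays "
            "at its initial value",
            stacklevel=2,
        )
    return clamped_water_trajectory(params, bath_conc, b0, m0, times)


def default_protocol(
    preset: AnalogPreset,
    *,
    sample_rate: float = 500.0,
    baseline_s: float = 10.0,
    bath_conc: float = 250.0,
    full_washout: bool = True,
) -> Protocol:
    """Protocol with durations adapted to the preset's kinetics.

    The drug phase lasts 12 membrane-exchange time constants (the loading
    bottleneck is membrane entry at rate ``k_lw``), which saturates the
    protein pool to well under 0.1%.  With ``full_washout`` the washout
    segment covers the reservoir-drain plateau plus six fast-rebinding decay
    constants, long enough for a 5%-window exponential fit; otherwise a short
    10 s washout is appended (enough for potentiation-only protocols).
    """
    k = preset.kinetics
    if k.k_lw <= 0:
        raise ValueError("preset k_lw must be > 0 to build a default protocol")
    drug_s = math.ceil(12.0 / k.k_lw)
    if full_washout:
        m_star = bath_conc * k.k_wl / k.k_lw
        plateau = math.log(max(m_star / k.K_d, 2.0)) / k.k_lw
        washout_s = math.ceil(plateau + 6.0 * scenario2_tau(k))
    else:
        washout_s = 10.0
    return Protocol(
        sample_rate=sample_rate,
        baseline_s=baseline_s,
        drug_s=float(drug_s),
        washout_s=float(washout_s),
        bath_conc=bath_conc,
    )


def _lowpass(x: np.ndarray, width: int) -> np.ndarray:
    """Two-pass centered moving average (crude stand-in for a Bessel filter)."""
    kernel = np.ones(width) / width
    pad = width  # reflect-pad to avoid edge droop
    xp = np.pad(x, pad, mode="reflect")
    for _ in range(2):
        xp = np.convolve(xp, kernel, mode="same")
    return xp[pad:-pad]


def generate_trace(
    preset: AnalogPreset,
    protocol: Protocol,
    noise_sd: float = 0.05,
    seed: int = 0,
    baseline_current: float = 1.0,
    lowpass_hz: float | None = None,
) -> Trace:
    """Simulate one baseline/drug/washout recording for an analog preset.

    ``noise_sd`` is the Gaussian noise standard deviation relative to the
    baseline current.  One integer seed governs the whole trace; each segment
    draws from its own deterministically derived substream, so identical
    seeds give bit-identical traces.  ``lowpass_hz`` optionally applies a
    two-pass moving-average filter with the given cutoff (off by default; the
    filter is irrelevant for time constants much larger than 10 ms).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fs = protocol.sample_rate
    n_base = round(protocol.baseline_s * fs)
    n_drug = round(protocol.drug_s * fs)
    n_wash = round(protocol.washout_s * fs)
    if min(n_base, n_drug, n_wash) < 2:
        raise ValueError("each protocol segment must span at least two samples")
    k = preset.kinetics

    # drug phase: integrate loading on the segment grid plus the exact segment
    # end point, which seeds the washout initial condition
    t_drug = np.arange(n_drug) / fs
    t_drug_full = np.append(t_drug, protocol.drug_s)
    loading = simulate_loading(k, protocol.bath_conc, t_drug_full)
    b_end, m_end = loading.bound[-1], loading.membrane[-1]

    t_wash = np.arange(n_wash) / fs
    washout = clamped_water_trajectory(k, 0.0, b_end, m_end, t_wash)

    bound = np.concatenate(
        [np.zeros(n_base), loading.bound[:-1], washout.bound]
    )
    membrane = np.concatenate(
        [np.zeros(n_base), loading.membrane[:-1], washout.membrane]
    )
    current = occupancy_to_current(bound, baseline_current, preset.fold_potentiation)

    segment = np.concatenate(
        [
            np.full(n_base, "baseline", dtype="U8"),
            np.full(n_drug, "drug", dtype="U8"),
            np.full(n_wash, "washout", dtype="U8"),
        ]
    )
    times = np.arange(n_base + n_drug + n_wash) / fs

    if noise_sd > 0:
        streams = np.random.SeedSequence(seed).spawn(3)
        noise = np.concatenate(
            [
                np.random.default_rng(s).normal(0.0, noise_sd * baseline_current, n)
                for s, n in zip(streams, (n_base, n_drug, n_wash))
            ]
        )
        current = current + noise
    if lowpass_hz is not None:
        width = max(1, round(fs / lowpass_hz / 2))
        current = _lowpass(current, width)

    meta = {
        "preset": preset.name,
        "fold_potentiation": preset.fold_potentiation,
        "rgroup_logP": preset.rgroup_logP,
        "seed": int(seed),
        "noise_sd": float(noise_sd),
        "baseline_current": float(baseline_current),
        "sample_rate": fs,
        "baseline_s": protocol.baseline_s,
        "drug_s": protocol.drug_s,
        "washout_s": protocol.washout_s,
        "bath_conc": protocol.bath_conc,
    }
    return Trace(times, current, segment, meta=meta)
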