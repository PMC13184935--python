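"""Estimation of fold-potentiation and washout time constants from traces.

Potentiation is the ratio of plateau current with drug to baseline current;
plateaus are the final 25% of each segment, which excludes equilibration
transients without assuming anything about the kinetics.  The washout decay
is summarized by a nonlinear least-squares fit of
``offset + amplitude * exp(-(t - t0)/tau)`` — the offset absorbs residual
baseline current, since real patches return toward, not exactly to,
baseline.  Replicates are reported as mean +- sample SD with n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .traces import Trace

__all__ = [
    "WashoutFit",
    "ReplicateSummary",
    "FitError",
    "estimate_potentiation",
    "fit_washout",
    "summarize",
]


class FitError(RuntimeError):
    """Raised when a decay fit cannot be performed or does not converge."""


@dataclass(frozen=True)
class WashoutFit:
    """Converged single-exponential washout fit."""

    tau: float
    amplitude: float
    offset: float
    rss: float
    window: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +- sample SD (n-1 denominator) over replicates."""

    mean: float
    sd: float
    n: int


def _plateau_mean(trace: Trace, segment: str) -> float:
    idx = trace.segment_indices(segment)
    n_plateau = max(1, idx.size // 4)
    return float(trace.current[idx[-n_plateau:]].mean())


def estimate_potentiation(trace: Trace, min_plateau_s: float = 1.0) -> float:
    """Fold-potentiation: mean drug-plateau current over mean baseline current.

    Both plateaus are the final 25% of their segments and must span at least
    ``min_plateau_s`` seconds.
    """
    for seg in ("baseline", "drug"):
        if trace.segment_duration(seg) < 4.0 * min_plateau_s:
            raise ValueError(
                f"{seg} segment too short: plateau (final 25%) must cover "
                f">= {min_plateau_s} s"
            )
    base = _plateau_mean(trace, "baseline")
    if base <= 0:
        raise ValueError("baseline plateau current must be positive")
    return _plateau_mean(trace, "drug") / base


def _noise_sd_estimate(y: np.ndarray) -> float:
    """Robust white-noise SD from the median absolute first difference."""
    d = np.abs(np.diff(y))
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    pad = width
    yp = np.pad(y, pad, mode="edge")
    out = np.convolve(yp, np.ones(width) / width, mode="same")
    return out[pad:-pad]


def fit_washout(
    trace: Trace,
    window_frac: float = 0.05,
    max_iter: int = 200,
) -> WashoutFit:
    """Fit ``offset + amplitude*exp(-(t-t0)/tau)`` to the washout segment.

    The fit window runs from washout start to the first crossing of
    ``window_frac`` of the decay amplitude (detected on a lightly smoothed
    copy so single noise samples cannot truncate it), or to the segment end
    if the decay is not covered that far.  Initial guesses: offset and
    amplitude from endpoint means, tau from log-linear regression on the
    upper half of the decay.

    Raises
    ------
    FitError
        If the decay amplitude is below three times the estimated noise SD,
        or the optimizer fails to converge.
    """
    idx = trace.segment_indices("washout")
    t = trace.times[idx] - trace.times[idx[0]]
    y = trace.current[idx]
    if t.size < 10:
        raise FitError("washout segment too short to fit")

    noise_sd = _noise_sd_estimate(y)
    n_tail = max(1, t.size // 10)
    n_head = max(1, t.size // 100)
    offset0 = float(y[-n_tail:].mean())
    amp0 = float(y[:n_head].mean()) - offset0
    if amp0 <= 3.0 * noise_sd:
        raise FitError(
            f"washout amplitude {amp0:.3g} is below 3x the noise floor "
            f"({noise_sd:.3g}); nothing to fit"
        )

    ysm = _smooth(y, max(1, t.size // 200))
    below = np.nonzero(ysm - offset0 <= window_frac * amp0)[0]
    end = int(below[0]) if below.size else t.size - 1
    end = max(end, 9)
    tf, yf = t[: end + 1], y[: end + 1]

    # log-linear initial guess for tau on the upper half of the decay
    upper = np.nonzero(ysm[: end + 1] - offset0 >= 0.5 * amp0)[0]
    tau0 = tf[-1] / 3.0
    if upper.size >= 2:
        z = ysm[upper] - offset0
        if np.all(z > 0):
            slope = np.polyfit(tf[upper], np.log(z), 1)[0]
            if slope < 0:
                tau0 = -1.0 / slope

    res = least_squares(
        lambda p: p[0] + p[1] * np.exp(-tf / p[2]) - yf,
        [offset0, amp0, tau0],
        bounds=([-np.inf, 0.0, np.finfo(float).tiny], [np.inf, np.inf, np.inf]),
        method="trf",
        xtol=1e-8,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter * 4,
    )
    if not res.success or not np.isfinite(res.x).all():
        raise FitError(f"washout fit did not converge: {res.message}")
    offset, amplitude, tau = res.x
    return WashoutFit(
        tau=float(tau),
        amplitude=float(amplitude),
        offset=float(offset),
        rss=float(np.sum(res.fun**2)),
        window=(float(trace.times[idx[0]]), float(trace.times[idx[0]] + tf[-1])),
        n_points=int(tf.size),
    )


def summarize(values: Sequence[float]) -> ReplicateSummary:
    """Sample mean, sample SD (n-1 denominator) and count of replicates."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list of replicates")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return ReplicateSummary(mean=float(arr.mean()), sd=sd, n=int(arr.size))
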