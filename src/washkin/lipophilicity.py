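"""Link between R-group lipophilicity and membrane-exit (washout) kinetics.

In the fast-rebinding regime the washout rate ``1/T`` is proportional to the
membrane exit rate ``k_lw``, and the ratio of ``k_lw`` between two analogs is
estimated from the octanol-water logP values of their conjugated R groups:

    k_lw1 / k_lw2 = 10**(-logP1/2) / 10**(-logP2/2)

i.e. the exit rate scales as the reciprocal square root of the R-group
partition coefficient.  A single free prefactor (``scale``) maps predicted
rates onto measured washout rates; it is fitted by minimizing squared errors
in the ratios of actual to predicted time constants, which avoids biasing the
fit toward analogs with large absolute time constants.  The goodness-of-fit
r^2 is computed on per-analog mean rates about their grand mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalogRecord",
    "RateModelFit",
    "klw_ratio",
    "predict_rate",
    "fit_rate_model",
    "error_bars",
    "read_analog_table",
    "write_analog_table",
]


@dataclass
class AnalogRecord:
    """Replicate washout measurements for one analog.

    ``rgroup_logP`` is the experimentally derived logP of the conjugated R
    group (not of the whole molecule); ``taus`` are replicate washout time
    constants in seconds.
    """

    name: str
    rgroup_logP: float
    taus: np.ndarray

    def __post_init__(self) -> None:
        self.taus = np.atleast_1d(np.asarray(self.taus, dtype=float))
        if self.taus.size == 0:
            raise ValueError(f"{self.name}: need at least one replicate tau")
        if np.any(self.taus <= 0):
            raise ValueError(f"{self.name}: all taus must be > 0")
        if not np.isfinite(self.rgroup_logP):
            raise ValueError(f"{self.name}: rgroup_logP must be finite")

    @property
    def rates(self) -> np.ndarray:
        """Replicate washout rates, reciprocal time constants (per second)."""
        return 1.0 / self.taus

    @property
    def mean_tau(self) -> float:
        return float(self.taus.mean())


def klw_ratio(logP1: float, logP2: float) -> float:
    """Ratio ``k_lw1/k_lw2`` of membrane exit rates from R-group logP values."""
    return float(10.0 ** ((logP2 - logP1) / 2.0))


def predict_rate(logP, scale: float):
    """Predicted washout rate ``scale * 10**(-logP/2)`` (per second).

    The predicted time constant is the reciprocal.  ``logP`` may be an array.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    return scale * 10.0 ** (-np.asarray(logP, dtype=float) / 2.0)


@dataclass
class RateModelFit:
    """One-parameter fit of the logP rate model to replicate washout data."""

    scale: float
    r2: float
    loss: str
    per_analog: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {
                "scale_per_s": self.scale,
                "r2": self.r2,
                "loss": self.loss,
                "per_analog": self.per_analog.to_dict(orient="records"),
            },
            indent=2,
        )


def fit_rate_model(
    records: Sequence[AnalogRecord],
    loss: Literal["ratio", "log_ratio"] = "ratio",
) -> RateModelFit:
    """Fit the rate-scale prefactor to per-analog mean time constants.

    With predicted time constants ``That_i(scale) = 1/(scale*10**(-logP_i/2))``
    the default loss is ``sum_i (Tbar_i/That_i - 1)**2`` over analogs, where
    ``Tbar_i`` is the mean replicate time constant.  The ratio residual is
    linear in ``scale`` (``Tbar_i/That_i = scale * Tbar_i * 10**(-logP_i/2)``),
    so the minimizer is closed form.  ``log_ratio`` minimizes squared
    log-ratios instead.  r^2 is computed on per-analog mean rates about their
    grand mean.
    """
    if len(records) < 2:
        raise ValueError("need at least two analogs to fit the rate model")
    names = [r.name for r in records]
    logp = np.array([r.rgroup_logP for r in records])
    mean_tau = np.array([r.mean_tau for r in records])
    u = mean_tau * 10.0 ** (-logp / 2.0)  # Tbar_i/That_i at scale = 1
    if loss == "ratio":
        scale = float(np.sum(u) / np.sum(u * u))
    elif loss == "log_ratio":
        scale = float(np.exp(-np.mean(np.log(u))))
    else:
        raise ValueError(f"unknown loss {loss!r}")
    mean_rate = 1.0 / mean_tau
    pred_rate = predict_rate(logp, scale)
    ss_res = float(np.sum((mean_rate - pred_rate) ** 2))
    ss_tot = float(np.sum((mean_rate - mean_rate.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    per_analog = pd.DataFrame(
        {
            "analog": names,
            "rgroup_logP": logp,
            "mean_tau_s": mean_tau,
            "mean_rate_per_s": mean_rate,
            "predicted_rate_per_s": pred_rate,
            "predicted_tau_s": 1.0 / pred_rate,
            "ratio_actual_to_predicted_tau": scale * u,
        }
    )
    return RateModelFit(scale=scale, r2=float(r2), loss=loss, per_analog=per_analog)


def error_bars(records: Sequence[AnalogRecord]) -> dict[str, float]:
    """Per-analog sample standard deviation (n-1) of replicate rates."""
    out: dict[str, float] = {}
    for r in records:
        if r.taus.size < 2:
            warnings.warn(
                f"{r.name}: single replicate, rate SD reported as 0", stacklevel=2
            )
            out[r.name] = 0.0
        else:
            out[r.name] = float(np.std(r.rates, ddof=1))
    return out


def write_analog_table(records: Iterable[AnalogRecord], path) -> None:
    """Write replicate taus as CSV with columns analog, rgroup_logP, tau_s."""
    rows = [
        {"analog": r.name, "rgroup_logP": r.rgroup_logP, "tau_s": tau}
        for r in records
        for tau in r.taus
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_analog_table(path) -> list[AnalogRecord]:
    """Read an analog replicate table (analog, rgroup_logP, tau_s rows)."""
    df = pd.read_csv(path)
    missing = {"analog", "rgroup_logP", "tau_s"} - set(df.columns)
    if missing:
        raise ValueError(f"analog table missing columns: {sorted(missing)}")
    records = []
    for name, grp in df.groupby("analog", sort=False):
        logps = grp["rgroup_logP"].unique()
        if len(logps) != 1:
            raise ValueError(f"{name}: inconsistent rgroup_logP values {logps}")
        records.append(AnalogRecord(str(name), float(logps[0]), grp["tau_s"].to_numpy()))
    return records
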