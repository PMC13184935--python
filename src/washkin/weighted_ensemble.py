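"""Toy weighted-ensemble (WE) rare-event sampler on a 1-D energy landscape.

The WE method runs many weighted trajectory replicas ("walkers") and, at
fixed resampling intervals, splits or merges them so each bin along a
progress coordinate holds a target number of walkers (default 4).  Splitting
and merging conserve total probability exactly, so the recycled probability
flux into an absorbing "unbound" boundary is an unbiased steady-state
estimator of the transition rate, even when direct crossings are rare.

This module replaces the all-atom protein/membrane system with overdamped
(Brownian) dynamics on a 1-D potential,

    x <- x - D U'(x) dt + sqrt(2 D dt) xi,    xi ~ N(0, 1),

in units of kT = 1.  It validates the rate-estimation methodology at desk
scale against brute-force first-passage simulations; it makes no claim about
the molecular system's rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ToySystem",
    "WeEnsemble",
    "RateEstimate",
    "BruteForceRate",
    "FirstPassageBudgetError",
    "make_system",
    "initialize_ensemble",
    "propagate",
    "split_merge",
    "run_we",
    "estimate_rate",
    "brute_force_rate",
    "run_from_config",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class ToySystem:
    """1-D overdamped-Langevin system in kT = 1 units."""

    potential: Callable[[np.ndarray], np.ndarray]
    grad: Callable[[np.ndarray], np.ndarray]
    diffusion_coeff: float = 1.0
    timestep: float = 1e-4
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.diffusion_coeff < 0 or self.timestep <= 0 or self.kT <= 0:
            raise ValueError("diffusion_coeff >= 0, timestep > 0, kT > 0 required")

    @property
    def step_sd(self) -> float:
        """Per-step displacement SD, ``sqrt(2 D dt)``."""
        return float(np.sqrt(2.0 * self.diffusion_coeff * self.timestep))


def make_system(
    name: str,
    diffusion_coeff: float = 1.0,
    timestep: float = 1e-4,
    **params: float,
) -> ToySystem:
    """Named potentials: ``double_well`` (barrier_height, minima at +-1),
    ``tilted`` (slope, downhill toward +x) and ``flat``."""
    if name == "double_well":
        h = params.pop("barrier_height", 4.0)
        pot = lambda x: h * (x**2 - 1.0) ** 2
        grad = lambda x: 4.0 * h * x * (x**2 - 1.0)
    elif name == "tilted":
        f = params.pop("slope", 1.0)
        pot = lambda x: -f * x
        grad = lambda x: -f * np.ones_like(np.asarray(x, dtype=float))
    elif name == "flat":
        pot = lambda x: np.zeros_like(np.asarray(x, dtype=float))
        grad = pot
    else:
        raise ValueError(f"unknown potential {name!r}")
    if params:
        raise TypeError(f"unused potential parameters: {sorted(params)}")
    return ToySystem(pot, grad, diffusion_coeff=diffusion_coeff, timestep=timestep)


@dataclass
class WeEnsemble:
    """Weighted-walker population with fixed bins and steady-state recycling.

    Walkers absorbed beyond ``recycle_boundary`` are re-initialized at
    ``source_position`` with their weight intact; the absorbed weight per
    round is appended to ``flux_history``.
    """

    positions: np.ndarray
    weights: np.ndarray
    bin_edges: np.ndarray
    target_per_bin: int = 4
    round_length: int = 100
    recycle_boundary: float = np.inf
    source_position: float = 0.0
    reflect_lower: float | None = None
    flux_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.positions.shape != self.weights.shape:
            raise ValueError("positions and weights must have equal shapes")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.target_per_bin < 1 or self.round_length < 1:
            raise ValueError("target_per_bin and round_length must be >= 1")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def initialize_ensemble(
    system: ToySystem,
    bin_edges,
    *,
    target_per_bin: int = 4,
    round_length: int = 100,
    recycle_boundary: float = np.inf,
    source_position: float = 0.0,
    reflect_lower: float | None = None,
) -> WeEnsemble:
    """Start ``target_per_bin`` equal-weight walkers at the source position.

    Validates the timestep against the bin geometry: the per-step
    displacement SD must be below 10% of the smallest bin width, otherwise
    walkers hop over bins within a single step and resampling cannot track
    the progress coordinate.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    min_width = float(np.min(np.diff(bin_edges)))
    if system.step_sd >= 0.1 * min_width:
        raise ValueError(
            f"timestep too large: per-step displacement SD {system.step_sd:.3g} "
            f"must be < 10% of the smallest bin width {min_width:.3g}"
        )
    n = target_per_bin
    return WeEnsemble(
        positions=np.full(n, float(source_position)),
        weights=np.full(n, 1.0 / n),
        bin_edges=bin_edges,
        target_per_bin=target_per_bin,
        round_length=round_length,
        recycle_boundary=recycle_boundary,
        source_position=source_position,
        reflect_lower=reflect_lower,
    )


def _brownian_steps(
    x: np.ndarray,
    system: ToySystem,
    n_steps: int,
    rng: np.random.Generator,
    recycle_boundary: float,
    source_position: float,
    weights: np.ndarray | None,
    reflect_lower: float | None,
) -> tuple[np.ndarray, float]:
    """Advance walkers; returns (positions, recycled weight)."""
    D, dt = system.diffusion_coeff, system.timestep
    sd = system.step_sd
    recycled = 0.0
    for _ in range(n_steps):
        x = x - D * system.grad(x) * dt
        if sd > 0:
            x = x + rng.normal(0.0, sd, x.shape)
        if reflect_lower is not None:
            low = x < reflect_lower
            if low.any():
                x[low] = 2.0 * reflect_lower - x[low]
        crossed = x >= recycle_boundary
        if crossed.any():
            if weights is not None:
                recycled += float(weights[crossed].sum())
            x[crossed] = source_position
    return x, recycled


def propagate(
    ensemble: WeEnsemble, system: ToySystem, seed: int | np.random.Generator = 0
) -> float:
    """Advance every walker ``round_length`` Brownian-dynamics steps in place.

    Weights are untouched; walkers reaching the recycle boundary are placed
    back at the source with weight intact, and the weight so recycled during
    the round is appended to ``flux_history`` and returned.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ensemble.positions, recycled = _brownian_steps(
        ensemble.positions.copy(),
        system,
        ensemble.round_length,
        rng,
        ensemble.recycle_boundary,
        ensemble.source_position,
        ensemble.weights,
        ensemble.reflect_lower,
    )
    ensemble.flux_history.append(recycled)
    return recycled


def split_merge(
    ensemble: WeEnsemble,
    rng: np.random.Generator | int | None = None,
    deterministic: bool = False,
) -> None:
    """Resample each occupied bin to exactly ``target_per_bin`` walkers.

    Underpopulated bins repeatedly split their highest-weight walker (weight
    halved per split); overpopulated bins repeatedly merge their two
    lowest-weight walkers, the survivor drawn with probability proportional
    to weight (``deterministic=True`` keeps the heavier one instead, for
    reproducible unit tests).  Total weight is conserved exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    target = ensemble.target_per_bin
    bins = np.digitize(ensemble.positions, ensemble.bin_edges)
    new_pos: list[float] = []
    new_w: list[float] = []
    for b in np.unique(bins):
        sel = np.nonzero(bins == b)[0]
        pos = list(ensemble.positions[sel])
        w = list(ensemble.weights[sel])
        while len(w) < target:
            i = int(np.argmax(w))
            w[i] *= 0.5
            w.append(w[i])
            pos.append(pos[i])
        while len(w) > target:
            order = np.argsort(w)
            i, j = int(order[0]), int(order[1])
            wi, wj = w[i], w[j]
            if deterministic:
                keep = i if wi >= wj else j
            else:
                keep = i if rng.random() < wi / (wi + wj) else j
            lose = j if keep == i else i
            w[keep] = wi + wj
            del w[lose], pos[lose]
        new_pos.extend(pos)
        new_w.extend(w)
    ensemble.positions = np.array(new_pos)
    ensemble.weights = np.array(new_w)


def run_we(
    system: ToySystem,
    ensemble: WeEnsemble,
    n_rounds: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Drive propagate/resample rounds; returns the per-round history table.

    Columns: ``round``, ``recycled_weight``, ``n_walkers``, ``total_weight``.
    """
    min_width = float(np.min(np.diff(ensemble.bin_edges)))
    if system.step_sd >= 0.1 * min_width:
        raise ValueError("timestep too large for the bin geometry")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_rounds):
        recycled = propagate(ensemble, system, rng)
        split_merge(ensemble, rng)
        total = ensemble.total_weight
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise RuntimeError(f"weight conservation violated: sum = {total!r}")
        rows.append(
            {
                "round": r,
                "recycled_weight": recycled,
                "n_walkers": ensemble.positions.size,
                "total_weight": total,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RateEstimate:
    """Flux-based steady-state rate with block-bootstrap uncertainty."""

    rate: float
    sd: float
    n_rounds_used: int
    n_events: int

    @property
    def relative_uncertainty(self) -> float:
        return self.sd / self.rate if self.rate > 0 else np.inf


def estimate_rate(
    history: pd.DataFrame | np.ndarray,
    round_time: float,
    burn_frac: float = 0.5,
    block: int | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> RateEstimate:
    """Mean recycled weight per unit time over the post-burn-in history.

    The first ``burn_frac`` of rounds is discarded as relaxation toward the
    recycling steady state.  The SD comes from a block bootstrap over blocks
    of ``block`` consecutive rounds (default: a tenth of the retained
    history), long enough to span the slow weight-redistribution
    correlations of the flux signal.  With no recycling events the rate is 0
    and the relative uncertainty is flagged infinite.
    """
    flux = (
        history["recycled_weight"].to_numpy()
        if isinstance(history, pd.DataFrame)
        else np.asarray(history, dtype=float)
    )
    if flux.size < 20:
        raise ValueError("need >= 20 rounds of history to estimate a rate")
    if round_time <= 0:
        raise ValueError("round_time must be > 0")
    tail = flux[int(burn_frac * flux.size) :]
    rate = float(tail.mean() / round_time)
    n_events = int(np.count_nonzero(tail))
    if n_events == 0:
        return RateEstimate(rate=0.0, sd=0.0, n_rounds_used=tail.size, n_events=0)
    if block is None:
        block = max(5, tail.size // 10)
    rng = np.random.default_rng(seed)
    n_blocks = max(1, tail.size // block)
    blocks = tail[: n_blocks * block].reshape(n_blocks, block)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        boot[i] = blocks[pick].mean() / round_time
    return RateEstimate(
        rate=rate,
        sd=float(boot.std(ddof=1)),
        n_rounds_used=int(tail.size),
        n_events=n_events,
    )


class FirstPassageBudgetError(RuntimeError):
    """Step budget exhausted before all first-passage events completed."""

    def __init__(self, message: str, fpts: np.ndarray):
        super().__init__(message)
        self.fpts = fpts  # completed first-passage times (partial statistics)


@dataclass(frozen=True)
class BruteForceRate:
    """Direct first-passage rate: ``1 / mean first-passage time``."""

    rate: float
    mean_fpt: float
    fpts: np.ndarray

    @property
    def rate_sd(self) -> float:
        """Delta-method SE of the rate from the FPT sample spread."""
        n = self.fpts.size
        return float(self.rate * self.fpts.std(ddof=1) / self.mean_fpt / np.sqrt(n))


def brute_force_rate(
    system: ToySystem,
    n_events: int,
    seed: int = 0,
    *,
    start: float = 0.0,
    absorbing_boundary: float = 1.0,
    reflect_lower: float | None = None,
    max_steps: int = 50_000_000,
) -> BruteForceRate:
    """Simulate independent first-passage events from ``start`` to the boundary.

    All events are propagated as one vectorized batch; each walker stops when
    it first reaches ``absorbing_boundary``.
    """
    if n_events < 10:
        raise ValueError("n_events must be >= 10 for a meaningful rate")
    rng = np.random.default_rng(seed)
    D, dt, sd = system.diffusion_coeff, system.timestep, system.step_sd
    x = np.full(n_events, float(start))
    fpt = np.full(n_events, np.nan)
    active = np.ones(n_events, dtype=bool)
    for step in range(1, max_steps + 1):
        xa = x[active]
        xa = xa - D * system.grad(xa) * dt
        if sd > 0:
            xa = xa + rng.normal(0.0, sd, xa.size)
        if reflect_lower is not None:
            low = xa < reflect_lower
            xa[low] = 2.0 * reflect_lower - xa[low]
        x[active] = xa
        done = xa >= absorbing_boundary
        if done.any():
            idx = np.nonzero(active)[0][done]
            fpt[idx] = step * dt
            active[idx] = False
            if not active.any():
                break
    else:
        completed = fpt[~np.isnan(fpt)]
        raise FirstPassageBudgetError(
            f"step budget {max_steps} exhausted with {completed.size}/{n_events} "
            "events completed",
            completed,
        )
    mean_fpt = float(fpt.mean())
    return BruteForceRate(rate=1.0 / mean_fpt, mean_fpt=mean_fpt, fpts=fpt)


def run_from_config(config: dict) -> tuple[pd.DataFrame, RateEstimate]:
    """Run a WE demo from a JSON-style config dict; returns (history, rate).

    Expected keys: ``potential`` ({name, params}), ``diffusion_coeff``,
    ``timestep``, ``bins`` (explicit edge array), ``target_per_bin``,
    ``round_length``, ``n_rounds``, ``seed``, ``recycle_boundary``,
    ``source_position``, optional ``reflect_lower``.
    """
    pot = config["potential"]
    system = make_system(
        pot["name"],
        diffusion_coeff=config.get("diffusion_coeff", 1.0),
        timestep=config.get("timestep", 1e-4),
        **pot.get("params", {}),
    )
    ensemble = initialize_ensemble(
        system,
        config["bins"],
        target_per_bin=config.get("target_per_bin", 4),
        round_length=config.get("round_length", 100),
        recycle_boundary=config["recycle_boundary"],
        source_position=config.get("source_position", 0.0),
        reflect_lower=config.get("reflect_lower"),
    )
    n_rounds = config.get("n_rounds", 200)
    seed = config.get("seed", 0)
    history = run_we(system, ensemble, n_rounds, seed=seed)
    rate = estimate_rate(
        history,
        round_time=ensemble.round_length * system.timestep,
        seed=seed,
    )
    return history, rate
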