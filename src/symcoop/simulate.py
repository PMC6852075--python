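"""Individual-based simulation of the host–symbiont life cycle.

Hosts form a fixed-size population with nonoverlapping generations; each
host carries exactly ``k`` symbionts. One generation:

1. Each host's symbiont group determines a survival weight ``x_g**s`` and a
   fecundity weight ``x_g**f`` (``0**0 == 1``).
2. Each offspring host is founded horizontally with probability ``lam``,
   otherwise vertically.
3. A vertically founded host picks one parent host (probability
   proportional to survival * fecundity) and draws its ``k`` founders with
   replacement from that host's symbionts, each symbiont weighted by its
   within-host share ``1 - x_i``.
4. A horizontally founded host draws its ``k`` founders with replacement
   from the global symbiont pool, where a symbiont in host ``h`` carries
   weight ``S_h * (1 - x_i) / (1 - x_g(h))`` — host survival times the
   symbiont's within-host share.
5. Each founder mutates with probability ``mu``: a Normal(0, sigma) step,
   reflected back into ``[0, x_max]``.

Selection is soft (weighted sampling at constant host number), mirroring
the relative-fitness structure of the analytic model. Optionally every
symbiont carries a neutral integer lineage tag, inherited unchanged, for
marker-based relatedness estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "PopulationState",
    "GenerationSummary",
    "SimulationResult",
    "initialize_population",
    "advance_generation",
    "run_simulation",
]


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulation run.

    Defaults give a desk-scale run of 1,000 hosts with 4 symbionts each and
    a rare (1%), small (sd 0.02) mutation per founding symbiont. ``x_max``
    clamps traits strictly below 1 because the within-host share
    ``(1 - x_i)/(1 - x_g)`` is singular there; a clonal population's
    analytic optimum of 1 is approached, never attained, in simulation.
    """

    n_hosts: int = 1000
    k: int = 4
    lam: float = 1.0
    s: float = 1.0
    f: float = 1.0
    mu: float = 0.01
    sigma: float = 0.02
    x_init: float = 0.5
    x_max: float = 1.0 - 1e-6
    n_generations: int = 3000
    record_every: int = 25
    seed: int = 0
    track_lineages: bool = False

    def __post_init__(self) -> None:
        if self.n_hosts < 1 or int(self.n_hosts) != self.n_hosts:
            raise ValueError(f"n_hosts must be a positive integer, got {self.n_hosts!r}")
        if self.k < 1 or int(self.k) != self.k:
            raise ValueError(f"k must be a positive integer, got {self.k!r}")
        for name, v in (("lam", self.lam), ("mu", self.mu)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name, v in (("s", self.s), ("f", self.f), ("sigma", self.sigma)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if not (0.0 < self.x_max < 1.0):
            raise ValueError(f"x_max must lie in (0, 1), got {self.x_max!r}")
        if not (0.0 <= self.x_init <= self.x_max):
            raise ValueError(
                f"x_init must lie in [0, x_max={self.x_max}], got {self.x_init!r}"
            )
        for name, v in (
            ("n_generations", self.n_generations),
            ("record_every", self.record_every),
        ):
            if v < 1 or int(v) != v:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass
class PopulationState:
    """Trait values of every symbiont, as an ``n_hosts x k`` array."""

    traits: np.ndarray
    generation: int = 0
    lineages: np.ndarray | None = None  # same shape; neutral inherited tags


@dataclass(frozen=True)
class GenerationSummary:
    """Per-generation population statistics recorded along a trajectory."""

    generation: int
    mean_x: float
    var_x: float
    realized_R: float  # NaN when the population is monomorphic
    n_modes: int
    frac_horizontal: float
    realized_R_marker: float = float("nan")


@dataclass
class SimulationResult:
    """Trajectory of one run: recorded summaries plus optional snapshots."""

    config: SimConfig
    summaries: pd.DataFrame
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def recorded_generations(self) -> np.ndarray:
        return self.summaries["generation"].to_numpy()


def _pow_arr(x: np.ndarray, e: float) -> np.ndarray:
    if e == 0.0:
        return np.ones_like(x)
    return x**e


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi] by reflection at both edges."""
    span = hi - lo
    y = np.mod(values - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


def _weighted_rows_choice(
    weights: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """For each row of `weights`, draw m column indices with replacement,
    probability proportional to the row's weights. Returns (n_rows, m)."""
    cum = np.cumsum(weights, axis=1)
    totals = cum[:, -1]
    zero = totals <= 0.0
    if np.any(zero):
        k = weights.shape[1]
        cum[zero] = np.arange(1, k + 1, dtype=float)  # uniform fallback
        totals = cum[:, -1]
    u = rng.random((weights.shape[0], m)) * totals[:, None]
    idx = np.sum(cum[:, None, :] < u[:, :, None], axis=2)
    return np.minimum(idx, weights.shape[1] - 1)


def initialize_population(cfg: SimConfig) -> PopulationState:
    """Monomorphic starting population at ``x_init``, generation 0."""
    traits = np.full((cfg.n_hosts, cfg.k), float(cfg.x_init))
    lineages = None
    if cfg.track_lineages:
        lineages = np.arange(cfg.n_hosts * cfg.k, dtype=np.int64).reshape(
            cfg.n_hosts, cfg.k
        )
    return PopulationState(traits=traits, generation=0, lineages=lineages)


def _step(
    state: PopulationState, cfg: SimConfig, rng: np.random.Generator
) -> tuple[PopulationState, float]:
    """One life-cycle step; returns (offspring state, realized horizontal fraction)."""
    x = state.traits
    n_hosts, k = x.shape
    x_g = x.mean(axis=1)
    survival = _pow_arr(x_g, cfg.s)
    fecundity = _pow_arr(x_g, cfg.f)

    track = state.lineages is not None
    new_traits = np.empty_like(x)
    new_lineages = np.empty_like(state.lineages) if track else None

    horizontal = rng.random(n_hosts) < cfg.lam
    n_h = int(horizontal.sum())
    n_v = n_hosts - n_h

    if n_v:
        host_w = survival * fecundity
        total = host_w.sum()
        if total <= 0.0:
            warnings.warn(
                "all parent-host weights are zero; sampling parents uniformly",
                RuntimeWarning,
                stacklevel=3,
            )
            p_host = None
        else:
            p_host = host_w / total
        parents = rng.choice(n_hosts, size=n_v, p=p_host)
        founder_cols = _weighted_rows_choice(1.0 - x[parents], k, rng)
        rows = parents[:, None]
        new_traits[~horizontal] = x[rows, founder_cols]
        if track:
            new_lineages[~horizontal] = state.lineages[rows, founder_cols]

    if n_h:
        pool_w = (survival / (1.0 - x_g))[:, None] * (1.0 - x)
        flat = pool_w.ravel()
        total = flat.sum()
        if total <= 0.0:
            warnings.warn(
                "all horizontal-pool weights are zero; sampling the pool uniformly",
                RuntimeWarning,
                stacklevel=3,
            )
            p_flat = None
        else:
            p_flat = flat / total
        picks = rng.choice(n_hosts * k, size=n_h * k, p=p_flat)
        new_traits[horizontal] = x.ravel()[picks].reshape(n_h, k)
        if track:
            new_lineages[horizontal] = state.lineages.ravel()[picks].reshape(n_h, k)

    mutate = rng.random((n_hosts, k)) < cfg.mu
    n_mut = int(mutate.sum())
    if n_mut:
        stepped = new_traits[mutate] + rng.normal(0.0, cfg.sigma, size=n_mut)
        new_traits[mutate] = _reflect(stepped, 0.0, cfg.x_max)

    next_state = PopulationState(
        traits=new_traits, generation=state.generation + 1, lineages=new_lineages
    )
    return next_state, n_h / n_hosts


def advance_generation(
    state: PopulationState, cfg: SimConfig, rng: np.random.Generator
) -> PopulationState:
    """Advance the population by one generation of the full life cycle."""
    next_state, _ = _step(state, cfg, rng)
    return next_state


def _summarize(
    state: PopulationState, cfg: SimConfig, frac_horizontal: float
) -> GenerationSummary:
    traits = state.traits.ravel()
    mean_x = float(traits.mean())
    var_x = float(traits.var())
    realized = _stats.realized_whole_group_relatedness(state)
    marker = float("nan")
    if state.lineages is not None:
        marker = _stats.marker_whole_group_relatedness(state)
    if traits.size >= 50 and var_x > 0.0:
        n_modes = len(_stats.detect_modes(traits, x_max=cfg.x_max).locations)
    else:
        n_modes = 1
    return GenerationSummary(
        generation=state.generation,
        mean_x=mean_x,
        var_x=var_x,
        realized_R=realized,
        n_modes=n_modes,
        frac_horizontal=frac_horizontal,
        realized_R_marker=marker,
    )


def run_simulation(cfg: SimConfig, keep_snapshots: bool = False) -> SimulationResult:
    """Run the full life cycle for ``cfg.n_generations`` generations.

    Summaries are recorded at generation 0 and every ``record_every``
    generations thereafter (plus the final generation). With
    ``keep_snapshots`` the full trait array is stored at each recorded
    generation — needed for branching classification. Output is
    bit-identical for identical configs, seed included.
    """
    logger.info("run_simulation config: %r", cfg)
    rng = np.random.default_rng(cfg.seed)
    state = initialize_population(cfg)
    summaries: list[GenerationSummary] = [_summarize(state, cfg, float("nan"))]
    snapshots: list[tuple[int, np.ndarray]] = []
    if keep_snapshots:
        snapshots.append((0, state.traits.copy()))

    for gen in range(1, cfg.n_generations + 1):
        state, frac_h = _step(state, cfg, rng)
        if gen % cfg.record_every == 0 or gen == cfg.n_generations:
            summaries.append(_summarize(state, cfg, frac_h))
            if keep_snapshots:
                snapshots.append((gen, state.traits.copy()))

    frame = pd.DataFrame([s.__dict__ for s in summaries])
    return SimulationResult(config=cfg, summaries=frame, snapshots=snapshots)
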