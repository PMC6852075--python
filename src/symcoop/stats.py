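"""Summary statistics over simulated symbiont populations.

Provides the empirical counterpart of the analytic quantities: a
regression-form estimator of whole-group relatedness, a kernel-density
mode counter for the trait distribution, and a persistence-based
classifier for evolutionary branching (a stable multimodal trait
polymorphism, as opposed to transient mutation–selection variation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "ModeEstimate",
    "BranchingCall",
    "realized_whole_group_relatedness",
    "marker_whole_group_relatedness",
    "detect_modes",
    "classify_branching",
    "compare_relatedness",
]

#: A mode must carry at least this density fraction of the global maximum.
MODE_DENSITY_FRACTION = 0.05
#: Two peaks merge unless the valley between them drops below this fraction
#: of the lower peak.
VALLEY_FRACTION = 0.5
#: Lower bound on the KDE bandwidth (trait units).
BANDWIDTH_FLOOR = 0.005
#: A mode must hold at least this fraction of symbionts to count toward a
#: branching call.
MODE_MASS_FRACTION = 0.05
#: Two modes must differ by at least this much (trait units) to count as
#: distinct strategies in a branching call; finer structure is drift /
#: mutation–selection noise within one strategy (5 mutation SDs at the
#: default mutation scale).
MIN_BRANCH_SEPARATION = 0.1


def _traits_of(population) -> np.ndarray:
    """Accept a PopulationState-like object or a bare array of traits."""
    traits = getattr(population, "traits", population)
    return np.asarray(traits, dtype=float)


def realized_whole_group_relatedness(population) -> float:
    """Regression estimate of whole-group relatedness at the trait itself.

    For each symbiont ``i`` in host ``h``, regress the host's whole-group
    mean ``x_g(h)`` (including self) on the individual value ``x_i``:
    ``R = cov(x_i, x_g(i)) / var(x_i)`` over all symbionts. Returns NaN for
    a monomorphic population, where the regression is undefined.

    Under neutral trait variation this recovers the pedigree expectation
    (e.g. ``1/k`` when groups are random draws from the population); once
    cooperation itself structures who shares a host, the estimate can
    depart from the demographic prediction.
    """
    traits = _traits_of(population)
    if traits.ndim != 2:
        raise ValueError("expected an (n_hosts, k) trait array")
    x = traits.ravel()
    if np.all(x == x[0]):
        return float("nan")
    x_g = np.repeat(traits.mean(axis=1), traits.shape[1])
    cov = np.mean((x - x.mean()) * (x_g - x_g.mean()))
    return float(cov / np.var(x))


def marker_whole_group_relatedness(population) -> float:
    """Whole-group relatedness at neutral inherited lineage tags.

    Pools the regression estimator over the indicator variable of every
    segregating tag: ``R = sum_t cov(I_t, Ig_t) / sum_t var(I_t)``, where
    ``I_t`` marks carriers of tag ``t`` and ``Ig_t`` is the carrier
    fraction in the focal symbiont's host (including self). Unlike the
    trait-based estimate this cannot be fed back on by selection on
    cooperation, so it tracks the pedigree prediction. NaN once a single
    tag has fixed.
    """
    lineages = getattr(population, "lineages", population)
    if lineages is None:
        raise ValueError("population carries no lineage tags")
    tags = np.asarray(lineages)
    if tags.ndim != 2:
        raise ValueError("expected an (n_hosts, k) lineage array")
    n_hosts, k = tags.shape
    n = n_hosts * k
    uniq, inv = np.unique(tags, return_inverse=True)
    if uniq.size < 2:
        return float("nan")
    inv = inv.reshape(n_hosts, k)
    # counts[h, t] = carriers of tag t in host h
    counts = np.zeros((n_hosts, uniq.size))
    np.add.at(counts, (np.repeat(np.arange(n_hosts), k), inv.ravel()), 1.0)
    freq = counts.sum(axis=0) / n  # population frequency of each tag
    group_frac = counts / k
    # cov(I_t, Ig_t) = E[I * Ig] - p^2, summed over symbionts and tags
    cov_sum = float(np.sum(group_frac[np.repeat(np.arange(n_hosts), k), inv.ravel()]) / n)
    cov_sum -= float(np.sum(freq**2))
    var_sum = float(np.sum(freq * (1.0 - freq)))
    return cov_sum / var_sum


@dataclass(frozen=True)
class ModeEstimate:
    """Modes of a trait sample: locations, per-mode mass, and the density."""

    locations: tuple[float, ...]
    masses: tuple[float, ...]
    grid: np.ndarray
    density: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.locations)


def detect_modes(
    traits: np.ndarray,
    x_max: float = 1.0 - 1e-6,
    bandwidth_rule: str = "silverman",
    grid_size: int = 512,
) -> ModeEstimate:
    """Count and locate modes of the trait distribution by Gaussian KDE.

    The density is estimated on ``[0, x_max]`` with the named bandwidth
    rule (floored at ``BANDWIDTH_FLOOR``). Local maxima below
    ``MODE_DENSITY_FRACTION`` of the global peak are discarded; adjacent
    maxima are merged unless the valley between them falls below
    ``VALLEY_FRACTION`` of the lower peak. Deterministic given the sample.
    """
    sample = np.asarray(traits, dtype=float).ravel()
    if sample.size < 50:
        raise ValueError(f"need at least 50 trait values, got {sample.size}")
    grid = np.linspace(0.0, x_max, grid_size)
    std = sample.std()
    if std == 0.0:
        density = np.zeros(grid_size)
        loc = float(sample[0])
        density[np.argmin(np.abs(grid - loc))] = 1.0
        return ModeEstimate((loc,), (1.0,), grid, density)

    kde = gaussian_kde(sample, bw_method=bandwidth_rule)
    bandwidth = kde.factor * std
    if bandwidth < BANDWIDTH_FLOOR:
        kde = gaussian_kde(sample, bw_method=BANDWIDTH_FLOOR / std)
    density = kde(grid)

    peak = density.max()
    interior = (density[1:-1] >= density[:-2]) & (density[1:-1] > density[2:])
    candidates = list(np.flatnonzero(interior) + 1)
    if density[0] > density[1]:
        candidates.insert(0, 0)
    if density[-1] > density[-2]:
        candidates.append(grid_size - 1)
    candidates = [i for i in candidates if density[i] > MODE_DENSITY_FRACTION * peak]

    # Merge neighbouring peaks that lack a deep enough valley between them.
    merged = True
    while merged and len(candidates) > 1:
        merged = False
        for j in range(len(candidates) - 1):
            a, b = candidates[j], candidates[j + 1]
            valley = density[a : b + 1].min()
            lower_peak = min(density[a], density[b])
            if valley >= VALLEY_FRACTION * lower_peak:
                drop = j if density[a] < density[b] else j + 1
                del candidates[drop]
                merged = True
                break

    locations = tuple(float(grid[i]) for i in candidates)
    # Basin boundaries at the deepest valley between retained modes.
    boundaries = []
    for j in range(len(candidates) - 1):
        a, b = candidates[j], candidates[j + 1]
        boundaries.append(grid[a + int(np.argmin(density[a : b + 1]))])
    edges = np.concatenate(([-np.inf], boundaries, [np.inf]))
    masses = tuple(
        float(np.mean((sample >= lo) & (sample < hi)))
        for lo, hi in zip(edges[:-1], edges[1:])
    )
    return ModeEstimate(locations, masses, grid, density)


@dataclass(frozen=True)
class BranchingCall:
    """Outcome of the branching classifier for one trajectory."""

    branched: bool
    n_modes_final: int
    first_branch_generation: int | None
    persistence: int


def classify_branching(
    result,
    min_persistence: int = 5,
) -> BranchingCall:
    """Decide whether a run underwent evolutionary branching.

    A recorded snapshot is *polymorphic* when it shows >= 2 modes that each
    hold at least ``MODE_MASS_FRACTION`` of the symbionts and are separated
    by at least ``MIN_BRANCH_SEPARATION`` in trait units. Branching is
    called when a streak of at least ``min_persistence`` consecutive
    polymorphic snapshots lies within the final half of the run — the
    persistence, mass and separation requirements screen out transient
    mutation–selection polymorphism and drift sub-clusters, which produce
    short-lived, marginal, or narrowly split extra modes.
    ``first_branch_generation`` is the start of the earliest qualifying
    streak, extended backwards through any contiguous polymorphic
    snapshots preceding it.

    ``result`` is a :class:`~symcoop.simulate.SimulationResult` run with
    ``keep_snapshots=True``.
    """
    snapshots = result.snapshots
    if len(snapshots) < 4 * min_persistence:
        raise ValueError(
            f"need >= {4 * min_persistence} recorded snapshots, got {len(snapshots)}"
        )
    x_max = result.config.x_max
    flags = []
    for _, traits in snapshots:
        est = detect_modes(traits, x_max=x_max)
        big = [
            loc
            for loc, m in zip(est.locations, est.masses)
            if m >= MODE_MASS_FRACTION
        ]
        separated = len(big) >= 2 and (max(big) - min(big)) >= MIN_BRANCH_SEPARATION
        flags.append(est.n_modes >= 2 and separated)
    flags = np.asarray(flags)
    generations = np.asarray([g for g, _ in snapshots])
    half = len(flags) // 2

    best_streak = 0
    first_branch: int | None = None
    run_start = None
    for i, flag in enumerate(flags):
        if flag:
            if run_start is None:
                run_start = i
        else:
            run_start = None
            continue
        # length of the current streak restricted to the final half
        in_final = max(0, i + 1 - max(run_start, half))
        streak = i + 1 - run_start
        if in_final >= min_persistence:
            best_streak = max(best_streak, streak)
            if first_branch is None:
                first_branch = int(generations[run_start])

    final_est = detect_modes(snapshots[-1][1], x_max=x_max)
    return BranchingCall(
        branched=first_branch is not None,
        n_modes_final=final_est.n_modes,
        first_branch_generation=first_branch,
        persistence=best_streak,
    )


def compare_relatedness(
    summaries: pd.DataFrame,
    predicted_R: float,
    burn_in_frac: float = 0.25,
    column: str = "realized_R",
) -> tuple[float, float, float]:
    """Demographically predicted vs realized whole-group relatedness.

    Averages the realized estimates over the post-burn-in portion of a
    trajectory and returns ``(predicted, observed, observed - predicted)``.
    In monomorphic regimes the difference is small; after branching the
    realized value typically exceeds the demographic prediction, because
    cooperative strains end up concentrated in purer groups.
    """
    gens = summaries["generation"].to_numpy()
    cutoff = burn_in_frac * gens.max()
    window = summaries.loc[gens >= cutoff, column].to_numpy()
    window = window[~np.isnan(window)]
    if window.size == 0:
        raise ValueError("no defined relatedness estimates after burn-in")
    observed = float(window.mean())
    return predicted_R, observed, observed - predicted_R
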