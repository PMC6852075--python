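"""Closed-form equilibrium analysis of symbiont cooperation.

The model: symbionts live obligately inside hosts (infinite host
population, nonoverlapping generations, no host structure). A symbiont
investing ``x_i`` into a host-benefiting service grows within its host at
relative rate ``(1 - x_i) / (1 - x_g)``, where ``x_g`` is the host's mean
symbiont investment. Cooperation raises host survival (``x_g**s``) and
fecundity (``x_g**f``). A fraction ``lam`` of new hosts are founded
horizontally (weighted by host survival only); the rest vertically
(weighted by survival times fecundity).

The selection gradient on cooperation is the inclusive-fitness effect

    dIF(x) = -1/(1-x) + R * [ (s + f*(1-lam))/x + 1/(1-x) ],

whose interior root is the candidate ESS

    x0* = R*A / (R*(A-1) + 1),    A = f*(1-lam) + s.

Closing the model demographically, whole-group relatedness becomes
``R = (k_h*(1-lam) + lam*k_v) / (k_h*(1 + (k_v-1)*lam))``, which under
equal bottlenecks ``k_h = k_v = k`` reduces to ``1/(1 + lam*(k-1))`` and
yields the closed-model ESS ``x_c* = A / (A + (k-1)*lam)``.

All derivative formulas here are closed forms; an independent
finite-difference/bisection oracle (:func:`numeric_ess_oracle`) and the
threshold scanners at the bottom of the module verify them numerically.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .params import (
    ClosedParams,
    EssSolution,
    OpenParams,
    RouteDecomposition,
    TraitTriple,
)

__all__ = [
    "symbiont_fitness",
    "inclusive_fitness_effect",
    "inclusive_fitness_slope",
    "ess_open",
    "whole_group_relatedness_closed",
    "ess_closed",
    "marginal_effect_relatedness",
    "marginal_effect_transmission",
    "dominant_factor_open",
    "route_decomposition_closed",
    "numeric_ess_oracle",
    "transmission_dominance_lambda_infimum",
    "transmission_dominance_ratio_infimum",
    "direct_route_lambda_infimum",
]

#: Absolute tolerance below which competing marginal effects are called a tie.
TIE_TOL = 1e-12


def _pow(base: float, exponent: float) -> float:
    """``base**exponent`` with the continuity convention ``0**0 == 1``."""
    if exponent == 0.0:
        return 1.0
    return base**exponent


def symbiont_fitness(t: TraitTriple, p: OpenParams) -> float:
    """Relative fitness of a focal symbiont.

    The vertical component (weight ``1 - lam``) carries both the host
    survival and fecundity factors; the horizontal component (weight
    ``lam``) carries survival only, because horizontally transmitted
    offspring leave before host reproduction matters to them.

    Returns 1 exactly when the focal symbiont, its host and the population
    all share the same trait value (the resident is its own reference).
    """
    if (p.s > 0 or p.f > 0) and t.x_bar == 0.0:
        raise ValueError(
            "x_bar = 0 with a positive survival or fecundity exponent makes "
            "the relative host-performance factors undefined"
        )
    within_host = (1.0 - t.x_i) / (1.0 - t.x_g)
    survival = _pow(t.x_g, p.s) / _pow(t.x_bar, p.s)
    fecundity = _pow(t.x_g, p.f) / _pow(t.x_bar, p.f)
    return (1.0 - p.lam) * within_host * survival * fecundity + p.lam * within_host * survival


def inclusive_fitness_effect(x: float, p: OpenParams) -> float:
    """Selection gradient dIF on cooperation at a monomorphic trait value.

    Combines the direct effect of a marginal trait change on the focal
    symbiont with the relatedness-weighted effect on its whole host group,
    all derivatives evaluated at ``x_i = x_g = x_bar = x``. The first term,
    ``-1/(1-x)``, is the within-host competitive cost; the second is the
    group benefit through host survival and (for vertically transmitted
    offspring) host fecundity.
    """
    if not (0.0 < x < 1.0):
        raise ValueError(f"gradient has poles at 0 and 1; need 0 < x < 1, got {x!r}")
    a = p.s + p.f * (1.0 - p.lam)
    return -1.0 / (1.0 - x) + p.R * (a / x + 1.0 / (1.0 - x))


def inclusive_fitness_slope(x: float, p: OpenParams) -> float:
    """d(dIF)/dx — negative at an interior root means the ESS is stable."""
    if not (0.0 < x < 1.0):
        raise ValueError(f"need 0 < x < 1, got {x!r}")
    a = p.s + p.f * (1.0 - p.lam)
    return (p.R - 1.0) / (1.0 - x) ** 2 - p.R * a / x**2


def ess_open(p: OpenParams) -> EssSolution:
    """Candidate ESS cooperation level of the open model.

    Interior stationary point ``x0* = R*A / (R*(A-1) + 1)`` with
    ``A = f*(1-lam) + s``. When ``R = 0`` or ``A = 0`` the gradient is
    negative everywhere on (0, 1), so selection removes cooperation
    entirely and the boundary 0 is returned (flagged stable). At ``R = 1``
    the formula gives exactly 1: clonal symbionts cooperate maximally.
    """
    a = p.benefit_exponent
    if p.R == 0.0 or a == 0.0:
        return EssSolution(x_star=0.0, delta_if_residual=math.nan, stable=True)
    x_star = p.R * a / (p.R * a + (1.0 - p.R))
    if x_star < 1e-150:
        # underflow at tiny R*A: indistinguishable from the boundary
        return EssSolution(x_star=0.0, delta_if_residual=math.nan, stable=True)
    if x_star >= 1.0:
        # R == 1 exactly: gradient positive on all of (0, 1).
        return EssSolution(x_star=1.0, delta_if_residual=math.nan, stable=True)
    residual = inclusive_fitness_effect(x_star, p)
    stable = inclusive_fitness_slope(x_star, p) <= 0.0
    return EssSolution(x_star=x_star, delta_if_residual=residual, stable=stable)


def whole_group_relatedness_closed(p: ClosedParams) -> float:
    """Whole-group relatedness generated by the transmission demography.

    ``R = (k_h*(1-lam) + lam*k_v) / (k_h*(1 + (k_v-1)*lam))``. Full
    vertical transmission (``lam = 0``) gives 1 — each host group is a pure
    clone line; full horizontal transmission gives ``1/k_h`` — groups are
    random draws of ``k_h`` unrelated founders. Under equal bottlenecks
    this reduces to ``1 / (1 + lam*(k-1))``.
    """
    num = p.k_h * (1.0 - p.lam) + p.lam * p.k_v
    den = p.k_h * (1.0 + (p.k_v - 1.0) * p.lam)
    # k_h = 1 makes num and den algebraically equal; clamp rounding overshoot
    return min(num / den, 1.0)


def ess_closed(p: ClosedParams) -> EssSolution:
    """Closed-model ESS under equal bottlenecks ``k_h = k_v = k``.

    Substituting the demographic relatedness into the open-model ESS gives
    ``x_c* = A / (A + (k-1)*lam)`` — an algebraic identity with
    ``ess_open`` evaluated at ``R = 1/(1 + lam*(k-1))``.
    """
    k = p.k  # raises when bottlenecks differ
    a = p.benefit_exponent
    if a == 0.0:
        return EssSolution(x_star=0.0, delta_if_residual=math.nan, stable=True)
    x_star = a / (a + (k - 1.0) * p.lam)
    if x_star >= 1.0:
        return EssSolution(x_star=1.0, delta_if_residual=math.nan, stable=True)
    open_p = OpenParams(R=whole_group_relatedness_closed(p), lam=p.lam, s=p.s, f=p.f)
    residual = inclusive_fitness_effect(x_star, open_p)
    stable = inclusive_fitness_slope(x_star, open_p) <= 0.0
    return EssSolution(x_star=x_star, delta_if_residual=residual, stable=stable)


def marginal_effect_relatedness(p: OpenParams) -> float:
    """Sensitivity of the open-model ESS to relatedness, ``dx0*/dR``.

    Equals ``A / (R*(A-1) + 1)**2`` — never negative: higher relatedness
    never lowers equilibrium cooperation.
    """
    a = p.benefit_exponent
    if a == 0.0:
        return 0.0
    return a / (p.R * a + (1.0 - p.R)) ** 2


def marginal_effect_transmission(p: OpenParams) -> float:
    """Sensitivity of the open-model ESS to transmission mode, ``dx0*/dlam``.

    Equals ``-f*R*(1-R) / (R*(A-1) + 1)**2`` — never positive (more
    horizontal transmission weakens the fecundity route of the group
    benefit) and identically zero at ``R = 0`` or ``R = 1``.
    """
    numerator = -p.f * p.R * (1.0 - p.R)
    if numerator == 0.0:
        return 0.0
    a = p.benefit_exponent
    return numerator / (p.R * a + (1.0 - p.R)) ** 2


def dominant_factor_open(p: OpenParams) -> str:
    """Which lever moves equilibrium cooperation more at this point.

    Compares ``|dx0*/dlam|`` with ``|dx0*/dR|``; returns ``"transmission"``
    only on a strict win, ``"tie"`` when they agree to within ``TIE_TOL``,
    else ``"relatedness"``.
    """
    d_rel = abs(marginal_effect_relatedness(p))
    d_trans = abs(marginal_effect_transmission(p))
    if abs(d_trans - d_rel) <= TIE_TOL:
        return "tie"
    return "transmission" if d_trans > d_rel else "relatedness"


def route_decomposition_closed(p: ClosedParams) -> RouteDecomposition:
    """Split the closed-model effect of transmission mode into two routes.

    ``total = dx_c*/dlam`` bundles everything transmission mode does;
    ``direct`` is the open-model derivative ``dx0*/dlam`` evaluated at the
    demographic relatedness (the host–symbiont interest-alignment route);
    ``indirect = total - direct`` is what transmission does by eroding
    relatedness between group mates. ``ratio = |indirect|/|direct|``
    (``inf`` when the direct route vanishes, e.g. ``lam = 0`` or ``f = 0``).
    """
    k = p.k
    a = p.benefit_exponent
    den = (a + p.lam * (k - 1.0)) ** 2
    if den == 0.0:
        raise ValueError("degenerate parameters: f*(1-lam) + s + lam*(k-1) = 0")
    total = -(k - 1.0) * (p.f + p.s) / den
    direct = -p.f * p.lam * (k - 1.0) / den
    indirect = total - direct
    ratio = abs(indirect) / abs(direct) if direct != 0.0 else math.inf
    return RouteDecomposition(total=total, direct=direct, indirect=indirect, ratio=ratio)


# ---------------------------------------------------------------------------
# Independent numerical oracle
# ---------------------------------------------------------------------------


def numeric_ess_oracle(
    p: OpenParams,
    tol: float = 1e-8,
    fd_step: float = 1e-6,
    bracket_eps: float = 1e-5,
    max_iter: int = 200,
) -> float:
    """ESS found without any closed-form algebra.

    Assembles the selection gradient purely from central finite differences
    of :func:`symbiont_fitness` in ``x_i`` and ``x_g`` (the neighbour-
    modulated recipe ``dW/dx_i + R*dW/dx_g``) and locates its root by
    bracketed bisection on ``(bracket_eps, 1 - bracket_eps)``. Returns the
    nearer boundary when the gradient never changes sign. Used in tests as
    the oracle against the closed forms; never the production path.
    """

    def grad(x: float) -> float:
        # step shrinks near the poles at 0 and 1 so the stencil stays in-domain
        h = min(fd_step, 0.1 * x, 0.1 * (1.0 - x))
        lo, hi = x - h, x + h
        w_i = (
            symbiont_fitness(TraitTriple(hi, x, x), p)
            - symbiont_fitness(TraitTriple(lo, x, x), p)
        ) / (hi - lo)
        w_g = (
            symbiont_fitness(TraitTriple(x, hi, x), p)
            - symbiont_fitness(TraitTriple(x, lo, x), p)
        ) / (hi - lo)
        return w_i + p.R * w_g

    lo, hi = bracket_eps, 1.0 - bracket_eps
    g_lo, g_hi = grad(lo), grad(hi)
    if g_lo <= 0.0 and g_hi <= 0.0:
        return 0.0
    if g_lo >= 0.0 and g_hi >= 0.0:
        return 1.0 - bracket_eps
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g_mid = grad(mid)
        if g_lo * g_mid <= 0.0:
            hi, g_hi = mid, g_mid
        else:
            lo, g_lo = mid, g_mid
        if hi - lo < 1e-12:
            break
    root = 0.5 * (lo + hi)
    if abs(grad(root)) > tol * max(1.0, abs(g_lo), abs(g_hi)):
        raise RuntimeError(
            f"bisection did not converge: |gradient| = {abs(grad(root)):.3e} at x = {root}"
        )
    return root


# ---------------------------------------------------------------------------
# Threshold scanners (vectorized feasibility + bisection)
# ---------------------------------------------------------------------------


def _margins_grid(
    r: np.ndarray, lam: float, s: float, f: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized |dx0*/dR| and |dx0*/dlam| over meshed (R, f) grids."""
    a = f * (1.0 - lam) + s
    den = (r * a + (1.0 - r)) ** 2
    d_rel = a / den
    d_trans = f * r * (1.0 - r) / den
    return d_rel, d_trans


def _bisect_infimum(
    feasible: Callable[[float], bool], lo: float, hi: float, tol: float
) -> float:
    """Smallest value in [lo, hi] where `feasible` holds (assumed monotone)."""
    if feasible(lo):
        return lo
    if not feasible(hi):
        raise RuntimeError("feasible region empty on the search interval")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _default_grids(max_ratio: float) -> tuple[np.ndarray, np.ndarray]:
    r = np.linspace(0.005, 0.995, 397)  # includes 0.5, where R*(1-R) peaks
    ratio = np.geomspace(1e-2, max_ratio, 241)
    return r[:, None], ratio[None, :]


def transmission_dominance_lambda_infimum(
    max_ratio: float = 1e4, tol: float = 1e-4
) -> float:
    """Least horizontal-transmission probability at which transmission mode
    can out-influence relatedness in the open model.

    Scans ``R`` in (0, 1) and the fecundity/survival ratio ``f/s`` up to
    ``max_ratio`` (with ``s = 1``) for any point where
    ``|dx0*/dlam| > |dx0*/dR|``, and bisects the smallest such ``lam``.
    """
    r, ratio = _default_grids(max_ratio)

    def feasible(lam: float) -> bool:
        d_rel, d_trans = _margins_grid(r, lam, 1.0, ratio)
        return bool(np.any(d_trans > d_rel))

    return _bisect_infimum(feasible, 0.0, 1.0, tol)


def transmission_dominance_ratio_infimum(
    lam: float = 1.0, max_ratio: float = 1e4, tol: float = 1e-4
) -> float:
    """Least ``f/s`` ratio at which transmission mode can dominate, at a
    fixed (by default fully horizontal) transmission mode."""
    r, _ = _default_grids(max_ratio)
    r = r.ravel()

    def feasible(log_ratio: float) -> bool:
        f = np.array([math.exp(log_ratio)])
        d_rel, d_trans = _margins_grid(r[:, None], lam, 1.0, f[None, :])
        return bool(np.any(d_trans > d_rel))

    log_inf = _bisect_infimum(
        feasible, math.log(1e-2), math.log(max_ratio), tol / 4.0
    )
    return math.exp(log_inf)


def direct_route_lambda_infimum(
    max_ratio: float = 1e4, k_values: tuple[int, ...] = (2, 4, 8, 16), tol: float = 1e-4
) -> float:
    """Least ``lam`` at which transmission mode's direct route can beat its
    via-relatedness route in the closed model.

    Uses :func:`route_decomposition_closed` over a grid of ``f/s`` ratios
    (``s = 1``) and bottleneck sizes; direct dominance means ``ratio < 1``.
    """
    ratios = np.geomspace(1e-2, max_ratio, 241)

    def feasible(lam: float) -> bool:
        if lam == 0.0:
            return False  # direct route is null without horizontal transmission
        for k in k_values:
            for f in ratios:
                dec = route_decomposition_closed(
                    ClosedParams(lam=lam, k_h=k, k_v=k, s=1.0, f=float(f))
                )
                if dec.ratio < 1.0:
                    return True
        return False

    return _bisect_infimum(feasible, 0.0, 1.0, tol)
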