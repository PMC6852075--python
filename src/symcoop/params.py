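"""Parameter containers for the analytic cooperation models.

Two parameterizations are used throughout the package:

* :class:`OpenParams` — the "open" model, where the whole-group relatedness
  ``R`` between symbionts sharing a host is a free parameter alongside the
  horizontal-transmission probability ``lam``.
* :class:`ClosedParams` — the "closed" model, where relatedness is produced
  demographically by the transmission bottlenecks ``k_h`` (horizontal) and
  ``k_v`` (vertical), so transmission mode influences cooperation both
  directly and via relatedness.

Host survival and fecundity are power laws of the within-host mean
cooperation, ``s(x) = x**s`` and ``f(x) = x**f``, with the convention
``0**0 == 1`` so that an exponent of zero means "host component insensitive
to cooperation".
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0 or math.isnan(value):
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class OpenParams:
    """Parameters of the open model (relatedness left free).

    Parameters
    ----------
    R : float
        Whole-group relatedness of a focal symbiont to its host's symbiont
        group (including itself), in ``[0, 1]``.
    lam : float
        Probability that a new host is founded horizontally (from the host
        population at large) rather than vertically (from its parent),
        in ``[0, 1]``.
    s : float
        Exponent of the host-survival benefit ``s(x_g) = x_g**s``; larger
        values mean host survival rises more steeply with symbiont
        cooperation. Must be ``>= 0``.
    f : float
        Exponent of the host-fecundity benefit ``f(x_g) = x_g**f``.
        Must be ``>= 0``.
    """

    R: float
    lam: float
    s: float
    f: float

    def __post_init__(self) -> None:
        _check_prob("R", self.R)
        _check_prob("lam", self.lam)
        _check_nonneg("s", self.s)
        _check_nonneg("f", self.f)

    @property
    def benefit_exponent(self) -> float:
        """Combined group-benefit exponent ``A = f*(1 - lam) + s``."""
        return self.f * (1.0 - self.lam) + self.s


@dataclass(frozen=True)
class ClosedParams:
    """Parameters of the demographically closed model.

    Relatedness is no longer free: it follows from the transmission mode
    ``lam`` and the founding bottleneck sizes. ``k_h`` symbionts found a
    horizontally infected host, ``k_v`` a vertically infected one.
    """

    lam: float
    k_h: int
    k_v: int
    s: float
    f: float

    def __post_init__(self) -> None:
        _check_prob("lam", self.lam)
        for name, k in (("k_h", self.k_h), ("k_v", self.k_v)):
            if int(k) != k or k < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {k!r}")
        _check_nonneg("s", self.s)
        _check_nonneg("f", self.f)

    @property
    def equal_bottlenecks(self) -> bool:
        return self.k_h == self.k_v

    @property
    def k(self) -> int:
        """Common bottleneck size; only defined when ``k_h == k_v``."""
        if not self.equal_bottlenecks:
            raise ValueError(
                f"common bottleneck k undefined: k_h={self.k_h} != k_v={self.k_v}"
            )
        return self.k_h

    @property
    def benefit_exponent(self) -> float:
        """Combined group-benefit exponent ``A = f*(1 - lam) + s``."""
        return self.f * (1.0 - self.lam) + self.s


@dataclass(frozen=True)
class TraitTriple:
    """Trait values entering the focal-symbiont fitness function.

    ``x_i`` is the focal symbiont's own investment into cooperation, ``x_g``
    the mean investment of all symbionts in the focal host (including the
    focal one), and ``x_bar`` the population-wide mean. All must be < 1
    because within-host growth scales as ``(1 - x_i) / (1 - x_g)``.
    """

    x_i: float
    x_g: float
    x_bar: float

    def __post_init__(self) -> None:
        for name, v in (("x_i", self.x_i), ("x_g", self.x_g), ("x_bar", self.x_bar)):
            if math.isnan(v) or v < 0.0 or v >= 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v!r}")


@dataclass(frozen=True)
class EssSolution:
    """A candidate evolutionarily stable level of cooperation.

    ``x_star`` is the equilibrium trait value in ``[0, 1]``;
    ``delta_if_residual`` is the inclusive-fitness effect evaluated at
    ``x_star`` (NaN at boundary solutions, where the gradient has a pole);
    ``stable`` is True when the selection gradient slopes downward through
    the root, i.e. the solution is a local fitness maximum.
    """

    x_star: float
    delta_if_residual: float
    stable: bool


@dataclass(frozen=True)
class RouteDecomposition:
    """Decomposition of how transmission mode shifts the closed-model ESS.

    ``total`` is the full derivative of the closed-model equilibrium with
    respect to ``lam``; ``direct`` is the open-model derivative holding
    relatedness fixed at its demographic value; ``indirect`` is the
    remainder, i.e. the effect routed through relatedness. ``ratio`` is
    ``|indirect| / |direct|`` (``inf`` when the direct route is null).
    """

    total: float
    direct: float
    indirect: float
    ratio: float
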