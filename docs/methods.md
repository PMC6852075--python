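# Methods

## The model

We consider an obligate symbiosis: symbionts live and reproduce only
inside hosts, hosts form an effectively unstructured population with
nonoverlapping generations, and each host carries a group of `k`
symbionts. A symbiont's heritable trait `x ∈ [0, 1)` is its investment
into a service that benefits the host (e.g. provisioning a nutrient) at a
direct cost to the symbiont's own within-host growth.

Host survival and fecundity rise with the *group mean* investment `x_g`
of the symbionts it carries, as power laws `s(x_g) = x_g^s` and
`f(x_g) = x_g^f` (`0^0 = 1`, so an exponent of 0 switches that benefit
channel off). A focal symbiont's share of its host's transmission output
is its relative within-host growth `(1 − x_i)/(1 − x_g)`. New hosts are
founded horizontally, from the host population at large, with probability
`λ`, and vertically, from the parent host, with probability `1 − λ`.
Horizontal founders are weighted by host survival only; vertical founders
by survival × fecundity, because only vertically transmitted symbionts
ride on their host's reproduction. The resulting focal-symbiont fitness is

    W = (1−λ) · (1−x_i)/(1−x_g) · (x_g/x̄)^s · (x_g/x̄)^f
      +    λ  · (1−x_i)/(1−x_g) · (x_g/x̄)^s

with `x̄` the population mean. Taking neighbour-modulated derivatives at a
monomorphic point `x_i = x_g = x̄ = x` gives the selection gradient

    ΔIF(x) = −1/(1−x) + R·[ (s + f(1−λ))/x + 1/(1−x) ],

where `R` is whole-group relatedness (focal to its host group, self
included). Its root is the candidate equilibrium

    x₀* = R·A / (R·A + 1 − R),       A = f(1−λ) + s,

implemented in `ess_open`. The slope of `ΔIF` is negative at every
interior root (checked on a parameter grid), so interior equilibria are
local fitness maxima. When `R = 0` or `A = 0` the gradient is negative on
all of (0, 1) and the boundary `x* = 0` is returned, flagged stable. At
`R = 1` the gradient is positive throughout and `x* = 1`: clonal symbiont
groups have no internal conflict.

### Closing the model

Transmission mode also *generates* relatedness. With `k_h` founders per
horizontally infected host and `k_v` per vertically infected host,
whole-group relatedness at demographic equilibrium is

    R = (k_h(1−λ) + λ·k_v) / (k_h·(1 + (k_v−1)λ)),

which under equal bottlenecks (`k_h = k_v = k`) becomes
`R = 1/(1 + λ(k−1))` and yields the closed-model equilibrium

    x_c* = A / (A + (k−1)λ).

`ess_closed` and `ess_open ∘ R(λ, k)` are the same function algebraically;
the test suite asserts their agreement to 1e−12 on a 1,000+ cell grid.

### Marginal effects and route decomposition

Two comparative-statics analyses are implemented in closed form:

* **Open model** — `∂x₀*/∂R = A/(RA+1−R)²` versus
  `∂x₀*/∂λ = −fR(1−R)/(RA+1−R)²`. Transmission mode moves the equilibrium
  more than relatedness only where `fR(1−R) > A`, which requires
  `λ > 3/4`, `f > 4s`, and interior `R`; the scanners
  `transmission_dominance_*_infimum` recover the 0.75 and 4.0 thresholds
  by bisecting a vectorized feasibility test over an (R, f/s) grid.
* **Closed model** — the total effect `∂x_c*/∂λ = −(k−1)(f+s)/(A+λ(k−1))²`
  splits into the *direct* route (the open-model derivative evaluated at
  the demographic relatedness, `−fλ(k−1)/(A+λ(k−1))²`) and the *indirect*
  route via relatedness (the remainder). Their magnitude ratio is
  `A/(fλ)`; the direct route can dominate only when `λ > 1/2` and `f > s`.

All closed-form derivatives are validated against central finite
differences of the ESS functions (relative tolerance 1e−4), and the ESS
itself against `numeric_ess_oracle`, a bisection root-finder built purely
from finite differences of `W` — the oracle never shares algebra with the
production path.

## The individual-based simulator

`run_simulation` iterates the exact life cycle above at finite host number
with soft selection (weighted multinomial sampling at constant host count,
matching the relative-fitness structure of `W`):

1. per host, survival weight `x_g^s` and fecundity weight `x_g^f`;
2. each offspring host is horizontal with probability `λ`;
3. vertical hosts draw one parent host ∝ survival × fecundity, then `k`
   founders with replacement from that host ∝ `1 − x_i` (the `1 − x_g`
   normalizer cancels within a host);
4. horizontal hosts draw `k` founders with replacement from the global
   pool, symbiont weight `survival_h · (1 − x_i)/(1 − x_g(h))`;
5. each founder mutates with probability `mu`, adding a Normal(0, `sigma`)
   step reflected into `[0, x_max]`.

Parents and founders are drawn with replacement (Wright–Fisher-style
multinomial reproduction). If every weight in a required pool is zero
(e.g. all `x_g = 0` with `s > 0`) the draw falls back to uniform with a
runtime warning rather than failing.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `n_hosts` | 1000 | large enough that drift does not swamp selection at the default mutation scale; desk-scale runtime (~3 ms/generation at k = 4) |
| `mu` | 0.01 per founder | rare mutation: the trait distribution stays near mutation–selection balance |
| `sigma` | 0.02 | small steps relative to the trait range, as assumed by the gradient analysis |
| `x_init` | 0.5 | mid-range start; equilibria are start-independent (asserted for starts 0.1 and 0.9) |
| `x_max` | 1 − 1e−6 | the within-host share and the horizontal weight are singular at 1; the clonal optimum `x* = 1` is approached, never attained |
| `record_every` | 25 | trajectory resolution vs. summary cost |

Reflection (not truncation) at the trait boundaries avoids probability
mass piling on an absorbing edge. Mutation reflects at `x_max`, so runs
whose predicted optimum is the boundary (`R = 1` cells: `λ = 0` or
`k = 1`) equilibrate visibly below 1 (measured 0.91–0.97): a
mutation-load offset that is a genuine finite-population effect, not an
estimator artifact. Quantitative recovery of the analytic prediction is
therefore asserted for interior equilibria; boundary cells are asserted
qualitatively (approach to `x_max`; decay to 0 when `s = f = 0`).

### What the simulator does and does not emulate

It reproduces the analytic life cycle exactly, relaxing the analytic
assumptions of infinite population, vanishing mutational variance, and
trait-independent relatedness. It does **not** include overlapping
generations, host population structure, a free-living symbiont stage, or
host-side evolution (sanctions, partner choice). Passing tests therefore
show internal consistency of model and simulation, not realism of any
particular empirical symbiosis.

## Statistics

**Realized whole-group relatedness** is the regression form
`cov(x_i, x_g(i)) / var(x_i)` over all symbionts, with `x_g(i)` the focal
symbiont's own-group mean including itself (undefined, NaN, for a
monomorphic population). Measured at the cooperation trait itself, this
estimator can be fed back on by selection — which is precisely what makes
branched runs interesting: once cooperators concentrate in purer groups,
realized relatedness exceeds the demographic prediction `1/(1+λ(k−1))`.
An optional neutral mode tracks inherited integer lineage tags and pools
the same regression over tag indicators; it cannot be affected by
selection on the trait and recovers the demographic expectation (used in
the neutral-recovery tests).

**Mode detection** is a Gaussian KDE on `[0, x_max]` (Silverman's
bandwidth, floored at 0.005 trait units), retaining local maxima above 5%
of the global peak and merging adjacent maxima unless the valley between
them drops below 50% of the lower peak. The estimate is deterministic
given the sample.

**Branching classification**: a snapshot is polymorphic when ≥ 2 modes
each hold ≥ 5% of symbionts *and* the extreme modes are ≥ 0.1 trait units
apart; a run is branched when ≥ `min_persistence` (default 5) consecutive
recorded snapshots in the final half of the run are polymorphic. The mass
and persistence rules screen transient mutation–selection polymorphism
(the inflated-variance regime at `λ = 0`, large `k`); the separation rule
(5 mutation SDs at the default mutation scale) screens drift sub-clusters
inside a single strategy cloud, which otherwise mimic persistent
bimodality at small population sizes — including at `k = 1`, where
branching is impossible because symbionts never share a host. All four
constants are module-level and declared; the branching map is asserted
robust to ±50% changes in the mass/valley/bandwidth constants on one
simulated grid row.

## Problem sizes used in tests and the acceptance script

Analytic checks run on grids of 200–1,100 parameter combinations and
complete in seconds. Simulation checks use: 3 seeds × 1,000 hosts × 2,500+
generations for the monomorphic-plateau check (plateau time-average
0.247–0.253 against the predicted 0.25); 5 seeds × 1,000 hosts × 1,500
generations for six interior non-branching recovery configurations
(λ ∈ {0.5, 0.75, 1} × k ∈ {2, 4}); and 500 hosts × 2,000 generations per
cell for branching-region structure (branching appears at intermediate λ
with weak bottlenecks, e.g. λ = 0.25, k = 8, with realized relatedness
exceeding the demographic prediction by ≈ 0.18). Sweep-mode simulations
default to 500 hosts × 2,000 generations per cell with per-cell seeds
derived by CRC32 from the base seed and cell/replicate indices.

## Known limitations

* The mutation kernel (Bernoulli–Gaussian with reflection) is a modelling
  choice; branching onset times and the exact extent of the branched
  region depend on it, though the region's qualitative structure does not.
* At small populations (≲ 500 symbionts) KDE mode counting is noisy;
  the separation rule makes the *branching call* robust, but per-snapshot
  `n_modes` can still exceed 1 transiently.
* Boundary equilibria (`x* = 0` or 1) are reported with a NaN gradient
  residual since the selection gradient has poles there.
* The route-decomposition ratio is reported as `inf` when the direct
  route is exactly null (`λ = 0` or `f = 0`).
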