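"""Unit and property tests for the analytic equilibrium module."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from symcoop import (
    ClosedParams,
    OpenParams,
    TraitTriple,
    dominant_factor_open,
    ess_closed,
    ess_open,
    inclusive_fitness_effect,
    inclusive_fitness_slope,
    marginal_effect_relatedness,
    marginal_effect_transmission,
    numeric_ess_oracle,
    route_decomposition_closed,
    symbiont_fitness,
    whole_group_relatedness_closed,
)

probs = st.floats(0.0, 1.0)
interior_probs = st.floats(0.01, 0.99)
exponents = st.floats(0.0, 5.0)
pos_exponents = st.floats(0.05, 5.0)


def open_params_grid(n_r=6, n_lam=6, n_s=4, n_f=4):
    for r in np.linspace(0.05, 0.95, n_r):
        for lam in np.linspace(0.0, 1.0, n_lam):
            for s in np.linspace(0.25, 3.0, n_s):
                for f in np.linspace(0.25, 3.0, n_f):
                    yield OpenParams(R=float(r), lam=float(lam), s=float(s), f=float(f))


class TestSymbiontFitness:
    @pytest.mark.parametrize(
        "triple, params, expected",
        [
            # resident fitness is 1 by construction
            ((0.5, 0.5, 0.5), (0.5, 0.3, 1, 1), 1.0),
            # full defector in an average host, fully vertical transmission
            ((0.0, 0.5, 0.5), (0.5, 0.0, 1, 1), 2.0),
            # fully horizontal: the fecundity factor drops out
            ((0.5, 0.5, 0.25), (0.5, 1.0, 1, 3), 2.0),
        ],
    )
    def test_known_values(self, triple, params, expected):
        t = TraitTriple(*triple)
        p = OpenParams(*params)
        assert symbiont_fitness(t, p) == pytest.approx(expected, rel=1e-12)

    @given(x=st.floats(0.01, 0.95), lam=probs, s=exponents, f=exponents)
    def test_resident_fitness_is_one(self, x, lam, s, f):
        p = OpenParams(R=0.5, lam=lam, s=s, f=f)
        assert symbiont_fitness(TraitTriple(x, x, x), p) == pytest.approx(1.0)

    def test_trait_domain_enforced(self):
        with pytest.raises(ValueError):
            TraitTriple(1.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            TraitTriple(0.5, -0.1, 0.5)

    def test_zero_population_mean_rejected_when_benefits_active(self):
        p = OpenParams(R=0.5, lam=0.5, s=1, f=1)
        with pytest.raises(ValueError):
            symbiont_fitness(TraitTriple(0.0, 0.0, 0.0), p)
        # but fine when both exponents are zero (0**0 == 1 convention)
        neutral = OpenParams(R=0.5, lam=0.5, s=0, f=0)
        assert symbiont_fitness(TraitTriple(0.0, 0.0, 0.0), neutral) == 1.0


class TestInclusiveFitnessEffect:
    @pytest.mark.parametrize(
        "x, params, expected",
        [
            (0.5, (1.0, 0.0, 1, 1), 4.0),
            (0.5, (0.0, 0.7, 2, 3), -2.0),
        ],
    )
    def test_known_values(self, x, params, expected):
        assert inclusive_fitness_effect(x, OpenParams(*params)) == pytest.approx(expected)

    def test_zero_at_interior_ess(self):
        p = OpenParams(R=0.4, lam=0.3, s=1.0, f=2.0)
        x = ess_open(p).x_star
        assert abs(inclusive_fitness_effect(x, p)) < 1e-12

    @given(x=st.floats(0.05, 0.95), R=interior_probs, lam=probs,
           s=pos_exponents, f=pos_exponents)
    def test_matches_finite_differences_of_fitness(self, x, R, lam, s, f):
        """The closed-form gradient equals dW/dx_i + R*dW/dx_g numerically."""
        p = OpenParams(R=R, lam=lam, s=s, f=f)
        h = 1e-6
        w_i = (
            symbiont_fitness(TraitTriple(x + h, x, x), p)
            - symbiont_fitness(TraitTriple(x - h, x, x), p)
        ) / (2 * h)
        w_g = (
            symbiont_fitness(TraitTriple(x, x + h, x), p)
            - symbiont_fitness(TraitTriple(x, x - h, x), p)
        ) / (2 * h)
        expected = w_i + R * w_g
        got = inclusive_fitness_effect(x, p)
        assert got == pytest.approx(expected, rel=1e-4, abs=1e-6)

    def test_poles_rejected(self):
        p = OpenParams(R=0.5, lam=0.5, s=1, f=1)
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                inclusive_fitness_effect(bad, p)


class TestEssOpen:
    @pytest.mark.parametrize(
        "params, expected",
        [
            ((1.0, 0.5, 1, 1), 1.0),  # clonal symbionts cooperate fully
            ((0.0, 0.2, 1, 2), 0.0),  # unrelated symbionts do not cooperate
            ((0.25, 0.5, 1, 2), 0.4),
        ],
    )
    def test_known_values(self, params, expected):
        assert ess_open(OpenParams(*params)).x_star == pytest.approx(expected, abs=1e-12)

    def test_boundary_and_clonal_solutions_flagged_stable(self):
        assert ess_open(OpenParams(0.0, 0.5, 1, 1)).stable
        assert ess_open(OpenParams(1.0, 0.5, 1, 1)).stable
        assert ess_open(OpenParams(0.3, 1.0, 0.0, 2.0)).x_star == 0.0  # A = 0

    def test_matches_bisection_oracle_on_grid(self):
        """>=200 parameter combinations: closed form vs pure finite-difference
        bisection agree to 1e-6."""
        count = 0
        for p in open_params_grid(5, 4, 4, 4):
            assert abs(ess_open(p).x_star - numeric_ess_oracle(p)) < 1e-6
            count += 1
        assert count >= 200

    def test_stability_at_interior_ess(self):
        for p in open_params_grid(5, 4, 3, 3):
            sol = ess_open(p)
            if 0.0 < sol.x_star < 1.0:
                assert sol.stable
                assert inclusive_fitness_slope(sol.x_star, p) < 0

    @given(R=probs, lam=probs, s=exponents, f=exponents)
    def test_range(self, R, lam, s, f):
        x = ess_open(OpenParams(R, lam, s, f)).x_star
        assert 0.0 <= x <= 1.0

    def test_monotonicity(self):
        grid = np.linspace(0.05, 0.95, 10)
        base = dict(R=0.4, lam=0.4, s=1.0, f=1.5)
        for name, sign in (("R", +1), ("s", +1), ("f", +1), ("lam", -1)):
            values = [
                ess_open(OpenParams(**{**base, name: float(v)})).x_star for v in grid
            ]
            diffs = sign * np.diff(values)
            assert np.all(diffs >= -1e-12), f"not monotone in {name}"

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            OpenParams(R=1.2, lam=0.5, s=1, f=1)
        with pytest.raises(ValueError):
            OpenParams(R=0.5, lam=-0.1, s=1, f=1)
        with pytest.raises(ValueError):
            OpenParams(R=0.5, lam=0.5, s=-1, f=1)


class TestWholeGroupRelatedness:
    @pytest.mark.parametrize(
        "lam, k_h, k_v, expected",
        [
            (0.0, 10, 10, 1.0),  # full vertical transmission: clonal groups
            (1.0, 4, 7, 0.25),  # full horizontal: 1/k_h
            (0.5, 2, 10, 6.0 / 11.0),
            (0.0, 3, 17, 1.0),
        ],
    )
    def test_known_values(self, lam, k_h, k_v, expected):
        p = ClosedParams(lam=lam, k_h=k_h, k_v=k_v, s=1, f=1)
        assert whole_group_relatedness_closed(p) == pytest.approx(expected, abs=1e-15)

    @given(lam=probs, k_h=st.integers(1, 50), k_v=st.integers(1, 50))
    def test_range(self, lam, k_h, k_v):
        r = whole_group_relatedness_closed(ClosedParams(lam, k_h, k_v, 1, 1))
        assert 0.0 < r <= 1.0

    def test_equal_bottleneck_simplification_nonincreasing(self):
        lams = np.linspace(0, 1, 11)
        for k in (1, 2, 5, 20):
            vals = [
                whole_group_relatedness_closed(ClosedParams(float(l), k, k, 1, 1))
                for l in lams
            ]
            assert np.all(np.diff(vals) <= 1e-15)
            expected = 1.0 / (1.0 + lams * (k - 1))
            np.testing.assert_allclose(vals, expected, atol=1e-15)
        for lam in (0.2, 0.8):
            vals = [
                whole_group_relatedness_closed(ClosedParams(lam, k, k, 1, 1))
                for k in (1, 2, 4, 8, 16)
            ]
            assert np.all(np.diff(vals) <= 0)

    def test_bottlenecks_validated(self):
        with pytest.raises(ValueError):
            ClosedParams(lam=0.5, k_h=0, k_v=3, s=1, f=1)
        with pytest.raises(ValueError):
            ClosedParams(lam=0.5, k_h=2.5, k_v=3, s=1, f=1)


class TestEssClosed:
    @pytest.mark.parametrize(
        "lam, k, s, f, expected",
        [
            (1.0, 4, 1, 1, 0.25),  # the simulated monomorphic plateau value
            (0.0, 20, 1, 1, 1.0),
            (0.5, 10, 1, 2, 2.0 / 6.5),
        ],
    )
    def test_known_values(self, lam, k, s, f, expected):
        p = ClosedParams(lam=lam, k_h=k, k_v=k, s=s, f=f)
        assert ess_closed(p).x_star == pytest.approx(expected, abs=1e-12)

    def test_identity_with_open_model_on_grid(self):
        """ess_closed == ess_open at the demographic relatedness, to 1e-12,
        over a >=1000-cell grid (algebraic identity)."""
        cells = 0
        for lam in np.linspace(0.0, 1.0, 11):
            for k in (1, 2, 3, 4, 6, 8, 12, 16, 24, 32):
                for s, f in [(1, 1), (0.5, 2), (2, 0.5), (1, 3), (3, 1),
                             (0.25, 0.25), (2, 2), (1, 0.1), (0.1, 1), (4, 4)]:
                    p = ClosedParams(lam=float(lam), k_h=k, k_v=k, s=s, f=f)
                    r = whole_group_relatedness_closed(p)
                    via_open = ess_open(OpenParams(R=r, lam=float(lam), s=s, f=f))
                    assert abs(ess_closed(p).x_star - via_open.x_star) < 1e-12
                    cells += 1
        assert cells >= 1000

    def test_unequal_bottlenecks_rejected(self):
        with pytest.raises(ValueError):
            ess_closed(ClosedParams(lam=0.5, k_h=2, k_v=3, s=1, f=1))

    def test_monotone_in_lam_and_k(self):
        for k in (2, 4, 8):
            vals = [
                ess_closed(ClosedParams(float(l), k, k, 1, 1)).x_star
                for l in np.linspace(0, 1, 11)
            ]
            assert np.all(np.diff(vals) <= 1e-15)
        for lam in (0.3, 0.9):
            vals = [
                ess_closed(ClosedParams(lam, k, k, 1, 1)).x_star
                for k in (1, 2, 4, 8, 16)
            ]
            assert np.all(np.diff(vals) <= 1e-15)


class TestMarginalEffects:
    def test_known_values(self):
        p = OpenParams(R=0.5, lam=0.0, s=1, f=1)
        assert marginal_effect_relatedness(p) == pytest.approx(2 / 2.25)
        assert marginal_effect_transmission(p) == pytest.approx(-0.25 / 2.25)

    def test_degenerate_zeros(self):
        # A = 0: the ESS is identically 0 in R, so the relatedness margin vanishes
        assert marginal_effect_relatedness(OpenParams(0.5, 1.0, 0.0, 3.0)) == 0.0
        # R*(1-R) = 0: clonal or unrelated symbionts are insensitive to lam
        assert marginal_effect_transmission(OpenParams(1.0, 0.5, 1, 1)) == 0.0
        assert marginal_effect_transmission(OpenParams(0.0, 0.5, 1, 1)) == 0.0

    def test_finite_difference_oracle(self):
        """Closed-form marginal effects match central finite differences of
        ess_open to 1e-4 relative error."""
        h = 1e-6
        for p in open_params_grid(5, 4, 3, 3):
            if not (h < p.R < 1 - h):
                continue
            fd_r = (
                ess_open(OpenParams(p.R + h, p.lam, p.s, p.f)).x_star
                - ess_open(OpenParams(p.R - h, p.lam, p.s, p.f)).x_star
            ) / (2 * h)
            assert marginal_effect_relatedness(p) == pytest.approx(
                fd_r, rel=1e-4, abs=1e-8
            )
            if h < p.lam < 1 - h:
                fd_l = (
                    ess_open(OpenParams(p.R, p.lam + h, p.s, p.f)).x_star
                    - ess_open(OpenParams(p.R, p.lam - h, p.s, p.f)).x_star
                ) / (2 * h)
                assert marginal_effect_transmission(p) == pytest.approx(
                    fd_l, rel=1e-4, abs=1e-8
                )

    @given(R=probs, lam=probs, s=exponents, f=exponents)
    def test_signs(self, R, lam, s, f):
        p = OpenParams(R, lam, s, f)
        assert marginal_effect_relatedness(p) >= 0.0
        assert marginal_effect_transmission(p) <= 0.0


class TestDominantFactor:
    @pytest.mark.parametrize(
        "params, expected",
        [
            ((0.5, 0.9, 0.1, 10), "transmission"),  # mostly horizontal, f >> s
            ((0.5, 0.5, 1, 1), "relatedness"),
            ((1.0, 0.5, 1, 1), "relatedness"),  # clonal: transmission effect is 0
            ((0.0, 0.5, 1, 1), "relatedness"),
        ],
    )
    def test_labels(self, params, expected):
        assert dominant_factor_open(OpenParams(*params)) == expected

    def test_tie_on_exact_equality(self):
        # f*R*(1-R) == f*(1-lam) + s at R=0.5, lam=1, s=1, f=4
        assert dominant_factor_open(OpenParams(0.5, 1.0, 1.0, 4.0)) == "tie"


class TestRouteDecomposition:
    def test_known_ratios(self):
        dec = route_decomposition_closed(ClosedParams(0.5, 4, 4, 1, 1))
        assert dec.ratio == pytest.approx(3.0)
        dec2 = route_decomposition_closed(ClosedParams(1.0, 4, 4, 1, 2))
        assert dec2.ratio == pytest.approx(0.5)

    def test_vertical_limit_ratio_infinite(self):
        dec = route_decomposition_closed(ClosedParams(0.0, 4, 4, 1, 1))
        assert math.isinf(dec.ratio)
        assert dec.direct == 0.0

    @given(lam=st.floats(0.05, 1.0), k=st.integers(2, 20),
           s=pos_exponents, f=pos_exponents)
    def test_routes_sum_to_total(self, lam, k, s, f):
        dec = route_decomposition_closed(ClosedParams(lam, k, k, s, f))
        assert dec.total == pytest.approx(dec.direct + dec.indirect, rel=1e-12)

    def test_total_matches_finite_difference_of_closed_ess(self):
        h = 1e-6
        for lam in (0.2, 0.5, 0.9):
            for k in (2, 4, 8):
                for s, f in [(1, 1), (0.5, 2), (2, 0.5)]:
                    fd = (
                        ess_closed(ClosedParams(lam + h, k, k, s, f)).x_star
                        - ess_closed(ClosedParams(lam - h, k, k, s, f)).x_star
                    ) / (2 * h)
                    dec = route_decomposition_closed(ClosedParams(lam, k, k, s, f))
                    assert dec.total == pytest.approx(fd, rel=1e-4)

    def test_direct_matches_open_margin_at_demographic_relatedness(self):
        for lam in (0.2, 0.5, 0.9):
            for k in (2, 4, 8):
                p = ClosedParams(lam, k, k, 1.0, 2.0)
                r = whole_group_relatedness_closed(p)
                margin = marginal_effect_transmission(OpenParams(r, lam, 1.0, 2.0))
                dec = route_decomposition_closed(p)
                assert dec.direct == pytest.approx(margin, rel=1e-12)


class TestNumericOracle:
    def test_boundary_cases(self):
        assert numeric_ess_oracle(OpenParams(0.0, 0.3, 1, 1)) == 0.0
        assert numeric_ess_oracle(OpenParams(1.0, 0.3, 1, 1)) > 0.999

    def test_interior_agreement(self):
        p = OpenParams(0.5, 0.0, 1, 1)
        assert numeric_ess_oracle(p) == pytest.approx(2.0 / 3.0, abs=1e-6)
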