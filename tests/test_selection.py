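"""Per-locus genetics: genotype variance, the exact two-sex recursion,
equilibrium solving, regime classification, and closed-form limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sexsel import (
    REGIME_BALANCING,
    REGIME_FIXATION,
    REGIME_MSB,
    LocusSelection,
    balancing_approx,
    classify_regime,
    delta_q,
    heterozygosity,
    msb_approx,
    solve_equilibrium,
    step_recursion,
    susceptibility_variance,
    sweep,
    variance_contribution,
    weak_selection_equilibrium,
)

U = 1e-6


# ---------------------------------------------------------------- types


class TestLocusValidation:
    def test_rejects_nonpositive_s(self):
        with pytest.raises(ValueError, match="s must be > 0"):
            LocusSelection(s=-0.01, t=0.01, u=U)

    @pytest.mark.parametrize("s,t", [(0.5, 0.01), (0.01, 0.6), (0.01, -0.51)])
    def test_rejects_lethal_genotypes(self, s, t):
        with pytest.raises(ValueError, match="fitnesses"):
            LocusSelection(s=s, t=t, u=U)

    @pytest.mark.parametrize("u", [-1e-6, 1.0])
    def test_rejects_bad_mutation_rate(self, u):
        with pytest.raises(ValueError, match="mutation rate"):
            LocusSelection(s=0.01, t=0.01, u=u)

    def test_disease_effect_consistency(self):
        LocusSelection(s=0.01, t=0.0, u=U, gamma_effect=0.02, c=0.5)
        with pytest.raises(ValueError, match="inconsistent"):
            LocusSelection(s=0.01, t=0.0, u=U, gamma_effect=0.02, c=1.0)


# ------------------------------------------------- susceptibility variance


@pytest.mark.parametrize(
    "p,q,gamma,expected",
    [
        (0.5, 0.5, 1.0, 0.5),  # maximal heterozygosity, unit effect
        (1.0, 0.0, 5.0, 0.0),  # monomorphic locus
        (0.9, 0.1, 2.0, 0.72),
    ],
)
def test_susceptibility_variance(p, q, gamma, expected):
    assert susceptibility_variance(p, q, gamma) == pytest.approx(expected)


def test_susceptibility_variance_rejects_inconsistent_frequencies():
    with pytest.raises(ValueError, match="sum to 1"):
        susceptibility_variance(0.5, 0.4, 1.0)


# ------------------------------------------------------------- recursion


def test_boundary_mutational_input():
    locus = LocusSelection(s=0.01, t=0.01, u=U)
    assert step_recursion(0.0, locus) == pytest.approx(U)


def test_absorbing_boundary_without_mutation():
    locus = LocusSelection(s=0.01, t=0.01, u=0.0)
    assert step_recursion(0.0, locus) == 0.0


def test_selection_removes_allele_above_msb_frequency():
    # above 2u/(s+t), purifying selection outweighs mutational input
    locus = LocusSelection(s=0.01, t=0.01, u=U)
    assert step_recursion(0.01, locus) < 0.01
    assert step_recursion(2 * U / 0.02 / 2, locus) > U / 0.02  # below it, input wins


@settings(max_examples=200, derandomize=True)
@given(
    log_s=st.floats(-4, -1.2),
    ratio=st.floats(-1.5, 2.5),
    log_u=st.floats(-8, -5),
    q=st.floats(0.0, 1.0),
)
def test_recursion_matches_weak_selection_expansion(log_s, ratio, log_u, q):
    """dq from the exact life cycle agrees with the weak-selection
    expansion u(1-q) - q(1-q)[(s+t)/2 + q(s^2+t^2)] to cubic order."""
    s = 10.0**log_s
    t = s * ratio
    u = 10.0**log_u
    if 2 * abs(t) >= 1:
        return
    locus = LocusSelection(s=s, t=t, u=u)
    exact = delta_q(q, locus)
    approx = u * (1 - q) - q * (1 - q) * ((s + t) / 2 + q * (s * s + t * t))
    bound = 10 * (abs(s) + abs(t)) ** 3 + 2 * u * (abs(s) + abs(t)) + 1e-18
    assert abs(exact - approx) <= bound


# ------------------------------------------------------- regime labels


@pytest.mark.parametrize(
    "s,t,regime",
    [
        (0.01, 0.01, REGIME_MSB),
        (0.01, -0.0102, REGIME_BALANCING),  # 4st = -4.08e-4 < s+t = -2e-4 < 0
        (0.01, -0.02, REGIME_FIXATION),  # s+t = -0.01 but 4st = -8e-4 is not smaller
        (0.01, -0.01, REGIME_MSB),  # s+t = 0: net selection not negative
        (0.01, 0.0, REGIME_MSB),
    ],
)
def test_classify_regime(s, t, regime):
    assert classify_regime(s, t) == regime


def test_classify_regime_requires_deleterious_in_sex1():
    with pytest.raises(ValueError):
        classify_regime(0.0, 0.01)


# --------------------------------------------------- closed-form helpers


@pytest.mark.parametrize(
    "s,t,u,expected",
    [
        (0.01, 0.01, U, 1e-4),
        (0.02, 0.0, U, 1e-4),  # sex-limited cost: the s >> t limit
        (1e-8, 1e-8, U, 1.0),  # cap engaged
    ],
)
def test_msb_approx(s, t, u, expected):
    assert msb_approx(s, t, u) == pytest.approx(expected)


def test_msb_approx_rejects_net_beneficial():
    with pytest.raises(ValueError):
        msb_approx(0.01, -0.02, U)


@pytest.mark.parametrize("q,expected", [(0.5, 0.5), (0.0, 0.0), (1e-4, 1.9998e-4)])
def test_heterozygosity(q, expected):
    assert heterozygosity(q) == pytest.approx(expected, rel=1e-12)


def test_variance_contribution_asymmetry_doubling():
    """A sex-limited allele (t=0) contributes ~4us to sex-1 variance,
    twice the ~2us of a symmetrically selected allele."""
    s = 0.01
    v_sym, _ = variance_contribution(
        LocusSelection(s=s, t=s, u=U), msb_approx(s, s, U)
    )
    v_lim, v2_lim = variance_contribution(
        LocusSelection(s=s, t=0.0, u=U), msb_approx(s, 0.0, U)
    )
    assert v_sym == pytest.approx(2 * U * s, rel=1e-3)
    assert v_lim == pytest.approx(4 * U * s, rel=1e-3)
    assert v2_lim == 0.0
    assert variance_contribution(LocusSelection(s=s, t=s, u=U), 0.0) == (0.0, 0.0)


# ------------------------------------------------------------- solver


class TestSolveEquilibrium:
    def test_symmetric_msb(self):
        res = solve_equilibrium(LocusSelection(s=0.01, t=0.01, u=U))
        assert res.regime == REGIME_MSB
        assert res.q_eq == pytest.approx(2 * U / 0.02, rel=1e-3)
        assert res.residual <= 1e-12

    def test_balancing_locus(self):
        # exact root sits near 0.50: mutation pressure shifts the
        # selection-only point 0.4901 by O(u/s^2)
        res = solve_equilibrium(LocusSelection(s=0.01, t=-0.0102, u=U))
        assert res.regime == REGIME_BALANCING
        assert res.q_eq == pytest.approx(balancing_approx(0.01, -0.0102), rel=0.05)
        assert 0.45 < res.q_eq < 0.55
        assert res.H == pytest.approx(2 * res.q_eq * (1 - res.q_eq))

    def test_no_mutation_purifying_fixes_wild_type(self):
        res = solve_equilibrium(LocusSelection(s=0.02, t=0.02, u=0.0))
        assert res.q_eq == 0.0

    def test_fixation_regime_reaches_boundary(self):
        res = solve_equilibrium(LocusSelection(s=0.005, t=-0.02, u=U))
        assert res.regime == REGIME_FIXATION
        assert res.q_eq == 1.0
        assert res.H == 0.0

    def test_mutation_pressure_near_fixation_flagged(self):
        # net selection far weaker than mutation: deterministic recursion
        # drives the allele toward fixation
        res = solve_equilibrium(LocusSelection(s=1e-8, t=1e-8, u=U))
        assert res.regime == REGIME_MSB
        assert res.q_eq > 0.999
        assert res.near_fixation

    @settings(max_examples=100, derandomize=True)
    @given(
        log_s=st.floats(-4, -0.7),
        ratio=st.floats(-1.5, 2.5),
        log_u=st.floats(-8, -5),
    )
    def test_fixed_point_property(self, log_s, ratio, log_u):
        """The reported equilibrium is a fixed point of the exact recursion."""
        s = 10.0**log_s
        t = s * ratio
        if 2 * abs(t) >= 1:
            return
        locus = LocusSelection(s=s, t=t, u=10.0**log_u)
        res = solve_equilibrium(locus)
        assert res.residual <= 1e-12
        assert step_recursion(res.q_eq, locus) == pytest.approx(res.q_eq, abs=1e-12)

    def test_msb_limit(self):
        """Where net purifying selection dominates mutation (s+t >= 100u),
        the solver agrees with 2u/(s+t) within 5%."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = 10 ** rng.uniform(-3.5, -0.7)
            t = s * rng.uniform(-0.9, 2.0)
            if s + t < 100 * U or 2 * abs(t) >= 1:
                continue
            q = solve_equilibrium(LocusSelection(s=s, t=t, u=U)).q_eq
            assert abs(q - msb_approx(s, t, U)) / q < 0.05

    @pytest.mark.parametrize("s,eps", [(0.01, 1.02), (0.02, 1.02), (0.05, 1.02), (0.1, 1.02)])
    def test_balancing_limit(self, s, eps):
        """In the balancing region, with the interior root well developed
        against mutation pressure (|s+t| >> max(s,|t|) sqrt(u)), the solver
        agrees with -(s+t)/(2(s^2+t^2)) within 5%."""
        t = -s * eps
        assert classify_regime(s, t) == REGIME_BALANCING
        assert abs(s + t) >= 13 * max(s, abs(t)) * np.sqrt(U)  # validity region
        q = solve_equilibrium(LocusSelection(s=s, t=t, u=U)).q_eq
        assert abs(q - balancing_approx(s, t)) / q < 0.05

    def test_asymmetry_doubling_from_solver(self):
        s = 0.02
        v_lim = solve_equilibrium(LocusSelection(s=s, t=0.0, u=U)).v1
        v_sym = solve_equilibrium(LocusSelection(s=s, t=s, u=U)).v1
        assert v_lim / v_sym == pytest.approx(2.0, rel=0.01)


def test_sweep_monotone_in_asymmetry():
    """Equilibrium frequency and heterozygosity are non-increasing in t/s
    at fixed s over the polymorphic range [-0.5, 2]."""
    table = sweep(s_values=(0.005, 0.01, 0.02), ts_min=-0.5, ts_max=2.0, ts_step=0.05, u=U)
    for _, grp in table.groupby("s"):
        g = grp.sort_values("t_over_s")
        assert np.all(np.diff(g["q_eq"]) <= 1e-15)
        assert np.all(np.diff(g["H"]) <= 1e-15)
        assert np.all(g["q_eq"] > 0)


def test_weak_selection_equilibrium_matches_solver():
    """The vectorised fast path agrees with the exact solver across
    purifying-selection loci."""
    rng = np.random.default_rng(1)
    s = 10 ** rng.uniform(-4, -0.8, 50)
    t = s * rng.uniform(0.0, 2.0, 50)
    q_fast = weak_selection_equilibrium(s, t, U)
    q_exact = np.array(
        [solve_equilibrium(LocusSelection(s=si, t=ti, u=U)).q_eq for si, ti in zip(s, t)]
    )
    np.testing.assert_allclose(q_fast, q_exact, rtol=1e-3)
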