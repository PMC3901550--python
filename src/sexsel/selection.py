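"""Per-locus population genetics of a biallelic disease locus under
sex-specific selection.

A disease-predisposing allele at an autosomal locus raises disease
susceptibility additively (0, gamma, 2*gamma per genotype) and carries a
proportional fitness cost in the focal sex ("sex 1": fitnesses 1, 1-s,
1-2s per disease-allele copy) and a possibly different cost or benefit in
the other sex ("sex 2": 1, 1-t, 1-2t; t < 0 means the allele is
beneficial to sex 2, i.e. sexually antagonistic). The life cycle is:
Hardy-Weinberg genotype formation, sex-specific viability selection,
equal-weight averaging of post-selection allele frequencies across the
sexes (allele frequencies are assumed equal between the sexes), then
one-way recurrent mutation wild-type -> disease at rate ``u`` per gamete.

The per-generation change admits an exact, cancellation-free factorisation

    dq = (1 - q) * g(q),   g(q) = u - (1 - u) * q * S(q) / 2,
    S(q) = s / (1 - 2 s q) + t / (1 - 2 t q),

which this module uses both for stepping the recursion and for root
finding. Because S is strictly increasing in q whenever the genotype
fitnesses are positive, g has at most one root in (0, 1); when no interior
root exists the disease allele fixes (or is pushed to fixation by mutation
pressure when selection is weaker than the mutation rate).

Selection regimes: with s > 0 the polymorphism is maintained indefinitely
by selection alone when 4st < s+t < 0 (balancing selection); when s+t < 0
without that condition the disease allele fixes; otherwise variation is
held at mutation-selection balance with the classical approximation
q_eq ~ 2u/(s+t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "REGIME_MSB",
    "REGIME_BALANCING",
    "REGIME_FIXATION",
    "LocusSelection",
    "EquilibriumResult",
    "susceptibility_variance",
    "step_recursion",
    "delta_q",
    "iterate_recursion",
    "classify_regime",
    "solve_equilibrium",
    "msb_approx",
    "balancing_approx",
    "heterozygosity",
    "variance_contribution",
    "weak_selection_equilibrium",
    "sweep",
    "solve_locus_table",
    "read_locus_table",
    "write_locus_table",
]

REGIME_MSB = "mutation_selection_balance"
REGIME_BALANCING = "balancing_selection"
REGIME_FIXATION = "disease_fixation"

#: q_eq above this, with net purifying selection weaker than mutation,
#: is reported with the ``near_fixation`` diagnostic flag.
_NEAR_FIXATION_Q = 1.0 - 1e-6

LOCUS_TABLE_COLUMNS = ["locus_id", "s", "t", "u", "q_eq", "regime", "H", "v1", "v2"]


@dataclass(frozen=True)
class LocusSelection:
    """Selection, mutation and (optional) disease-effect parameters of one locus.

    Parameters
    ----------
    s
        Fitness cost per disease-allele copy in sex 1 (additive; must be
        positive: the allele is deleterious in the focal sex).
    t
        Fitness effect per copy in sex 2; negative values are sexually
        antagonistic (beneficial to sex 2).
    u
        One-way mutation rate wild-type -> disease, per gamete per
        generation.
    gamma_effect
        Disease effect size per allele copy (arbitrary units). Optional;
        when given it must satisfy s = c * gamma_effect.
    c
        Positive constant mapping disease effect to fitness cost.
    """

    s: float
    t: float
    u: float
    gamma_effect: float | None = None
    c: float = 1.0

    def __post_init__(self) -> None:
        if not (self.s > 0.0):
            raise ValueError(f"s must be > 0 (disease allele deleterious in sex 1), got {self.s}")
        if not (2.0 * abs(self.s) < 1.0 and 2.0 * abs(self.t) < 1.0):
            raise ValueError(
                f"genotype fitnesses must stay positive: need 2|s| < 1 and 2|t| < 1, got s={self.s}, t={self.t}"
            )
        if not (0.0 <= self.u < 1.0):
            raise ValueError(f"mutation rate must satisfy 0 <= u < 1, got {self.u}")
        if not (self.c > 0.0):
            raise ValueError(f"c must be positive, got {self.c}")
        if self.gamma_effect is not None:
            expected = self.c * self.gamma_effect
            if abs(self.s - expected) > 1e-9 * max(1.0, abs(self.s)):
                raise ValueError(
                    f"inconsistent disease effect: s={self.s} but c*gamma_effect={expected}"
                )


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium state of one locus.

    Attributes
    ----------
    q_eq
        Equilibrium disease-allele frequency in [0, 1].
    regime
        One of ``mutation_selection_balance``, ``balancing_selection``,
        ``disease_fixation`` (classified from the selection coefficients).
    H
        Heterozygosity 2 q (1 - q) at equilibrium.
    v1, v2
        Per-sex additive variance contributions 2 q (1 - q) s^2 and
        2 q (1 - q) t^2.
    residual
        |dq| evaluated at the reported root.
    near_fixation
        True when net selection is too weak to oppose recurrent mutation
        and the deterministic recursion drives the allele to (near)
        fixation despite a mutation-selection-balance classification.
    """

    q_eq: float
    regime: str
    H: float
    v1: float
    v2: float
    residual: float
    near_fixation: bool = False


def susceptibility_variance(p: float, q: float, gamma_effect: float) -> float:
    """Contribution 2 p q gamma^2 of a locus to population variance in
    disease susceptibility, with genotype effects (0, gamma, 2 gamma).
    """
    if abs(p + q - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1, got p + q = {p + q}")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must lie in [0, 1], got {q}")
    return 2.0 * p * q * gamma_effect**2


def _selection_sum(q, s, t):
    """S(q) = s/(1-2sq) + t/(1-2tq); strictly increasing in q."""
    return s / (1.0 - 2.0 * s * q) + t / (1.0 - 2.0 * t * q)


def _g(q, s, t, u):
    """dq = (1-q) g(q); cancellation-free residual function."""
    return u - (1.0 - u) * 0.5 * q * _selection_sum(q, s, t)


def delta_q(q: float, locus: LocusSelection) -> float:
    """Exact per-generation change in disease-allele frequency."""
    return (1.0 - q) * _g(q, locus.s, locus.t, locus.u)


def step_recursion(q: float, locus: LocusSelection) -> float:
    """One generation of the exact two-sex viability-selection + mutation
    life cycle; returns the next-generation frequency, clamped to [0, 1].
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"frequency must lie in [0, 1], got {q}")
    wbar1 = 1.0 - 2.0 * locus.s * q
    wbar2 = 1.0 - 2.0 * locus.t * q
    if wbar1 <= 0.0 or wbar2 <= 0.0:
        raise ValueError("mean fitness non-positive in one sex (locus invariant violated)")
    return min(1.0, max(0.0, q + delta_q(q, locus)))


def iterate_recursion(
    locus: LocusSelection,
    q0: float | None = None,
    max_iter: int = 1_000_000,
    stop_delta: float = 0.0,
) -> tuple[float, int]:
    """Iterate the exact recursion from ``q0`` (default: u, the fate of a
    recurrent new mutation). Returns (frequency, iterations used). Stops
    early once |dq| <= stop_delta.

    This is the brute-force dynamical oracle for the root solver: slow but
    with no root-finding machinery of its own.
    """
    q = locus.u if q0 is None else q0
    for i in range(max_iter):
        dq = delta_q(q, locus)
        q = min(1.0, max(0.0, q + dq))
        if abs(dq) <= stop_delta:
            return q, i + 1
    return q, max_iter


def classify_regime(s: float, t: float) -> str:
    """Selection regime from the sex-specific coefficients (s > 0 required).

    Balancing selection maintains the polymorphism indefinitely iff
    4st < s+t < 0; s+t < 0 without that condition fixes the disease
    allele; otherwise mutation-selection balance.
    """
    if not (s > 0.0):
        raise ValueError(f"s must be > 0, got {s}")
    if s + t < 0.0:
        return REGIME_BALANCING if 4.0 * s * t < s + t else REGIME_FIXATION
    return REGIME_MSB


def msb_approx(s: float, t: float, u: float) -> float:
    """Classical mutation-selection-balance frequency 2u/(s+t), capped at 1.

    Only defined for net purifying selection (s + t > 0).
    """
    if s + t <= 0.0:
        raise ValueError("msb_approx requires s + t > 0 (net purifying selection)")
    if u < 0.0:
        raise ValueError(f"mutation rate must be non-negative, got {u}")
    return min(1.0, 2.0 * u / (s + t))


def balancing_approx(s: float, t: float) -> float:
    """Weak-selection interior equilibrium -(s+t) / (2 (s^2+t^2)) under
    balancing selection (4st < s+t < 0), ignoring mutation."""
    if classify_regime(s, t) != REGIME_BALANCING:
        raise ValueError("balancing_approx requires 4st < s+t < 0")
    return -(s + t) / (2.0 * (s * s + t * t))


def heterozygosity(q):
    """H = 2 q (1 - q); accepts scalars or arrays."""
    qa = np.asarray(q, dtype=float)
    if np.any(qa < 0.0) or np.any(qa > 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    out = 2.0 * qa * (1.0 - qa)
    return float(out) if np.isscalar(q) else out


def variance_contribution(locus: LocusSelection, q_eq: float) -> tuple[float, float]:
    """Per-sex additive variance contributions (2 q(1-q) s^2, 2 q(1-q) t^2)."""
    if not (0.0 <= q_eq <= 1.0):
        raise ValueError(f"q_eq must lie in [0, 1], got {q_eq}")
    pq2 = 2.0 * q_eq * (1.0 - q_eq)
    return pq2 * locus.s**2, pq2 * locus.t**2


def solve_equilibrium(locus: LocusSelection, tol: float = 1e-12) -> EquilibriumResult:
    """Equilibrium frequency of the disease allele: the stable root of
    dq = 0 in [0, 1] reachable from q0 = u.

    Roots are located by bracketed Brent iteration on the residual
    g(q) = u - (1-u) q S(q)/2 (dq = (1-q) g(q)). S(q) is strictly
    increasing on (0, 1), so g has at most one interior root and it is
    the stable equilibrium approached from q0 = u; when g has no sign
    change on (0, 1) the boundary q = 1 is the attractor (disease
    fixation, or near-fixation by mutation pressure on effectively
    neutral loci).
    """
    if not (tol > 0.0):
        raise ValueError("tol must be positive")
    s, t, u = locus.s, locus.t, locus.u
    regime = classify_regime(s, t)
    near_fix = False

    if u == 0.0:
        if regime == REGIME_BALANCING:
            # selection-only interior root where S(q) = 0
            hi = 1.0 - 1e-12
            q = brentq(_selection_sum, 1e-15, hi, args=(s, t), xtol=1e-15)
        elif regime == REGIME_FIXATION:
            q = 1.0
        else:
            q = 0.0
    else:
        lo = min(u, 1e-15)
        hi = 1.0 - 1e-15
        if _g(hi, s, t, u) < 0.0:
            q = brentq(_g, lo, hi, args=(s, t, u), xtol=1e-15, maxiter=200)
        else:
            q = 1.0  # mutation pressure wins: no interior root
            near_fix = regime == REGIME_MSB

    residual = abs(delta_q(q, locus))
    if residual > tol:
        raise RuntimeError(
            f"equilibrium solver failed: residual {residual:.3e} > tol {tol:.1e} "
            f"at q={q!r} for s={s}, t={t}, u={u}"
        )
    if regime == REGIME_MSB and q > _NEAR_FIXATION_Q:
        near_fix = True
    v1, v2 = variance_contribution(locus, q)
    return EquilibriumResult(
        q_eq=q,
        regime=regime,
        H=heterozygosity(q),
        v1=v1,
        v2=v2,
        residual=residual,
        near_fixation=near_fix,
    )


def weak_selection_equilibrium(s, t, u):
    """Vectorised weak-selection equilibrium frequency.

    Root of the quadratic (s^2+t^2) q^2 + (s+t)/2 q - u = 0, i.e. the
    O(s^2) expansion of dq = 0 with the (1-q) factor removed. Evaluated
    in the cancellation-safe form 2u / (b + sqrt(b^2 + 4au)) when the net
    selection b = (s+t)/2 is purifying. Results are clipped to [0, 1]
    (effectively neutral loci, whose exact attractor is fixation, clip
    to 1).
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    a = s * s + t * t
    b = 0.5 * (s + t)
    disc = np.sqrt(b * b + 4.0 * a * u)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(b > 0.0, 2.0 * u / (b + disc), (disc - b) / (2.0 * a))
    return np.clip(q, 0.0, 1.0)


def sweep(
    s_values=(0.005, 0.01, 0.02),
    ts_min: float = -0.5,
    ts_max: float = 2.0,
    ts_step: float = 0.01,
    u: float = 1e-6,
) -> pd.DataFrame:
    """Equilibrium frequency and heterozygosity over a grid of selection
    asymmetries t/s, one curve per value of s (exact solver per point).

    Returns a DataFrame with columns s, t_over_s, q_eq, H.
    """
    s_values = [float(v) for v in np.atleast_1d(s_values)]
    if not s_values:
        raise ValueError("empty s grid")
    n_steps = int(round((ts_max - ts_min) / ts_step)) if ts_step > 0 else 0
    ratios = ts_min + ts_step * np.arange(n_steps + 1)
    ratios = ratios[ratios <= ts_max + 1e-12]
    if ratios.size == 0:
        raise ValueError("empty t/s grid")
    rows = []
    for s in s_values:
        for r in ratios:
            res = solve_equilibrium(LocusSelection(s=s, t=float(r) * s, u=u))
            rows.append((s, float(r), res.q_eq, res.H))
    return pd.DataFrame(rows, columns=["s", "t_over_s", "q_eq", "H"])


def solve_locus_table(table: pd.DataFrame, tol: float = 1e-12) -> pd.DataFrame:
    """Solve every locus of a table with columns locus_id, s, t, u; returns
    the table extended with q_eq, regime, H, v1, v2."""
    out = table.copy()
    results = [
        solve_equilibrium(LocusSelection(s=row.s, t=row.t, u=row.u), tol=tol)
        for row in table.itertuples()
    ]
    out["q_eq"] = [r.q_eq for r in results]
    out["regime"] = [r.regime for r in results]
    out["H"] = [r.H for r in results]
    out["v1"] = [r.v1 for r in results]
    out["v2"] = [r.v2 for r in results]
    return out[LOCUS_TABLE_COLUMNS]


def read_locus_table(path) -> pd.DataFrame:
    """Read a tab-separated locus table (header row required)."""
    return pd.read_csv(path, sep="\t")


def write_locus_table(table: pd.DataFrame, path) -> None:
    """Write a locus table as TSV ('.' decimal, header row)."""
    table.to_csv(path, sep="\t", index=False)
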