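"""Partition of sex-1 additive genetic variance by between-sex effect
asymmetry (t/s) across a sampled set of mutations.

Each locus contributes additive variance proportionally to
q_eq(1-q_eq) s^2, where q_eq is its equilibrium frequency under two-sex
selection with recurrent mutation. Because q_eq shrinks roughly like
2u/(s+t), loci whose cost falls mostly on sex 1 (t/s < 1) equilibrate at
higher frequencies for a given s and therefore carry a disproportionate
share of sex-1 variance. The hypothesis that asymmetric loci dominate is
cov[q_eq(1-q_eq) s^2, t/s] < 0, which for equal marginal distributions of
s and t reduces (by Taylor expansion in the small-variance limit) to
r_st < 1: any imperfect between-sex correlation suffices.

The per-locus equilibrium uses a vectorised weak-selection root ("fast
path"); an exact-recursion Brent solve on a verification subsample guards
against expansion error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from .dfe import DFEParams, MutationSample, sample_bivariate_gamma
from .selection import _g, weak_selection_equilibrium

__all__ = [
    "PartitionBins",
    "PartitionResult",
    "CriticalCorrelationResult",
    "DEFAULT_BIN_EDGES",
    "equilibrium_frequencies",
    "variance_weights",
    "partition",
    "covariance_statistic",
    "taylor_criterion_equal_marginals",
    "critical_correlation",
]

#: symmetric-on-log-scale default edges; cumulative thresholds 1/4 and 1/2
#: are the headline asymmetry classes (four-fold / two-fold larger sex-1 cost)
DEFAULT_BIN_EDGES = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, math.inf)
DEFAULT_CUMULATIVE_THRESHOLDS = (0.25, 0.5, 1.0)


@dataclass(frozen=True)
class PartitionBins:
    """Half-open t/s intervals (a, b] plus cumulative summary thresholds."""

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    cumulative_thresholds: tuple[float, ...] = DEFAULT_CUMULATIVE_THRESHOLDS

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(
            self, "cumulative_thresholds", tuple(float(c) for c in self.cumulative_thresholds)
        )
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing with at least two entries")
        if edges[0] < 0.0:
            raise ValueError("bin edges must be non-negative for deleterious-both-sexes samples")


@dataclass(frozen=True)
class PartitionResult:
    """Variance partition of one mutation sample.

    Fractions are over the loci that tile the bins; ``cumulative_variance_fraction``
    maps each threshold to the share of total sex-1 variance from loci with
    t/s strictly below it. ``covariance_stat`` is the sample covariance of
    the per-locus weight q(1-q)s^2 with t/s. ``verification_max_diff`` is
    the largest absolute difference between fast-path and exact-recursion
    per-bin variance fractions on the verification subsample (NaN when no
    verification was requested).
    """

    bin_edges: tuple[float, ...]
    per_bin_variance_fraction: np.ndarray
    per_bin_locus_fraction: np.ndarray
    cumulative_variance_fraction: dict[float, float]
    covariance_stat: float
    n_effective: int
    u: float
    verification_max_diff: float = math.nan


@dataclass(frozen=True)
class CriticalCorrelationResult:
    """Bisection estimate of the correlation where the covariance between
    q(1-q)s^2 and t/s stops being (significantly) negative."""

    estimate: float
    bracket: tuple[float, float]
    no_sign_change: bool
    n_per_evaluation: int
    evaluations: tuple[tuple[float, float], ...]  # (r, covariance) pairs


def _exact_equilibria(s: np.ndarray, t: np.ndarray, u: float) -> np.ndarray:
    """Per-locus exact-recursion roots (scalar Brent per locus).

    The upper bracket stays below any fitness singularity 1/(2 max(s, t));
    loci with no interior root (selection weaker than mutation pressure)
    are at the fixation boundary q = 1.
    """
    q = np.empty(s.size)
    for i in range(s.size):
        si, ti = float(s[i]), float(t[i])
        hi = min(1.0 - 1e-12, 0.499 / max(si, ti, 1e-300))
        if _g(hi, si, ti, u) < 0.0:
            q[i] = brentq(_g, min(u, 1e-15), hi, args=(si, ti, u), xtol=1e-15)
        else:
            q[i] = 1.0
    return q


def equilibrium_frequencies(
    sample: MutationSample, u: float, method: str = "fast"
) -> np.ndarray:
    """Equilibrium frequency per locus; ``method`` is ``fast``
    (weak-selection root, vectorised) or ``exact`` (Brent on the exact
    recursion residual, looped)."""
    if method == "fast":
        return weak_selection_equilibrium(sample.s_values, sample.t_values, u)
    if method == "exact":
        return _exact_equilibria(sample.s_values, sample.t_values, u)
    raise ValueError(f"unknown method {method!r}")


def variance_weights(sample: MutationSample, u: float, method: str = "fast") -> np.ndarray:
    """Per-locus sex-1 variance weight q_eq (1 - q_eq) s^2 (the constant
    factor 2 cancels from every reported fraction)."""
    if not (u > 0.0):
        raise ValueError(f"mutation rate must be positive, got {u}")
    q = equilibrium_frequencies(sample, u, method=method)
    return q * (1.0 - q) * sample.s_values**2


def _bin_fractions(ratio: np.ndarray, weights: np.ndarray, edges: tuple[float, ...]):
    """Weight fraction per half-open bin (a, b]; ties on an edge go to the
    lower bin."""
    idx = np.searchsorted(edges, ratio, side="left") - 1
    in_range = (idx >= 0) & (idx < len(edges) - 1)
    total = float(weights[in_range].sum())
    frac = np.bincount(idx[in_range], weights=weights[in_range], minlength=len(edges) - 1)
    return frac / total if total > 0 else frac, int(in_range.sum())


def partition(
    sample: MutationSample,
    u: float,
    bins: PartitionBins | None = None,
    method: str = "fast",
    verify_n: int = 0,
) -> PartitionResult:
    """Partition sex-1 additive variance across t/s asymmetry classes.

    Per-locus weights are q_eq(1-q_eq) s^2 at the equilibrium under
    mutation rate ``u``. ``verify_n`` > 0 re-solves an evenly spaced
    subsample with the exact recursion and records the largest deviation
    of the per-bin variance fractions between the two solvers.
    """
    bins = bins or PartitionBins()
    w = variance_weights(sample, u, method=method)
    ratio = sample.t_values / sample.s_values

    var_frac, n_eff = _bin_fractions(ratio, w, bins.edges)
    locus_frac, _ = _bin_fractions(ratio, np.ones_like(w), bins.edges)

    total = float(w.sum())
    cumulative = {
        thr: (float(w[ratio < thr].sum()) / total if total > 0 else 0.0)
        for thr in bins.cumulative_thresholds
    }

    cov = covariance_statistic(sample, u, method=method) if sample.n >= 2 else math.nan

    verification = math.nan
    if verify_n > 0 and method == "fast":
        step = max(1, sample.n // verify_n)
        idx = np.arange(0, sample.n, step)[:verify_n]
        sub_fast = w[idx]
        sub_exact_q = _exact_equilibria(sample.s_values[idx], sample.t_values[idx], u)
        sub_exact = sub_exact_q * (1.0 - sub_exact_q) * sample.s_values[idx] ** 2
        f_fast, _ = _bin_fractions(ratio[idx], sub_fast, bins.edges)
        f_exact, _ = _bin_fractions(ratio[idx], sub_exact, bins.edges)
        verification = float(np.max(np.abs(f_fast - f_exact)))

    return PartitionResult(
        bin_edges=bins.edges,
        per_bin_variance_fraction=var_frac,
        per_bin_locus_fraction=locus_frac,
        cumulative_variance_fraction=cumulative,
        covariance_stat=cov,
        n_effective=n_eff,
        u=u,
        verification_max_diff=verification,
    )


def covariance_statistic(sample: MutationSample, u: float, method: str = "fast") -> float:
    """Sample covariance across loci between the variance weight
    q_eq(1-q_eq) s^2 and the asymmetry ratio t/s. Negative values mean
    loci with disproportionately large sex-1 costs dominate sex-1
    variance."""
    if sample.n < 2:
        raise ValueError("covariance needs at least two loci")
    w = variance_weights(sample, u, method=method)
    ratio = sample.t_values / sample.s_values
    return float(np.cov(w, ratio, ddof=1)[0, 1])


def taylor_criterion_equal_marginals(r_st: float) -> int:
    """Predicted sign of cov[q(1-q)s^2, t/s] for equal marginals in the
    small-variance limit: negative (-1) iff r_st < 1, zero (0) at r_st = 1."""
    if not (0.0 <= r_st <= 1.0):
        raise ValueError(f"correlation must lie in [0, 1], got {r_st}")
    return -1 if r_st < 1.0 else 0


def _crn_covariance(
    uniforms: np.ndarray, r: float, shape: float, scale: float, u: float
) -> tuple[float, float]:
    """Covariance (and its MC standard error) at correlation r, using
    common random numbers: fixed uniforms mapped through the gamma
    quantile function so the estimate is continuous in r."""
    k_shared = shape * r
    k_own = shape * (1.0 - r)

    def comp(us, k):
        if k <= 0.0:
            return np.zeros_like(us)
        return gamma_dist.ppf(us, k) * scale

    g0 = comp(uniforms[0], k_shared)
    s = g0 + comp(uniforms[1], k_own)
    t = g0 + comp(uniforms[2], k_own)
    pos = (s > 0.0) & (t > 0.0)
    s, t = s[pos], t[pos]
    q = weak_selection_equilibrium(s, t, u)
    w = q * (1.0 - q) * s * s
    ratio = t / s
    prod = (w - w.mean()) * (ratio - ratio.mean())
    n = s.size
    cov = float(prod.sum() / (n - 1))
    se = float(prod.std(ddof=1) / math.sqrt(n))
    return cov, se


def critical_correlation(
    shape: float,
    scale: float,
    u: float = 1e-6,
    bracket: tuple[float, float] = (0.0, 1.0),
    n: int = 100_000,
    seed: int = 0,
    r_tol: float = 0.005,
) -> CriticalCorrelationResult:
    """Estimate the between-sex correlation r* at which the covariance
    between q(1-q)s^2 and t/s ceases to be negative.

    Monte-Carlo covariances are computed on common random numbers (shared
    uniforms through the gamma quantile transform) so the covariance is a
    deterministic, continuous function of r given the seed; the boundary
    between 'significantly negative' (cov < -3 SE) and 'consistent with
    zero' is then bisected to width ``r_tol``. If the covariance is still
    significantly negative at the upper bracket end, no sign change exists
    in the bracket and ``no_sign_change`` is set.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"bracket must be within [0, 1], got {bracket}")
    rng = np.random.default_rng(seed)
    uniforms = rng.random((3, n))

    evals = []

    def significantly_negative(r: float) -> bool:
        cov, se = _crn_covariance(uniforms, r, shape, scale, u)
        evals.append((r, cov))
        return cov < -3.0 * se

    if not significantly_negative(lo):
        # no negative region at all: nothing to bisect
        return CriticalCorrelationResult(
            estimate=math.nan,
            bracket=(lo, hi),
            no_sign_change=True,
            n_per_evaluation=n,
            evaluations=tuple(evals),
        )
    if significantly_negative(hi):
        return CriticalCorrelationResult(
            estimate=math.nan,
            bracket=(lo, hi),
            no_sign_change=True,
            n_per_evaluation=n,
            evaluations=tuple(evals),
        )

    while hi - lo > r_tol:
        mid = 0.5 * (lo + hi)
        if significantly_negative(mid):
            lo = mid
        else:
            hi = mid

    return CriticalCorrelationResult(
        estimate=0.5 * (lo + hi),
        bracket=(lo, hi),
        no_sign_change=False,
        n_per_evaluation=n,
        evaluations=tuple(evals),
    )
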