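# Methods

## The two-sex locus model

Each locus is biallelic and autosomal with a wild-type and a
disease-predisposing allele (frequency q). Disease susceptibility is
additive (0, γ, 2γ per disease-allele copy) and fitness costs are
proportional to it: genotype fitnesses `1, 1−s, 1−2s` in sex 1 with
`s = cγ > 0`, and `1, 1−t, 1−2t` in sex 2. The constant c and the factor
2 cancel from every relative quantity the package reports, so c defaults
to 1. The sign conventions are: t > 0, allele deleterious in both sexes;
t = 0, sex-limited cost; t < 0, sexually antagonistic.

Assumptions: random mating, infinite population (no drift), no dominance
(additive within locus), no epistasis or linkage disequilibrium between
loci, autosomal inheritance, and allele frequencies equal in the two sexes
(each generation averages the post-selection frequencies of the two sexes
with weight 1/2). Mutation is one-way, wild-type → disease, at rate u per
gamete per generation; back mutation is not modelled (it would only
perturb equilibria at O(u·q), negligible everywhere the package is used).

### The recursion and its factorisation

One life cycle (Hardy–Weinberg formation, sex-specific viability
selection, averaging, mutation) gives, per sex, the post-selection
frequency `q_x = q(1 − x(1+q))/(1 − 2xq)` for coefficient x ∈ {s, t};
mean fitness in that sex is `1 − 2xq`. The per-generation change
factorises exactly (no weak-selection approximation and no catastrophic
cancellation):

    Δq = (1 − q) · g(q),    g(q) = u − (1−u) · q·S(q)/2,
    S(q) = s/(1−2sq) + t/(1−2tq).

Both fractions in S are increasing in q whenever genotype fitnesses are
positive (the enforced invariant 2|s| < 1, 2|t| < 1), so S is strictly
increasing and g has **at most one root** in (0, 1). That root is the
stable equilibrium approached from q₀ = u, which removes any
root-selection ambiguity. When g has no interior sign change the boundary
q = 1 is the attractor: either true disease fixation (net selection
favours the allele, `s + t < 0` without the balancing condition) or
fixation by mutation pressure at effectively neutral loci (s + t ≲ u);
the latter is reported with a `near_fixation` diagnostic flag. Such loci
are irrelevant to variance partitions because their weight carries s² ≈
u².

### Regimes and closed forms

- balancing selection iff `4st < s+t < 0`: selection alone maintains the
  polymorphism; weak-selection interior point `−(s+t)/(2(s²+t²))`.
- disease fixation iff `s+t < 0` otherwise.
- mutation–selection balance (MSB) for `s+t ≥ 0`: `q_eq ≈ 2u/(s+t)`.

Validity of the closed forms against the exact root: the MSB form is
within 5% whenever `s+t ≥ 100u`. The balancing form additionally needs
the interior root to be well-developed against mutation pressure: the
restoring force at the root is O(q̂²·2(s²+t²)), so mutation displaces the
root by a relative `≈ 4u(s²+t²)/(s+t)²`, and the 5% agreement requires
roughly `|s+t| ≥ 13·max(s,|t|)·√u`. Near the boundary of the balancing
region the displacement is O(u/s²) and can be large (e.g. s = 0.01,
t = −0.0102, u = 10⁻⁶: exact root 0.5000 vs closed form 0.4901). Tests
assert the closed forms only inside these regions.

### Numerics

- Root finding: Brent's method on g over `[min(u, 10⁻¹⁵), 1−10⁻¹⁵]`
  (xtol 10⁻¹⁵); the residual |Δq| at the reported root is checked against
  the tolerance (default 10⁻¹²) and is typically < 10⁻¹⁷.
- u = 0 degenerate cases: purifying/MSB loci return q = 0; balancing loci
  return the root of S(q) = 0 (the attractor of any interior frequency);
  fixation loci return 1.
- All frequencies are clamped to [0, 1] after each recursion step.
- The vectorised fast path solves the weak-selection quadratic
  `(s²+t²)q² + ((s+t)/2)q − u = 0` in the cancellation-safe form
  `q = 2u/(b + √(b²+4au))`, accurate to O(s) relative error ~10⁻³ against
  the exact root; partitions computed with fast and exact roots agree to
  ~10⁻¹¹ in the bin fractions (a built-in verification subsample re-solves
  loci with the exact recursion on every CLI partition run).

## The correlated DFE

New mutations draw (s, t) — costs per copy in sex 1 and sex 2 — from a
bivariate gamma with equal marginals Gamma(k, θ) and Pearson correlation
`r_st ∈ [0, 1]`. Default parameters follow the empirical DFE literature
for deleterious mutations: shape k = 0.2 (strongly leptokurtic, as
inferred from human and Drosophila nonsynonymous polymorphism), mean
E(s) = E(t) = kθ = 0.02, r_st = 0.75, u = 10⁻⁶ per locus. All
coefficients are positive, so every locus equilibrates at MSB and the
partition results are a conservative lower baseline for the contribution
of asymmetric loci (sexual antagonism would only amplify it).

Three exchangeable couplings with identical gamma marginals:

- **Kibble** (default): sampled via the Poisson mixture
  `s ~ Gamma(k, θ)`, `N | s ~ Poisson(r·s/((1−r)θ))`,
  `t | N ~ Gamma(k+N, (1−r)θ)`. Marginals and the Pearson correlation are
  exact. Conditional on a large s, t concentrates near r·s, so strongly
  selected loci have genuinely dispersed asymmetry ratios. This coupling
  is the default because it is the canonical bivariate gamma and is the
  one that reproduces the published partition of variance for this model
  family (the trivariate reduction concentrates ~60% of loci at t/s ≈ 1
  through the shared component and yields a far weaker asymmetry
  signal).
- **Trivariate reduction (Cherian)**: `s = G0+G1, t = G0+G2` with
  `G0 ~ Gamma(kr, θ)`, `G1, G2 ~ Gamma(k(1−r), θ)`. Exact marginals and
  correlation. Floating-point caveat: for leptokurtic shapes G1 and G2
  are frequently below one ulp of G0, so s and t collide to equal floats;
  the sampler restores the real-arithmetic ordering with a one-ulp
  `nextafter` nudge in the direction of the component gap (otherwise the
  t < s split is biased by the tie atom).
- **Gaussian copula**: gamma quantile transform of a bivariate normal
  with correlation r_st; the realized Pearson correlation is attenuated
  below r_st (matched only approximately).

Degenerate values are handled explicitly: r = 1 collapses to t ≡ s; zero
component shapes are point masses at 0; any coefficient that underflows
to exactly 0 is resampled (positivity is required by t/s and the locus
invariants). Samples are deterministic given (parameters, seed).

## Variance partition

Per-locus sex-1 weight: `w = q_eq(1−q_eq)s²` (the factor 2 cancels in all
fractions). Default t/s bins `{0, 1/4, 1/2, 1, 2, 4, ∞}` — log-symmetric
around 1, with the cumulative thresholds 1/4 and 1/2 fixed by the
headline asymmetry classes (four-fold and two-fold larger sex-1 effect).
Intervals are half-open (a, b]; a ratio exactly on an edge goes to the
lower bin (deterministic tie-break). Cumulative fractions use strict
`t/s < threshold`.

The covariance statistic `cov[q_eq(1−q_eq)s², t/s]` is the formal
criterion for asymmetric loci dominating sex-1 variance. Caveat for
heavy-tailed DFEs: for k ≤ 1 the population moment E[t/s] does not exist
(E[1/s] diverges), so the sample covariance at small k is sign-stable but
scale-free — only its sign is meaningful, and tests assert only the sign.
In the small-variance limit (Taylor expansion around the means) the
criterion for equal marginals reduces to `r_st < 1`.

`critical_correlation` locates the r_st at which the covariance stops
being significantly negative. Covariances across r values use common
random numbers (fixed uniforms through the gamma quantile transform of
the shared/own-component construction), making the Monte-Carlo covariance
a deterministic, continuous function of r for a given seed; the boundary
between `cov < −3·SE` and `cov ≥ −3·SE` is bisected to a bracket of width
0.005. With k = 50 and n = 10⁵ per evaluation, the negative signal is
resolvable to within ~0.003 of r = 1, so the estimate is 1.00 ± 0.01.

## Problem sizes and reproducibility

Headline partitions use n = 10⁶ loci (seconds on one CPU with the fast
path); monotonicity and invariance scans use n = 2×10⁵; the
solver-vs-iteration oracle grid runs the exact recursion to |Δq| < 10⁻¹⁴
(up to 2×10⁸ generations, JIT-compiled in the test suite, ~1 s). Every
random quantity is reproducible from the recorded (parameters, seed)
provenance; the CLI writes JSON sidecars with the full configuration.

## What the generator does and does not emulate

The synthetic DFE reproduces the statistical structure the model assumes:
equal leptokurtic gamma marginals, a single between-sex correlation, a
constant per-locus mutation rate, and free recombination. It does not
emulate drift in finite populations (deterministic equilibria only),
dominance (h = 1/2 throughout; at MSB replacing s, t by sh, th leaves
t/s unchanged), X-linkage, epistasis, variable mutation rates across
loci, or genotype–environment interaction. Passing tests therefore show
that the deterministic theory is implemented correctly and that its
predictions hold under the stated DFE — not that real genomes match these
distributions.

## Known limitations

- Negative between-sex correlations cannot be produced by any of the
  three couplings (not needed for mutations deleterious in both sexes).
- The balancing-selection closed form degrades near the regime boundary
  (see validity region above); the exact solver remains correct there.
- The deterministic recursion sends effectively neutral loci (s+t ≲ u)
  to fixation by mutation pressure; in a finite population drift would
  dominate these loci. Their variance weights are O(u²), so partition
  results are insensitive to this choice (checked by the u-invariance
  test).
- For leptokurtic DFEs the covariance statistic has no finite population
  moment; use its sign, or the partition fractions, not its magnitude.
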