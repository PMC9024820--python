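# Methods

## Model and assumptions

All procedures assume a linear acyclic structural equation model over
observed variables (treatment `X`, outcome `Y`, candidate pool `O`) and
arbitrary latent variables `U`:

```
V_i = Σ_{V_j ∈ Pa(V_i)} b_ij V_j + ε_i,
```

with mutually independent, zero-mean, non-Gaussian noise terms of nonzero
variance, and faithfulness (no vanishing-by-coincidence covariances).  In
reduced form `V = A ε` with `A = (I − B)⁻¹`; every population quantity the
package computes — covariances, noise loadings, the GIN oracle — is exact
linear algebra on `A` and the diagonal noise-variance matrix `Ω`.

## The GIN condition and why non-Gaussianity matters

For column sets `P`, `Q`, the surrogate is `E = ωᵀP` with ω a unit-norm
left-null vector of the cross-covariance `Σ_PQ`.  The package restricts
attention to `|P| = |Q| + 1`, the only regime the instrument test needs
(P = {X, Y} ∪ W, Q = {Z} ∪ W); there the null space is generically
one-dimensional, and a second vanishing singular value (relative threshold
1e-8) is flagged as a faithfulness violation rather than silently
resolved.  Sign convention: first nonzero ω entry positive.

By construction `cov(E, Q) = 0`.  Independence is a strictly stronger
statement: writing both sides in terms of noise loadings, the
Darmois–Skitovitch theorem makes `E` and `Q` dependent exactly when some
*non-Gaussian* noise loads on both.  With Gaussian noise the test is blind
— zero covariance already implies independence — which the
`motivating_demo` reproduces.  The population oracle
(`population_gin_oracle`) applies this criterion with loading tolerance
1e-9 and answers GIN queries exactly on a known SEM; it is the reference
against which the finite-sample test is validated.

The trek-based graphical characterisation (`ivgin_graphical_criterion`)
holds iff some choke node `C` covers, causally upstream, every trek
between the `{X, Y} ∪ W` side and the `{Z} ∪ W` side, some node of
`{C} ∪ W` has a directed path into `{X, Y}`, and no proper subset of `W`
already suffices.  Two interpretive choices were genuinely open and are
fixed as follows, each validated by a worked example: a trek endpoint
counts as lying on the trek (with "causally earlier" satisfied trivially
when the covering node *is* the `P`-side endpoint, and otherwise requiring
the trek edge on the `P` side to point away from the covering node); and
`C` may be any node of the graph including `Z` itself — the direct-effect
example (`fig8`) is only covered by `C = Z`.  The equivalence of this
criterion with the Darmois–Skitovitch oracle is asserted over hundreds of
random SEMs in the test suite.

Necessity caveat: validity of `Z` given `W` implies GIN *unconditionally*
(W = ∅) and in the conditional configurations shipped as fixtures, and
this is tested with zero tolerated exceptions.  It is **not** a theorem
for arbitrary conditional configurations: if a latent ancestor of the
conditioning set also feeds `Y` directly, `{Z} ∪ W` spans more noise terms
than the surrogate's degrees of freedom can cancel, and GIN fails even for
a d-separation-valid instrument.  The benchmark scenario S3 is
constructed so that its conditional instrument (`Z1` given `{Z3}`) lies in
the regime where necessity does hold (the latent driving `Z3` feeds `X`,
not `Y`); this is forced — under the alternative wiring no algorithm based
on the GIN condition could ever recover `Z1`.

## Finite-sample testing

* **HSIC.**  Biased V-statistic with Gaussian kernels; bandwidth per
  vector by the median heuristic (squared bandwidth = half the median
  positive squared distance, estimated from up to 1024 of the test
  points).  Null approximations: a two-moment gamma fit (default) or
  permutation (default 500 permutations).  Inputs longer than
  `max_points` (default 2000) are subsampled uniformly with a seed; Gram
  matrices are float32 (the moment sums are accumulated in float64).
* **Fisher combination.**  The GIN test checks the surrogate pairwise
  against each member of `Q`; `−2 Σ log p_k` is referred to χ² with
  `2|Q|` degrees of freedom.  p-values are clipped to [1e-300, 1].
* **Level distortion.**  ω is estimated from the same sample, so the
  surrogate direction is off by O(n^-1/2) and the tested independence is
  only approximately true even for a valid instrument.  The resulting
  false-rejection rate of valid instruments is a few percent at n = 5000
  rather than the nominal α = 0.01, for any subsample cap between 800 and
  the full sample; this is a property of the plug-in surrogate, not of the
  gamma approximation (permutation p-values behave identically), and it is
  what bounds the correct-selecting rate slightly below 1 in the
  benchmark.
* **Relevance pre-check.**  Before each GIN test, `Z` must remain
  dependent on `X` given `W` (Fisher-z partial correlation at the same α).
  This also protects the GIN step from the degenerate case of an
  irrelevant candidate, whose zero cross-covariance makes ω undefined.
  The check can be disabled (`relevance_check=False`).

## Selection algorithm

Candidates are scanned at conditioning-set sizes L = 0, 1, …; for each
not-yet-admitted `Z`, subsets `W ⊆ O \ {Z}` with `|W| = L` are enumerated
in lexicographic order (the pool is name-sorted, making the output
invariant to input column order).  A candidate is admitted at its first
passing `W` — the minimal conditioning set — and never retested.  The
scan stops when L reaches the number of still-unadmitted candidates.  At
level L the loop formally iterates over the unadmitted set; the admitted
set `C` starts empty, so the iteration must be over its complement for
the procedure to do anything, and that is how it is implemented.  A
`max_cond_size` option truncates the scan for large pools.  Defaults:
α = 0.01 shared by the GIN test and the pre-check; gamma HSIC; subsample
cap 2000.

A population-oracle mode (`select_candidates_oracle`) runs the identical
control flow with the exact oracle and graphical relevance check; on a
known SEM it returns exact answers and backs the completeness check
(every graphically valid instrument appears in the output — tested on all
scenarios).

Selection is *screening*: the GIN condition is necessary, not sufficient.
An exogenous candidate with a direct effect on `Y` passes every
observational test (its noise is removed from the surrogate exactly), so
the output is a candidate set and is reported as such.

## Effect estimation

For an admitted `Z` with conditioning set `W`, the effect of `X` on `Y`
is the partial-covariance ratio `b_YX = σ_ZY·W / σ_ZX·W`, computed by
Schur complement from the empirical (or population) covariance.  A
denominator below 1e-10 relative to the partial standard deviations
raises a weak-instrument error.  The Results object attaches a
nonparametric bootstrap standard error (default 200 resamples).  On
population covariances the estimator recovers the generating coefficient
exactly for valid instruments (tested to machine precision on the simple
and the two-covariate conditional fixtures).

## Synthetic benchmark

The generator reproduces the simulation study's conditions: coefficients
drawn uniformly from [−2, −0.5] ∪ [0.5, 2]; noise at every node is the
square of an Exp(1) draw, centered by subtracting its mean 2 (variance
20, strongly skewed) and deliberately not rescaled — centering is forced
by the zero-mean convention, rescaling is not.  The exponential rate is
taken as 1 where unstated.  Scenario topologies (the printed figure is
not machine-readable) are reconstructed minimally from the stated
validity facts:

* **S1** — `Zk → X` (k = 1..3), `U1 → Z1`, `U1 → X`, `U1 → Y`, `X → Y`.
  Valid: Z2, Z3 given ∅; Z1 invalid (unblockable `Z1 ← U1 → Y`).
* **S2** — S1 plus `U2 → Z3`, `U2 → X` (an active nondirected path
  between Z3 and X).  Same labels.
* **S3** — `Z3 → Z1`, `Z3 → Y`, `U1 → Z3`, `U1 → X`, `Z1 → X`, `Z2 → X`,
  `U2 → X`, `U2 → Y`, `X → Y`, `X → Z4 ← Y`.  Valid: Z1 given {Z3}, Z2
  given ∅; Z3 invalid (direct edge), Z4 invalid (collider child).  See
  the necessity caveat above for why `U1` feeds `X` rather than `Y`, and
  note `Z3` must have a latent parent at all — as a root its direct
  effect on `Y` would be undetectable and commission would triple.

The confounding-sensitivity task pins the `U1 → X` / `U1 → Y`
coefficients (where present) to λ ∈ {0.125, 0.25} after drawing the rest;
the direction-reversal task replaces `X → Y` by `Y → X` leaving
everything else, including the ground-truth labels, unchanged — the GIN
query is symmetric in `X` and `Y`, which is the point of that experiment.
One seed per replicate drives coefficients, noise, and HSIC subsampling
(replicate r uses seed + r), making every report exactly reproducible.

Metrics: correct-selecting rate = recovered valid IVs / all valid IVs;
selection commission = falsely admitted / admitted, defined as 0 for an
empty output (the ratio is otherwise 0/0).  A candidate counts as correct
by membership; conditioning sets are logged in the audit trail but not
required to match the minimal one.

What the generator does *not* emulate: measurement error, nonlinear
mechanisms, cyclic structure, selection bias, and discrete or mixed
variable types.  Passing benchmarks therefore certify correctness of the
method under its own model class, not robustness beyond it.

## Problem sizes and numerical choices

The default test suite runs the benchmark cells at n = 5000 with
replicate counts allocated by precision need (100 for the cells whose
mean sits nearest a band edge, 50 for the remaining three-candidate
cells, 25 for the costly S3 cells; the ±0.07 bands account for the
binomial noise at those sizes), and `scripts/acceptance.py` uses the
study's 50 replicates per cell.  Property batteries use hundreds of random
SEMs with ≤ 7 nodes, coefficients bounded away from zero, and skip
queries flagged as degenerate (rank-deficient cross-covariance) or not
pairwise correlated, mirroring the faithfulness assumption.  Tolerances:
singular-value degeneracy 1e-8 (relative), oracle noise loadings 1e-9,
weak-instrument denominator 1e-10 (relative), p-value clipping 1e-300.

## Known limitations

* Candidate sets, not certificates: condition "no directed `Z → Y` path
  bypassing `X`" is untestable observationally; downstream use of the
  estimates should treat agreement across several admitted instruments as
  the meaningful robustness signal.
* The plug-in level distortion above means α is not the exact
  false-rejection rate of valid instruments at finite n.
* Near-Gaussian noise weakens the Darmois–Skitovitch signal smoothly; the
  method degrades toward the Gaussian blind spot.
* The scan enumerates subsets; pools beyond ~15 candidates need
  `max_cond_size` to stay tractable.
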