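# Methods

## Measurement model

`cronpower` works under the parallel-items (essential tau-equivalence) model:
item score `Y_ij = mu_i + e_ij`, `mu_i ~ N(mu, sigma_mu^2)` independent of
`e_ij ~ N(0, sigma_e^2)`, errors conditionally independent across items and
administrations. This forces a compound-symmetric item covariance
`Sigma = sigma_e^2 I + sigma_mu^2 11'` and makes Cronbach alpha, the scale-score
reliability, and the test-retest correlation of scale scores one and the same
quantity, `C_a = k rho / (1 + rho (k-1))`.

Two modelling commitments matter:

* **Fixed true-score variance.** `sigma_mu^2` is treated as a population
  constant; item quality only moves `sigma_e^2 = (1/rho - 1) sigma_mu^2`. This
  is what makes every power function monotone increasing in `C_a`. Under the
  alternative convention (fixed *total* variance) the two-sample power would
  *decrease* with `rho`, as in cluster-correlated designs.
* **Independent errors per administration.** Test/retest and pre/post scores
  share the subject's `mu_i` but draw fresh errors. Reusing the same errors
  would force a test-retest correlation of 1 and contradict the covariance
  algebra (`Cov(S_test, S_retest) = k^2 rho sigma^2`), so independence is the
  only coherent reading.

## Closed forms and their conventions

The theoretical power functions use standard-normal quantiles throughout —
variances are treated as known at the design stage — while the Monte Carlo
engine applies t-tests with estimated variances, the way a practitioner would
analyse the data. At `N >= 30` the two differ by at most a few Monte Carlo
standard errors (the largest gap is the paired design at small `N` and high
power: at `N = 30`, `C_a = 0.8`, `D = 0.4` the normal form gives 0.873 versus
an exact noncentral-t power of 0.850).

* **One-tail convention.** Two-sided power is computed from the rejection tail
  on the side of the true effect only; the opposite tail's contribution is
  dropped, so power at a null effect is exactly `alpha/2`. The
  `both_tails=True` flag restores the exact two-sided value. The default keeps
  the closed forms in their simplest published shape.
* **Boundary alpha.** `C_a = 1` (error-free items) is a valid input to the
  two-sample power/sample-size functions — they reduce to the classical normal
  formulas — but a domain error in the paired and interaction designs, whose
  difference scores would be degenerate, and in the Fisher-z test, whose
  transform diverges.
* **Continuous N and k.** The sample-size and item-count formulas return both
  the continuous solution and its ceiling (the conventional conservative
  rounding; no rounding rule is canonical). The power functions accept any
  positive real `N` (and the rho-parameterized form any real `k > 0`) so that
  power(samplesize(phi)) = phi holds exactly for the continuous solution, even
  where it falls below a practically meaningful design size. `DesignSpec`, the
  gateway to simulation, enforces integer `N >= 2` (`>= 4` for the Fisher-z
  design, which needs `N > 3`).
* **Item-count discrepancy in the interaction design.** The published
  item-count formula for the between-within design carries a numerator factor
  2, but inverting the between-within power function in `k` — and matching the
  factor-4 per-group sample-size formula — gives factor 4. `items_required`
  returns the self-consistent factor-4 value by default, reports the factor-2
  variant alongside it (`k_continuous_printed`), and lets `formula="printed"`
  select it. Neither is silently discarded.

## Simulator

`simulate_scores` draws `mu_i` and the error matrix directly from their
normal distributions; intervention effects enter as a fixed location shift
`delta = D * sigma_mu` added to every item score of the shifted administration
or group (post-intervention arm, or treatment group). Defaults `mu = 0`,
`sigma_mu^2 = 1` lose no generality because effects are standardized. In the
between-within design the two groups' true scores are independent draws from
the same population; group sizes are equal.

Randomness: one root integer seed per `SimulationConfig`; replicate `r` uses
the `r`-th child of `numpy.random.SeedSequence(seed).spawn(n_reps)` with the
PCG64 bit generator. Runs are bit-reproducible and any single replicate can be
regenerated in isolation.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: binary/ordinal (Likert) item marginals, unequal
item variances or non-exchangeable correlation structures, subject-specific
(random) treatment effects, drop-out, or group imbalance. The validation shows
the closed forms are correct *under the model*, not that real instruments are
parallel.

## Monte Carlo engine

Per replicate the design-appropriate test is applied to scale scores: paired
t-test (pre-post), pooled two-sample t-test on per-subject pre-post differences
(between-within — the unique t-test whose known-variance analogue is the
interaction z statistic), pooled two-sample t-test (two-sample). Pooled
variance is the default since the model guarantees equal variances; Welch is a
flag. Empirical power is the strict-inequality rejection fraction
`sum 1(p_s < alpha) / n_reps`, reported with the binomial standard error
`sqrt(p(1-p)/n_reps)`. A degenerate all-zero difference vector (only possible
with `rho = 1` and no shift) counts as a non-rejection rather than raising,
keeping simulation loops total.

`reproduce_table` drives four validation grids: (1) mean test-retest Pearson
correlation vs its target `C_a` over `C_a in {0.1..0.9}`, `N in {30, 50}`,
`k in {5, 10}`; (2)–(4) empirical vs theoretical power for the three
comparison designs over `C_a in {0.5..0.9}` with `(N, D)` blocks `(30, 0.4)` /
`(50, 0.3)` for the longitudinal designs and `(50, 0.7)` / `(100, 0.5)` for the
two-sample design, at 1000 replicates by default.

## Problem sizes and tolerances

The test suite uses 1000 replicates per validation cell (binomial SE ~0.015 at
mid power), 10^4 replicates for type-I-error calibration (3 SE band of ±0.0065
around 0.05) and for the standard-normality checks of the known-variance z
statistics, and single draws of N = 10^5 subjects for the moment checks of the
generator (inter-item correlation within 0.01, scale-score variance within 1
of `k^2 sigma_mu^2 / C_a`). Algebraic identities — the alpha/rho round trip,
the equality of the two `Var(S)` parameterizations, the rho- vs
alpha-parameterized power forms, the sample-size/power duality — are asserted
to 1e-10..1e-12. Empirical-vs-theoretical power agreement is asserted within 4
binomial SE per cell, with the SE taken at the observed proportion (at the
theoretical value when the observed proportion is exactly 0 or 1, where the
plug-in SE degenerates).

## Known limitations

* All results are asymptotic-normal on the theory side; for `N` well below 30
  the t-vs-normal gap is no longer negligible and the closed forms are
  optimistic at high power.
* The sample alpha estimator assumes the plug-in covariance form; no
  confidence intervals or non-parallel corrections are provided.
* The Fisher-z alpha test targets a zero null only; testing against a nonzero
  reference alpha is out of scope.
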