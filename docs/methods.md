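# Methods

This note documents the statistical model, the preprocessing contract, the
sampler, the synthetic-data generator and the design decisions behind
`dmscore`, in enough detail to judge what the package's tests do and do
not establish.

## Observation model and preprocessing

A growth screen delivers raw sequencing counts `c[v,t,r]` for variant `v`,
selection round `t = 0..T` and replicate `r = 1..R`.  Preprocessing is a
four-step contract:

1. **Filter** — variants missing more than `max_missing_frac` (default
   0.5) of their count cells are dropped (counted and logged).
2. **Impute** — a missing cell is filled with the mean of observed counts
   at the same (position, round, replicate); if nothing at that position
   was observed in that column, the pseudocount (0.5) is used.  Observed
   cells are never altered.
3. **Normalize** — `m = log(c + 0.5) − log(column total) − center`, where
   `center` is the per-column median over synonymous variants (the
   total-count median when a screen has no synonymous variants).  This
   anchors the synonymous null at zero in every column and removes
   sequencing-depth differences.
4. **Mappings** — `p(v)`: synonymous variants form one virtual control
   position; deletions and insertions form one pseudo-position each; a
   real position with fewer than `min_pos_variants` (default 5) variants
   is merged into the next larger position, cascading, with a sparse
   terminal position merging backward.  `g(v)`: variants are binned into
   `n_mean_groups` (default 5) equal-frequency groups of a naive
   per-variant least-squares slope, so that error scales can be pooled
   across variants of similar abundance trajectory.

The aligned count is modelled as linear in scaled round time:
`m[v,t,r] ~ Normal(beta_v t/T + b_v, eps_{g(v)}^2)`, with
`eps_g ~ InvGamma(1,1)` on the **scale** (not the variance) and
`b ~ Normal(0,1)` — the intercept prior is weak and symmetric because `b`
only encodes round-0 abundance.

## Score prior and the constrained substitution effects

The full model's score prior is
`beta_v ~ Normal(phi_p + nu_a rho_p, sigma2_p)` with
`phi ~ Normal(0,1)`, `sigma2 ~ InvGamma(1,1)`, `rho ~ Beta(1.5,1.5)`.

Substitution groups are built from BLOSUM90: distinct observed missense
scores, ascending, are greedily merged until each bin's variants appear in
at least 20% of the real position groups (a `coverage_mode="variants"`
switch measures coverage over variants instead; a trailing undersized bin
merges backward).  Nonsense changes form one dedicated group; deletions
and insertions one group each.  The synonymous group's effect is a
structural zero.  Whether indel groups carry substitution effects is
configurable (`indel_effects`); the default gives them effects, since they
are non-synonymous and only the synonymous group is excluded from the
identifying constraint.  The alternative reading (indels as pure
pseudo-position effects) is one flag away.

Identifiability of `phi` versus `nu` requires a constraint.  With `w` the
mean-normalized variant counts of the A−1 non-synonymous groups, the prior
is the degenerate Gaussian
`nu_{-A} ~ Normal(0, diag(w)^{-1} M diag(w)^{-1})`, where `M` has ones on
the diagonal and `−1/(A−2)` off it.  `M` has rank A−2: eigenvalue
`(A−1)/(A−2)` with multiplicity A−2 and a null direction along the ones
vector.  We factor `M = B Bᵀ` over the positive eigenpairs and sample
`nu = diag(w)^{-1} B z` with `z ~ Normal(0, I)`; since `Bᵀ1 = 0`, the
count-weighted sum `Σ w_a nu_a` is **exactly** zero on every draw — the
constraint is parameterized away rather than soft-enforced.  This needs at
least three constrained groups (A ≥ 4); coarser screens get a clear error.

## Posterior sampling

All conditionals except two are conjugate, so the sampler is blocked
Gibbs:

* `(beta_v, b_v)` — bivariate Gaussian, sampled jointly per variant;
* `(phi, z)` — one joint Gaussian block (~P+A dimensions).  Sampling them
  together matters: a substitution group observed at few positions (an
  indel pseudo-position, say) makes `phi` and `nu` strongly coupled, and
  separate updates random-walk along that ridge;
* `sigma2` — conjugate inverse-gamma, floored at 1e−6 against
  degenerate positions;
* `rho` — per-position slice sampling on [0,1] (shrinkage from the full
  interval); positions with no constrained variants fall back to exact
  Beta(1.5,1.5) draws;
* `eps` — slice sampling on the log scale (the InvGamma prior on a scale
  is non-conjugate);
* a Metropolis **scale move** (`nu → c·nu`, `rho → rho/c`) along the
  direction that leaves `nu*rho` invariant, accepted against the
  hyperpriors and the Jacobian — the remaining weakly identified
  direction of the full model.

Defaults: 4 chains, 1000 warmup + 1000 kept draws, explicit seed
required.  Convergence is summarized by split-R-hat (threshold 1.05, with
a warning — never silent success); bulk effective sample sizes are
available on demand via arviz.  There is no divergence diagnostic because
the sampler is not gradient-based; calibration is checked empirically
instead (below).  Per-variant testing uses the local false sign rate
`min(Pr[beta>0], Pr[beta<0])` estimated from pooled draws.

Model nesting (model 3 at `rho ≡ 1` equals model 2; at `nu ≡ 0` equals
model 1) is asserted on the likelihood-plus-score-prior density.  The
pinned parameters' own hyperpriors are excluded from that comparison by
construction: Beta(1.5,1.5) has zero density at `rho = 1`, so a comparison
including it would be vacuously −∞; the shared density terms are the
meaningful ones.

## Variance decomposition and summaries

Protein-level shares are posterior-mean plug-ins over non-synonymous
variants: with `V = Var_v(beta_hat)`,

* `share_position = Var_v(phi_hat_{p(v)}) / V`
* `share_aa = Var_v(rho_hat_{p(v)} nu_hat_{a(v)}) / V`
* `share_cross = 2 Cov_v(...) / V` — reported separately so the two main
  shares stay additive
* `share_unexplained = Var_v(beta_hat − prior mean) / V`

Population variances throughout; the shares are location-invariant and
sum to ≈1 on self-consistent fits (the posterior mean of a product is not
the product of posterior means, so exact additivity is not guaranteed).
Shape classification thresholds the spread of `phi_hat` across real
positions (default sd ≥ 0.5) and `share_aa` (default ≥ 0.05): both low →
`no_effect`; spread only → `position_only`; share only → `aa_only`;
both → `both`.  Cross-condition comparison computes, per position, the
population variance across conditions of the posterior means of `phi` and
`rho` and flags `var(phi) ≥ 1` and/or `var(rho) ≥ 0.01`.

## Prediction difficulty and guided subsampling

`prediction_r2_by_bin` bins real positions into quantile bins (default
deciles; any bin count) of posterior-mean `rho` or `sigma2` and reports
the within-bin R² of `beta_hat` against the model's prior-mean prediction
`phi_hat + nu_hat rho_hat` — or against any external per-variant predictor
column (e.g. a pathogenicity score).

The subsampling experiment treats a full screen as the ground-truth pool.
Round 1 samples 20% of each position's variants uniformly and fits the
full model; round 2 adds either a uniform 25% or a `sigma2`-guided
10/20/30/40% across quartile bins of the round-1 `sigma2` estimates (the
arithmetic schedule averages to the uniform rate, so both modes draw the
same expected total; guided draws only from not-yet-sampled variants and
takes what remains when a position is exhausted).  Unsampled variants are
predicted by the prior mean of the refitted model; the held-out reference
score is the per-variant least-squares slope from the **full** aligned
counts — observable, deterministic and identical for both arms, so the
paired difference isolates the sampling policy.  Synonymous variants are
always retained in full because normalization centers on them.  Subset
fits relax the position-merge threshold to 3 variants.

Two design caveats the experiments exposed, both inherent to the method
rather than artifacts: (i) round-1 `sigma2` estimates from ~4 variants per
position are noisy, so the guided gain is only realized when the variance
classes are separated enough to rank reliably — the packaged experiment
therefore uses a two-level quiet/noisy variance design for the guided
comparison, while the predictability analysis uses a continuous variance
spread where decile bins are natural; (ii) under homoscedasticity there is
no signal and the paired difference is centred at zero.

## Synthetic-data generator

`simulate` draws a saturating roster — per position: 19 missense changes
against a random wild type, one synonymous control, one single-residue
deletion (21 variants/position; fractions configurable) — for 50 positions,
T=3 rounds, R=3 replicates by default.  Truth distributions mirror the
model where the model has an informative prior (`phi ~ Normal(0,1)`,
`rho ~ Beta(1.5,1.5)`, raw `nu ~ Normal(0,1)` projected exactly onto the
weighted sum-to-zero space) and use desk-realistic spreads elsewhere:
`sigma2` log-uniform on (0.1, 1.0) — residual spread comparable to the
position-effect scale, and sitting in the bulk of the InvGamma(1,1) prior
so that interval-calibration checks measure calibration rather than
prior/generator mismatch — or discrete levels via `sigma2_levels`;
replicate noise scales 0.1–0.3 across five mean groups; intercepts
`b ~ Normal(0, 0.3)`; per-column library sizes 3e5–1e6.  Aligned counts
are drawn from the likelihood and inverted to raw counts by column-wise
rescaling to the library size and rounding, so preprocessing approximately
recovers the generated `m`.  Everything is deterministic given (config,
seed).

What the generator does *not* emulate: PCR/sequencing error mechanisms,
overdispersed count noise, variant dropout correlated with fitness,
epistasis (multi-mutation variants), or selection dynamics beyond linear
log-growth.  Passing recovery and calibration tests therefore demonstrates
correctness of the inference machinery under the stated generative model,
not robustness to every artifact of real screens.

Calibration observed under these conditions: 90% credible intervals for
`phi` cover truth at ~92–94% (averaged over replicate screens).  The mild
conservativeness is understood: the InvGamma(1,1) prior adds its rate to
the posterior of `sigma2` (+~0.1 at 19 variants/position), slightly
widening position-effect intervals when true residual variances are small.

## Numerical choices and limitations

* `sigma2` floored at 1e−6; `eps` slice-sampled within [1e−4, 1e3] on the
  log scale; `rho` within [1e−9, 1−1e−9].
* Quantile binning uses rank-based equal-frequency splits; duplicate bin
  edges are dropped (fewer bins) rather than erroring.
* Position merging is forward ("into the next position"), terminal
  backward; group labels are `"<first>-<last>"` spans.
* The `nu*rho` scale direction and single-position substitution groups
  are intrinsically weakly identified; the joint block and the scale move
  keep split-R-hat ≈ 1.05 at default settings, with the deletion
  pseudo-position's `rho` the slowest quantity.
* Only single-mutation variants are modelled; multi-mutation rows are
  dropped at ingest.  Scores assume growth screens with log-linear
  trajectories; binding or FACS-based designs are out of scope.
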