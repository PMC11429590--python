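# Methods

This note records the statistical model, the estimation machinery, the
numerical choices, and the limits of what the bundled simulations can
demonstrate.

## Model family

A six-generation biparental design (P1, P2, F1, F2, BC1P1, BC1P2) is
modelled jointly: generation *g* is a finite normal mixture whose
components are major-locus genotype classes.  The generative rule is
the single source of truth for all 24 catalogued models:

1. Enumerate genotype classes per generation with Mendelian
   frequencies (per locus — F2 1:2:1; BC1P1 1 AA : 1 Aa; BC1P2
   1 Aa : 1 aa; loci unlinked, products of per-locus frequencies).
   Genotypes are coded u ∈ {+1, 0, −1} per locus.
2. The class mean is linear in the effects:
   u·d_a + (1−|u|)·h_a + v·d_b + (1−|v|)·h_b plus digenic epistasis
   u·v·i + u(1−|v|)·j_ab + (1−|u|)v·j_ba + (1−|u|)(1−|v|)·l.
3. The polygene contributes a generation mean shift α[d] + β[h] with
   (α, β) = (1,0), (−1,0), (0,1), (0,½), (½,½), (−½,½) for P1, P2,
   F1, F2, BC1P1, BC1P2, and a per-generation variance σ²_pg(g) in the
   segregating generations.  Epistatic polygene variants ("ADI") add
   collective shifts α²[i] + αβ[j] + β²[l]; this coefficient
   convention is the standard generation-mean one, and since no
   external definition of the polygenic-epistasis parameterization is
   available it should be treated as this package's documented choice
   (the free-parameter counts it implies are externally confirmed, the
   coefficients themselves are not).

Each model code is a constraint set: `A` fixes dominance and epistasis
at 0; `AD` fixes epistasis at 0; `ADI` frees everything; `EA` ties
d_a = d_b with no dominance; `CD`/`NCD` tie h_i = ±d_i; `EAD` ties all
additive and dominance effects to a single value (for one locus this
is complete dominance, h = d).  Mendelian weights and design
coefficients are exact rationals; classes whose reduced mean
expressions coincide exactly are merged (structural merging — no
floating-point comparison of realized means).

**Variance convention.**  Every model fits one environmental variance
σ²_e, shared by P1, P2, F1 (and by all generations of pure major-gene
models).  Models with a polygene part additionally fit one free
polygenic variance per segregating generation, so the within-component
variance of generation g is v_g = σ²_e + σ²_pg(g) and the AIC
parameter count is k = (free mean parameters) + 1 + 3.  This
per-generation convention, rather than a single shared σ²_pg, is the
one whose parameter counts are consistent with the published
likelihood/AIC tables of the reference analysis, and it is what allows
σ²_pg estimates like (239.25, 26.25, 0.00) across the three
segregating generations of one cross.

## Estimation

The joint log-likelihood is Σ_g Σ_i log Σ_c π_gc N(x_gi; μ_gc, v_g),
computed with log-sum-exp (stable to |x−μ|/σ ≈ 40).  Maximization is
EM with conditional maximization (IECM):

* **E-step** — within-generation component responsibilities.
* **CM-1** — the free mean vector θ solves the responsibility-weighted
  normal equations Σ_g A_gᵀ diag(N_gc/v_g) A_g θ = Σ_g A_gᵀ S_g/v_g
  (A_g the component design matrix, N_gc responsibility sums, S_g
  responsibility-weighted data sums); exact weighted least squares.
* **CM-2** — the variance block (σ²_e, v_g) is maximized jointly in
  closed form under v_g ≥ σ²_e ≥ floor: unconstrained optima are
  residual sums over n; a segregating generation whose unconstrained
  variance falls below σ²_e is pooled into the σ²_e block (this is the
  σ²_pg ≥ 0 floor, reported per generation via `pg_floor_active`).

Both CM steps are exact coordinate maximizers of the EM Q-function, so
the likelihood is non-decreasing; a decrease beyond −1e−8·(1+|lnL|)
raises immediately.  Convergence is declared when the absolute change
in lnL falls below `tol` (default 1e−8; default `max_iter` 2000).

**Multi-start.**  Mixture likelihoods are multimodal.  The first start
regresses the six generation means on the weight-averaged design rows
(moment start); the remaining `n_starts − 1` (default 10 total) jitter
θ by Normal(0, 0.5·SD_pooled) and the variance inits by a log-normal
factor, all driven by one seeded generator.  The best final lnL wins;
ties within 1e−6 go to the lexicographically smallest |θ|.

**Identifiability convention.**  In mixed models whose major loci are
additive-only (MX1-A-AD, MX2-A-AD, MX2-EA-AD) the transform
(d_i, [d]) → (−d_i, [d] + 2d_i) permutes component means within every
generation and leaves the likelihood exactly invariant, as does
relabelling the two loci.  The reported representative has
|d_a| ≥ |d_b|, d_a ≥ 0 (the P1 allele at the leading locus increases
the trait), and remaining sign ambiguity resolved in favour of the
largest [d] (equivalently d_b ≤ 0) — the sign pattern conventional in
published analyses of this design.  Candidate relabellings are applied
only after an exact symmetry check on the (mean, weight) multisets, so
models where dominance or parental means break the symmetry are never
transformed.

**Numerical safeguards.**  Component variances are floored at
1e−6 × pooled sample variance; a component whose responsibility mass
falls below one individual triggers a starvation warning; a fit that
exhausts `max_iter` is returned with `converged=False` rather than
raising.  Near the optimum EM converges linearly and flat ridges (a
weakly identified second locus) can take ~10³ iterations to reach the
1e−8 tolerance; the model-sweep protocol therefore uses tol 1e−6,
500 iterations, 3 starts (spot-checked against 10-start, 1e−8 runs:
identical maximizers to ~1e−3 lnL).

## Suitability tests

Adequacy is tested per generation on the probability-integral
transform y_i = Σ_c π_c Φ((x_i − μ_c)/σ_c) of the data through the
fitted mixture (exact CDF, fitted — not true — parameters).  U1², U2²,
U3² are Neyman smooth components: squared normalized sample means of
the first three shifted Legendre polynomials on [0, 1], each referred
to χ²(1); U1² equals the first-moment contrast 12n(ȳ − ½)², and U2²,
U3² are the analogous second- and third-moment contrasts.  nW² is the
Cramér–von Mises statistic with the asymptotic (Bessel-series)
significance level; Dn the Kolmogorov statistic with the asymptotic
Kolmogorov level.  Published analyses of this design do not print the
U2²/U3² formulas, so the implemented forms are validated by
calibration: on uniform samples (n = 200, 1000 replicates) each of the
five tests rejects at the 5% level with empirical rate within
[2%, 8%] — this calibration, not any printed table entry, is the
testable contract.  Estimating parameters before the PIT makes the
tests conservative, which matches their screening role.

## Model selection

The two lowest-AIC models advance to the suitability tests; the winner
has the fewest significant statistics (p < 0.05 across 5 statistics ×
6 generations), with ties broken by the smaller free-parameter count
and then by lower AIC.  "Smaller parameter value" is read as "fewer
free parameters", the standard JSA reading.

## Genetic parameters

First-order effects are re-derived from the fitted component means by
generalized least squares on the stacked design matrices, weighted by
effective component sizes (summed responsibilities) over component
variances; because the EM already parameterizes means by θ this is the
identity map when the design has full rank, and the two routes are
required to agree to 1e−6 (a rank-deficient design raises, naming the
confounded parameters).  The polygene dominance degree is [h]/[d],
undefined at [d] = 0.

Second-order parameters per segregating generation: σ²_p is the n−1
sample variance; σ²_e and σ²_pg(g) come from the fit; σ²_mg is
obtained **by subtraction** (σ²_p − σ²_e − σ²_pg, floored at 0 with a
warning) so that the additivity identity holds exactly — subtraction,
not the dispersion of fitted component means, is what reproduces the
additivity of published variance-component tables.  Heritabilities are
percentages of σ²_p.  One published cross-B BC1P2 phenotypic variance
(281.71) contradicts both this identity and the same source's
descriptive table (287.71); the bundled reference values carry the
corrected number and keep the printed one alongside (see
`segjoint/reference.py`).

## Simulator and what the simulations do (and do not) show

`simulate` draws component labels from the exact Mendelian weights and
phenotypes from the component normals; each generation uses an
independent substream of the master seed (adding or resizing one
generation never perturbs another), so runs are bit-reproducible.
Bundled presets encode the two published crosses: effects
(m, d_a, d_b, [d], [h]) = (107.11, 22.43, −6.34, 19.65, −0.52) with
σ²_e = 71.93 and σ²_pg = (0, 239.25, 26.25) for (F2, BC1P1, BC1P2) in
cross A; (103.92, 30.72, −9.61, 15.95, 3.20) with σ²_e = 67.07 and
σ²_pg = (0, 33.91, 73.31) in cross B; generation sizes
50/50/46/217/128/123 (A) and 50/50/48/245/119/111 (B).

The simulator reproduces the statistical structure the analysis
assumes — Mendelian mixtures with normal components.  It deliberately
does not reproduce features of the real data outside that model:
skewness and excess kurtosis within components, selection or scoring
artifacts, or linkage.  Three consequences matter for interpreting
test results:

* **Recovery works where the model is informative.**  At the cross-A
  preset the mean recovered d_a over 20 seeds is within ±2 of 22.43
  and the mean F2 major-gene heritability within a few points of its
  generative value (≈79% — the published 82.5% refers to real data
  whose F2 variance exceeds the model-implied one).
* **The second major gene is near the identifiability boundary.**
  With |d_b| ≈ 6–10 against within-component SDs ≈ 8.2–8.5, the
  sub-mixture it generates (spacing ≈ 1.2σ) is almost exactly normal,
  and the free per-generation σ²_pg absorbs its variance: the
  log-likelihood gain of the two-gene mixed model over its one-gene
  reduction is ≈ 0.05 at n = 100/generation and only ≈ 1.5 at
  n = 2000/generation.  Model selection on data simulated *from the
  fitted parameters* therefore prefers one-gene mixed models — the
  decisive separation seen in the real-data analysis must rest on
  non-normal features the generative model does not carry.  The
  selection study in `scripts/acceptance.py` reports the measured win
  rates under the published parameter values.
* **CV ordering.**  At cross-A parameters the analytic mixture CV is
  largest in F2 among the offspring generations (17.35% vs 17.19%
  BC1P2, 16.96% BC1P1), matching the qualitative claim of the
  reference analysis; at cross-B parameters BC1P2's analytic CV
  (22.98%) marginally exceeds F2's (22.92%) because the model-implied
  BC1P2 variance is much larger than the observed one — a limitation
  of emulating data from fitted parameters, recorded here rather than
  hidden.

## Protocol sizes

Study sizes used by the tests and the acceptance script, chosen once
as a balance between Monte-Carlo error and practical runtime on a
single core: parameter recovery — 20 seeds at the published sample
sizes, 10 EM starts; model selection — 20 seeds × full 24-model sweep
at n = 100 per generation with the sweep EM protocol above; test
calibration — 1000 uniform replicates at n = 200; oracle checks —
50-digit arbitrary-precision naive summation on a 12-point dataset,
closed-form least squares in the single-component limit, and
brute-force genotype enumeration of the MX2-A-AD structures.

## Known limitations

Standard errors and confidence intervals for effect estimates are not
provided (none are reported in the reference workflow).  Linked major
genes, designs other than the six-generation family, and per-locus
polygenic architecture are out of scope.  The ADI polygene mean
parameterization is a documented reconstruction.  AIC-based selection
among these models inherits the classical weakness shown above: major
genes whose effects are small relative to the within-component SD are
statistically invisible at realistic sample sizes.
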