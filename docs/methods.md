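# Methods

`sirenorm` implements a three-stage mapping pipeline for genotype-by-
environment interaction (GxE) in progeny-tested dairy populations,
together with a synthetic-data generator that makes every stage
verifiable end to end.

## The reaction-norm sire model

A corrected daughter yield `cy`, recorded at a herd test day (HTD) whose
quality is summarised by a standardised environmental descriptor `E`, is
modelled as a first-order random-regression sire model:

    cy_ijk = mu + b*E_k + s_j0 + s_j1*E_k + d_ij0 + d_ij1*E_k + e_ijk

for daughter `i` of sire `j` at HTD `k`.  The sire pair (s_j0, s_j1) is
multivariate normal with an unstructured 2x2 covariance, i.i.d. across
sires; the daughter pair (d_ij0, d_ij1) likewise, nested in sires.
Residual variance is heterogeneous across 10 classes of equal size
formed by ranking records on `E` (deciles), with zero covariance across
classes.  Because `E` is centred at the average environment, the sire
intercept BLUP estimates *general production* (GP) and the slope BLUP
*environmental sensitivity* (ES); variance in the slope is GxE.
Sires are modelled i.i.d. rather than pedigree-correlated; with large
daughter groups the estimates are driven almost entirely by progeny
records, and the package can refit the same likelihood with sire
effects correlated through the numerator relationship matrix A to
verify the simplification (the acceptance suite checks that the two GP
vectors correlate above 0.98 at 150 daughters per sire).

### Environmental descriptor

The descriptor of an HTD is its mean milk *energy yield*,
`0.802*milk + 38.4*fat + 23.6*protein` (kilogram inputs), a single
linear combination of the three highly correlated production levels.
HTD means are standardised over HTDs (each HTD weighted equally) with
the sample SD (ddof = 1).  In operational practice the HTD levels would
come from a routine genetic evaluation; here they are within-HTD means
of record-level energy yield, the natural estimator when no external
evaluation exists.  Residual classes are contiguous groups of records
ranked by `E`; group sizes differ by at most one, remainder records go
to the lowest classes, ties keep stable record order.

### REML evaluation and fitting

The restricted likelihood is evaluated exactly in O(n) by two nested
low-rank absorptions: daughter blocks (at most 2x2) are absorbed into
the record metric first, then sire blocks (2x2).  With pedigree-
correlated sires the sire-level system becomes one 2q x 2q solve per
evaluation (q = number of sires), using A^-1 ⊗ G_s^-1 plus the
block-diagonal absorbed information.  Covariance blocks are
parameterised by log-Cholesky factors and residual variances by logs,
so every iterate is positive definite by construction.  Optimisation is
L-BFGS-B with 3-point numerical gradients, one restart from the best
point (a fresh quasi-Newton memory reliably clears stalls on this
surface), and a Nelder-Mead fallback; variances are floored at 1e-10
times the phenotypic variance and estimates at the floor are reported
as 0 with a boundary flag.  Convergence uses relative log-likelihood
change (1e-10) under an iteration cap of 200; non-convergence raises an
error carrying the best state found.  Standard errors for the sire
components come from a central-difference Hessian on the working scale,
pseudo-inverted and mapped by the delta method.

**A deliberate non-identifiability.**  With the default design of one
record per daughter, the daughter intercept variance enters the
marginal likelihood only as a constant added to every record's
residual variance, and a constant lies in the span of the 10 decile
step functions: the REML surface has an exactly flat ridge between
`sigma_d0_sq` and a uniform shift of the residual-class variances.
The fit is well defined in likelihood, fixed effects, sire components
and BLUPs — only the split between daughter intercept and residual
level is arbitrary, which is why the pseudo-inverse is used for the
Hessian and why recovery tests assert sire components only.  Repeated
records per daughter (`records_per_daughter > 1`) restore full
identifiability.

### Log-scale mode

On log-transformed yields the full model is poorly conditioned, so the
`homogeneous_intercept_daughter` mode drops the daughter slope and uses
a single residual variance; the sire intercept/slope block is kept.
This is a mode switch on one likelihood implementation, not a separate
code path.  Whether the log-scale sire slope variance is distinguishable
from zero is assessed by a REML likelihood-ratio test against the
intercept-only sire model, referred to a 0.5*chi2(1) + 0.5*chi2(2)
mixture because one variance sits on the boundary and the covariance is
then unidentified; this is the package's operational definition of "the
transformation removed the interaction", since a raw REML point
estimate of a true-zero variance is positive with probability about
one half and is therefore not a usable indicator by itself.

## Association and validation

Sire GP or ES estimates are the response of a per-SNP mixed linear
model `s_hat_j = mu + b_k*x_jk + u_j + e_j`, with `x` counting copies
of the SNP's more frequent allele (designated on the full post-QC panel
before the split, so signs are comparable across sets) and
`u ~ N(0, A*sg2)` controlling population structure via the pedigree
numerator relationship matrix.  A is eigendecomposed once per sire set;
each SNP then costs a one-dimensional profile of the restricted
likelihood over the variance ratio (searched on log gamma in [-16, 16]
plus the gamma = 0 boundary) and a weighted regression.  The variance
ratio is re-profiled per SNP (exact); p-values are Wald tests with a
normal reference, appropriate at the sire counts involved and verified
by permutation calibration.  Discovery significance is P < 0.001;
false-discovery-rate q-values follow Storey's procedure, with pi0
estimated on the lambda grid 0.05..0.95 (step 0.05) by a natural cubic
fit evaluated at the largest lambda and clipped to (0, 1]; forcing
pi0 = 1 reproduces Benjamini-Hochberg exactly.  The q-value of the
weakest significant SNP estimates the false-positive share among the
significant set.  A SNP is *validated* when its refit on the held-out
sires gives P < 0.01 with the same strict effect sign (a zero estimate
never validates); validation-set estimates are the reporting estimates
because discovery-set estimates at selected loci are inflated (Beavis
effect).  The same A (restricted to the relevant sires) serves both
fits.

## Scaling decomposition

Scaling GxE — spread changes across environments without re-ranking —
is removable by a monotone transformation; persistent GxE is not.  The
package runs the observed-scale pipeline (full model) and the log-scale
pipeline (reduced model on ln yields) on the *same* discovery/validation
split and classifies every SNP tested for ES as `observed_only`
(scaling-removable), `both` (persistent), `log_only` or `neither`.

One model-selection guard is essential here.  When a scale's true sire
slope variance is zero, REML typically fits a tiny positive slope
variance together with a noisy intercept-slope covariance, and the
slope BLUPs then reduce to (covariance) x (intercept information) — a
deterministic multiple of the GP estimates.  Association statistics
are scale-invariant, so an "ES" scan on such estimates silently tests
general production, and any GP locus would appear to validate for ES.
The comparison therefore runs a scale's ES association only when that
scale's slope variance is statistically supported by the slope LRT
(default alpha 0.05); an unsupported scale contributes an empty
validated-ES set, which is the correct reading of "no detectable
genetic variance in environmental sensitivity on this scale".
Only the natural log is implemented; the transformation is injectable
for Box-Cox-style extensions but none is provided.  Effects are
reported raw and standardised by the fitted sire slope SD of their own
scale so the two scales are comparable.

## Genotype quality control

Individuals with more than 10% missing genotypes are removed first
(strict inequality); SNP statistics are then computed on the survivors.
A SNP fails for minor allele frequency < 3%, call rate < 90%,
Hardy-Weinberg 1-df chi-square P < 0.001 (no continuity correction; the
conventional, hand-verifiable default), unknown position, or a
sex-chromosome label; every failure reason is recorded and a SNP fails
iff at least one reason is present.  Setting a numeric threshold to 0
disables that filter.  Sporadic missing calls surviving QC are imputed
to the modal genotype class, ties broken toward the class nearest the
expected dosage 2f and then toward the smaller class — haplotype-based
imputation is out of scope and at sub-10% missingness the choice is
low-impact.

## Pedigree relationships

A is assembled by the tabular method over the pedigree closure of the
requested ids and then restricted: a_ii = 1 + a(sire,dam)/2,
a_ij = (a(j,sire_i) + a(j,dam_i))/2, unknown parents acting as
unrelated non-inbred founders.  Cycles and requested ids absent from
the pedigree are hard errors.  No A-inverse (Henderson rules) or
genomic relationship matrix is built; the association model needs A
itself at moderate sire counts.

## The synthetic-data generator

The generator emulates a daughter design: `n_sires` genotyped sires in
a two-generation half-sib pedigree (grandsire founders), each with
`daughters_per_sire` ungenotyped daughters recorded once (by default)
at an HTD drawn uniformly; HTD environments are i.i.d. standard normal
(no herd time-series structure).  Genotypes are Hardy-Weinberg draws at
unlinked SNPs with allele frequencies from `maf_range`; there is no
linkage disequilibrium, selection or generation overlap.  Sire effects
are a QTL part plus a polygenic remainder: QTL effects come from a
two-component mixture (many small, few large) and are rescaled so the
realised QTL covariance over sires equals `qtl_var_fraction` times the
target sire covariance exactly, with the polygenic remainder drawn from
the complement — so total sire (co)variances converge to the configured
2x2 matrix.  In multiplicative mode yields are
`mu * exp(b*E + s'_0 + d'_0 + e')` with all parameters on the log
scale and no slope terms: observed-scale GxE is then pure scaling by
construction, the canonical positive control for the decomposition.
All randomness flows from one seed through named substreams, so each
stage's output is bit-reproducible and unchanged when other stages'
parameters move.

### Default parameter choices

Sire components default to a German Holstein protein-yield scale
(grams per test day): intercept variance 2379.37, slope variance 17.02,
correlation 0.79; overall mean 1000 g and a fixed environment
regression of 40 g per environment SD.  Daughter and residual defaults
(`sigma_d0_sq` = 1200, `sigma_d1_sq` = 12, `rho_d` = 0.5; residual
decile variances linearly spaced 900..1800 g^2) are deliberately
moderate: the generator emulates yields *already corrected* by a
routine evaluation, and the defaults were fixed once so that sire
components are estimable with usable Monte-Carlo precision at
desk-scale designs (hundreds of sires, tens of daughters).  Raw
test-day data carry substantially larger daughter and residual
variation; passing recovery tests at these settings demonstrates
correctness of the estimator, not attainable accuracy on raw field
data.  The multiplicative preset uses log-scale variances of 0.003
(sire), 0.0015 (daughter) and 0.0017 (residual), i.e. coefficients of
variation of a few percent, matching the observed-scale defaults in
spirit.

## Problem sizes used by the test and acceptance suites

Oracle-equivalence checks run on instances of at most 50 records
against naive dense-matrix implementations.  Variance-component
recovery uses 20 replicates of 500 sires x 60 daughters; the
pedigree-simplification check uses 200 sires x 150 daughters; type-I
calibration scans 10,000 null SNPs at 1797 discovery sires; the
scaling decomposition uses 10 replicates of 240 sires x 60 daughters
with one planted intercept QTL explaining 70% of the log-scale sire
variance and a fixed log-scale environment regression of 0.15 (chosen
a priori so the validation stage has adequate power at 60 held-out
sires).  These sizes make the whole suite run on a single CPU in
minutes while leaving every statistical check non-trivial.

## Known limitations

- First-order reaction norms only; no quadratic terms, no repeated-
  records permanent-environment modelling.
- Single-trait analyses; the three milk component yields enter only
  through the energy-yield descriptor.
- The generator's auxiliary milk/fat/protein columns are a convenience
  for exercising the descriptor stage, not a full multi-trait model.
- No LD, so mapping resolution questions (clumping, fine-mapping,
  multi-marker models) are out of scope.
- Association assumes complete post-QC genotypes (imputation first).
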