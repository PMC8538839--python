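# Methods

## Scientific setting

`airmeth` implements the analysis chain of a repeated-measures epigenetic
exposure-biomarker study: residential prenatal particulate-matter exposure
(PM2.5 and PM10) is assigned from ambient monitor networks by
inverse-distance weighting; saliva DNA methylation measured on a 450k-style
array at two childhood visits (around ages 9 and 15) is quality-controlled
and summarized into *cumulative DNA-methylation scores* — weighted sums of
beta values at exposure-associated CpGs, with weights taken from an
independent cord-blood meta-analysis — and the scores are regressed on
exposure with per-visit linear models and random-intercept mixed models,
reporting effects per interquartile range (IQR) of exposure.

Because the motivating cohort's individual-level data are restricted, the
package ships a first-class synthetic-cohort generator whose defaults
encode that cohort's published summary statistics.  Every downstream stage
is exercised, and its statistical behaviour tested, against this generator.

## Exposure assignment (inverse-distance weighting)

Daily concentration at a residence p on day t is

    c(p, t) = sum_k x_k / d_k  /  sum_k 1 / d_k

over monitors k within 60 km (inclusive) reporting on t, with d_k the
haversine distance (mean Earth radius 6371.0088 km) and power 1.  A monitor
coinciding with the residence returns its own value (the d -> 0 limit).
The window exposure is the mean of daily values over the 91 days ending
the day *before* the anchor date (a half-open three-month window; the
source analysis never defines its month arithmetic, so 91 days is fixed
here as the design choice).  Days without an in-radius reading are omitted
from the mean; if fewer than 75% of window days are covered
(`min_coverage`, configurable) the estimate is reported missing rather
than extrapolated.  Monitor selection is evaluated daily.

## Methylation QC

Sample filters, applied in order with first-match attribution:

1. **detection** — strictly more than 10% of probes with detection
   p > 0.01;
2. **sex_discordant** — methylation-predicted sex differs from recorded
   sex (the predicted-sex call is consumed as a precomputed feature;
   re-implementing array sex prediction is out of scope);
3. **abnormal_intensity** — sex-chromosome intensity outside a configurable
   band (default ±2 on the generator's standardized intensity scale; no
   published numeric definition exists, so the band is a labelled feature
   of the generator).

Probe filters: detection p > 0.01 in **at least** 5% of post-sample-QC
samples (the inclusive reading of an ambiguous "in 5% of samples"), plus a
user-supplied cross-reactive blocklist.  In the pipeline the probe filter
runs on the visit-pooled detection matrix so both visits share one probe
set.  Both filters are idempotent.

Cell composition uses a two-cell immune/epithelial model: a sample's beta
vector at reference CpGs is fit as p·immune + (1−p)·epithelial with
0 ≤ p ≤ 1.  For two cell types with a sum-to-one constraint this is a 1-D
problem whose constrained least-squares solution is the unconstrained
scalar estimate projected onto [0, 1]; the implementation is exact, and
collinear reference columns raise an error carrying the condition number.
The packaged reference matrix is synthetic (the published childhood saliva
panel is not redistributed); real-data use requires supplying a real panel.

## Cumulative scores

For weight table {w_j} and beta matrix β (CpG × sample):

    S_i = sum_j w_j · t(β_ij),

with t the per-site z-score (`zscored`, the primary variant), identity
(`raw`), or per-site mean-centering (`centered`).  Site statistics are
computed over the standardization population — all QC-passing observations
pooled across visits by default (`standardize_pop="visit"` switches both
site statistics and the final standardization to within-visit).  S is then
z-score-standardized over the same population, so modelled effects are in
SD units.  Missing weight-table CpGs are dropped with a warning and
reflected in `n_sites_used`; weights are *not* renormalized, preserving
the semantics of the source weights at the cost of comparability (logged).
Zero-variance sites are dropped under `zscored`.

Two provable identities are used as tests: after standardization `raw` and
`centered` are identical (centering shifts every sample's sum by the same
constant), and rescaling all weights by a common factor leaves standardized
scores unchanged.

The PM10 weight table contains the six published cord-blood meta-analysis
sites (cg00905156, cg06849931, cg15082635, cg18640183, cg20340716,
cg24127244; weights 0.001, −0.001, 0.001, 0.001, −0.002, 0.001).  The
PM2.5 (14 sites) and NO2 (10 sites) tables are synthetic placeholders —
the corresponding published site lists are not reproduced — shipped so the
multi-pollutant pipeline runs end to end; their filenames and docstrings
say so.

## Association models

All models adjust for child sex, age at methylation measure, maternal
income-to-needs ratio, marital status (reference: married), race/ethnicity
(reference: largest category), and the immune cell proportion.  With
exactly two cell types the estimated proportions sum to one, so including
both immune and epithelial would be rank-deficient; the immune fraction
alone carries the same information.  Analyses are complete-case.

* Per-visit models: OLS; CI and p from the t distribution with residual
  degrees of freedom.
* Pooled models: random-intercept linear mixed models fit by REML
  (statsmodels MixedLM), Wald-z intervals on the fixed exposure effect;
  participants with a single observation are retained.  When every
  participant has one observation the fit degenerates to OLS (tested to
  1e-6).
* Effects are reported per exposure IQR: per-unit coefficient × IQR.  The
  IQR is the analytic subsample's by default; the fixed reference IQRs of
  the motivating cohort (10.73 µg/m³/day for PM2.5, 3.20 for PM10) can be
  supplied for exact comparability, and are what the calibration targets
  use.  No multiple-testing correction is applied, matching the reporting
  convention being emulated.
* Bivariate median-split tests (ties to the lower stratum): Welch t for
  continuous covariates; Fisher's exact for 2×2 categorical tables and a
  seeded Monte-Carlo Freeman–Halton test (2000 tables drawn with fixed
  margins via `scipy.stats.random_table`) for larger tables, since no
  exact r×c Fisher implementation exists in the stack.
* Sensitivity suite: co-pollutant adjustment, postnatal (age-1/age-3)
  exposure adjustment, an NO2-score specificity check, and single-CpG
  models for the six PM10 sites with percent methylation (100×beta) as the
  outcome.  Rank deficiency raises an error listing the aliased terms.

## Synthetic-data generator

The generator is the package's test-bed and defines the study conditions;
all of the following defaults are fixed constants of the design.

**Exposures.**  Six variables (PM2.5/PM10 × birth/age-1/age-3 windows) are
drawn through a Gaussian copula with truncated-normal marginals.  The
marginals are *moment-matched*: the parent mean/sd are solved numerically
so that the realized truncated distribution has the target mean, sd and
range — PM2.5 mean 27.9, sd 7.04, range 14.3–45.0 µg/m³/day; PM10 mean
15.0, sd 3.06, range 7.5–20.2 (naively truncating at the target moments
would shift the realized mean by ~0.3 µg/m³).  Latent correlations use the
published values where they exist (PM2.5 birth–age1 0.54, birth–age3
0.57; PM10 0.71, 0.69; cross-pollutant at birth 0.20) and one-time
generator choices elsewhere (PM2.5 age1–age3 0.55; PM10 age1–age3 0.70;
cross-pollutant cross-window 0.12); the assembled 6×6 matrix is checked
for positive semi-definiteness and an informative error names the
offending block otherwise.  The copula preserves the latent Pearson
correlations only approximately (attenuation under these truncations is
≲0.01).  Real exposure distributions are skewed — the published IQRs
(10.73, 3.20) are inconsistent with a truncated normal at the published
sd — so the reference IQRs are carried as constants rather than re-derived
from the synthetic marginals.

**Monitors and residences.**  Each residence sits on a grid with >120 km
pairwise separation and has one co-located monitor whose daily series in
each 91-day window is noise around the drawn window mean, recentred so the
window mean is exact.  The IDW stage therefore round-trips the planted
exposures exactly, giving the pipeline a checkable invariant.  This
deliberately sacrifices spatial realism (no shared monitors, no urban
clustering); IDW's numerical behaviour is tested separately on
multi-monitor fixtures.

**Methylation.**  Score-CpG betas follow β_ij = b_j + s_j·z_ij with
mid-range baselines b_j ~ U(0.3, 0.7), scale 0.05 (betas clipped to
(0, 1); the per-site affine scale cancels out of the standardized score),
and latent z_ij = ρ_j·Ẽ_i + sqrt(1−ρ_j²)·η_ij, where Ẽ is the
standardized realized prenatal exposure.  Taking ρ_j = r·sign(w_j), the
planted standardized-score slope per reference IQR, δ, gives the
closed-form loading

    r = sign(δ) · sqrt( D²B / (A² − D²(A² − B)) ),
    D = δ·sd(E)/IQR_ref,  A = Σ|w_j|,  B = Σw_j².

Defaults plant δ = −0.029 (PM2.5), −0.024 (PM10), 0 (NO2, the specificity
null).  The site residual η is split into a cross-visit-shared and a
visit-unique part with mixing λ per pollutant; λ defaults are solved from
the closed-form score-correlation identity so the between-visit score
correlations hit the published 0.55 (PM2.5) and 0.22 (PM10) (with these
tiny loadings, λ ≈ the score correlation).  Background CpGs are bimodal
logit-normal (modes near beta 0.1 and 0.9, logit-scale noise sd 0.3),
drawn independently across visits — the within-person correlation of
non-score CpGs is not published and is a generator choice.  Reference
CpGs mix a synthetic immune/epithelial reference with per-observation
immune fractions drawn from a Beta distribution matched to mean 0.939,
sd 0.10 (the published sd, 0.136, implies a Beta shape parameter below 1
with an integrable spike at 1; 0.10 keeps proportions realistic while
preserving the mean — a deliberate mild departure).  Detection p-values
are U(0, 0.005) for good calls and U(0.02, 1) for planted failures, so
the 0.01 threshold is never ambiguous.

**Structure and faults.**  Visit membership is count-exact (defaults
747 both / 2 age-9-only / 46 age-15-only, reproducing the analytic
749/793/1542 counts; `flowchart_config` provides an 1811-observation
pre-QC preset with planted fault counts 43/20/3 — the pre-QC visit split
is not published and is a generator choice).  Fault injection samples
disjoint observations without replacement: detection faults flip 12% of a
sample's probes (safely past the 10% rule), sex faults flip the predicted
sex, intensity faults push the intensity to ~3, outside the ±2 band.
Covariates are drawn from the published frequency profile (50.1% male;
race/ethnicity 16.6/56.3/19.8/2.9/4.4%; 23.7% married; income-to-needs
lognormal with mean 2.27, sd 2.49; visit ages N(9.30, 0.34²) and
N(15.4, 0.49²)) independently of exposure, so adjusted and unadjusted
planted slopes coincide in expectation.  One integer seed drives
everything; identical config + seed reproduces the cohort byte-for-byte.

## What the synthetic data do and do not show

The generator reproduces the *statistical interface* of the real study —
marginal calibration, cross-time exposure correlation, longitudinal score
stability, planted effect sizes, QC fault counts — but not: spatial
monitor structure, probe-type chemistry or batch effects, correlation of
covariates with exposure (confounding), cell-composition dependence of
score CpGs, or skewed exposure marginals.  Passing tests therefore
validate the correctness and calibration of the *methods*, not the
substantive findings on any real cohort.

## Numerical choices

* Truncated-normal moment matching: `scipy.optimize.root` on (mu,
  log sigma), tolerance 1e-12.
* Degenerate score sites: a site sd at float-epsilon scale (≤1e-12) is
  treated as constant and dropped under `zscored`.
* Deconvolution collinearity: ‖immune − epithelial‖² below 1e-12 per CpG
  raises, reporting the reference condition number.
* Median split ties go to the lower stratum; Monte-Carlo Fisher p uses the
  add-one estimator (1 + #{P_sim ≤ P_obs})/(B + 1), B = 2000.
* Mixed models: REML, Wald-z CIs; ML and profile intervals are not
  implemented (configuration `reml=False` gives ML point estimates).
* Problem sizes in the shipped checks: calibration at n = 10,000 draws;
  paired-score correlations on 747-pair cohorts (averaged over 8 seeds);
  effect recovery over 200 replicates of n = 735; null coverage over
  400–500 replicates at n = 120.

## Known limitations

* Two-cell deconvolution only; multi-cell reference panels (Houseman-type)
  are out of scope.
* The PM2.5/NO2 weight tables are placeholders; conclusions about those
  pollutants' scores on real data require the real weights.
* The IDW module handles calendar dates only (no time zones) and point
  coordinates (no census-tract polygons).
* Survey design features of the emulated cohort (3:1 unmarried oversample)
  are noted but not modelled; no survey weights.
* The mixed model assumes a single random intercept; random slopes and
  serial correlation structures are not exposed.
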