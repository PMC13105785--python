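# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions adopted where the design was
genuinely open.

## Toxicity grading and the hematologic toxicity index

Weekly lab series are graded per analyte against CTCAE v5.0 laboratory
bands shipped as an editable YAML config (`toxbiome/data/ctcae_v5.yaml`).
Each band is a half-open interval [lower, upper) in the analyte's units
(10⁹/L for counts, g/L for hemoglobin); bands must be contiguous, cover
(0, ∞), and grade must increase as the value falls. Two conventions in the
config are editable rather than canonical: the grade-1 lower bounds are
local lower-limits-of-normal, and grade-4 anemia — which CTCAE defines
clinically, not by a cutoff — is given a 65 g/L bound so grading stays a
pure function of the lab value. Every grading run records a hash of the
config. The pre-treatment baseline (week 0) is included in the max-grade
scan by default (configurable): treatment-era grading does not exclude
baseline cytopenias.

The hematologic toxicity index collapses a patient's per-AE maximum grades
into one number. The defining sum is order-dependent, and the grades are
sorted **descending** before evaluation. This makes the index a pure
function of the grade multiset, dominated by the worst toxicity: for any
grade set with maximum g ≥ 1, g ≤ HTI < g+1 (verified exhaustively over all
5-tuples of grades 0–4). Zero grades contribute nothing and leave the
denominators unchanged, so all five AEs can always enter the formula.

Cohort tables dichotomize each AE at grade ≥ 1 (lymphopenia at ≥ 3, the
clinically used 0–2 vs 3–4 split) and the HTI at ≤ median vs > median with
ties to the lower group. The default categorical test is Pearson chi-square
with 1 df and no continuity correction; Fisher's exact test is behind a
flag. Chi-square is the default because the cohort table's printed p-values
are reproduced to three decimals by chi-square (verified against the
two-proportion z² identity), not by Fisher's method.

## Diversity

Counts are total-sum normalized before every diversity computation; there
is no rarefaction, so results are deterministic. Shannon entropy uses the
natural log (the convention of the common R ecology tooling — the base
changes values, so it is pinned); inverse Simpson is 1/Σp². Beta diversity
is Bray–Curtis on relative abundances; PCoA is the classical Gower
double-centering of −d²/2 followed by eigendecomposition, with negative
eigenvalues reported raw (no Cailliez/Lingoes correction by default) and
proportion explained taken over the positive eigenvalues only.

PERMANOVA partitions the distance-based total sum of squares
(Σ_{i<j} d²ᵢⱼ / n) sequentially (type-I) over an ordered term list via
hat-matrix projections of the Gower-centered matrix, so term order matters
and is the caller's choice; R² per term plus residual sums to 1. p-values
use whole-row permutations, p = (1 + #{F\* ≥ F}) / (1 + n_perm), with a
relative tie tolerance of 1e-9 on the F comparison so that
label-equivalent permutations (which reproduce the observed F up to
floating-point noise) count as "as extreme" — without it the permutation p
is biased low on small designs.

The Scheirer–Ray–Hare test mid-ranks all N observations jointly and forms
two-way ANOVA sums of squares on the ranks (sequential: A, B, A×B, the
convention of the test's common implementations for unbalanced designs).
H = SS_effect / (SS_total/(N−1)) with SS_total computed from the actual
mid-ranks; because tied mid-ranks shrink SS_total by exactly the classical
factor D = 1 − Σ(t³−t)/(N³−N), this H equals the textbook tie-corrected
H′ = H/D, and with one single-level factor it reduces exactly to the
tie-corrected Kruskal–Wallis statistic (asserted in the tests). Constant
data yields H = 0, p = 1 with a warning.

## Multivariable associations

Feature tables are prevalence-filtered (default: present in ≥ 10% of
samples above a zero abundance floor), total-sum normalized, and
log2-transformed with a per-feature pseudocount of half the minimum
positive normalized value — the pinned reading of the association tooling's
"default parameters". Each feature is then fit by ordinary least squares on
a target variable plus fixed-effect covariates; random effects are excluded
by design (few repeated measurements per subject make the random-effect
variance unstable). Per-target p-values from the coefficient t-test are
BH-adjusted **across features within each target**, matching per-association
q-values, with significance at q < 0.25. Rows with missing covariates are
dropped and logged; a rank-deficient design is an error rather than a
silent pseudo-inverse fit.

The LEfSe-style screen rescales abundances to a per-sample total of 1e6,
filters by Kruskal–Wallis across classes (α = 0.05), and scores survivors
by log10 of the between-class mean gap (floored at 1 so tiny gaps cannot
produce negative infinities), optionally averaged over seeded 2/3
subsamples. The canonical one-against-all subclass (Wilcoxon) stage is
omitted: the study design has no subclass structure. With n_boot = 0 the
screen is fully deterministic.

## Co-occurrence networks and driver taxa

Networks are built per group (e.g. low vs high toxicity, post-treatment
samples only) from Spearman correlations between relative abundances of
taxa present in ≥ 20% of samples; pairwise p-values are BH-adjusted across
all pairs and edges kept at q ≤ 0.05 and |ρ| ≥ 0.3. Spearman on relative
abundances is a deliberate, simple choice; compositionality-aware
estimators (SparCC-style) are out of scope. Fewer than 10 samples is
refused outright — rank correlations on fewer are noise.

Driver scoring between a low- and a high-toxicity network is
**NetShift-inspired, not the published NESH formula** (which is not fully
specified in the sources this package follows): per shared node, the
neighbor-shift score is the Jaccard distance between its neighbor sets, the
betweenness delta is normalized shortest-path betweenness (high − low), and
the combined score is neighbor-shift × max(delta, 0) rescaled to [0, 1],
with nodes at or above the 0.9 score quantile (and positive score, hence
rising betweenness) flagged as drivers.

## Two-sample Mendelian randomization

Instruments are exposure SNPs with p < 1e-5, greedily clumped in ascending
p order: a kept SNP removes remaining candidates within 1000 kb whose r²
with it strictly exceeds 0.01 ("strictly" is the adopted reading of the
exclusion rule). Harmonization aligns outcome to exposure effect alleles:
swapped alleles flip the outcome beta and frequency; strand complements are
resolved by complementing first; palindromic (A/T, C/G) SNPs are kept only
when both allele frequencies are away from 0.5 (MAF ≤ 0.42, the common
tooling convention) and agree in orientation, otherwise dropped;
instruments absent from the outcome take the highest-r² proxy at r² ≥ 0.8
(proxy effect sizes are used as-is, with no r² attenuation adjustment — a
documented simplification), else are dropped. Every decision is recorded in
a per-SNP audit table, and harmonization is idempotent.

Estimators: IVW is the weighted regression of outcome on exposure betas
through the origin (weights 1/se²_out) with the standard error scaled by
max(1, residual SD) — multiplicative random effects, the common default;
a fixed-effect variant is a flag, and a single SNP reduces to the Wald
ratio βy/βx with se = se_out/|βx|. MR-Egger adds a free intercept with
exposure effects sign-oriented positive; slope and intercept are t-tested
on n−2 df with the same max(1, ·) scale factor. The weighted median uses
weights β²x/se²_out with cumulative-weight interpolation at 0.5; its
standard error comes from a seeded parametric bootstrap (default 1000
draws) rather than a closed form, trading a little runtime for a
reproducible, transparent estimator. Sensitivity: Cochran's Q on the Wald
ratios with first-order weights (χ², n−1 df), the Egger intercept test,
and leave-one-out IVW.

## Synthetic-data generators

The generators define the conditions under which the pipeline is tested;
all are pure functions of their parameters including the seed, and a single
global seed expands into per-component child seeds by fixed offsets.

**Cohort.** Blood counts evolve multiplicatively from a lognormal baseline:
value(week) = baseline × decline^week × lognormal noise, which keeps values
positive and yields realistic grade mixes. The planted sex effect
multiplies the weekly **decline rate** of one sex (default: females, 0.95),
not the baseline — the disparity is treatment-induced, not constitutive. An
oxaliplatin effect (0.93) adds lymphocyte-specific decline for the ~35% of
patients on the oxaliplatin-containing regimen. Default baselines are
population-typical adult values (WBC 6.6, ANC 4.2, ALC 1.9 ×10⁹/L, Hgb 140
g/L, Plt 250 ×10⁹/L) and the noise scale is per-analyte (0.18–0.20 for
leukocyte lineages, 0.06 for hemoglobin, 0.12 for platelets — hemoglobin
varies far less week to week). The per-analyte declines (0.91, 0.90, 0.80,
0.98, 0.95 per week over 5 weeks) were chosen once so the induced AE
frequency profile resembles a pelvic-chemoradiotherapy cohort: nearly
universal lymphopenia with roughly half grade 3–4, leukopenia in about
two-thirds, neutropenia and anemia in roughly a third, thrombocytopenia
uncommon. The defaults are configurable and are not calibrated to any
individual cohort's per-analyte distributions, which are not published.

**Microbiome.** Taxon log-abundance baselines are N(0, 2); per-sample
compositions are softmax of the baselines shifted by planted sex (log-fold)
and HTI (log-fold per index unit) effects, drawn Dirichlet(c·p) with
concentration c = 200 and then multinomial at the sequencing depth (50 000
by default), so per-sample totals equal the depth exactly. The longitudinal
structure is a mid-treatment alpha-diversity dip for low-toxicity subjects:
from time point 2 on, their centered log-abundances are stretched by
time_dip × 0.5^(t−2) (dip 0.5, halving each later time point — a dip with
slow recovery). A single-time-point dip was tried first and discarded: it
caps the rank-test group-effect power near 0.75 regardless of magnitude,
and the decay profile is also the more faithful emulation of a
dip-then-slow-recovery trajectory. Metabolite intensities are log-normal
with planted linear sex/HTI effects on the log scale, matching the
downstream log-linear association model.

**GWAS pairs.** SNPs sit every 50 kb on one chromosome with block-diagonal
AR(1) LD (|ρ| < 1) and zero LD between blocks; the first SNP of each of the
first n_instruments blocks carries a positive exposure effect U(0.08, 0.25)
with se 0.01 (z ≥ 8, comfortably past the p < 1e-5 gate), remaining SNPs
are null. Positive instrument effects encode the usual convention that the
effect allele is the trait-increasing allele, which is what makes planted
pleiotropy *directional*. Outcome effects are θ·β_true + pleiotropy +
noise with pleiotropy ~ N(mean, sd) per SNP. The truth record stores θ, the
instrument ids and the pleiotropy draws.

**What the generators do not emulate:** read-level data, chimeras and batch
effects, real LD panels or genotypes (LD is summary-level only), real
taxonomies, correlated AE lineages beyond the shared decline structure, and
informative missingness. Passing tests therefore demonstrate correctness of
the statistics and recoverability of planted effects under clean
conditions, not robustness to every artifact of real sequencing data.

## Calibration and problem sizes

The test suite checks, beyond unit oracles: empirical type-I error in
[0.03, 0.07] at α = 0.05 over 500 seeded replicates for PERMANOVA (n = 20,
99 permutations), Scheirer–Ray–Hare (N = 80), the per-feature association
t-test (100 samples × 50 features) and the Egger-intercept test (50
instruments); IVW recovery of θ = 0.3 within 0.05 and 95% CI coverage in
[93%, 97%] over 500 replicates; planted microbiome sex/HTI effects
top-ranked by the association stage (200 samples, depth 50 000); and the
planted diversity dip detected by the rank test with power ≥ 0.8 at 120
samples. Monte-Carlo checks of the cohort generator use 200 replicates of
n = 400. These sizes were chosen as the smallest at which the binomial
noise of the check is well inside the asserted bands.

Under a global null, BH at q < 0.25 still makes at least one discovery with
probability close to the q threshold; the null-calibration test therefore
asserts an empty significant set in ≥ 70% of replicates and a mean
false-discovery fraction ≤ 0.25, which is what FDR control guarantees.

## Known limitations

* CTCAE numeric bands ship as a best-effort transcription with two
  editable conventions (LLNs, grade-4 anemia bound); site-specific configs
  should replace them.
* Sequential (type-I) PERMANOVA R² depends on term order; marginal SS is
  not implemented.
* The driver score is a labelled stand-in for NESH; absolute scores are
  comparable within one network pair only.
* Weighted-median bootstrap standard errors are seed-dependent at the third
  decimal for small instrument counts.
* The MR stack assumes summary statistics on a continuous scale; binary
  outcome log-odds are handled only through the exponentiated odds-ratio
  view of the estimates.
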