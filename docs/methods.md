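# Methods

## Model

`mutpath` treats a cohort of tumors of one cancer type as the unit of
analysis. Three data layers enter: a log-scale expression matrix (genes ×
samples), a 0/1 matrix of gene-level non-silent somatic mutation
indicators, and a numeric matrix of gene-level copy-number values
(continuous or thresholded; they are used as given). The working
hypothesis is that a biologically important pathway is one whose
expression-level activity, *relative to other tumors of the same type*,
can be predicted from the somatic alterations present in each tumor. The
method is case-only: no matched normals, and no pathway topology.

### Single-sample scoring

For gene *i* with cohort values `x_i1..x_in`, the Gaussian-kernel CDF
estimate is

    ẑ_ij = (1/n) Σ_k Φ((x_ij − x_ik) / h_i),   h_i = s_i / 4,

with `s_i` the per-gene sample standard deviation (ddof = 1). The
transform is exactly invariant to per-gene location shifts and positive
rescaling, so platform- or gene-specific scale has no effect. Within each
sample, genes are ordered by decreasing `ẑ` (exact ties broken by input
gene order via a stable sort — a deterministic, seed-free policy) and the
position at rank *t* carries weight `r = |p/2 − t|`: genes near the
cohort-typical middle of the ranking carry little weight, extremes carry
the most. For a gene set γ the score is a weighted random walk over the
ranking,

    ν(ℓ) = Σ_{t≤ℓ, in γ} r_t^τ / Σ_{in γ} r_t^τ  −  #{t≤ℓ, not in γ}/(p−|γ|),

summarised by default as `ES = max(0, max ν) + min(0, min ν)` (the "diff"
statistic, which rewards sets whose members move together in one
direction; the paper-standard choice here). The alternative `es_mode="max"`
takes the single largest-magnitude excursion and can respond to sets with
both up- and down-regulated members. `ES ∈ [−1, 1]` always. The Gaussian
kernel assumes continuous (log-processed) expression; raw counts are out
of scope. An ssGSEA backend (within-sample ranks weighted by `rank^α`,
α = 0.25, running-sum statistic, matrix rescaled by its global score
range) is provided for sensitivity analyses; all downstream stages are
scorer-agnostic.

Sets are intersected with measured genes and retained when the
intersection has 5–500 members (standard collection practice; both bounds
configurable). Zero-variance genes are dropped with a logged count rather
than failing the run, because a handful of flat genes is routine in real
matrices.

### Alteration features and the null

Features are (gene, type) pairs: `TP53` (mutation indicator) or
`MET (CNV)`. Mutation columns need at least `min_mutated = 3` carriers —
a one-carrier indicator cannot be assessed in cross-validation — and
constant columns of either type are dropped. Restriction to a cancer gene
census is a column subset. The randomized control permutes each column
independently across samples (preserving every marginal, destroying both
feature–pathway and feature–feature association); a row-permutation mode
that preserves co-mutation structure is available, but the independent
column permutation is the stricter null and the default.

### Regression

Per pathway, scores are regressed on features under the objective

    (1/2n) Σ_j (y_j − β₀ − x_j·β)² + λ ‖β‖₁

with columns standardised internally (coefficients reported on the
original scale). λ is selected over a 100-point log grid descending from
`λ_max = max_j |x_jᵀ(y − ȳ)|/n` to `10⁻³·λ_max` by K-fold
cross-validation (K = 10). Per test fold, `R²_k = 1 − SSE/SST` where both
the model and the null mean come from the training fold only; `R²_pred`
is the unweighted mean over folds (a pooled-deviance variant is behind a
flag). Because the null mean is out-of-sample, `R²_pred` can be negative
and is never clamped in model output — the negative tail is real
information about overfitting. The default selection rule is the
CV-optimal λ ("min"); the "one_se" rule is available. Fold assignment is
drawn once per run from the seed and shared across pathways so that
`R²_pred` values are comparable between pathway models, and results are
bit-identical regardless of the joblib worker count.

The unpenalised refit uses only the LASSO-selected columns: OLS
coefficients, classical t-test p-values on `n − k − 1` degrees of
freedom, residual variance, and the intercept-augmented Gram inverse. If
selection returns ≥ n − 1 predictors, the refit keeps the top
`min(k, n−2)` by |penalised coefficient| (a small-cohort guard);
collinear columns are dropped greedily in input order with a warning. An
empty selection yields an intercept-only model with an empty p-value
table. Personalised prediction for a profile `x₀` is
`ŷ ± t_{1−α/2, n−k−1} · σ̂ · √(1 + x₀ᵀGx₀)` — the classical OLS
prediction interval, "approximate" because it ignores the upstream
selection step.

### Interpretation

Pathway ranking is by descending `R²_pred` (ties broken lexicographically
for determinism). The driver weight of feature *g* is

    W_g = (1/M) Σ_{m=1..M} s_gm · max(0, R²_pred,m),

with `s_gm = −log₁₀ p_gm` when *g* was selected in model *m* and 0
otherwise, and M the total number of models in the collection. Averaging
over all models — not just those containing *g* — means a feature
significant in 3 of 200 weak models scores below one significant in 50
strong models. Negative `R²_pred` is clamped to zero *inside W only*: a
model with no predictive power contributes no evidence, rather than
signed anti-evidence. The log base only rescales W by a constant, so the
ranking is base-invariant. Driver-gene labels apply at the gene level
(both the MUT and CNV features of a driver gene count as driver
features). Enrichment of known drivers among W uses a one-sided Wilcoxon
rank-sum test (drivers larger; exact enumeration when both groups ≤ 10
and weights are tie-free, else the tie-corrected normal approximation),
with Benjamini–Hochberg q-values across any tested family. Candidate
novel drivers are non-census features whose top-k ranking replicates
across at least two independently scored collections.

Known bias, inherited from the weight definition: features associated
with genes annotated to many overlapping pathways have inflated W. No
overlap correction is applied.

## Synthetic cohorts and what they do (not) show

The generator emulates the structure the regression assumes: pathway *m*
has latent activity `a_m = Σ_d β_d·v_d + ε`, linear in a few driver
features, with ε scaled so drivers explain exactly the designed fraction
*f* of `var(a_m)`; member-gene expression is
`baseline + loading·a_m + N(0, 0.5²)`, noise genes are baseline + N(0,1).
Defaults: 300 samples; 8000 genes; 20 disjoint pathways of 60–100 genes;
100 mutation genes (Bernoulli, frequency 0.15 — a recurrently mutated
cancer gene) and 100 CNV genes (standard-normal dosage); 10 driver
features assigned round-robin (2 per pathway, so every driver influences
≥ 2 pathways and ground truth is never vacuous); f = 0.5. A
transcriptome-scale gene background matters: when pathway members are a
small minority of ranked genes, as in real data, the enrichment score is
a faithful monotone readout of latent activity (squared correlation
≈ 0.93, close to the ≈ 0.955 ceiling imposed by correlating a Gaussian
variable with its own rank transform). Sign-mixed expression loadings are
available to exercise the "max" scoring variant.

What the fixtures do *not* emulate: overlapping pathway memberships,
co-mutation structure, mutation-CNV correlation at a locus,
subtype heterogeneity, and realistic mutation spectra. Passing tests
therefore demonstrate the statistical machinery — calibration of the
null, recovery of planted effect sizes and drivers — not robustness to
those real-data complications.

Recovery of *f* as mean `R²_pred` is inherently slightly lossy: the score
is a bounded rank statistic of activity, not activity itself, so even at
n = 1000 the recovered mean sits a few percent below *f* (the rank
nonlinearity accounts for ~4.5 points at f = 0.5, the walk statistic and
member noise for the remainder).

## Numerical and design choices

- LASSO solutions come from coordinate-descent path fitting
  (scikit-learn); the CV protocol, `R²_pred` definition, refit, and
  intervals are implemented here. Orthonormal-design soft-thresholding
  and normal-equations OLS serve as closed-form oracles in the tests.
- BH q-values, rank-sum tests, and Spearman correlations are delegated to
  statsmodels/scipy and cross-checked in tests against step-up
  enumeration, exact rank enumeration, and rank-then-Pearson oracles.
- p-values of exactly 0 in a refit are replaced by the smallest positive
  double (logged) before taking logs.
- Degenerate inputs fail loudly at the operation level (constant
  response, zero-variance gene in the kernel CDF, set covering all
  genes, n_folds > n) but per-pathway failures inside a cohort run are
  logged and skipped so one bad pathway cannot abort an analysis.
- Problem sizes in the test suite and acceptance script (cohorts of
  120–1000 samples, 200 features, 20 pathways per cohort, 200 null
  models) are chosen as the smallest designs at which the binomial and
  CV noise bands in the assertions are meaningful.

## Limitations

Methylation, fusions, non-coding mutations and interaction terms are not
modelled as predictors. Mutation indicators do not distinguish
gain-of-function from loss-of-function. `R²_pred` values carry no formal
significance test (their joint distribution is unknown; the randomized
null is the calibration reference). The prediction interval is
approximate post-selection. Gene identifiers are opaque case-sensitive
strings; any symbol harmonisation must happen upstream.
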