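# Methods

## The asymmetry index

For matched left/right contrast estimates L and R the package computes
Δ = (L − R)/(|L| + |R|) and A = (|L| + |R|)/2 per subject, task epoch
and vertex. The index is bounded in [−1, 1], antisymmetric under
hemisphere exchange, invariant to positive rescaling of the contrast
units, and satisfies the exact reconstruction Δ·(|L|+|R|) = L − R. Its
denominator is the bilateral signal magnitude, so deactivation
(negative contrasts in both hemispheres) contributes positive amplitude
— a property of the printed formula that users should keep in mind when
interpreting A in epochs dominated by deactivation.

Numerical choices:

* |L| + |R| = 0 is masked (NaN), not zero-filled: a 0/0 cell carries no
  lateralization information. Masked cells propagate through network
  averages as missing values.
* No epsilon regularization of near-zero denominators. Single-vertex Δ
  values near a zero denominator are noisy but bounded; network
  averaging absorbs them. This preserves the threshold-independent
  character of the measure — no activation cutoff is applied at any
  stage.

## Vertex correspondence

The two hemisphere meshes are treated as mirror images up to vertex
reordering. Both coordinate sets are centered on their bounding boxes,
the right x-axis is negated, and each left vertex is matched to the
nearest right vertex (k-d tree). The assignment must be a bijection;
colliding assignments raise an error with a diagnostic count rather
than silently merging vertices. Match quality is summarized as the
Pearson correlation of matched coordinate vectors (three axes
concatenated) and the correspondence is rejected unless it exceeds
`min_fit` (default 0.995), a hard gate. On near-regular meshes the
procedure tolerates coordinate jitter of ~1% of the bounding-box span;
on fully irregular point clouds with near-coincident vertices the
nearest-neighbor assignment can collide, which is reported rather than
repaired — inputs are assumed to be surface meshes, which have roughly
uniform vertex spacing.

## Network aggregation and rankings

Δ and A are averaged within a 12-network partition per subject and
epoch, vertex-first: the index is averaged, never recomputed from
averaged hemisphere signals, so the bound |Δ| ≤ 1 is preserved. Means
are unweighted over a network's unmasked vertices; no surface-area
weighting is applied. Background vertices (label −1) are excluded.
Networks are ranked by the RMS of cohort-mean Δ across epochs, epochs
by the mean of cohort-mean Δ across networks; both rankings operate on
the subject-averaged table, descending, with the canonical input order
breaking ties. An optional mode re-expresses the five motor epochs
relative to their within-task mean before ranking (useful when the
contralateral motor pattern should be read against the motor task's
overall asymmetry); both raw-epoch and centered code paths are provided
and the raw mode is the default.

## Group statistics

Per-epoch vertex-wise inference proceeds as: (1) OLS residualization of
age, with the group mean re-added; (2) multiplicative grand-mean
scaling across sex × race cells — each subject's value is scaled by
grand mean / cell mean, the simplest normalization that equalizes cell
means (cells with mean zero cannot be scaled and pass through
unchanged); (3) two-sided one-sample t-tests of Δ against zero; (4)
Benjamini–Hochberg FDR over all vertices with a defined statistic.
Zero-variance vertices are flagged and excluded from the FDR family.
Rejection follows the classic boundary-inclusive step-up rule
(p(k) ≤ kα/m). Effect sizes are Cohen's d = mean/SD with the Hedges
small-sample factor J = 1 − 3/(4ν − 1), ν = n − 1; the uncorrected d
is available by flag. Two-sided tests are used throughout because the
sign of asymmetry is itself the finding. The pipeline regresses age and
scales sex/race — it does not regress the categorical covariates — and
an analyst wanting full covariate regression should residualize
externally.

## Amplitude–asymmetry coupling

Two views. Vertex-wise: per vertex and epoch, the across-subject
Pearson correlation between A and Δ, averaged over the 17 epochs
(epochs with zero variance at a vertex are excluded from that vertex's
mean). Rank-binned: within each (epoch, network), subjects are sorted
by network-mean amplitude and grouped into consecutive blocks of 10;
remainder subjects after the last full group are dropped (the most
conservative reading of fixed-size grouping — group homogeneity is
preserved and the dropped count is reported). Group-mean A is then
correlated with group-mean Δ per cell. With 100 groups the null
standard error of each cell's r is ≈0.1; users comparing many cells
should account for that multiplicity.

## Accuracy associations and model comparison

Subject-level network measures (Δ or A) are correlated with accuracy
per (network, scored epoch) cell, missing accuracy dropped pairwise,
with Bonferroni control over all cells tested in one call (the family
is the call, by design; the binned display mode exists separately).
Linear vs polynomial structure is compared by OLS fits of degree 1–3
with AIC = n·ln(RSS/n) + 2k, k = degree + 2. The selected model is the
lowest degree within 4 AIC units of the minimum: models within a few
units are comparably supported, and a higher-order polynomial is
preferred only when its advantage is decisive (plain argmin selection
is available via `parsimony_margin=0`). ΔAIC is reported both as a
difference and as a percentage of the linear model's AIC.

## PLS prediction

Network-mean measures form wide matrices — 9 major networks × 17 epochs
= 153 columns, epoch-major, canonical network order within epoch. The
ORA, VMM and PMM networks are excluded by default (small, diffuse,
weakly task-specific); requesting them raises unless explicitly
overridden. Internally the matrices are named B (amplitude), D
(asymmetry) and C (accuracy, 12 scored epochs in fixed order, missing
cells mean-imputed with the imputation mask carried forward so
evaluation can exclude them).

The model is PLS2 regression with NIPALS-type extraction and X
deflation (scikit-learn's implementation, run at a tightened inner
tolerance of 1e-10), wrapped in a Model/Results interface. Columns of X
and Y are centered and scaled to unit variance with training statistics
only — predictors span networks with very different scales, and without
scaling the loadings are dominated by high-variance networks. The
number of components defaults to 12 and is validated, not auto-selected;
k-fold cross-validation (random fold assignment from the run seed, no
stratification) reports out-of-fold explained response variance per
component count as a diagnostic, computed in the training-scaled
response space so it is directly comparable with the within-sample
figure. Both response-variance and predictor-variance explained are
reported, since "variance explained" is otherwise ambiguous.
Cross-sample validation fits on one cohort and evaluates per-response
predicted-vs-observed correlations within and out of sample, in both
directions. Component scores are tested for age (Pearson) and sex
(two-sample t) effects with Bonferroni control across components.

## Matched splitting

Discovery/Replication subsamples are formed by stratified random
allocation: sex × age-quartile × BMI-quartile strata, shuffled within
stratum, allocated at the requested fraction with a largest-remainder
carry across strata so the arm sizes match the fraction within one
subject. Task accuracy is reported in the balance check but never used
to form strata (no selection on the outcome). Balance is descriptive:
t-tests for numeric covariates, chi-square for categorical, SMDs for
all (maximum per-level proportion SMD for categoricals), no
multiplicity adjustment.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
at desk scale. Per subject i, network k, epoch e:

    f_i   ~ Normal(β_age·z(age_i) + β_sex·sex_i, 1)
    A_ike = Ā_ke (1 + s f_i)
    Δ_ike = Δ̄_ke + c_ke (s f_i) + s ε_ike
    L     = A(1 + Δ) + vertex noise,  R = A(1 − Δ) + vertex noise

with s the subject-level noise SD, Ā and Δ̄ the planted network × epoch
tables, and c the coupling coefficients linking the amplitude deviation
s·f to asymmetry. Age enters z-scored so the latent factor stays O(1)
regardless of the age unit. Because L, R ≥ 0 when |Δ| < 1, the
asymmetry index inverts the construction exactly: at zero noise the
pipeline returns the planted tables to machine precision, which anchors
all parameter-recovery tests. Δ is clipped to ±0.999 after noise so the
hemisphere signals stay non-negative.

Defaults (chosen once): 200 subjects, 2,000 vertices, 17 epochs, 12
networks; planted Δ̄ mirrors the qualitative pattern of task
lateralization (contralateral motor responses in SMM at ±0.3–0.35,
story-listening leftward in LAN/FPN/DMN/AUD up to +0.35, rightward
face-matching asymmetry in DAN, mild rightward DMN bias elsewhere);
Ā ≈ 1 contrast unit, higher (1.3–1.7) in task-relevant networks;
coupling strongest in LAN/FPN/DAN (0.2); accuracy is generated at the
network-summary level (where the associations are measured) as a
baseline of 80% plus a few network-measure weights of 2–4 percentage
points per SD and 5% noise, clipped to [0, 100]; vertex noise SD 0.15,
subject noise SD 0.10; age in [22, 36] years uniform, sex Bernoulli(½),
BMI ~ N(26.5, 4.5²), motion |N(0.6, 0.4²)| mm.

What the generator does **not** emulate: spatial smoothness within
networks (activation is block-constant plus independent vertex noise),
hemodynamic time series (contrasts are generated directly), any
within-subject correlation across epochs beyond the single latent
factor, spatially varying coupling within a network, and realistic
accuracy distributions (linear-Gaussian, clipped). Passing tests
therefore demonstrate correctness of the estimators under the assumed
generative structure — planted-parameter recovery, null calibration,
invariances — not robustness to the spatial and temporal complexities
of real surface data. The mesh geometry is a jittered grid with a
guaranteed minimum vertex separation, matching the near-uniform spacing
of real surface meshes; fully irregular point clouds would break the
nearest-neighbor correspondence that both the generator and real
pipelines rely on.

Everything is reproducible bit-for-bit from (config, seed); cohort
sizes beyond a few hundred subjects at a few thousand vertices are
generated in seconds, and the test suite deliberately works at 40–1,000
subjects × 12–2,000 vertices to keep the full run under a couple of
minutes.

## Known limitations

* Only cortical surface vertices are analyzed; subcortical structures
  have no left/right vertex correspondence in this framework and are
  out of scope.
* Grand-mean scaling is a multiplicative cell-mean equalization; it is
  one reading of "normalizing across categorical variables" and other
  normalizations (e.g., full categorical regression) would give
  different vertex statistics.
* The rank-binned coupling correlation has a large per-cell sampling
  error (SE ≈ 0.1 at 100 groups); single-cell values should not be
  over-interpreted.
* PLS explained variance is reported on standardized responses;
  unstandardized shares can differ when response variances are very
  unequal.
* The correspondence algorithm assumes mirror symmetry up to jitter; it
  does not perform surface registration or resampling, and it rejects
  rather than repairs ambiguous geometry.
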