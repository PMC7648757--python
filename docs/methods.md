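# Methods

## Analysis model

The pipeline tests two families of hypotheses on a three-group cohort
(patients with hallucinations H+, patients without H−, healthy controls HC).

**Sulcal metrics.** For each sulcus (paracingulate PCS, superior temporal
STS), hemisphere and measure (length, depth in mm), group contrasts are
ordinary least squares fits of the metric on group indicators plus age, sex
(0/1 indicator, F = 1), scanning site (k−1 dummies, lexicographically first
site as reference) and total intracranial volume. The contrast *t* uses
n − p residual degrees of freedom. A "standardized beta" is reported as the
same contrast coefficient after z-scoring the outcome over the analysis
sample — i.e. the adjusted group difference in SD units. (Conventions for a
standardized coefficient on a categorical contrast vary; the one used is
recorded here and in the output metadata.) Planned contrasts (left PCS
length, H+ vs H− and H+ vs HC) are evaluated at α = 0.05 uncorrected; the
remaining sulcal contrasts form one Benjamini–Hochberg family at FDR 0.05.
Hemispheres and measures are pooled into that single exploratory family by
default; the family composition is a parameter, not a fact of the data.

The asymmetry index AI = 2(R − L)/(R + L) is dimensionless, bounded in
[−2, 2], antisymmetric under hemisphere exchange and scale-invariant; it is
undefined (flagged missing, never a division error) when both sides are 0,
which encodes a bilaterally absent sulcus. AIs are tested against 0 within
group (one-sample *t*) and across groups (one-way ANOVA, Tukey HSD with the
Tukey–Kramer unequal-n adjustment).

**Structural covariance.** Parcel-wise local gyrification index (LGI) is
residualized on [intercept, age, sex, site, TIV] by OLS fitted on the pooled
sample (all groups together). Pooled fitting — rather than per-group — keeps
the covariate adjustment a fixed property of each participant, which is what
makes the group-label permutation scheme coherent: permutations shuffle
labels while every subject keeps their residualized values. Per-group
fitting is available behind a flag for sensitivity analyses. Within each
group, the parcels × parcels Pearson correlation matrix of residuals is
averaged into blocks defined by eight resting-state networks (and by
network × hemisphere for the 16×16 decomposition). Within-network means
average the off-diagonal upper triangle (the diagonal is identically 1 and
would inflate the mean); between-network means average all cross pairs.
Zero-variance parcels produce missing entries that are excluded from means
with their counts logged. The 8×8 block means are exactly the
pair-count-weighted averages of the 16×16 ones, a tested identity.

Threshold curves report the mean over block entries strictly greater than τ
(entries ≤ τ are discarded, not zeroed) for τ on a grid from −0.2 to 1.0 in
steps of 0.05; at τ = −1 this equals the unthresholded block mean exactly.
Strict inequality is an arbitrary but fixed convention; the default grid
avoids ties in practice. 95% confidence intervals are percentile bootstrap
over subjects resampled with replacement within group (default 5000
resamples).

**Permutation inference.** The test statistic for a block is the difference
of group block means M_a − M_b. Under each of B permutations all
participants are reassigned to three new groups of the original sizes (even
when a single pairwise contrast is tested), and the statistic is recomputed
on the two relevant permuted groups. The two-tailed p-value uses the add-one
estimator p = (1 + #{|null| ≥ |observed|})/(B + 1), which avoids p = 0 and
makes the null distribution of p conservative (stochastically ≥ uniform).
The tested family — by default the three blocks salience-within,
auditory-within, salience–auditory, for the H+ vs H− contrast — is corrected
by Benjamini–Hochberg FDR; the 16×16 tests form their own family and are
reported separately. Residualization is not recomputed inside permutations.

**Summary-statistic reconstructions.** When only printed per-group summaries
exist, one-way ANOVA is reconstructed as SSB = Σ nᵢ(mᵢ − m̄)²,
SSW = Σ (nᵢ−1)sᵢ², F = [SSB/(k−1)]/[SSW/(N−k)] — algebraically identical to
the raw-data ANOVA. Contingency tables use Pearson χ² without continuity
correction (the correction applies to 2×2 tables; the gender table is 5×2).
Method agreement uses the two-way random-effects, absolute-agreement,
single-measure intraclass correlation, ICC(A,1); the variant is labelled in
the output because conventions differ.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's conditions: group sizes 101/80/63; 360 parcels balanced over
8 networks × 2 hemispheres (test runs shrink this); covariates drawn per
group (age and TIV normal with group-specific means matched to published
demographic summaries, sex Bernoulli, three categorical sites); PANSS P3
scores drawn so that group means land near the published ~4.0 (H+) and
~1.15 (H−).

**LGI factor model.** For a subject in group g, parcel p in network k:

    LGI(s, p) = μ_p + β·x_s + σ·(√a_g·G_s + √a_k·F_{s,k} + √u_p·ε_{s,p})

with a global factor G, correlated network factors F (Cholesky of the
network-factor correlation matrix), unique variance u_p = 1 − a_g − a_k, and
covariate shift β·x_s centred at reference covariate values so planted group
means are preserved. Expected inter-subject correlation of two parcels is
a_g + a_k within network k, and a_g + c_ij·√(a_i·a_j) across networks i, j
where c_ij is the planted factor correlation — so planted block correlations
are available in closed form and generation is O(n·p). Subject factors are
redrawn independently per group, so between-group covariance differences are
planted exactly rather than inherited. Default planted block correlations
reproduce the reported group block means (salience within
0.493/0.371/0.375 for H+/H−/HC; auditory 0.631/0.532/0.523;
salience–auditory 0.501/0.355/0.375) on a global baseline of 0.20 and a
generic within-network level of 0.35 for the other six networks; the
baseline and generic levels are realistic choices, made once, since only
the three salience/auditory blocks are constrained by published values.

**Sulcal model.** Lengths and depths are normal draws truncated at zero
(resampled), with group means planting the reported sign structure: left PCS
shortened by ~0.5 SD in H+ (39 vs 50/52 mm, SD 22); leftward PCS length and
depth asymmetry in HC and H− but not H+; leftward STS length and rightward
STS depth asymmetry in all groups, with right STS depth slightly reduced in
H+. Magnitudes are realistic mm-scale choices; no distributional form is
published for these metrics, and the normality assumption is recorded in the
ground-truth manifest that accompanies every generated cohort.

**What the generator does not emulate.** Spatial structure within networks
(all parcels in a block are exchangeable), non-Gaussian or heavy-tailed LGI
distributions, site-by-group interactions, missing data, and any coupling
between sulcal metrics and LGI (the supplementary LGI–sulcal correlation
check therefore uses separately planted dependence). Passing tests show the
statistical machinery is correct and calibrated under the assumed model,
not that the model captures every feature of real morphometric data.

## Numerical and design choices

* All randomness flows from one seed via SHA-256 stage-name splitting
  (`child_seed`), keeping every stage independently reproducible and all
  derived seeds below 2³¹.
* Matrices are indexed by sorted subject id, and the permutation test sorts
  subjects internally, so no result depends on file row order.
* Constant covariate columns are dropped from designs (absorbed by the
  intercept); genuinely collinear designs raise an error naming the columns.
* Degenerate cases are flagged, not raised: zero-variance groups give
  infinite *t*; a constant outcome gives a zero contrast marked degenerate;
  empty surviving threshold sets and zero-variance parcels propagate as
  missing with counts.
* Problem sizes in the test suite: most tests run at 16–60 parcels with a
  balanced atlas (the block structure is preserved at any multiple of 16);
  the permutation type-I calibration uses 200 replicates of n = 80/group at
  B = 500, and the covariance power check 50 replicates of n = 150/group at
  B = 1000.
* The power check plants a 0.15 between-block excess on a low-correlation
  baseline (global 0.05, within 0.20 vs 0.30, between 0.10 vs 0.25). This is
  a scenario-design choice: the sampling variance of a block mean grows with
  the baseline correlation level (entries become more dependent through the
  shared factors), so the same absolute excess is easier to detect on a low
  baseline. The study-condition defaults are unchanged by this; power under
  those defaults at n = 150/group is close to, but not reliably above, the
  scenario's detection rate.

## Known limitations

* The parcel→network mapping of the real 360-parcel atlas is user-supplied;
  the package ships only a balanced synthetic assignment.
* "Partial correlation" on residualized values is treated as identical to
  Pearson correlation of residuals.
* The exploratory FDR family composition and the ICC variant are
  conventions; both are configurable/labelled rather than fixed facts.
* Published-summary reconstructions inherit the 2-decimal rounding of
  printed inputs (~1–2% relative slack on reconstructed F statistics).
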