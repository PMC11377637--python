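# Methods

This document specifies the statistical model behind each stage, the
default parameters with units and rationale, what the synthetic
generator does and does not emulate, and the numerical design
decisions. Module names in parentheses.

## 1. Synthetic data generator (`rimla.synth`)

The generator is first-class code: every downstream component is
validated against data whose ground truth it controls.

**Healthy maps.** Each modality X ∈ {T1, T2, T2/T1} follows the same
linear model the atlas later fits:

E[X | age, sex] = β₀ + β_sex·sex + β_age·(age − a₀) + β_age²·(age − a₀)²,

with i.i.d. Gaussian voxel noise of SD σ_X. Defaults (units of the
modality): T1 (ms): β₀ = 850, β_sex = 20, β_age = 1.5, β_age² = 0.02,
σ = 30; T2 (ms): 75, 2, 0.15, 0.005, σ = 4; T2/T1 (unitless): 0.088,
−0.002, −2·10⁻⁴, 2·10⁻⁶, σ = 0.006. These are plausible 3 T orders of
magnitude; their exact values are irrelevant to the tests, which check
recovery of whatever is configured. Ages are uniform on [20, 54.6]
years, 66 % of subjects are female, and a₀ = 37.3 years.

**Patient cases.** Non-overlapping digital spheres are planted in the
white-matter compartment of a three-tissue mask, separated by at least
2·(3.5 mm + r_max) so perilesional rings never interact. Each lesion
belongs to one of four longitudinal classes with prevalences
0.624 / 0.146 / 0.121 / 0.109 (stable / shrinking / enlarging / new)
and receives a class-specific target z-score in its core and inner
ring; voxel values are E[X] + σ_X·z, so the planted z is exactly
recoverable when the atlas is known.

**Volume trajectories.** v(t) = v₀ + slope·t observed at n_t visits
182.5 days apart with Gaussian error of SD COV·v(t) (resampled above a
small positive floor — a measured lesion volume cannot be ≤ 0).
Class slopes default to 0 / +0.5 / −0.5 / 0 µL/day; for the shrinking
class the baseline is raised so the true trajectory stays positive over
the follow-up. "New" lesions are flagged undetected at all but the
last visit.

**Feature tables.** For cohort-scale statistics the generator can also
emit the 18-metric feature table directly, drawing each metric from
class-conditional normal profiles (median, IQR/1.3490 as SD) with a
shared per-patient random offset (SD 0.2) so rows within a patient are
correlated, plus an 11 % secondary-progressive course fraction.

**Not emulated:** spatial noise correlation, scanner/site effects,
registration error (QC is exercised via the atlas-vs-image mutual
information instead), partial-volume effects, lesion shape complexity,
longitudinal change in the quantitative values themselves.

## 2. Lesion geometry (`rimla.geometry`)

- Connected components at 26-connectivity (6 and 18 also available);
  labels are assigned in scan order for determinism.
- Volume filter: lesions with volume in **[3, 150] µL inclusive** are
  kept. The lower bound rejects segmentation specks whose volume
  trajectory is dominated by noise; the upper bound removes confluent
  lesion conglomerates whose "volume" is not a single lesion's.
- Distance maps: exact Euclidean distance transform per lesion
  (`scipy.ndimage.distance_transform_edt` with anisotropic `sampling`),
  combined by minimum; ties in the nearest-lesion id break toward the
  lower label.
- Perilesional rings: ring 1 is 0 < d < 2 mm, ring 2 is
  2 ≤ d < 3.5 mm (half-open at the top so a voxel belongs to exactly
  one ring). A voxel within 3.5 mm of **two or more** lesions is
  excluded from all rings — its signal would be ambiguous.
- White-matter restriction: a lesion is kept only if all its voxels lie
  inside the white-matter mask eroded by one voxel (26-connectivity),
  which excludes periventricular/juxtacortical partial-volume cases.

## 3. Normative atlas and z-scores (`rimla.normative`)

Per voxel, ordinary least squares of the healthy values on
[1, sex, age_c, age_c²] with age centred at the cohort mean by default
(configurable to a fixed centre). The residual SD uses an n − 4
denominator (4 fitted coefficients). Voxels with σ < 10⁻⁶ are flagged
invalid and z-score to NaN — a zero-variance voxel carries no normative
information. At least 5 subjects are required; a rank-deficient design
(e.g. a single-sex cohort) flags all voxels invalid with a warning
rather than producing garbage coefficients.

z(v) = (x(v) − E[X | age, sex](v)) / σ(v).

The T2/T1 ratio map is computed voxelwise with non-positive T1 mapped
to NaN. Registration/acquisition QC: the mutual information (in nats,
64 equal-width bins over the jointly finite voxels) between each
patient image and the atlas mean is computed; subjects below the 5th
percentile of the cohort MI distribution fail QC and are excluded.

## 4. RIMLA longitudinal labels (`rimla.longitudinal`)

1. **COV estimation**: from scan–rescan data, lesions are matched
   across repeated segmentations by maximal voxel overlap; per lesion
   COV = SD(volumes, ddof = 1)/mean(volumes); the cohort COV is the
   unweighted mean (default truth in simulations: 0.17).
2. **Synthetic volumes**: each measured volume v_t spawns 100 draws
   from N(v_t, (COV·v_t)²), resampled above a small floor.
3. **Bootstrap**: 100 OLS lines are fitted, each to one random synthetic
   volume per timepoint (closed-form slope, vectorized).
4. **Label rule**: if ≥95 % (inclusive) of bootstrap slopes are
   positive → *enlarging*; ≥95 % negative → *shrinking*; otherwise
   *stable*. Lesions detected only at the last timepoint are *new*;
   lesions undetected at an intermediate timepoint are *discarded*
   (their trajectory is not interpretable). The reported
   `bootstrap_p = 1 − max(frac⁺, frac⁻)` and the median slope is in
   µL/day.

Slopes are reported per day because visits are scheduled in days;
multiply by 365.25 for µL/year (the method is equivariant under time
rescaling, and the tests check this).

Calibration at the defaults (5 visits, COV 0.17): ≈6–7 % of truly
stable lesions are labelled enlarging or shrinking per side — the
nominal 5 % plus bootstrap discreteness. Slopes of ±0.5 µL/day over 4
semi-annual visits are recovered essentially always.

## 5. Features (`rimla.features`)

Per lesion: mean and sample SD (ddof = 1) of each modality's z-scores
over the lesion core, ring 1 and ring 2 → 18 metrics, plus the lesion
volume. Regions with fewer than 2 finite z-voxels yield NaN SD and the
row is flagged incomplete. Lesions whose longitudinal label is missing
or *discarded* are excluded from the feature table with a logged
reason.

## 6. Univariate statistics (`rimla.stats`)

Aligned-rank ANOVA (ART): the least-squares fit of the nuisance
effects (patient identity and disease course, treatment-coded dummies)
is subtracted, the aligned values are mid-ranked, and a fixed-effects
ANOVA (again including the nuisance terms) tests the class effect;
effect size is partial η² = SS_class/(SS_class + SS_resid). This is a
rank method, so it is invariant to monotone transforms of the metric,
and the planted-null simulations show a 2–8 % type-I rate at α = 0.05.
Classes with fewer than 2 observations are dropped with a warning.

Across the metric family, p-values are Holm-adjusted. Post-hoc
pairwise comparisons use two-sided rank-sum tests, Holm-corrected over
the pairs. The relapsing–remitting vs secondary-progressive contrast
uses the two-sided Wilcoxon rank-sum test (exact for small untied
samples, tie-corrected normal approximation otherwise).

## 7. Multivariate classification (`rimla.classify`)

A balanced random forest: each of the trees (default 250 draws per
class per tree in the full-scale configuration) is grown on a
with-replacement draw containing equally many lesions of each class,
so the majority (stable) class cannot dominate; trees are CART with
√d feature subsampling. Reported on a held-out split (resampled until
both parts contain every class):

- per-class balanced accuracy = (recall + specificity)/2, one-vs-rest;
- Hand–Till multiclass AUC: mean over ordered class pairs of the
  rank-based (tie-aware) AUC of class i's probability on lesions of
  class i vs class j;
- Krippendorff's nominal α = 1 − D_o/D_e from the coincidence matrix
  of (truth, prediction), with a one-sided permutation p-value;
- permutation variable importance: mean drop in held-out accuracy over
  repeated column permutations (mean ± SD);
- variance inflation factors of the predictors (1/(1 − R²_j); exact
  collinearity reported as +inf, constants as NaN).

## 8. Pipeline and reproducibility (`rimla.pipeline`, `rimla.cli`)

`PipelineConfig` is the single source of every constant; it validates
on construction, round-trips through YAML losslessly, and hashes to a
16-hex config fingerprint recorded in the manifest. The bundled demo
scene (48³ voxels, 30 healthy subjects, 16 patients × 8 lesions, 200
scan–rescan lesions) is sized to finish in seconds while exercising
every stage; it is the package's own choice, not a claim about any
study's size.

Numerical choices for bit-identical reruns:

- all randomness flows through per-entity child generators seeded by
  (seed, string key), so results do not depend on processing order;
- NIfTI outputs are written uncompressed (gzip embeds a timestamp);
- CSV floats use a fixed `%.9g` format;
- the manifest stores a SHA-256 digest of every output file, and a
  rerun under the same config produces identical digests.

Derived seeds stay below 2³¹.
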