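# Methods

`stromaquant` quantifies cell phenotypes and stromal/immune composition from
multiplex immunofluorescence (mIF) images of tissue cores, aggregates
per-core measurements into per-sample ratios, and runs the cohort-level
statistics used in studies of cancer-associated fibroblasts (CAFs) and
regulatory T cells (Tregs) — most directly the INHBA(+)-CAF / Treg axis in
high-grade serous ovarian carcinoma. Because real mIF cohorts cannot ship
with a software package, every analysis component is paired with a seeded
simulator that plants known ground truth, so correctness is checked by
recovery rather than by regression against opaque fixtures.

## 1. Image model and cell phenotyping

### Channels and markers

A core image is a stack of co-registered 2-D channels: DAPI (nuclei) plus
one channel per antibody marker. The gated markers are CD3, CD4, CD8 and
FOXP3 (T-cell lineage), alpha-SMA (myofibroblast) and cytokeratin 8/18
(epithelial/cancer). FOXP3 is a nuclear transcription factor; the others
stain membrane/cytoplasm.

### Marker masks

Each marker channel is thresholded into a binary mask. The default
comparison is inclusive (`>=` threshold; a strict mode is available).
Connected pixel groups with **fewer than 9 pixels are excluded** — the
standard mIF despeckling rule — using 8-connectivity by default
(4-connectivity configurable). Components of exactly 9 pixels survive.

### Nuclear segmentation

DAPI is thresholded (fixed value, or Otsu when unset), holes are filled,
components below `min_nucleus_area` (default 20 px) are dropped, and
touching nuclei are split by watershed on the Gaussian-smoothed Euclidean
distance transform (`smooth_sigma` 1.0, `peak_min_distance` 5). A component
whose peaks are all suppressed is kept as a single nucleus rather than
lost. Labels are relabelled to be contiguous from 1.

### Doughnut (perinuclear ring) construction

Membrane/cytoplasmic staining is measured in a "doughnut": each nucleus is
expanded outward by a distance equal to **one third of the mean nuclear
radius**, where a nucleus's radius is its equivalent-circle radius
`sqrt(area / pi)` and the mean is taken over all nuclei in the image. The
ring excludes every nucleus interior (its own and its neighbours'). A pixel
reachable from several nuclei is assigned to the **nearest** nucleus by
Euclidean distance to the nucleus region; exact ties go to the lower label.
This assignment is implemented with per-label distance transforms and is
tested bit-for-bit against an exhaustive per-pixel nearest-nucleus oracle.

### Density gating

For each cell and marker, positive pixels of the marker mask are counted in
the relevant region — the doughnut for membrane markers, the **nucleus for
FOXP3** (configurable to the ring). A cell is marker-positive when the
measurement **strictly exceeds** the gate. Two gating modes exist:

- `count`: the gate is a raw positive-pixel count.
- `per_mm2`: the count is divided by the region area in mm²
  (`pixel_size`, default 0.5 µm/px).

The preloaded defaults are the published raw gates CD3 240, CD4 640,
CD8 520, FOXP3 1200. Their units are not standardized across instruments,
so they ship as configuration; the synthetic-image experiments use
count-mode gates of 30, sized to the simulated doughnut areas
(~60–200 px), which no unstained region can reach and every stained region
comfortably exceeds.

### Compound phenotypes and compartments

Marker flags map to phenotypes by the first matching rule, in order:

1. Treg: CD3+ CD4+ FOXP3+
2. CD4T: CD3+ CD4+
3. CD8T: CD3+ CD8+
4. fibroblast: aSMA+
5. cancer: CK8/18+
6. other

Each cell is also assigned a tissue compartment from the overlap of its
doughnut with the fibroblast and cancer marker masks: a compartment is
assigned when the overlap fraction exceeds 0.5, with fibroblast taking
precedence when both exceed it (a centroid-based mode is available).

## 2. Cohort aggregation

Per-core cell counts feed four ratios:

- `fibroblast_ratio` = fibroblasts / (fibroblasts + cancer + immunocytes)
- `asma_ratio` = aSMA-positive fibroblasts / fibroblasts
- `inhba_ratio` = INHBA-positive fibroblasts / fibroblasts
- `treg_ratio` = CD3+CD4+FOXP3+ / CD3+CD4+

A zero denominator yields NaN, never an exception; negative counts are
rejected. Cores with **fewer than 500 cancer cells are excluded** (exactly
500 is kept); each sample's remaining 1–3 cores are averaged with equal
weight. Samples are split at the **cohort mean** of the chosen ratio:
strictly above the mean is "high", ties and below are "low"; an empty
stratum raises a warning.

## 3. Statistics

Standard tests are delegated to `scipy.stats` and `lifelines`; this
package owns the wiring (grouping, pairing, stratification):

- **Survival**: Kaplan–Meier curves per stratum and the asymptotic
  log-rank test between exactly two strata, each required to contain at
  least one event.
- **Group comparisons** of a ratio across primary / metastatic / recurrent
  lesions: one-way ANOVA across all groups, plus paired t-tests by patient
  for primary-vs-metastatic and primary-vs-recurrent (patients missing one
  member of a pair are dropped in the combined report; requesting strict
  pairing names the unmatched patients). Identical paired vectors return
  statistic 0.0, p 1.0 by convention (the raw 0/0 is undefined).
- **Mann–Whitney U** between low/high strata; **Pearson correlation**
  between continuous measurements.
- **Metagene correlation**: a metagene score is the mean of per-gene
  z-scores over the member genes (median and first-principal-component
  scores available); INHBA expression is Pearson-correlated against each
  metagene score.

## 4. Simulators — what they emulate and what they do not

### Core images

Nuclei are non-overlapping discs with Normal radii (mean 7 px, sd 1 px,
truncated at 2 px). Membrane markers paint a 3-px annulus around the
nucleus; FOXP3 paints the nucleus. Placement enforces a centre separation
of at least `r1 + r2 + 2·ring_thickness + 2` px, so no cell's stain can
reach a neighbour's doughnut — recovery failures therefore indicate
pipeline defects, not ambiguous geometry. Optional Gaussian camera noise
and "speckles" (isolated 3–8-px blobs with a 1-px guard band, the exact
target of the <9-px rule) exercise the robustness path. Not modelled:
irregular nucleus shapes, overlapping/touching cells in crowded tissue,
staining gradients, autofluorescence, channel bleed-through.

### Cell-count cohorts

Per-core phenotype counts are Poisson (defaults: fibroblasts 800, cancer
2000, immunocytes 400, others 300, CD3+CD4+ 150) with binomial
INHBA/aSMA/Treg positives. Patients carry a Normal random effect on the
INHBA rate shared across their lesion groups, making paired tests
meaningful. Group means (primary 0.15, metastatic 0.30, recurrent 0.30)
plant the elevated-INHBA-in-metastasis effect. A configurable fraction of
cores is forced under 500 cancer cells to exercise the exclusion rule.

### Survival

Overall survival is exponential with baseline hazard 0.02/month multiplied
by `hazard_ratio^(stratum==high)`; a record is censored with probability
0.2, in which case the reported time is the event time scaled by a
Uniform(0,1) draw. Not modelled: non-proportional hazards, covariates,
administrative censoring.

### Expression

Gene expression uses latent metagene factors (member-gene loading 0.7)
plus independent noise genes. The INHBA–Treg-metagene correlation is
planted by **empirical conditioning**: INHBA is built from the realized
standardized metagene score plus a residual orthogonalized against it, so
the in-sample Pearson r equals the requested value exactly (the same idea
as `MASS::mvrnorm(empirical = TRUE)`). This is a deliberate design choice:
with plain bivariate sampling the sd of r-hat at n = 130, r = 0.6 is
~0.056, which would conflate analysis error with sampling noise.

## 5. Numerical and determinism choices

- All randomness flows from `numpy.random.default_rng(seed)`; the pipeline
  derives stage seeds via `SeedSequence(seed).spawn`, reduced mod 2^31.
- Doughnut ties break to the lower nucleus label with a 1e-9 distance
  tolerance; the brute-force oracle uses the same convention.
- Density gating is strictly greater-than; channel thresholding is
  inclusive by default.
- Phenotype sampling in the image simulator iterates phenotype labels in
  sorted order, so results are invariant to dict insertion order (and to
  YAML round-trips of a run configuration).
- CSVs are written with `%.10g` floats and `\n` line endings; TIFFs are
  multi-page uint16 with a JSON description tag and no timestamps — equal
  seeds give byte-identical files.
- The run manifest records the configuration, a SHA-256 of its canonical
  JSON, stage seeds, library versions, and a SHA-256 per output file; a
  failed stage is recorded in the manifest before the error propagates.

## 6. Validation problem sizes

Chosen to give tight statistical power within a few minutes of runtime:

- Small-component filter vs flood-fill oracle: 200 random 32×32 masks.
- Doughnut geometry vs nearest-nucleus oracle: 50 random layouts.
- Phenotype recovery: 20 noise-free images (50 cells each; perfect
  recovery required) and 20 images at noise sd = 10% of foreground
  (per-marker F1 ≥ 0.95 required; measured 1.0).
- Ratio pipeline: 5 images against planted truth within binomial standard
  error; one 256-core cohort against an explicit-loop spreadsheet-style
  recomputation (exact).
- Log-rank calibration: 2000 null cohorts of n = 40; KM ordering: 500
  cohorts at hazard ratio 3.
- Metagene recovery: 200 seeds at r = 0.6 (MAE ≤ 0.05) and 20 null seeds
  (|r| ≤ 0.1).
- Determinism: two full pipeline runs compared byte-for-byte.

## 7. Known limitations

- The asymptotic log-rank chi-square test is mildly anticonservative at
  small n: at n = 40 per cohort the measured type-I error is ~0.056–0.059
  (about 0.056 even without censoring), shrinking toward 0.05 by n = 200.
  This is an inherent small-sample property of the standard test, not a
  defect of the simulator or wiring; the calibration check's ±0.01
  tolerance around 0.05 accounts for it.
- The watershed splitter is tuned for roughly convex nuclei; heavily
  elongated or deeply overlapping nuclei may merge or over-split.
- The published raw density gates (240/640/520/1200) are instrument- and
  unit-dependent and are treated as configuration, not ground truth.
- `per_mm2` densities assume square pixels of uniform known size.
- Core averaging weights cores equally regardless of cell count.
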