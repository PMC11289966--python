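# Methods

## Data model and preprocessing

The unit of analysis is the **tumour**, not the patient. A record carries an
opaque patient id (so the bootstrap can resample patients), body side,
clockface breast region (0–12; 0 = retroareolar), nipple distance in cm, and
the set of node fields containing SLNs. Two preprocessing rules run before
any estimation:

1. **Retroareolar reclassification** — tumours with nipple distance ≤ 1 cm
   (boundary inclusive) move to region 0.
2. **Reflection** — drainage and prevalence are treated as symmetric between
   sides, so right-sided records are mirrored to the left: clockface
   h ↦ 12 − h for h ∈ 1..11, with 0 and 12 fixed on the mirror axis; node
   field labels are side-agnostic after reflection. The map is idempotent.

Records with no drained field are rejected: in the imaging protocol being
modelled, SPECT/CT was only acquired when lymphoscintigraphy showed at
least one SLN, so such patients never enter the analysis cohort. A patient
id may appear at most twice (bilateral tumours, analysed as independent
drainage systems). Opposite-sidedness of bilateral pairs holds for raw
cohorts only — after reflection everything is left-sided — so the container
does not enforce it.

## Reference cohort reconstruction

The shipped reference data is an aggregate 13 × 12 contingency table
(N = 869 tumours, 861 patients). Record-level drainage sets behind it are
not public, so `reconstruct_reference_cohort` builds a deterministic
869-record cohort whose marginals match the table exactly: within each
region the largest-count field fills a prefix of records and the
second-largest a suffix (for every region the two largest counts cover the
region total, so each record drains somewhere); remaining fields fill
prefixes. All single-field statistics depend only on the marginals and are
therefore exact. **Joint multi-field drainage statistics are not
recoverable from the reconstruction** and must not be read off it. The
bilateral pairing (8 patients) and the 452 L / 417 R side split are likewise
not public at record level; both are fixed deterministically (pairing the
first and last records; sides drawn once with a frozen seed). These choices
perturb only the patient-level bootstrap, and only through the cluster
structure of 8 of 861 resampling units.

Two rows of the aggregate table admit more than one digit grouping in the
available source material; the shipped values are the groupings consistent
with all row/column totals and anatomically plausible per-region rates.
Whole-breast statistics are unaffected (row totals are fixed).

## Interval methods

* **Beta-binomial (drainage)** — posterior Beta(n+1, N−n+1) under the
  uniform prior; point estimate = posterior mean; equal-tailed 95% interval
  from the Beta quantiles. Computed in closed form rather than by MCMC:
  the model is identical and the output deterministic. Consequence: two
  published cells that carried Monte-Carlo error in their original MCMC
  summaries differ here by one final digit; the exact values are asserted
  in the tests.
* **Dirichlet-multinomial (prevalence)** — posterior Dirichlet(counts + 1);
  region marginals Beta(n_r+1, N−n_r+12).
* **Patient-level bootstrap** — resampling unit defaults to the patient
  (multinomial weights over the 861 clusters, each carrying its 1–2
  tumours); a tumour-level option exists for sensitivity checks. Interval
  type is the simple 2.5/97.5 percentile (no BCa). Replicate weights are
  shared across the 12 node fields so a full table costs one resampling
  pass. Note the percentile of resampled proportions lives on the 1/N count
  grid (0.115 pp at N = 869): two honest runs of a small-count cell can
  differ by one grid step when the target quantile falls on a CDF plateau
  boundary.
* **Logit-Wald (regression)** — the saturated logistic fit's value per cell
  equals the sample proportion, so the interval is computed directly as
  logit(p̂) ± z·√(1/n + 1/(N−n)) back-transformed (verified in the tests
  against a statsmodels GLM fit). Degenerate cells (n = 0 or n = N) get a
  one-sided interval with the exact Clopper–Pearson bound on the undefined
  side and a `degenerate` flag; the logit interval does not exist there.
* **Sison–Glaz (simultaneous multinomial)** — the published 1995 procedure:
  the multinomial is represented as independent Poissons conditioned on
  their sum; the simultaneous coverage ν(c) is the product of
  truncated-Poisson cell masses times a fourth-order Edgeworth density
  correction for the conditioning; c is the largest integer with
  ν(c) ≤ 1 − α and γ = (1 − α − ν(c)) / (ν(c+1) − ν(c)) interpolates. All
  pre-clamp widths are equal; bounds are clamped to [0, 1]. Implemented
  from the published algorithm because no installed package provides it.

Rounding to percentages (half-up, 1 dp by default) happens only in the
rendering layer; all internal values keep full precision.

## Synthetic cohort generator

`simulate_cohort` is the generative inverse of the estimation models, with
defaults frozen at the reference-cohort conditions: 861 patients, bilateral
rate 8/861, right fraction 417/869, region probabilities and 13 × 12
drainage matrix taken from the reference table. Per tumour: region ~
multinomial; each field drained independently ~ Bernoulli(matrix[r, f]);
tumours with no drained field have their **field vector redrawn (region
kept)**, encoding the enrolment filter. Field-wise independence is an
assumption — the reference data provides only marginals — and the redraw
biases post-enrolment drainage probabilities upward by the closed-form
factor 1/(1 − ∏_f (1 − p_rf)), which `conditional_drainage_truth` exposes;
calibration tests score interval coverage against this conditional truth,
not the raw matrix. The generator emulates marginal structure only: it has
no within-patient correlation between bilateral breasts, no field-field
dependence, and no covariate effects, so passing calibration tests
demonstrates correctness of the estimators under the stated model, not
robustness to real-data dependence.

## Geometry

Coordinates are physical patient-frame mm; voxel indices are 0-based; masks
are used in their stored orientation (spacing, origin, orthonormal
direction; no implicit reorientation).

* **Sphere volume fraction** — deterministic sub-voxel sampling: a fixed
  cell-centre lattice of ≥ 1000 points in the unit ball, rotated once by a
  fixed irrational-angle rotation so no lattice plane aligns with the
  coordinate axes (a planar CTV face then sees ~m² distinct levels instead
  of m, keeping the fraction error below ~0.005 for axis-aligned planes and
  ~0.01 for arbitrary ones). The lattice is centrally symmetric, so a
  sphere centred on a planar boundary scores exactly 0.5. Each lattice
  point maps through the mask's physical-to-index transform with
  nearest-neighbour lookup; against a *set* of CTVs the fraction is taken
  over the union of foregrounds. Seed-free and bit-reproducible.
* **Coverage rule** — covered iff fraction > 0.5 strictly.
* **Centroid distance** — 0 if the centroid's nearest voxel is foreground
  in any mask; otherwise the minimum distance to boundary-voxel centres
  (foreground voxels 6-connected to background), via a KD-tree in physical
  coordinates honouring anisotropic spacing. This agrees exactly with
  brute-force nearest-boundary-voxel search and is accurate to half a
  voxel relative to the continuous surface. A non-covered SLN whose
  centroid is nonetheless inside a CTV contributes distance 0 and is
  counted in a dedicated report column.
* **Correspondence** — axilla I subfields → L1 (interpectoral → INTPECT),
  axilla II → L2, axilla III → L3, supraclavicular → L4, internal mammary
  → {IMN, IC4}. Mediastinal, interval and contralateral fields have no
  corresponding CTV and are excluded from scoring. Left and right CTV sets
  are scored independently and merged for "both sides" rows. Summary rows
  omit the distance SD when exactly one SLN is non-covered and omit
  distances entirely when none is.

The geometry generator rasterizes boxes and balls and certifies analytic
ground truth where a closed form exists: sphere–ball overlap via the lens
volume, sphere–box via the spherical-cap formula when exactly one face
plane cuts the sphere within the face's lateral extent (otherwise the row
is marked uncertified and excluded from oracle comparisons). Primitives are
assumed pairwise disjoint.

## Registration QC

Landmark error is the Euclidean distance between corresponding named
landmarks of two sets (same subject frame), summarised by mean and sample
SD (SD undefined for a single shared landmark). The inter-observer summary
pools distances per observer pair over all shared subjects; single-observer
subjects are skipped with a warning; pooling all distances (rather than
averaging per-subject means) is the default aggregation. The 13 landmark
names are configuration, not code — any consistent name list is accepted.
Reference-subject selection takes the subject whose scapula length equals
the sample median, using the lower middle value for even counts (the
selected subject is always real) and lexicographic subject-id order to
break length ties.

## Test problem sizes

The suite validates the bootstrap against an exhaustive binomial oracle on
a 20-tumour toy cohort at B = 200,000; simultaneous Sison–Glaz coverage on
2,000 multinomial draws at the reference proportions (threshold ≥ 0.93);
and Bayesian interval calibration on 500 synthetic cohorts at the full
reference size (≈ 869 tumours each), pooling the 12 whole-breast fields
(6,000 indicators, tolerance ±0.015 around 0.95 — the exact frequentist
coverage of an equal-tailed credible interval oscillates with the
binomial discreteness between roughly 0.93 and 0.955 across the truth
values involved). Geometry oracles use 60³ unit-spacing grids with box
faces on voxel midplanes so rasterized and analytic boundaries coincide.

## Known limitations

* Joint drainage statistics (co-drainage of field pairs) are outside the
  reconstruction's contract, and the generator's independence assumption is
  a knob, not an inference.
* The Sison–Glaz ν(c) is an Edgeworth approximation; for very small N or
  extremely skewed count vectors the achieved simultaneous coverage can
  drift below nominal (the tests bound it at ≥ 0.93 at the reference
  parameters).
* Mask-based distances are voxel-centre quantities; sub-voxel surface
  accuracy would require a contour representation, which is outside the
  input contract (masks are the contract).
* The registration algorithms themselves (linear/deformable) are out of
  scope; only their landmark-based evaluation is provided.
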