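# Methods

## Biomarker definitions

All quantities are computed from a 3D body-weight SUV volume and a binary
lesion mask on the same axis-aligned voxel lattice (spacing in mm,
voxel-center world convention, 0-based indices).

A **lesion** is a maximal connected component of the mask. The default
adjacency is 26-connectivity (voxels sharing a face, edge or corner belong
to the same lesion); 6 and 18 are available. 26 is the most inclusive of
the standard choices and matches the intuition that PET lesions are blobby;
clinical practice does not pin this down, so it is configuration rather
than fact.

Per lesion:

* volume (cm^3) = voxel count x voxel volume (mm^3) / 1000,
* SUVmean = arithmetic mean SUV over the lesion's voxels (no partial-volume
  correction),
* TLG = SUVmean x volume. TLG is physically SUV.cm^3; reports label the
  column `tlg` without a unit to avoid implying a pure volume,
* centroid = unweighted mean of the voxel-center world coordinates. An
  SUV-weighted centroid would be equally defensible; the unweighted
  geometric centroid is the parsimonious reading of "centroid" and is what
  is implemented.

Per patient and reader: MTV = sum of lesion volumes, TLG = sum of lesion
TLGs, and **Dmax** = the Euclidean distance (cm = mm/10) between the
centroids of the two most widely separated lesions, defined as exactly 0
when fewer than two lesions exist.

The **small-lesion filter** removes lesions *strictly* smaller than a
threshold (default 3 cm^3) before any patient-level metric is computed; a
lesion of exactly 3 cm^3 is retained. Filtered Dmax is the maximum over a
subset of the unfiltered centroid pairs, so filtering can never increase
MTV, TLG or Dmax (a property the tests enforce).

## Agreement statistics

Given paired per-patient values from Readings A and B:

* **Spearman's rho** is the Pearson correlation of average-ranked values
  (ties receive average ranks). The 95% CI uses the Fisher z transform,
  z = artanh(rho), standard error 1/sqrt(n-3), back-transformed; the
  two-sided p-value uses the t approximation with n-2 degrees of freedom.
  The CI method is a convention choice — the closed-form Fisher interval is
  the standard default when nothing else is specified.
* **Bland-Altman**: differences d = A - B; bias = mean(d); limits of
  agreement = bias +/- 1.96 x SD(d). All SDs use the n-1 denominator.
* **Median split**: both readings are dichotomized at a single shared
  cutoff, the median of the pooled 2n values. (Splitting each reading at
  its own median is implemented as an option; the pooled cutoff is the
  default because a shared cutoff is what a clinical threshold would be,
  and the 58/59-style marginals of a 117-patient cohort are consistent with
  it.) Tie rule: value < cutoff is "below", value >= cutoff is "above".
* **Percentage agreement** = 100 x (concordant cells)/n on the resulting
  2x2 table; **Cohen's kappa** = (P0 - Pe)/(1 - Pe) with Pe from the row
  and column marginals. A degenerate table where every patient falls in one
  class on both readings (Pe = 1, P0 = 1) is reported as kappa = 1; Pe = 1
  with imperfect agreement raises an error rather than inventing a value.
* Quantiles (median, IQR) use linear interpolation between order
  statistics (numpy's default, "type 7"). No multiplicity adjustment is
  applied to p-values.

## Synthetic phantom cohorts

The generator replaces patient scans with a cohort whose geometry and
reader behaviour are fully controlled:

* **Grid**: 64 x 64 x 160 voxels at 4 mm isotropic spacing (25.6 x 25.6 x
  64 cm), a whole-body FDG PET field of view at typical reconstruction
  resolution.
* **Lesions per patient**: max(1, Poisson(mean 6)).
* **Radii**: log-uniform in 5-35 mm. The log-uniform (right-skewed) shape
  reflects lymphoma burden — many small nodes, an occasional bulky mass —
  and is what makes the small-lesion omission channel consequential: with
  radii uniform on the same interval almost every lesion is large (volume
  grows as r^3) and the phantom would understate exactly the mechanism it
  exists to exercise.
* **SUV**: background 1.0; inside lesion i the profile is background +
  (peak_i - background)(1 - (d/r)^2), a parabolic falloff reaching the
  background exactly at the boundary, with peaks uniform in 8-25.
* **Placement**: centers uniform in the grid with full containment
  (radius + jitter clearance) and pairwise center separation of at least
  the sum of radii plus two voxels, so ground-truth lesions never merge
  under any connectivity and the true lesion count is unambiguous.
* **Reader model**: per lesion, independently per reader — (i) if the
  lesion is smaller than 3 cm^3, it is omitted entirely with probability
  0.3; (ii) otherwise its boundary is dilated or eroded by a signed margin
  uniform in +/-6 mm, truncated toward zero to whole structuring-element
  steps of the smallest voxel edge (so at 4 mm spacing the realized margins
  are -1, 0 or +1 steps with probabilities 1/6, 2/3, 1/6), using an
  isotropic-in-mm structuring element. Zero jitter and zero omission
  probability reproduce the truth bit-for-bit.
* **Randomness**: every draw derives from the master seed through named
  per-patient substreams (truth, reader A, reader B), so cohorts are
  byte-reproducible and the two readers are independent. The omission and
  margin draws are consumed for every lesion regardless of the decision, so
  cohorts differing only in perturbation probabilities stay paired at the
  same seed — which is what makes paired replicate comparisons sharp.

Defaults put the pooled cohort medians in the magnitude range reported for
untreated aggressive lymphoma (MTV of order hundreds of cm^3, TLG of order
10^3, Dmax of order tens of cm). The distributional choices (Poisson
counts, log-uniform radii, uniform peaks) are otherwise arbitrary: nothing
anchors them to a real cohort, and exact cohort medians are not a target.

### What the phantom does and does not emulate

It emulates the two disagreement channels that matter for the agreement
analysis: boundary delineation noise and inconsistent inclusion of small,
spatially separated lesions. It does **not** simulate PET physics (Poisson
counts, PSF, scatter, reconstruction artifacts), anatomy (organ placement,
spleen/bone-marrow uptake rules), or reader-specific bias (both readers are
exchangeable by construction, so the expected bias is zero — as in a study
where readers are randomly assigned to the A/B roles). Consequently,
passing tests show the *pipeline* is correct and that the omission
mechanism moves Dmax agreement more than MTV agreement; they do not certify
effect sizes on real scans. One known qualitative difference: on real data
the 3 cm^3 filter improved Dmax agreement, while in the phantom the filter
also creates a new discordance channel (boundary jitter pushes
near-threshold lesions across the cutoff for one reader only), so filtered
Dmax agreement is not reliably higher than unfiltered.

## Numerical choices and degenerate inputs

* Grid compatibility: spacings must agree within 1e-3 mm per axis, origins
  within 1e-2 mm; shapes exactly. Only axis-aligned NIfTI affines are
  accepted (permutations and flips are canonicalized on load; shear or
  oblique rotation is an error) because the volume/centroid arithmetic
  assumes an orthogonal lattice.
* Masks are written as uint8, volumes as float64 (exact round trip).
* Unit conversions are fixed: mm^3 -> cm^3 by /1000, mm -> cm by /10.
* Component ordering is deterministic (by lexicographically smallest
  voxel), so relabeling cannot change any metric.
* Constant metric vectors (e.g. every patient's filtered Dmax = 0 in a
  tiny cohort) make rank correlation undefined; the agreement stage raises
  a descriptive error rather than emitting NaN.
* Empty masks are valid inputs: MTV = TLG = Dmax = 0 with zero lesions.

## Problem sizes

The test suite and the acceptance script run cohorts of 10-117 patients on
the default grid; the replicated mechanism check uses 20 paired seed
replicates of 30 patients each (paired by construction through the shared
truth stream), and the sign test at 15/20 wins corresponds to a one-sided
binomial p of about 0.02. Labeling/Dmax oracle equivalence is checked
against brute-force flood fill and exhaustive pairwise search on masks up
to 20^3, where the brute force is still instant.

## Known limitations

* SUV values are taken as given; no computation from activity, dose and
  weight, and no DICOM ingestion.
* No resampling: volume and mask must already share a grid.
* No intra-reader variability, no reader-specific effects, no survival or
  prognostic modelling.
* The reader model perturbs lesions independently; real readers make
  spatially correlated decisions (e.g. skipping a whole nodal region).
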