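# petquant

Quantitative FDG PET/CT biomarkers for lymphoma — **MTV**, **TLG** and
**Dmax** — and the statistics used to ask whether two physicians measuring
them independently would reach the same clinical conclusion.

Baseline tumour burden and dissemination on FDG PET carry prognostic
information in Hodgkin and diffuse large B-cell lymphoma, but only if the
numbers are reproducible across readers. Given a patient's SUV volume and a
binary lesion segmentation, this package computes, per reader:

* **MTV** (metabolic tumour volume, cm^3): total volume of all voxels
  labelled as lymphoma,
* **TLG** (total lesion glycolysis): sum over lesions of
  SUVmean x lesion volume,
* **Dmax** (cm): Euclidean distance between the centroids of the two most
  widely separated lesions (0 if fewer than two lesions),

where a lesion is a 3D connected component of the mask (26-connectivity by
default). For two paired readings A and B over a cohort it then computes
Spearman's rho with a Fisher-z 95% CI, Bland-Altman bias and 95% limits of
agreement (bias +/- 1.96 x SD of the differences), and — after splitting
each metric at the pooled cohort median — the 2x2 below/above contingency
table, the percentage agreement and Cohen's kappa,
kappa = (P0 - Pe)/(1 - Pe). Every analysis can be repeated excluding
lesions smaller than 3 cm^3, which isolates the influence of small,
spatially separated lesions: these barely move MTV or TLG but can swing
Dmax by tens of centimetres.

Because no patient scans ship with the package, a synthetic phantom module
generates fully reproducible two-reader cohorts: spherical lesions with
radial SUV falloff on a whole-body-scale grid, and a reader model with two
disagreement channels — boundary dilation/erosion jitter and random
omission of sub-3 cm^3 lesions. See `docs/methods.md` for the model and its
limits.

## Worked example

```bash
$ cat config.yaml
n_patients: 20
seed: 42

$ petquant simulate --config config.yaml --out cohort
cohort/manifest.json
$ petquant metrics --manifest cohort/manifest.json --out metrics.csv
$ petquant agreement --metrics metrics.csv --out-json agreement.json
$ petquant report --json agreement.json

=== filter variant: all ===
metric    n    rho         95% CI       bias    LoA +/-  % agree  kappa
MTV      20   0.95   [0.87, 0.98]      -8.32       72.5     95.0   0.90
TLG      20   0.99   [0.98, 1.00]      -4.53        165    100.0   1.00
Dmax     20   0.75   [0.47, 0.90]        1.3       25.3     80.0   0.60

=== filter variant: ge3cm3 ===
metric    n    rho         95% CI       bias    LoA +/-  % agree  kappa
MTV      20   0.95   [0.89, 0.98]      -8.12       72.6     95.0   0.90
TLG      20   0.98   [0.96, 0.99]     -0.119        162     90.0   0.80
Dmax     20   0.77   [0.50, 0.91]       0.45       22.9     90.0   0.80
```

Reading the output: volume-type metrics agree almost perfectly between the
simulated readers (MTV rho 0.95, kappa 0.90), while Dmax — driven by which
small distant lesions each reader happened to include — is visibly less
stable (rho 0.75, kappa 0.60). Excluding lesions under 3 cm^3 removes that
channel and lifts Dmax agreement (kappa 0.80). `bias` is the mean A-B
difference in the metric's own units, and `LoA +/-` the half-width of the
interval expected to contain ~95% of the paired differences.

The same pipeline runs on real data: point `metrics` at a
`manifest.json` listing each patient's SUV NIfTI and the two reader-mask
NIfTIs, or skip straight to `agreement` with your own per-patient CSV
(columns `patient_id, reader_id, filter_label, mtv_cm3, tlg, dmax_cm,
n_lesions`).

As a library:

```python
from petquant import load_suv_volume, load_mask, compute_patient_metrics

vol = load_suv_volume("P001_suv.nii.gz", patient_id="P001")
mask = load_mask("P001_mask_A.nii.gz", reader_id="A", patient_id="P001")
rec = compute_patient_metrics(vol, mask, min_volume_cm3=3.0)
print(rec.mtv_cm3, rec.tlg, rec.dmax_cm, rec.n_lesions)
```

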