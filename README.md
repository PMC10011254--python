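# petseg-consensus

Consensus contours for ¹⁸F-FDG PET tumor delineation, evaluated on
simulated lung lesions with known ground truth.

Automatic PET tumor segmentation is notoriously sensitive to the choice of
method and to the user-drawn initial region around the lesion. This package
implements a full evaluation pipeline for one mitigation strategy —
majority-vote consensus over several independent segmentations — aimed at
physicists and image-analysis researchers who want to quantify both the
*accuracy* and the *robustness* of delineation methods:

* a **digital phantom generator** producing irregular lung lesions whose
  uptake derives from the two-tissue compartment FDG model, with optional
  respiratory-motion averaging and PET-like image degradation;
* four **segmentation methods**: a region-based active contour (MASAC),
  affinity-propagation clustering (AP), contrast-oriented adaptive
  thresholding (ST), and a fixed 41%-of-maximum threshold (41MAX), each run
  inside a rectangle or an irregular initial mask;
* **consensus fusion** (ConSeg, majority vote) and metric averaging (AveSeg);
* **metrics and statistics**: MATV, RE, DSC, test–retest (TRT) statistics,
  Friedman and post hoc Wilcoxon/Bonferroni tests.

## The model

Tissue uptake follows the two-tissue compartment model

```
dC_f/dt = K1·Cp(t) − (k2 + k3)·C_f + k4·C_b
dC_b/dt = k3·C_f − k4·C_b
C_T(t)  = (1 − V_B)(C_f + C_b) + V_B·Cp(t)
```

with the Feng population curve as the arterial input `Cp`. Lesions carry
three concentric activity levels (intratumoral heterogeneity); the
background is normalized so normal lung equals 1.

Segmentations `SM` are scored against the ground truth `GT` by

```
RE  = (MATV(SM) − MATV(GT)) / MATV(GT) × 100 %
DSC = 2|SM ∩ GT| / (|SM| + |GT|)
TRT = (M_rectangle − M_irregular) / ((M_rectangle + M_irregular)/2)
```

where MATV is the contour volume and TRT measures how reproducible a
metric `M` is between the two initial-mask conditions (0 = perfectly
robust, bounded by ±2 for non-negative metrics).

## Worked example

```python
>>> from petseg_consensus import compute_uptake_ratios
>>> compute_uptake_ratios()          # lesion-to-lung ratios at 70 min
(10.93459065595382, 10.07417994004755, 6.585090592592517)
```

The three numbers are the Level I/II/III lesion-to-lung activity ratios at
70 min post injection — the intensity contrast the phantom lesions carry.

A small end-to-end run from the shell:

```bash
petseg-consensus simulate --config spec.yaml --out simcase
petseg-consensus segment --method st --image simcase/pet.nii.gz \
    --mask simcase/mask_rectangle.nii.gz --out seg_st.nii.gz
# ... same for masac / ap / 41max ...
petseg-consensus consensus --inputs seg_masac.nii.gz --inputs seg_ap.nii.gz \
    --inputs seg_st.nii.gz --inputs seg_41max.nii.gz --k 3 --out conseg.nii.gz
petseg-consensus metrics --seg conseg.nii.gz --gt simcase/gt.nii.gz
{
  "MATV_cm3": 7.732599640274053,
  "RE_pct": -50.53763440860215,
  "DSC": 0.6618705035971223
}
```

Here the consensus contour of an 8 cm³ lesion simulated *with* respiratory
motion covers 7.73 cm³, underestimating the motion-blurred ground-truth
union by 51% with a Dice overlap of 0.66 — the systematic underestimation
that motion averaging induces in every threshold-like method.

The full study (13-case cohort, both mask conditions, all methods,
consensus, TRT and statistics) runs in under a minute:

```bash
petseg-consensus study --n-cases 13 --seed 2023 --out study_out
```

and writes `metrics.csv`, `trt.csv`, `summary.csv` (median and
interquartile range per method × mask condition), `trt_summary.csv` and
`stats.json`.

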