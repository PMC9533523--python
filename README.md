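# deepimmune

Reusable analysis pipeline for scoring immune-related tissue composition in
patch-grid tissue probability maps of colorectal-cancer whole-slide images,
and validating the scores against survival.

From per-slide grids of 9-class patch probabilities (ADI, BAC, DEB, LYM,
MUC, MUS, NOR, STR, TUM — produced by any pluggable patch classifier), the
pipeline computes:

- **deep_tsr** — the stroma fraction of the tumour bed, #STR / (#STR + #TUM)
  patches; split at 50% into high/low stroma groups;
- **deep_til** — the mean LYM probability inside the stroma mask; split at
  the 33rd/66th percentiles of a reference cohort into low/middle/high;
- **immune score** — a 4-level composite (stroma high/low scores 0/1 point,
  infiltration low/middle/high scores 1/2/3; the composite is the sum);
- **stroma-CD3 density** — CD3+ cell detections with centroid in the stroma
  ROI of an IHC slide, divided by the stroma area (cells/mm²);
- **survival validation** — Kaplan–Meier curves and 5-year rates, k-group
  log-rank tests, uni/multivariate Cox fits (Efron ties, Wald 95% CIs),
  Harrell's C-index, and the IPCW cumulative/dynamic AUC integrated over
  0–5 years, with stage-stratified analyses.

A synthetic-data module generates desk-scale cohorts with the full
statistical structure (tissue maps or rendered label images with a mock
colour-lookup classifier, CD3 detections at group-calibrated densities,
exponential survival calibrated to group 5-year rates), so every stage is
testable without slide data.

## Command-line pipeline

```sh
# generate a synthetic cohort (maps, IHC detections, clinical table, truth)
deepimmune simulate --seed 7 --n 60 --out-dir run/cohort

# score every slide; fits the tertile calibration on this cohort
deepimmune score --maps-dir run/cohort/maps --out-dir run/out

# reuse a primary-cohort calibration on a validation cohort
deepimmune score --maps-dir run/val/maps --calibration run/out/calibration.json \
    --out-dir run/val_out

# stroma-CD3 density per slide
deepimmune density --maps-dir run/cohort/ihc_maps \
    --detections run/cohort/detections.csv --out-dir run/out

# KM / log-rank / Cox / C-index / iAUC
deepimmune survival --clinical run/cohort/clinical.csv \
    --scores run/out/scores.csv --out-dir run/out

# human-readable summary
deepimmune report --dir run/out
```

All randomness is routed through the configured seed; identical reruns
produce byte-identical artifacts. Exit codes: 0 ok, 1 user error,
2 internal error.

### File dialects

- map store: `<slide_id>/meta.json` plus `probs.npz` (dense) or `probs.csv`
  (`row,col,ADI,...,TUM`); both dialects are read.
- scores CSV: `patient_id,deep_tsr,tsr_group,deep_til,til_group,immune_score`
- detections CSV: `slide_id,x_px,y_px,area_px2`
- density CSV: `patient_id,n_cells_in_stroma,stroma_area_mm2,density_cells_per_mm2`
- clinical CSV: `patient_id,cohort,age,sex,stage,location,grade,cea,os_years,os_event`
- calibration JSON: `{t33,t66,reference_cohort_id,n_reference,degenerate}`

## Documented conventions

- tiling: patches fully inside the image; default stride 112 px (50%
  overlap), incomplete margins dropped; each grid cell stores the vector of
  the patch anchored there (no cross-patch averaging).
- argmax ties in segmentation go to the lowest class index.
- a stroma fraction exactly at the cutoff is assigned to the *high* group;
  tertile boundaries are inclusive on the lower group.
- stroma area uses the stride footprint, `#STR × (stride × mpp)² / 10⁶` mm²,
  so overlapping patches are not double-counted; a detection counts if its
  centroid falls in an STR grid cell.
- the reference IHC detector thresholds a brown-likeness channel
  (min(R,G) − B, unit-scaled, default 0.3) with an area window of
  [30, 5000] px²; it is a documented stand-in for real cell segmentation.
- survival: Efron tie handling, two-sided tests at 0.05, 95% CIs; the iAUC
  is the IPCW cumulative/dynamic AUC on a grid of event times, trapezoid
  integrated and normalized by the grid span.
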