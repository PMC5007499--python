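# purkinje3d

Label-free, fully automatic detection and quantification of Purkinje
cells in 3D phase-contrast tomograms of cerebellar tissue.

Hard X-ray phase tomography images paraffin-embedded brain tissue in 3D
at isotropic micrometre resolution without staining — close enough to
the cell level that the large Purkinje neurons, and even their
nucleoli, are visible as local maxima of the reconstructed phase shift.
Counting those cells by hand across tens of cubic millimetres is
impractical; this package automates the whole chain, from a raw volume
to classified objects, refined cell masks with nucleoli, the extracted
Purkinje-layer manifold, and surface/volume density statistics. It is
written for researchers post-processing synchrotron phase tomograms of
neural tissue, and for anyone who needs a tested, desk-scale reference
implementation of the underlying algorithms.

## Method

Given a volume with isotropic voxel length (reference data: 1.75 μm),
the pipeline runs:

1. **Normalise** — percentile clip (0.1/99.9) and rescale to [0, 1].
2. **Frangi vesselness** — per-voxel measure from the ordered Hessian
   eigenvalues |λ1| ≤ |λ2| ≤ |λ3| at Gaussian scales s = 3…6 voxels,

       V_s = (1 − e^(−R_a²/2α²)) · e^(−R_b²/2β²) · (1 − e^(−S²/2γ²)),

   with R_a = |λ2|/|λ3|, R_b = |λ1|/√(|λ2||λ3|), S = ‖λ‖₂, and
   α = 0.2, β = 0.5, γ = 40 (cell mode); response = max over scales.
   A dendrite mode (scales 1–3, α = 0.5, β = 0.1, γ = 10) segments the
   dendritic tree in sub-micron volumes.
3. **Extract & classify objects** — threshold, close + fill, 26-connected
   labelling; discard objects outside 300–3000 voxels or within 10
   voxels of the border; compute each object's mean signed-distance
   (level-set) value; |mean| > 12 ⇒ Corpus amylaceum, size/mean² > 450
   ⇒ blood vessel, else Purkinje-cell candidate.
4. **Refine** — region-grow each candidate (intensity tolerance 0.0385
   to the seed mean, 5-voxel cap) and segment the nucleolus at the
   in-cell intensity maximum via Otsu thresholding.
5. **Layer & density** — keep the largest connected block of occupied
   50-voxel cubes (the Purkinje layer), extract the layer manifold as
   the 44-voxel zero level set of the smoothed cell-distance field
   (marching cubes), and colour it by local cell density in a 100 μm
   neighbourhood (cells/mm²).
6. **Evaluate** — detection error against a ground-truth table
   (100·(FP+FN)/detections, greedy 10 μm matching), SNR
   |x̄_mol − x̄_par|/σ_par, and the whole-cerebellum scan budget.

A synthetic phantom generator renders a cerebellum-like scene — folded
cell layer between two tissue strata, somata with nucleoli, vessels,
Corpora amylacea, background gradients, SNR-calibrated noise — with an
exact ground-truth table, so the full pipeline is testable on a
laptop. See `docs/methods.md` for the model details and parameter
rationale.

## Worked example

Run the whole chain on the default 256³ phantom (0.45 mm side,
1.75 μm voxels, 165 cells/mm², SNR 13, seed 42):

```sh
purkinje3d all --seed 42 --out out/
```

which logs the stage counts and prints the summary:

```
INFO purkinje3d: phantom: 26 cells, 3 vessels, 8 corpora
INFO purkinje3d: detect: 35 objects (cell_candidate=26, rejected_border=2, rejected_size=7)
INFO purkinje3d: layer population: kept 26 of 26 candidates
{
 "n_cells": 26,
 "mean_cell_volume_um3": 5081.51,
 "area_mm2": 0.412,
 "mean_density_per_mm2": 179.3,
 "vertex_mean_density_per_mm2": 172.5,
 "global_density_per_mm2": 126.1,
 "volumetric_density_per_mm3": 289.2,
 "detection_error": {"n_detected": 26, "n_truth": 26,
                     "true_positives": 26, "false_positives": 0,
                     "false_negatives": 0, "error_pct": 0.0, ...}
}
```

Reading the numbers: all 26 planted cells were recovered with no false
positives (error 0%); the mean region-grown cell volume, 5,082 μm³, is
within 5% of the planted 4,850 μm³ soma; the area-weighted local
surface density, 179 cells/mm², recovers the planted 165 cells/mm² to
within 9% (the closed offset manifold has area 0.41 mm², twice the
~0.2 mm² cell sheet, hence the lower global figure). Artifacts written
to `out/`: the phantom volume (TIFF), ground truth and object/cell
tables (CSV), the density-coloured layer mesh (`layer.ply`), the
summary (JSON) and a run manifest with the config hash and seed.

Each stage is also available separately (`purkinje3d phantom | detect |
refine | layer | evaluate | snr | plan`) and as plain library calls;
volumes are read and written as multi-page TIFF, NRRD or raw+JSON.
`purkinje3d plan` prints the beam-time arithmetic for scanning a whole
human cerebellum (6,500 scans, 23 days at 5 min/scan).

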