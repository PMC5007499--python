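# Methods

`purkinje3d` implements a fully automatic, label-free pipeline that
detects and quantifies Purkinje cells in 3D phase-contrast tomograms of
paraffin-embedded cerebellar tissue, together with a synthetic phantom
generator that makes every stage testable without tomography data.
This note documents the model behind each stage, the parameters that
matter, the numerical choices, and the limits of what the phantom can
show.

## Pipeline model

The input is a reconstructed phase tomogram: a 3D scalar grid with an
isotropic voxel length (1.75 μm for the reference acquisition), carried
as a `Volume` in `(z, y, x)` order with voxel centres at integer
coordinates. All physical quantities are voxels × voxel length.

**Normalisation.** Absolute reconstruction units vary between
beamlines, but two downstream parameters are absolute intensities: the
region-growing tolerance (0.0385) and the vesselness sensitivity γ.
Every volume therefore enters the pipeline through percentile clipping
(defaults 0.1 / 99.9) and rescaling to [0, 1]. Rare very bright
structures (nucleoli, Corpora amylacea) may clip against the upper
percentile; this does not affect detection, which only needs
soma-to-neuropil contrast, but it compresses nucleolus/soma contrast on
scenes where bright voxels are less than 0.1% of the volume.

**Vesselness.** Structures are enhanced with the Frangi measure built
from the eigenvalues λ1, λ2, λ3 (|λ1| ≤ |λ2| ≤ |λ3|) of the Gaussian
scale-space Hessian:

    R_a = |λ2|/|λ3|,  R_b = |λ1|/√(|λ2||λ3|),  S = √(λ1²+λ2²+λ3²)
    V_s = (1 − e^{−R_a²/2α²}) · e^{−R_b²/2β²} · (1 − e^{−S²/2γ²})

zeroed where λ2 > 0 or λ3 > 0 (bright polarity; mirrored for dark),
maximised over an inclusive integer scale range. Cell mode uses
α = 0.2, β = 0.5, γ = 40 at scales 3–6 voxels (5.25–10.5 μm — the soma
scale); dendrite mode uses α = 0.5, β = 0.1, γ = 10 at scales 1–3
voxels on sub-micron data. Numerical choices:

* **γ-normalisation**: the Hessian is multiplied by s² so scales
  compete fairly in the maximum; without it the smallest scale always
  wins.
* **intensity scale**: γ = 40 is an absolute sensitivity. On [0, 1]
  data S ≈ 0.3 and the last factor collapses to ~10⁻⁵, extinguishing
  the response. `FrangiParams.intensity_scale` (default 255, an
  8-bit-equivalent dynamic range) maps the normalised volume onto the
  range γ refers to. The default was calibrated once, forward, on a
  noiseless soma fixture: at 255 a soma of radius 6 voxels yields peak
  responses of 0.07–0.26 and thresholded components of 600–1800 voxels,
  inside the published [300, 3000] object gate; at 1000 the S factor
  saturates and components balloon past the gate.
* **kernels**: Gaussian derivatives truncated at 4σ (truncation error
  < 10⁻⁴), reflect boundaries; the truncated second-derivative kernel's
  small DC gain is subtracted so constant regions have exactly zero
  curvature.
* **eigenvalues**: closed-form trigonometric solution for symmetric
  3×3 matrices, vectorised over the volume (per-voxel LAPACK calls
  would dominate the runtime at 256³), verified against
  `numpy.linalg.eigvalsh` in the tests.

**Object extraction.** The response is binarised (default threshold
0.10; the original study set its thresholds by visual inspection, and
Otsu-on-response is available as an alternative). The vesselness of a
blob peaks on its *boundary shell*: at realistic noise the shell is
punctured and the enclosed body partially missing, so the binary volume
is morphologically closed (3³) and hole-filled before 26-connected
labelling — objects of interest are tens of voxels apart, so closing
cannot merge them. The threshold default matters: at 0.05 the
component includes the blob's exterior halo (effective radius ≈ 7.6
voxels for a radius-6 soma), doubling object size and dragging the
tube ratio (below) across the vessel threshold; 0.10 tracks the soma
boundary. Components outside the size gate [300, 3000] voxels are
tagged `rejected_size` (the gate is read as strict exclusion of
"smaller than 300" and "larger than 3000", hence closed interval
kept), and components with any voxel within 10 voxels of a volume face
are tagged `rejected_border`.

**Geometry sorting.** Each surviving object is summarised by its mean
level-set value: the mean over its voxels of the signed exact Euclidean
distance transform (negative inside, voxel units). A solid ball of
radius R has |mean| ≈ R/4 + ½ voxel; a long tube of radius r has
|mean| ≈ r/3 + ½. Classification applies, in a fixed order: sphere
test first (|mean_lsv| > 12 ⇒ Corpus amylaceum), then tube test
(size/mean_lsv² > 450 ⇒ blood vessel), else Purkinje-cell candidate.
With a raw voxel-unit distance transform the sphere threshold 12
corresponds to balls of radius ≈ 48 voxels — far beyond anything
passing the size gate — so on the default phantom Corpora are instead
excluded by their size (below 300 voxels); both thresholds remain
configuration values for data whose level-set embedding is scaled
differently.

**Refinement.** Cell candidates are region-grown: 26-neighbours join
while their intensity stays within 0.0385 of the *initial* seed mean
(the reference is fixed — updating it lets the region drift and can
destroy the fixpoint), and growth is capped at a Euclidean distance of
5 voxels from the seed so noisy low-contrast boundaries cannot leak.
The nucleolus is seeded at the in-cell intensity maximum (the maximal
phase shift; ties broken lexicographically in (z, y, x)), thresholded
by Otsu on the in-cell histogram (256 bins), and taken as the
26-connected above-threshold component containing the seed.

**Layer manifold and densities.** Detections are sorted into 50-voxel
cubes; the largest connected component of occupied cubes is the
Purkinje-layer domain and everything else is discarded as off-layer
mis-segmentation. Cube adjacency defaults to 26-connectivity: at 165
cells/mm² a 50-voxel cube column holds ~1.3 cells on average, so face
adjacency fragments the folded layer at desk-scale volumes while
vertex adjacency keeps it one component and still drops isolated
off-layer cubes (6-connectivity remains available). Ties between
equally large components go to the one containing the lexicographically
smallest cube index.

The manifold itself is the zero level set of the smoothed distance
field: Euclidean distance (voxels) to the nearest kept cell, sampled on
a coarse grid with 10-voxel spacing, Gaussian-smoothed (σ = 2 nodes),
minus the 44-voxel zero level, triangulated by marching cubes. The
result is a *closed offset surface* enclosing the cell sheet; its area
is ≈ 2× the mid-layer area, so the global surface density divides by
area/2.

Per-vertex local density counts cells within a 100 μm ball of the
vertex. Each vertex sits ≈ 44 voxels (77 μm at 1.75 μm voxels) off the
cell sheet, so the ball only reaches a chord disc of radius
√(R² − offset²) ≈ 64 μm on the sheet; the count is divided by that
disc's area (falling back to πR² when the offset reaches R). Without
this correction the estimate would be biased low by the offset/radius
geometry (a factor ≈ 2.5 at the defaults). The headline statistic is
the area-weighted vertex mean; the unweighted vertex mean and the
global density are also reported, since different averaging conventions
give visibly different numbers on a folded sheet.

**Evaluation.** Detection error matches detected and true centroids
greedily by distance (each point used once) within a 10 μm radius —
adequate for somata spaced ≥ 50 μm, and guarded against an exhaustive
optimal-assignment oracle in the tests. The error is
100·(FP+FN)/n_detected, the convention that reproduces the published
accounting (3 FP + 2 FN over 108 detections → 4.63% → "5%"); the
denominator is stated in the report. SNR is |x̄_mol − x̄_par|/σ_par
over regions of at least 600 voxels. The scan-budget calculator uses
ceilings throughout (partial scans and days are still necessary beam
time).

## The phantom

The generator emulates the reference acquisition at desk scale: a 256³
volume at 1.75 μm voxels (~0.45 mm side, 0.09 mm³) containing

* two tissue strata — Stratum granulosum (intensity 0.45) below,
  Stratum moleculare (0.35) above — separated by the folded sheet
  z = z0 + A·sin(2πx/Lx)·sin(2πy/Ly) (A = 40 μm, one period per side),
  with a 50 μm paraffin slab (0.15) at the top;
* somata of radius 10.5 μm (≈ 905 voxels ≈ 4,850 μm³, the reported
  mean cell volume) at intensity 0.55, dart-thrown on the sheet at 165
  cells/mm² with minimum spacing 0.7/√density (≈ 54 μm, approximating
  the regular spacing of the real layer; never below one soma
  diameter), each with a 1.5 μm nucleolus at 0.75 offset ≤ 3 μm from
  the centre;
* three random-walk vessels (radius 3.5–5.25 μm) crossing the granular
  stratum and eight Corpora amylacea (radius 4–5.5 μm, intensity 0.7)
  off the layer;
* linear and radial background gradients (amplitude 0.02, the
  local-tomography artefact), and Gaussian noise with
  σ = (moleculare − paraffin)/SNR_target (default target 13, the
  better of the two reported beamline values), so that measuring the
  SNR on the phantom recovers the target by construction. The default
  intensities make soma−moleculare equal moleculare−paraffin, so the
  soma-to-neuropil contrast satisfies the same calibration.

Spheres and tubes are rendered with a ~1-voxel anti-aliased edge.
Somata keep 32 μm clear of the x/y faces so that no planted cell is
cut by the 10-voxel border rule — the ground truth only contains
recoverable objects, mirroring the study's own exclusion of border
objects. All randomness flows through one seeded generator; a fixed
seed reproduces the volume bit for bit.

What the phantom does **not** model: granule-cell texture (the real
granular stratum is speckled, not smooth), ring artefacts, beam
hardening, the point-spread function of phase retrieval, partial-volume
anisotropy, dendritic trees in the cell-scale volume (a separate
single-cell fixture with a branching tube tree exists for the dendrite
mode), and realistic vessel topology. Passing the phantom tests
therefore demonstrates that the chain of algorithms is implemented
correctly and is self-consistent at realistic contrast, noise and
density — not that the parameter defaults transfer unchanged to any
particular beamline's data.

## Problem sizes and runtime

The acceptance analogue runs the full chain on the default 256³
phantom (≈ 26 recoverable cells) in a few minutes on one CPU; unit
tests use 96³–128³ phantoms with the fold amplitude scaled to fit the
smaller tissue slab. The cell-scale Frangi filter is the dominant cost
(6 Gaussian-derivative convolutions and one closed-form
eigen-decomposition per scale, 4 scales, float32).

## Known limitations

* Objects touching each other (a soma against a vessel) are not split;
  watershed separation is out of scope.
* The nucleolus segmentation returns the single component at the
  intensity maximum; binucleate cells are not handled.
* The sphere rule (|mean_lsv| > 12) cannot fire on objects small
  enough to pass the size gate when the level set is a raw voxel-unit
  distance transform (see above); it is retained for data with
  differently scaled embeddings.
* Percentile normalisation makes the effective region-growing
  tolerance scene-dependent; on scenes with a very different intensity
  histogram the tolerance (and the response threshold) may need
  re-calibration, which is why both are exposed in the configuration.
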