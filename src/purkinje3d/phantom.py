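"""Synthetic cerebellum-like tomograms with exact ground truth.

The phantom emulates a paraffin-embedded cerebellar specimen as seen in
local phase-contrast tomography at 1.75 μm voxels:

* two tissue strata (Stratum granulosum below, Stratum moleculare
  above) separated by a folded sheet ``z(x, y) = z0 + A sin(2πx/Lx)
  sin(2πy/Ly)``, with a paraffin slab at the top of the volume;
* Purkinje somata as smooth-edged bright spheres seeded on the sheet by
  dart throwing at the target surface density, each with a small,
  brighter nucleolar sphere strictly inside;
* blood vessels as random-walk tubes crossing the granular stratum and
  Corpora amylacea as small bright spheres off the layer;
* smooth linear + radial background gradients (the local-tomography
  artefact) and Gaussian noise calibrated to a target signal-to-noise
  ratio.

Intensity polarity is bright-on-dark (cells and nucleoli above tissue
background, tissue above paraffin), matching phase-tomography contrast
of embedded tissue.  The noise level is σ = (moleculare − paraffin
contrast) / target_snr, i.e. the contrast entering the pipeline's SNR
definition, so measuring the SNR on the generated volume recovers the
target by construction.

All generator randomness flows through one ``numpy`` Generator seeded
by ``rng_seed``; a fixed seed reproduces the volume bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import RoiBox, Volume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate",
    "truth_to_csv",
    "truth_from_csv",
    "snr_measurement_rois",
    "make_dendrite_phantom",
]

_TRUTH_COLUMNS = ["class", "z", "y", "x", "param1", "param2",
                  "nucleolus_z", "nucleolus_y", "nucleolus_x"]


@dataclass(frozen=True)
class PhantomConfig:
    """Scene description; all lengths in μm, intensities on a [0, 1]-ish scale."""

    shape: tuple[int, int, int] = (256, 256, 256)
    voxel_len_um: float = 1.75

    # folded Purkinje layer: z = z0 + A sin(2πx/Lx) sin(2πy/Ly)
    layer_amplitude_um: float = 40.0
    layer_wavelengths_um: tuple[float, float] = (448.0, 448.0)
    layer_offset_um: float | None = None  # default: centre of the tissue region

    cell_density_per_mm2: float = 165.0
    soma_radius_um: float = 10.5          # ≈ 905 voxels ≈ 4,850 μm³ at 1.75 μm voxels
    soma_intensity: float = 0.55
    nucleolus_radius_um: float = 1.5
    nucleolus_intensity: float = 0.75
    nucleolus_max_offset_um: float = 3.0

    n_vessels: int = 3
    vessel_radius_um: tuple[float, float] = (3.5, 5.25)
    vessel_intensity: float = 0.55

    n_corpora: int = 8
    corpus_radius_um: tuple[float, float] = (4.0, 5.5)
    corpus_intensity: float = 0.70

    moleculare_intensity: float = 0.35
    granulosum_intensity: float = 0.45
    paraffin_intensity: float = 0.15
    paraffin_thickness_um: float = 50.0

    linear_gradient: float = 0.02
    radial_gradient: float = 0.02
    target_snr: float = 13.0

    # somata are kept this far from the x/y faces so that no planted cell is
    # cut by the detector's 10-voxel border-margin rule
    placement_margin_um: float = 32.0
    min_spacing_factor: float = 0.7

    rng_seed: int = 42

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ValueError("phantom shape must be at least 32 voxels per axis")
        if self.voxel_len_um <= 0 or self.target_snr <= 0:
            raise ValueError("voxel_len_um and target_snr must be positive")
        if self.cell_density_per_mm2 < 0:
            raise ValueError("cell density must be non-negative")
        if not 0 < self.nucleolus_radius_um < self.soma_radius_um:
            raise ValueError("need 0 < nucleolus radius < soma radius")
        if self.nucleolus_intensity <= self.soma_intensity:
            raise ValueError("nucleolus must be brighter than the soma")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_len_um for n in self.shape)  # type: ignore[return-value]

    @property
    def paraffin_z_um(self) -> float:
        return self.extent_um[0] - self.paraffin_thickness_um

    @property
    def layer_z0_um(self) -> float:
        if self.layer_offset_um is not None:
            return self.layer_offset_um
        return self.paraffin_z_um / 2.0

    def surface_z_um(self, x_um, y_um):
        """Height of the Purkinje-layer sheet above the z=0 face."""
        lx, ly = self.layer_wavelengths_um
        return (self.layer_z0_um
                + self.layer_amplitude_um
                * np.sin(2 * np.pi * np.asarray(x_um) / lx)
                * np.sin(2 * np.pi * np.asarray(y_um) / ly))

    def sheet_area_mm2(self, n_grid: int = 400) -> float:
        """Area of the sheet over the cell-placement window (numeric quadrature)."""
        m = self.placement_margin_um
        _, ey, ex = self.extent_um
        x = np.linspace(m, ex - m, n_grid)
        y = np.linspace(m, ey - m, n_grid)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        lx, ly = self.layer_wavelengths_um
        a = self.layer_amplitude_um
        dzdx = a * (2 * np.pi / lx) * np.cos(2 * np.pi * xx / lx) * np.sin(2 * np.pi * yy / ly)
        dzdy = a * (2 * np.pi / ly) * np.sin(2 * np.pi * xx / lx) * np.cos(2 * np.pi * yy / ly)
        integrand = np.sqrt(1.0 + dzdx ** 2 + dzdy ** 2)
        area_um2 = np.trapezoid(np.trapezoid(integrand, y, axis=1), x)
        return float(area_um2) / 1e6


@dataclass
class PhantomTruth:
    """Ground-truth object table; coordinates in voxel units (z, y, x)."""

    df: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return int((self.df["class"] == "cell").sum())

    def centroids_vox(self, cls: str = "cell") -> np.ndarray:
        sub = self.df[self.df["class"] == cls]
        return sub[["z", "y", "x"]].to_numpy(dtype=float)


def truth_to_csv(t: PhantomTruth, path: str | Path) -> Path:
    path = Path(path)
    t.df.to_csv(path, index=False, columns=_TRUTH_COLUMNS)
    return path


def truth_from_csv(path: str | Path) -> PhantomTruth:
    df = pd.read_csv(path)
    missing = [c for c in _TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"truth table misses columns {missing}")
    return PhantomTruth(df[_TRUTH_COLUMNS].copy())


# ---------------------------------------------------------------------------
# painting primitives (all coordinates in μm, voxel centres at index*voxel_len)
# ---------------------------------------------------------------------------

def _paint_ball(data: np.ndarray, voxel: float, centre_um, radius_um: float,
                intensity: float) -> None:
    """Blend a sphere into the volume with a ~1-voxel anti-aliased edge."""
    c = np.asarray(centre_um, dtype=float)
    lo = np.maximum(np.floor((c - radius_um) / voxel).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((c + radius_um) / voxel).astype(int) + 2, data.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * voxel - c[0])[:, None, None]
    yy = (np.arange(lo[1], hi[1]) * voxel - c[1])[None, :, None]
    xx = (np.arange(lo[2], hi[2]) * voxel - c[2])[None, None, :]
    d = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    w = np.clip((radius_um - d) / voxel + 0.5, 0.0, 1.0).astype(np.float32)
    sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub += (intensity - sub) * w


def _paint_tube(data: np.ndarray, voxel: float, points_um: np.ndarray,
                radius_um: float, intensity: float) -> None:
    """Paint a polyline tube by stamping spheres at sub-voxel spacing.

    Overlapping stamps blend with a running maximum of the coverage, so
    the tube surface stays smooth.
    """
    # accumulate coverage on the tube's bounding box, then blend once
    lo = np.maximum(np.floor((points_um.min(0) - radius_um) / voxel).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((points_um.max(0) + radius_um) / voxel).astype(int) + 2, data.shape)
    if np.any(lo >= hi):
        return
    cover = np.zeros(tuple(hi - lo), dtype=np.float32)
    for a, b in zip(points_um[:-1], points_um[1:]):
        seg = b - a
        n = max(int(np.ceil(np.linalg.norm(seg) / (0.5 * voxel))), 1)
        for t in np.linspace(0.0, 1.0, n + 1):
            c = a + t * seg
            clo = np.maximum(np.floor((c - radius_um) / voxel).astype(int) - 1, lo)
            chi = np.minimum(np.ceil((c + radius_um) / voxel).astype(int) + 2, hi)
            if np.any(clo >= chi):
                continue
            zz = (np.arange(clo[0], chi[0]) * voxel - c[0])[:, None, None]
            yy = (np.arange(clo[1], chi[1]) * voxel - c[1])[None, :, None]
            xx = (np.arange(clo[2], chi[2]) * voxel - c[2])[None, None, :]
            d = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
            w = np.clip((radius_um - d) / voxel + 0.5, 0.0, 1.0).astype(np.float32)
            view = cover[clo[0]-lo[0]:chi[0]-lo[0], clo[1]-lo[1]:chi[1]-lo[1],
                         clo[2]-lo[2]:chi[2]-lo[2]]
            np.maximum(view, w, out=view)
    sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub += (intensity - sub) * cover


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _background(cfg: PhantomConfig) -> np.ndarray:
    nz, ny, nx = cfg.shape
    voxel = cfg.voxel_len_um
    z = (np.arange(nz, dtype=np.float32) * voxel)[:, None, None]
    y = (np.arange(ny, dtype=np.float32) * voxel)[None, :, None]
    x = (np.arange(nx, dtype=np.float32) * voxel)[None, None, :]
    zsurf = cfg.surface_z_um(x, y).astype(np.float32)
    # granular below the sheet, molecular above, ~1 voxel ramp
    w = np.clip((z - zsurf) / voxel + 0.5, 0.0, 1.0)
    vol = cfg.granulosum_intensity + (cfg.moleculare_intensity
                                      - cfg.granulosum_intensity) * w
    # paraffin slab at the top
    wp = np.clip((z - cfg.paraffin_z_um) / voxel + 0.5, 0.0, 1.0)
    vol += (cfg.paraffin_intensity - vol) * wp
    # local-tomography artefact: smooth linear + radial gradients
    ez, ey, ex = cfg.extent_um
    vol += cfg.linear_gradient * ((x - ex / 2) / (ex / 2)).astype(np.float32)
    r2 = (((y - ey / 2) / (ey / 2)) ** 2 + ((x - ex / 2) / (ex / 2)) ** 2) / 2.0
    vol += cfg.radial_gradient * (r2 - 0.5).astype(np.float32)
    return vol.astype(np.float32)


def _place_cells(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Dart-throw soma centres (μm) on the sheet with minimum spacing."""
    area = cfg.sheet_area_mm2()
    n_target = int(round(cfg.cell_density_per_mm2 * area))
    if n_target == 0:
        return np.empty((0, 3))
    # 0.7/sqrt(density) approximates the regular spacing of the real layer;
    # never closer than one soma diameter so that somata cannot overlap
    spacing_um = max(
        cfg.min_spacing_factor / np.sqrt(cfg.cell_density_per_mm2) * 1000.0,
        2.0 * cfg.soma_radius_um + cfg.voxel_len_um)
    m = cfg.placement_margin_um
    _, ey, ex = cfg.extent_um
    accepted: list[np.ndarray] = []
    tries = 0
    max_tries = 300 * n_target
    while len(accepted) < n_target:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"cell placement failed: {len(accepted)}/{n_target} cells after "
                f"{max_tries} draws; density infeasible for this surface")
        x = rng.uniform(m, ex - m)
        y = rng.uniform(m, ey - m)
        z = float(cfg.surface_z_um(x, y))
        c = np.array([z, y, x])
        if accepted:
            d = np.linalg.norm(np.asarray(accepted) - c, axis=1)
            if d.min() < spacing_um:
                continue
        accepted.append(c)
    return np.asarray(accepted)


def _granular_band_um(cfg: PhantomConfig) -> tuple[float, float]:
    """z-range (μm) of the granular stratum clear of the folded layer."""
    z_lo = 10.0
    z_hi = cfg.layer_z0_um - cfg.layer_amplitude_um - 25.0
    return z_lo, z_hi


def _vessel_path(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Random-walk polyline crossing the volume inside the granular stratum."""
    voxel = cfg.voxel_len_um
    _, ey, ex = cfg.extent_um
    z_lo, z_hi = _granular_band_um(cfg)
    if z_hi - z_lo < 25.0:
        raise ValueError(
            "granular stratum too thin for vessels: reduce layer_amplitude_um, "
            "enlarge the volume, or set n_vessels=0")
    along_x = rng.random() < 0.5
    span = ex if along_x else ey
    t = 0.0
    z = rng.uniform(z_lo + 10, z_hi - 10)
    u = rng.uniform(40.0, (ey if along_x else ex) - 40.0)
    pts = []
    step = 2.0 * voxel
    while t <= span:
        pts.append([z, u, t] if along_x else [z, t, u])
        t += step
        z = np.clip(z + rng.normal(0.0, 0.6 * voxel), z_lo, z_hi)
        u = np.clip(u + rng.normal(0.0, 0.6 * voxel), 5.0, (ey if along_x else ex) - 5.0)
    pts = np.asarray(pts)
    if along_x:
        return pts[:, [0, 1, 2]]  # (z, y=u, x=t)
    return pts


def generate(cfg: PhantomConfig = PhantomConfig()) -> tuple[Volume, PhantomTruth]:
    """Render the phantom volume and return it with its ground truth.

    Deterministic for a fixed ``cfg.rng_seed``.  Raises ``RuntimeError``
    when the requested cell density cannot be met by dart throwing.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    voxel = cfg.voxel_len_um
    vol = _background(cfg)
    records: list[dict] = []

    # vessels first so that somata are painted over any accidental contact
    for _ in range(cfg.n_vessels):
        radius = rng.uniform(*cfg.vessel_radius_um)
        pts = _vessel_path(cfg, rng)
        _paint_tube(vol, voxel, pts, radius, cfg.vessel_intensity)
        centre = pts.mean(axis=0) / voxel
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        records.append(dict(zip(_TRUTH_COLUMNS,
                                ["vessel", *centre, radius, length,
                                 np.nan, np.nan, np.nan])))

    # Corpora amylacea: small bright spheres off the layer (granular side)
    z_lo, z_hi = _granular_band_um(cfg)
    if cfg.n_corpora > 0 and z_hi - z_lo < 15.0:
        raise ValueError(
            "granular stratum too thin for Corpora amylacea: reduce "
            "layer_amplitude_um, enlarge the volume, or set n_corpora=0")
    corpus_centres: list[np.ndarray] = []
    for _ in range(cfg.n_corpora):
        radius = rng.uniform(*cfg.corpus_radius_um)
        for _attempt in range(200):
            m = cfg.placement_margin_um
            _, ey, ex = cfg.extent_um
            c = np.array([rng.uniform(z_lo + radius, z_hi - radius),
                          rng.uniform(m, ey - m),
                          rng.uniform(m, ex - m)])
            if all(np.linalg.norm(c - p) > 4 * radius for p in corpus_centres):
                break
        corpus_centres.append(c)
        _paint_ball(vol, voxel, c, radius, cfg.corpus_intensity)
        records.append(dict(zip(_TRUTH_COLUMNS,
                                ["corpus", *(c / voxel), radius, 0.0,
                                 np.nan, np.nan, np.nan])))

    # Purkinje somata on the folded sheet, each with a nucleolus
    centres = _place_cells(cfg, rng)
    max_off = min(cfg.nucleolus_max_offset_um,
                  cfg.soma_radius_um - cfg.nucleolus_radius_um - 1.5 * voxel)
    max_off = max(max_off, 0.0)
    for c in centres:
        _paint_ball(vol, voxel, c, cfg.soma_radius_um, cfg.soma_intensity)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        nuc = c + direction * rng.uniform(0.0, max_off)
        _paint_ball(vol, voxel, nuc, cfg.nucleolus_radius_um, cfg.nucleolus_intensity)
        records.append(dict(zip(_TRUTH_COLUMNS,
                                ["cell", *(c / voxel), cfg.soma_radius_um, 0.0,
                                 *(nuc / voxel)])))

    # Gaussian noise calibrated to the target SNR (tissue/paraffin contrast)
    contrast = abs(cfg.moleculare_intensity - cfg.paraffin_intensity)
    sigma = contrast / cfg.target_snr
    vol += rng.normal(0.0, sigma, size=vol.shape).astype(np.float32)

    df = pd.DataFrame(records, columns=_TRUTH_COLUMNS)
    volume = Volume(vol, voxel, provenance=f"synthetic phantom, seed {cfg.rng_seed}")
    return volume, PhantomTruth(df)


def snr_measurement_rois(cfg: PhantomConfig) -> tuple[RoiBox, RoiBox]:
    """Default Stratum-moleculare and paraffin patches for SNR measurement."""
    voxel = cfg.voxel_len_um
    nz, ny, nx = cfg.shape
    z_mol = int((cfg.layer_z0_um + cfg.layer_amplitude_um + 27.0) / voxel)
    z_par = int(cfg.paraffin_z_um / voxel) + 3
    side = 32
    oy, ox = ny // 2 - side // 2, nx // 2 - side // 2
    mol = RoiBox((z_mol, oy, ox), (10, side, side))
    par = RoiBox((min(z_par, nz - 11), oy, ox), (10, side, side))
    return mol, par


def make_dendrite_phantom(shape: tuple[int, int, int] = (96, 96, 96),
                          voxel_len_um: float = 0.45,
                          rng_seed: int = 0) -> tuple[Volume, dict]:
    """Single-cell fixture for the dendrite mode: soma + branching tubes.

    A simplified high-resolution scene (sub-micron voxels): one soma
    with a rising trunk that bifurcates twice, plus a short disjoint
    tube acting as a decoy for largest-component selection.  Returns
    the volume and a dict with the painted tube polylines.
    """
    rng = np.random.default_rng(rng_seed)
    voxel = voxel_len_um
    data = np.full(shape, 0.30, dtype=np.float32)
    ez = shape[0] * voxel
    centre = np.array([0.28 * ez, shape[1] * voxel / 2, shape[2] * voxel / 2])
    soma_r = 8.0
    _paint_ball(data, voxel, centre, soma_r, 0.55)
    tube_r = 1.6 * voxel

    def branch(start, direction, length, n=24):
        direction = np.asarray(direction, dtype=float)
        direction /= np.linalg.norm(direction)
        pts = [np.asarray(start, dtype=float)]
        step = length / n
        d = direction.copy()
        for _ in range(n):
            d = d + rng.normal(0.0, 0.12, 3)
            d /= np.linalg.norm(d)
            pts.append(pts[-1] + d * step)
        return np.asarray(pts)

    trunk = branch(centre + [soma_r - 1.0, 0, 0], [1, 0, 0], 12.0)
    b1 = branch(trunk[-1], [1, 0.8, 0.2], 10.0)
    b2 = branch(trunk[-1], [1, -0.7, -0.3], 10.0)
    b3 = branch(b1[-1], [1, 0.2, 0.9], 7.0)
    tubes = [trunk, b1, b2, b3]
    for t in tubes:
        _paint_tube(data, voxel, t, tube_r, 0.55)
    # disjoint decoy tube, far from the tree
    decoy = branch(np.array([0.75 * ez, 10.0, 10.0]), [0, 1, 0.3], 6.0)
    _paint_tube(data, voxel, decoy, tube_r, 0.55)
    data += rng.normal(0.0, 0.04, size=shape).astype(np.float32)
    return (Volume(data, voxel_len_um, provenance="synthetic dendrite fixture"),
            {"tree": tubes, "decoy": decoy, "soma_centre_um": centre,
             "soma_radius_um": soma_r})
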