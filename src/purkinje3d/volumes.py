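"""Volume container and file I/O for the tomogram pipeline.

All volumes are 3D scalar grids in ``(z, y, x)`` axis order with an
isotropic voxel edge length in micrometres.  Physical quantities are
always derived as ``voxels * voxel_len_um``; voxel centres sit at
integer coordinates.

Supported on-disk formats
-------------------------
* multi-page TIFF (grayscale; voxel size stored as ImageJ ``spacing``
  metadata plus X/Y resolution tags)
* NRRD, raw encoding, with per-axis ``spacings`` (isotropy enforced)
* raw float32/.. binary next to a JSON sidecar
  ``{"shape": [nz, ny, nx], "voxel_len_um": ..., "dtype": ..., "order": "zyx"}``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "RoiBox",
    "read_volume",
    "write_volume",
    "normalise",
    "crop",
    "bin_volume",
]

# relative tolerance for declaring per-axis voxel spacings isotropic
_ISO_RTOL = 1e-3


@dataclass
class Volume:
    """A 3D scalar grid with isotropic voxel length.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities.
    voxel_len_um : float
        Edge length of the cubic voxel in micrometres; identical along
        all three axes.
    provenance : str
        Free-text note on where the data came from and what was done
        to it (file path, normalisation, binning...).
    """

    data: np.ndarray
    voxel_len_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a non-empty 3D grid, got shape {self.data.shape}")
        if not (self.voxel_len_um > 0):
            raise ValueError(f"voxel_len_um must be positive, got {self.voxel_len_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_len_um) ** 3

    def with_data(self, data: np.ndarray, note: str = "") -> "Volume":
        """Copy of this volume carrying new data on the same grid."""
        prov = f"{self.provenance}; {note}" if note else self.provenance
        return Volume(data, self.voxel_len_um, prov)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned region of interest in voxel coordinates (z, y, x)."""

    origin: tuple[int, int, int]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.shape) != 3:
            raise ValueError("origin and shape must be voxel triples")
        if any(o < 0 for o in self.origin):
            raise ValueError(f"roi origin must be non-negative, got {self.origin}")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"roi shape must be positive, got {self.shape}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.shape))  # type: ignore[return-value]

    def check_within(self, volume_shape: tuple[int, int, int]) -> None:
        for ax, (o, s, n) in enumerate(zip(self.origin, self.shape, volume_shape)):
            if o + s > n:
                raise ValueError(
                    f"roi exceeds volume bounds on axis {ax}: {o}+{s} > {n}"
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, voxel_len_um: float | None = None) -> Volume:
    """Read a volume from TIFF, NRRD or raw+JSON sidecar.

    Voxel length is taken from file metadata when present, otherwise
    from the ``voxel_len_um`` argument; an error is raised when neither
    is available, or when the stored spacings are anisotropic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data, meta_len = _read_tiff(path)
    elif suffix == ".nrrd":
        data, meta_len = _read_nrrd(path)
    elif suffix == ".raw":
        data, meta_len = _read_raw(path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    length = meta_len if meta_len is not None else voxel_len_um
    if length is None:
        raise ValueError(
            f"{path.name} carries no voxel size metadata and no voxel_len_um was given"
        )
    return Volume(data, float(length), provenance=f"read from {path.name}")


def write_volume(v: Volume, path: str | Path) -> Path:
    """Write a volume to TIFF, NRRD or raw+JSON, inferred from the suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        _write_tiff(v, path)
    elif suffix == ".nrrd":
        _write_nrrd(v, path)
    elif suffix == ".raw":
        _write_raw(v, path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path


def _read_tiff(path: Path) -> tuple[np.ndarray, float | None]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        length: float | None = None
        ij = tif.imagej_metadata
        if ij is not None and "spacing" in ij:
            spacing = float(ij["spacing"])
            page = tif.pages[0]
            xy = _tiff_pixel_size(page)
            if xy is not None and not np.isclose(xy, spacing, rtol=_ISO_RTOL):
                raise ValueError(
                    f"{path.name}: anisotropic voxels (xy {xy} vs z {spacing})"
                )
            length = spacing
        else:
            length = _tiff_pixel_size(tif.pages[0])
    if data.ndim == 2:
        data = data[np.newaxis]
    return data, length


def _tiff_pixel_size(page) -> float | None:
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is None or yres is None:
        return None
    def as_len(tag):
        num, den = tag.value
        return den / num if num else None
    x, y = as_len(xres), as_len(yres)
    if x is None or y is None:
        return None
    if x == 1.0 and y == 1.0:
        return None  # the default 1:1 tags carry no physical calibration
    if not np.isclose(x, y, rtol=_ISO_RTOL):
        raise ValueError(f"anisotropic in-plane pixel size: {x} vs {y}")
    return float(x)


def _write_tiff(v: Volume, path: Path) -> None:
    data = v.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)  # ImageJ TIFF has no float64
    res = 1.0 / v.voxel_len_um
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(res, res),
        metadata={"spacing": v.voxel_len_um, "unit": "um", "axes": "ZYX"},
    )


# NRRD support is deliberately minimal: 3D, raw encoding, little endian.
_NRRD_TYPES = {
    "uint8": np.uint8, "uchar": np.uint8,
    "uint16": np.uint16, "unsigned short": np.uint16,
    "int16": np.int16, "short": np.int16,
    "int32": np.int32, "int": np.int32,
    "float": np.float32, "double": np.float64,
}
_NRRD_NAMES = {np.dtype(np.uint8): "uint8", np.dtype(np.uint16): "uint16",
               np.dtype(np.int16): "int16", np.dtype(np.int32): "int32",
               np.dtype(np.float32): "float", np.dtype(np.float64): "double"}


def _read_nrrd(path: Path) -> tuple[np.ndarray, float | None]:
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path.name} is not an NRRD file")
        header: dict[str, str] = {}
        while True:
            line = fh.readline().decode("ascii", "replace")
            if line in ("\n", "\r\n", ""):
                break
            line = line.strip()
            if line.startswith("#") or ":" not in line:
                continue
            key, _, value = line.partition(":")
            header[key.strip().lower()] = value.lstrip("=").strip()
        payload = fh.read()
    if header.get("encoding", "raw") != "raw":
        raise ValueError(f"{path.name}: only raw NRRD encoding is supported")
    if int(header.get("dimension", "3")) != 3:
        raise ValueError(f"{path.name}: only 3D NRRD volumes are supported")
    sizes = [int(t) for t in header["sizes"].split()]  # fastest axis first: x y z
    dtype = np.dtype(_NRRD_TYPES[header["type"]])
    if header.get("endian", "little") == "big":
        dtype = dtype.newbyteorder(">")
    data = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    data = data.reshape(sizes[::-1])  # (z, y, x)
    length: float | None = None
    if "spacings" in header:
        sp = [float(t) for t in header["spacings"].split()]
        if not np.allclose(sp, sp[0], rtol=_ISO_RTOL):
            raise ValueError(f"{path.name}: anisotropic NRRD spacings {sp}")
        length = sp[0]
    return np.ascontiguousarray(data), length


def _write_nrrd(v: Volume, path: Path) -> None:
    dtype = v.data.dtype
    if dtype not in _NRRD_NAMES:
        raise ValueError(f"unsupported dtype for NRRD: {dtype}")
    nz, ny, nx = v.data.shape
    s = v.voxel_len_um
    header = (
        "NRRD0004\n"
        f"type: {_NRRD_NAMES[np.dtype(dtype)]}\n"
        "dimension: 3\n"
        f"sizes: {nx} {ny} {nz}\n"
        f"spacings: {s:.10g} {s:.10g} {s:.10g}\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(v.data).astype(dtype, copy=False).tobytes())


def _read_raw(path: Path) -> tuple[np.ndarray, float | None]:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"raw volume {path.name} requires a JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    if meta.get("order", "zyx") != "zyx":
        raise ValueError(f"{sidecar.name}: only zyx axis order is supported")
    data = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "float32")))
    data = data.reshape(meta["shape"])
    return data, meta.get("voxel_len_um")


def _write_raw(v: Volume, path: Path) -> None:
    np.ascontiguousarray(v.data).tofile(path)
    meta = {
        "shape": list(v.data.shape),
        "voxel_len_um": v.voxel_len_um,
        "dtype": str(v.data.dtype),
        "order": "zyx",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def normalise(v: Volume, lo_pct: float = 0.1, hi_pct: float = 99.9) -> Volume:
    """Percentile-clip intensities and rescale to [0, 1].

    Mandatory entry step of the pipeline: the region-growing intensity
    tolerance (0.0385) is only meaningful on a fixed intensity scale.
    """
    if not lo_pct < hi_pct:
        raise ValueError(f"lo_pct must be < hi_pct, got {lo_pct} >= {hi_pct}")
    data = v.data.astype(np.float32, copy=False)
    lo, hi = np.percentile(data, [lo_pct, hi_pct])
    if hi <= lo:
        raise ValueError("volume has zero dynamic range between the given percentiles")
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return v.with_data(out, note=f"normalised to [0,1] at percentiles ({lo_pct}, {hi_pct})")


def crop(v: Volume, roi: RoiBox) -> Volume:
    """Extract an axis-aligned sub-volume; voxel length is unchanged."""
    roi.check_within(v.shape)
    out = v.data[roi.slices()].copy()
    return v.with_data(out, note=f"cropped to roi origin={roi.origin} shape={roi.shape}")


def bin_volume(v: Volume, factor: int) -> Volume:
    """Average non-overlapping ``factor³`` blocks.

    Trailing partial blocks are dropped (unbiased block means); the
    voxel length is multiplied by the factor.
    """
    if factor < 1 or factor != int(factor):
        raise ValueError(f"bin factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return v.with_data(v.data.copy())
    if any(n < factor for n in v.shape):
        raise ValueError(f"bin factor {factor} exceeds volume shape {v.shape}")
    nz, ny, nx = (n // factor for n in v.shape)
    d = v.data[: nz * factor, : ny * factor, : nx * factor].astype(np.float64)
    d = d.reshape(nz, factor, ny, factor, nx, factor).mean(axis=(1, 3, 5))
    out = Volume(d.astype(np.float32), v.voxel_len_um * factor,
                 provenance=f"{v.provenance}; binned x{factor}")
    return out
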