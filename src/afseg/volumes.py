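"""Image stacks, label volumes and intensity normalization.

Conventions used throughout the package: a volume is a ``(z, y, x)`` array
with slice index ``z`` starting at 0 at the first acquired plane, row index
``y`` increasing downward and column index ``x`` increasing rightward; all
pixel coordinates are 0-based.  Intensities are floating point after load and
lie in ``[0, 1]`` after :func:`normalize_intensity`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

#: Lateral pixel size (micrometres) assumed when a stack carries no metadata.
DEFAULT_PIXEL_SIZE_UM = 0.254
#: Perpendicular inter-plane distance (micrometres) assumed by default.
DEFAULT_SLICE_SPACING_UM = 1.0


@dataclass
class ImageVolume:
    """An ordered stack of 2-D grayscale slices with physical metadata.

    Parameters
    ----------
    data
        ``(n_slices, height, width)`` float array of intensities.
    pixel_size
        Lateral pixel size in micrometres per pixel.
    slice_spacing
        Distance between consecutive planes in micrometres.
    source_path
        Optional provenance string (where the stack was read from).
    """

    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    slice_spacing: float = DEFAULT_SLICE_SPACING_UM
    source_path: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"volume must be (z, y, x); got shape {arr.shape}")
        self.data = arr.astype(np.float64, copy=False)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer class assignment per pixel plus a code -> name table."""

    data: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"label volume must be (z, y, x); got shape {arr.shape}")
        if arr.size and arr.min() < 0:
            raise ValueError("label codes must be non-negative")
        self.data = arr.astype(np.int64, copy=False)

    def validate_names(self) -> None:
        """Raise if any label code present in the data lacks a name."""
        present = np.unique(self.data)
        missing = [int(c) for c in present if int(c) not in self.class_names]
        if missing:
            raise ValueError(f"label codes without a class name: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# sidecar metadata


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.txt")


def write_sidecar(path: Path, entries: dict[str, str]) -> Path:
    """Write plain ``key=value`` metadata next to an image file."""
    side = _sidecar_path(Path(path))
    lines = [f"{k}={v}" for k, v in entries.items()]
    side.write_text("\n".join(lines) + "\n")
    return side


def read_sidecar(path: Path) -> dict[str, str]:
    side = _sidecar_path(Path(path))
    if not side.exists():
        return {}
    out: dict[str, str] = {}
    for line in side.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


# ---------------------------------------------------------------------------
# intensity stacks


def read_stack(path: str | os.PathLike) -> ImageVolume:
    """Read a multi-page TIFF (or directory of per-slice TIFFs) as a volume.

    Integer pixel values are converted to float without rescaling.  A
    directory is read in lexical filename order.  Pixel size and slice
    spacing default to 0.254 um and 1 um when no sidecar metadata is found.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such stack: {p}")
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in {".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {p}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice shapes in {p}: {sorted(shapes)}")
        if slices[0].ndim != 2:
            raise ValueError("per-slice TIFFs must be single-page 2-D images")
        data = np.stack(slices)
        meta = read_sidecar(p / "stack.tif")
    else:
        data = tifffile.imread(p)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"unsupported TIFF layout with shape {data.shape}")
        meta = read_sidecar(p)
    if data.dtype.kind not in "uif":
        raise ValueError(f"unsupported sample format {data.dtype}")
    return ImageVolume(
        data=data.astype(np.float64),
        pixel_size=float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
        slice_spacing=float(meta.get("slice_spacing_um", DEFAULT_SLICE_SPACING_UM)),
        source_path=str(p),
    )


def write_stack(
    volume: ImageVolume,
    path: str | os.PathLike,
    dtype: str = "uint16",
    extra_meta: dict[str, str] | None = None,
) -> Path:
    """Write a volume as a multi-page TIFF with a plain-text sidecar.

    Float data in [0, 1] is scaled to the full integer range for ``uint8`` /
    ``uint16``; ``float32`` writes values untouched.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if dtype in ("uint8", "uint16"):
        maxval = np.iinfo(dtype).max
        out = np.clip(np.rint(data * maxval), 0, maxval).astype(dtype)
    elif dtype == "float32":
        out = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported output dtype {dtype!r}")
    tifffile.imwrite(p, out, photometric="minisblack")
    meta = {
        "pixel_size_um": repr(volume.pixel_size),
        "slice_spacing_um": repr(volume.slice_spacing),
        "dtype": dtype,
    }
    if extra_meta:
        meta.update(extra_meta)
    write_sidecar(p, meta)
    return p


def normalize_intensity(
    volume: ImageVolume, low_pct: float = 0.5, high_pct: float = 99.5
) -> ImageVolume:
    """Rescale intensities so given percentiles map to [0, 1], then clip.

    Percentiles are computed over the whole volume, not per slice, so that
    genuine depth attenuation remains visible after normalization.  Raises
    ``ValueError`` on a constant volume (zero dynamic range).
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low < high <= 100, got ({low_pct}, {high_pct})")
    lo, hi = np.percentile(volume.data, [low_pct, high_pct])
    if hi <= lo:
        raise ValueError(
            "degenerate intensity volume: percentile range is empty "
            f"(p{low_pct}={lo}, p{high_pct}={hi})"
        )
    scaled = np.clip((volume.data - lo) / (hi - lo), 0.0, 1.0)
    return replace(volume, data=scaled)


# ---------------------------------------------------------------------------
# label volumes


def write_label_volume(labels: LabelVolume, path: str | os.PathLike) -> Path:
    """Write labels as 8-bit multi-page TIFF with the name table in a sidecar."""
    labels.validate_names()
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if labels.data.max(initial=0) > 255:
        raise ValueError("label codes exceed 8-bit range")
    tifffile.imwrite(p, labels.data.astype(np.uint8), photometric="minisblack")
    meta = {f"class_{code}": name for code, name in sorted(labels.class_names.items())}
    write_sidecar(p, meta)
    return p


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such label volume: {p}")
    data = tifffile.imread(p)
    if data.ndim == 2:
        data = data[None]
    meta = read_sidecar(p)
    names = {
        int(k.removeprefix("class_")): v
        for k, v in meta.items()
        if k.startswith("class_")
    }
    vol = LabelVolume(data=data.astype(np.int64), class_names=names)
    vol.validate_names()
    return vol
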