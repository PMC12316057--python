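"""Gabor filter bank and per-pixel feature assembly.

The texture front-end of the segmentation pipeline: a bank of complex Gabor
kernels covering six wavelengths and four orientations (24 filters at the
defaults), whose per-pixel magnitude responses — Gaussian-smoothed for
spatial coherence — join the raw intensity and the pixel coordinates in a
z-scored per-pixel feature stack.

Orientation convention: a filter's ``orientation`` is the angle of its wave
normal in the image plane (x rightward, y downward), so a sinusoidal grating
whose intensity varies along direction theta maximally excites the filter
with ``orientation = theta`` and matching wavelength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.filters import gabor_kernel

DEFAULT_ORIENTATIONS: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
#: Shortest default wavelength, px/cycle; the series doubles from here.
BASE_WAVELENGTH = 4.0 / np.sqrt(2.0)
N_DEFAULT_WAVELENGTHS = 6


@dataclass(frozen=True)
class GaborParams:
    """One filter: wavelength (px/cycle), orientation (radians in [0, pi)),
    bandwidth (octaves) and carrier phase (radians)."""

    wavelength: float
    orientation: float
    bandwidth: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength < 2:
            raise ValueError(f"wavelength must be >= 2 px, got {self.wavelength}")
        object.__setattr__(self, "orientation", float(self.orientation) % np.pi)

    @property
    def name(self) -> str:
        deg = int(round(np.degrees(self.orientation)))
        return f"gabor_w{self.wavelength:.2f}_o{deg}"


@dataclass
class GaborBank:
    """Ordered filter list (wavelength-major, orientation-minor) + kernels."""

    filters: list[GaborParams]
    kernels: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.filters)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.filters]


def default_wavelengths(image_width: int, image_height: int | None = None) -> list[float]:
    """Octave series of up to six wavelengths, capped at image diagonal / 4.

    Wavelengths are ``4/sqrt(2) * 2**k`` for ``k = 0..5`` px/cycle; any value
    exceeding a quarter of the image diagonal is dropped from the top and a
    warning is recorded, since such coarse filters see essentially one period
    across the field of view.
    """
    if image_width < 16:
        raise ValueError(f"image too small for a Gabor bank: width {image_width} < 16")
    if image_height is None:
        image_height = image_width
    cap = float(np.hypot(image_width, image_height)) / 4.0
    candidates = [BASE_WAVELENGTH * 2**k for k in range(N_DEFAULT_WAVELENGTHS)]
    kept = [w for w in candidates if w <= cap * (1 + 1e-12)]
    if not kept:
        raise ValueError(
            f"image {image_width}x{image_height} too small for any default wavelength"
        )
    if len(kept) < N_DEFAULT_WAVELENGTHS:
        warnings.warn(
            f"only {len(kept)} of {N_DEFAULT_WAVELENGTHS} default wavelengths fit "
            f"an image of diagonal {4 * cap:.0f} px (cap {cap:.1f} px)",
            stacklevel=2,
        )
    return kept


def build_gabor_bank(
    wavelengths,
    orientations=DEFAULT_ORIENTATIONS,
    bandwidth: float = 1.0,
) -> GaborBank:
    """Build one complex kernel per (wavelength, orientation) pair.

    Each kernel's real part has its mean removed, so the bank is DC-free:
    constant images yield (numerically) zero magnitude response.
    """
    wavelengths = list(wavelengths)
    orientations = list(orientations)
    if not wavelengths or not orientations:
        raise ValueError("need at least one wavelength and one orientation")
    filters: list[GaborParams] = []
    kernels: list[np.ndarray] = []
    for lam in wavelengths:
        for theta in orientations:
            params = GaborParams(wavelength=lam, orientation=theta, bandwidth=bandwidth)
            k = gabor_kernel(
                frequency=1.0 / lam, theta=params.orientation, bandwidth=bandwidth
            ).astype(np.complex128)
            k = k - (k.real.mean() + 1j * k.imag.mean())
            filters.append(params)
            kernels.append(k)
    return GaborBank(filters=filters, kernels=kernels)


def _convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same' convolution with reflected boundaries, FFT-accelerated."""
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    # reflect padding cannot exceed image extent; tile reflections if needed
    padded = image
    ry, rx = ph, pw
    while ry > 0 or rx > 0:
        sy = min(ry, padded.shape[0] - 1)
        sx = min(rx, padded.shape[1] - 1)
        padded = np.pad(padded, ((sy, sy), (sx, sx)), mode="reflect")
        ry -= sy
        rx -= sx
    out = signal.fftconvolve(padded, kernel, mode="same")
    return out[ph : ph + image.shape[0], pw : pw + image.shape[1]]


def apply_gabor(slice2d: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Per-filter magnitude of the complex Gabor convolution.

    Returns an ``(n_filters, H, W)`` array; boundaries handled by reflection.
    """
    img = np.asarray(slice2d, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {img.shape}")
    out = np.empty((len(bank), *img.shape), dtype=np.float64)
    for i, kernel in enumerate(bank.kernels):
        out[i] = np.abs(_convolve_reflect(img, kernel))
    return out


def smooth_responses(
    responses: np.ndarray, bank: GaborBank, smoothing_factor: float = 0.5
) -> np.ndarray:
    """Gaussian-smooth each magnitude plane with SD = factor * its wavelength.

    Smoothing turns the oscillation-riddled raw magnitudes into locally
    averaged texture energy, which is what makes clusters spatially coherent;
    ``smoothing_factor = 0`` is the identity.
    """
    if smoothing_factor < 0:
        raise ValueError("smoothing_factor must be >= 0")
    if responses.shape[0] != len(bank):
        raise ValueError("responses do not match bank size")
    if smoothing_factor == 0:
        return responses.copy()
    out = np.empty_like(responses)
    for i, params in enumerate(bank.filters):
        sigma = smoothing_factor * params.wavelength
        out[i] = ndimage.gaussian_filter(responses[i], sigma=sigma, mode="reflect")
    return out


@dataclass
class FeatureStack:
    """Standardized per-pixel features for one slice.

    ``planes`` is ``(H, W, F)``; every non-constant plane is z-scored to mean
    0, SD 1 (constant planes are set to 0 and flagged), after which the two
    coordinate planes are multiplied by ``spatial_weight``.
    """

    planes: np.ndarray
    names: list[str]
    means: np.ndarray
    sds: np.ndarray
    constant: np.ndarray  # per-plane flag: plane had zero variance
    spatial_weight: float = 1.0
    spatial_indices: list[int] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.planes.shape[2]

    @property
    def appearance_indices(self) -> list[int]:
        """Indices of the non-spatial (intensity + texture) planes."""
        return [i for i in range(self.n_features) if i not in self.spatial_indices]

    def as_points(self) -> np.ndarray:
        """Flatten to ``(H*W, F)`` points for clustering."""
        h, w, f = self.planes.shape
        return self.planes.reshape(h * w, f)


def assemble_features(
    slice2d: np.ndarray,
    smoothed_responses: np.ndarray,
    bank: GaborBank,
    include_intensity: bool = True,
    include_spatial: bool = True,
    spatial_weight: float = 1.0,
) -> FeatureStack:
    """Stack intensity + texture + coordinate planes and z-score each one.

    Raises ``ValueError`` if every enabled plane is constant (nothing to
    cluster).
    """
    img = np.asarray(slice2d, dtype=np.float64)
    h, w = img.shape
    if smoothed_responses.shape[1:] != (h, w):
        raise ValueError("response planes do not match slice shape")
    planes: list[np.ndarray] = []
    names: list[str] = []
    if include_intensity:
        planes.append(img)
        names.append("intensity")
    planes.extend(smoothed_responses)
    names.extend(bank.names)
    spatial_indices: list[int] = []
    if include_spatial:
        y, x = np.mgrid[0:h, 0:w].astype(np.float64)
        spatial_indices = [len(planes), len(planes) + 1]
        planes.extend([x, y])
        names.extend(["coord_x", "coord_y"])

    stack = np.stack(planes, axis=-1)
    means = stack.reshape(-1, stack.shape[-1]).mean(axis=0)
    sds = stack.reshape(-1, stack.shape[-1]).std(axis=0)
    constant = sds == 0
    if constant.all():
        raise ValueError("all feature planes are constant; nothing to cluster")
    safe_sds = np.where(constant, 1.0, sds)
    z = (stack - means) / safe_sds
    z[..., constant] = 0.0
    for idx in spatial_indices:
        z[..., idx] *= spatial_weight
    return FeatureStack(
        planes=z,
        names=names,
        means=means,
        sds=sds,
        constant=constant,
        spatial_weight=spatial_weight,
        spatial_indices=spatial_indices,
    )


def compute_features(
    slice2d: np.ndarray,
    bank: GaborBank,
    smoothing_factor: float = 0.5,
    include_intensity: bool = True,
    include_spatial: bool = True,
    spatial_weight: float = 1.0,
) -> FeatureStack:
    """Convenience chain: apply_gabor -> smooth_responses -> assemble_features."""
    responses = apply_gabor(slice2d, bank)
    smoothed = smooth_responses(responses, bank, smoothing_factor)
    return assemble_features(
        slice2d,
        smoothed,
        bank,
        include_intensity=include_intensity,
        include_spatial=include_spatial,
        spatial_weight=spatial_weight,
    )
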