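"""Synthetic autofluorescence phantoms with known tissue labels.

The phantom emulates a cleared-muscle light-sheet field of view containing an
implanted ECM scaffold: four spatially contiguous tissue classes, each
separable by the features the segmentation stage uses —

* **muscle** (code 0): oriented periodic fiber texture (band-pass, so the
  Gabor bank sees it),
* **scaffold** (code 1): smooth low-frequency blobby texture,
* **interstitium** (code 2): thin dark seams between muscle fiber bundles and
  at the muscle-scaffold border,
* **vessel** (code 3): bright thin curvilinear tubes overlaid on either
  tissue, taking label precedence because a pixel carries one ground truth.

Intensity decays with depth by a per-slice contrast factor, and sCMOS-style
noise (Poisson photon statistics scaled by a gain, then additive Gaussian
read noise) is applied last.  Identical config + seed gives a bit-identical
phantom.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .volumes import ImageVolume, LabelVolume, write_label_volume, write_sidecar, write_stack

MUSCLE, SCAFFOLD, INTERSTITIUM, VESSEL = 0, 1, 2, 3
CLASS_NAMES: dict[int, str] = {
    MUSCLE: "muscle",
    SCAFFOLD: "scaffold",
    INTERSTITIUM: "interstitium",
    VESSEL: "vessel",
}


@dataclass
class MuscleParams:
    orientation: float = 0.35  # fiber axis, radians from the x axis
    period: float = 12.0  # fiber spacing, pixels
    contrast: float = 0.35
    squareness: float = 8.0  # striation edge sharpness; 0 = pure sinusoid


@dataclass
class ScaffoldParams:
    length_scale: float = 45.0  # blob correlation length, pixels
    contrast: float = 0.4


@dataclass
class InterstitiumParams:
    gap_width: int = 10  # seam thickness, pixels
    bundle_period: float = 80.0  # fiber-bundle spacing, pixels
    contrast: float = 0.9  # darkness: intensity = 0.5 * (1 - contrast)
    grain: float = 0.3  # fine collagen-speckle amplitude within the gaps


@dataclass
class VesselParams:
    count: int = 8
    radius: int = 6  # dilation radius, pixels (tube width 2r+1)
    brightness: float = 2.0  # multiplier on the 0.5 base level, >= 1
    grain: float = 0.0  # fine speckle amplitude inside the lumen


@dataclass
class NoiseParams:
    photon_gain: float = 200.0  # expected photons at intensity 1.0; 0 disables
    read_sd: float = 0.01  # additive Gaussian SD on the [0, 1] scale


@dataclass
class PhantomConfig:
    """Full description of a synthetic Z-stack; see module docstring."""

    width: int = 256
    height: int = 256
    n_slices: int = 5
    pixel_size: float = 0.254  # um per pixel
    slice_spacing: float = 1.0  # um between planes
    muscle: MuscleParams = field(default_factory=MuscleParams)
    scaffold: ScaffoldParams = field(default_factory=ScaffoldParams)
    interstitium: InterstitiumParams = field(default_factory=InterstitiumParams)
    vessel: VesselParams = field(default_factory=VesselParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    depth_attenuation: float = 0.98  # per-slice contrast decay, in (0, 1]
    scaffold_radius_frac: float = 0.30  # scaffold radius / min(height, width)
    scaffold_wobble: float = 0.10  # relative boundary perturbation
    seed: int = 0

    def validate(self) -> None:
        if min(self.width, self.height, self.n_slices) < 1:
            raise ValueError("width, height and n_slices must all be >= 1")
        for name, c in [
            ("muscle", self.muscle.contrast),
            ("scaffold", self.scaffold.contrast),
            ("interstitium", self.interstitium.contrast),
        ]:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{name} contrast must be in [0, 1], got {c}")
        if not 0.0 < self.depth_attenuation <= 1.0:
            raise ValueError("depth_attenuation must be in (0, 1]")
        if self.muscle.period < 2:
            raise ValueError("muscle fiber period must be >= 2 px")
        if self.vessel.count < 0:
            raise ValueError("vessel count must be >= 0")
        if self.vessel.brightness < 1.0:
            raise ValueError("vessel brightness multiplier must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Phantom:
    """Generated intensity volume plus its ground-truth label volume."""

    intensity: ImageVolume
    labels: LabelVolume
    config: PhantomConfig


# ---------------------------------------------------------------------------
# texture primitives


def generate_muscle_texture(
    shape: tuple[int, int],
    orientation: float,
    period: float,
    contrast: float,
    rng: np.random.Generator,
    squareness: float = 0.0,
) -> np.ndarray:
    """Oriented periodic fiber texture with mean 0.5 and amplitude contrast/2.

    ``orientation`` is the fiber axis; the intensity varies along the
    perpendicular, so the dominant spatial frequency is ``1/period`` along the
    wave normal ``orientation + pi/2``.  The phase is drawn from ``rng``.
    ``squareness > 0`` sharpens the sinusoid toward a square wave
    (``tanh(s*g)/tanh(s)``), adding the odd harmonics that real striations
    carry while preserving the fundamental, the mean and the amplitude.
    """
    if period < 2:
        raise ValueError(f"period must be >= 2 px (Nyquist), got {period}")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError(f"contrast must be in [0, 1], got {contrast}")
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    normal = orientation + np.pi / 2
    u = x * np.cos(normal) + y * np.sin(normal)
    phase = rng.uniform(0, 2 * np.pi)
    g = np.cos(2 * np.pi * u / period + phase)
    if squareness > 0:
        g = np.tanh(squareness * g) / np.tanh(squareness)
    return 0.5 + 0.5 * contrast * g


def generate_speckle(
    shape: tuple[int, int],
    amplitude: float,
    rng: np.random.Generator,
    correlation: float = 0.7,
) -> np.ndarray:
    """Zero-mean fine isotropic speckle with SD ``amplitude`` (clipped at 2 SD)."""
    if amplitude == 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return amplitude * np.clip(smooth, -2.0, 2.0)


def generate_scaffold_texture(
    shape: tuple[int, int],
    length_scale: float,
    contrast: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth blobby texture: Gaussian-filtered white noise around 0.5."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=length_scale, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / (3.0 * sd)  # ~99.7% of values within +/-1
    return 0.5 + 0.5 * contrast * np.clip(smooth, -1.0, 1.0)


def generate_vessel_mask(
    shape: tuple[int, int],
    n_vessels: int,
    radius: int,
    rng: np.random.Generator,
    return_centerlines: bool = False,
    start_mask: np.ndarray | None = None,
):
    """Union of ``n_vessels`` dilated random-walk centerlines.

    Each centerline is a persistent random walk (unit steps, slowly drifting
    heading) clipped to the image, dilated by a disk of the given radius.
    The connected-component count of the mask is at most ``n_vessels``.
    ``start_mask`` restricts walk starting points to a region (vascularization
    concentrates over the implant in the tissue this emulates); walks may
    still wander out of it.  When ``return_centerlines`` is true, also
    returns the list of per-vessel ``(n_steps, 2)`` integer centerline
    coordinates.
    """
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    centerlines: list[np.ndarray] = []
    walk_len = max(8, int(0.75 * min(h, w)))
    selem = disk(radius)
    starts = np.argwhere(start_mask) if start_mask is not None else None
    for _ in range(n_vessels):
        if starts is not None and len(starts):
            pos = starts[rng.integers(len(starts))].astype(np.float64)
        else:
            pos = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        heading = rng.uniform(0, 2 * np.pi)
        pts = np.empty((walk_len, 2), dtype=np.int64)
        for i in range(walk_len):
            heading += rng.normal(0.0, 0.15)
            pos += np.array([np.sin(heading), np.cos(heading)])
            # reflect at the borders so tubes do not slide along the frame
            for ax, bound in ((0, h - 1), (1, w - 1)):
                if pos[ax] < 0 or pos[ax] > bound:
                    pos[ax] = np.clip(2 * np.clip(pos[ax], 0, bound) - pos[ax], 0, bound)
                    heading = -heading if ax == 0 else np.pi - heading
            pts[i] = np.rint(pos)
        centerlines.append(pts)
        line = np.zeros(shape, dtype=bool)
        line[pts[:, 0], pts[:, 1]] = True
        mask |= ndimage.binary_dilation(line, structure=selem)
    if return_centerlines:
        return mask, centerlines
    return mask


# ---------------------------------------------------------------------------
# geometry


def _scaffold_mask(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Central blob-bounded scaffold region: a disk with a wobbly boundary."""
    h, w = config.height, config.width
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(y - cy, x - cx)
    theta = np.arctan2(y - cy, x - cx)
    r0 = config.scaffold_radius_frac * min(h, w)
    # low-order angular harmonics perturb the radius
    wobble = np.zeros_like(theta)
    for k in (2, 3, 5):
        amp = rng.normal(0.0, config.scaffold_wobble / 2)
        phase = rng.uniform(0, 2 * np.pi)
        wobble += amp * np.cos(k * theta + phase)
    return r <= r0 * (1.0 + wobble)


def _build_labels(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """One 2-D label map shared by all slices (geometry is depth-stationary)."""
    h, w = config.height, config.width
    labels = np.full((h, w), MUSCLE, dtype=np.int64)
    scaffold = _scaffold_mask(config, rng)
    labels[scaffold] = SCAFFOLD

    gap = config.interstitium.gap_width
    if gap > 0:
        # seams between muscle fiber bundles, parallel to the fiber axis
        y, x = np.mgrid[0:h, 0:w].astype(np.float64)
        normal = config.muscle.orientation + np.pi / 2
        u = x * np.cos(normal) + y * np.sin(normal)
        offset = rng.uniform(0, config.interstitium.bundle_period)
        seams = np.mod(u + offset, config.interstitium.bundle_period) < gap
        labels[seams & ~scaffold] = INTERSTITIUM
        # seam at the muscle-scaffold border (on the muscle side)
        border = ndimage.binary_dilation(scaffold, structure=disk(gap)) & ~scaffold
        labels[border] = INTERSTITIUM

    if config.vessel.count > 0:
        # vessels run through the muscle bed around the implant; starting
        # them outside the scaffold keeps the implant interior avascular
        outside = ~ndimage.binary_dilation(scaffold, structure=disk(3), iterations=8)
        vessels = generate_vessel_mask(
            (h, w),
            config.vessel.count,
            config.vessel.radius,
            rng,
            start_mask=outside,
        )
        labels[vessels] = VESSEL  # vessels take precedence
    return labels


# ---------------------------------------------------------------------------
# assembly


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Generate the intensity Z-stack and its ground-truth label volume."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w, nz = config.height, config.width, config.n_slices

    label2d = _build_labels(config, rng)
    labels = np.broadcast_to(label2d, (nz, h, w)).copy()

    interstitium_level = 0.5 * (1.0 - config.interstitium.contrast)
    vessel_level = min(1.0, 0.5 * config.vessel.brightness)

    intensity = np.empty((nz, h, w), dtype=np.float64)
    for z in range(nz):
        muscle_tex = generate_muscle_texture(
            (h, w),
            config.muscle.orientation,
            config.muscle.period,
            config.muscle.contrast,
            rng,
            squareness=config.muscle.squareness,
        )
        scaffold_tex = generate_scaffold_texture(
            (h, w), config.scaffold.length_scale, config.scaffold.contrast, rng
        )
        inter_tex = interstitium_level + generate_speckle(
            (h, w), config.interstitium.grain, rng
        )
        vessel_tex = vessel_level + generate_speckle((h, w), config.vessel.grain, rng)
        plane = np.where(label2d == SCAFFOLD, scaffold_tex, muscle_tex)
        inter_mask = label2d == INTERSTITIUM
        plane[inter_mask] = np.clip(inter_tex[inter_mask], 0.0, 1.0)
        ves_mask = label2d == VESSEL
        plane[ves_mask] = np.clip(vessel_tex[ves_mask], 0.0, 1.0)
        # depth-dependent contrast decay about the mid level
        plane = 0.5 + (plane - 0.5) * config.depth_attenuation**z
        intensity[z] = plane

    intensity = _apply_noise(intensity, config.noise, rng)

    vol = ImageVolume(
        data=intensity,
        pixel_size=config.pixel_size,
        slice_spacing=config.slice_spacing,
    )
    lab = LabelVolume(data=labels, class_names=dict(CLASS_NAMES))
    return Phantom(intensity=vol, labels=lab, config=config)


def _apply_noise(
    intensity: np.ndarray, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """Poisson photon noise (scaled by gain) then additive Gaussian read noise."""
    out = intensity
    if noise.photon_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.photon_gain) / noise.photon_gain
    if noise.read_sd > 0:
        out = out + rng.normal(0.0, noise.read_sd, size=out.shape)
    return out


def write_phantom(
    phantom: Phantom, out_dir: str | Path, dtype: str = "uint16"
) -> dict[str, Path]:
    """Write intensity + labels as multi-page TIFFs with sidecar metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # intensity may exceed [0, 1] after noise; clip for integer encoding
    inten = phantom.intensity
    data = np.clip(inten.data, 0.0, 1.0)
    inten_path = write_stack(
        ImageVolume(data, inten.pixel_size, inten.slice_spacing),
        out / "intensity.tif",
        dtype=dtype,
        extra_meta={"seed": str(phantom.config.seed)},
    )
    label_path = write_label_volume(phantom.labels, out / "labels.tif")
    cfg_lines = {f"config.{k}": repr(v) for k, v in phantom.config.to_dict().items()}
    write_sidecar(out / "phantom.tif", cfg_lines)
    return {"intensity": inten_path, "labels": label_path}
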