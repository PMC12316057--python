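"""End-to-end pipeline: simulate/load -> features -> segment -> evaluate.

One seeded, logged run produces a self-describing output directory:
normalized stack, harmonized label volume, per-slice K-means summaries,
Dice report against ground truth when available, and a JSON manifest of the
fully resolved configuration so a rerun reproduces every output
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import DiceReport, evaluate_images
from .gabor import build_gabor_bank, compute_features, default_wavelengths
from .kmeans import KMeansConfig, harmonize_volume, segment_slice
from .phantom import CLASS_NAMES, PhantomConfig, generate_phantom, write_phantom
from .volumes import (
    ImageVolume,
    LabelVolume,
    normalize_intensity,
    read_label_volume,
    read_stack,
    write_label_volume,
    write_stack,
)

log = logging.getLogger("afseg")


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage (and slice)."""


@dataclass
class PipelineConfig:
    """Everything a run needs; every field lands in the manifest."""

    # input: either a stack on disk or a phantom to simulate
    input_stack: str | None = None
    truth_labels: str | None = None
    phantom: PhantomConfig | None = None
    # normalization
    low_pct: float = 0.5
    high_pct: float = 99.5
    # features
    wavelengths: list[float] | None = None  # None -> default octave series
    orientations_deg: list[float] = field(default_factory=lambda: [0, 45, 90, 135])
    smoothing_factor: float = 0.5
    include_intensity: bool = True
    include_spatial: bool = True
    spatial_weight: float = 0.5
    # clustering
    kmeans: KMeansConfig = field(default_factory=KMeansConfig)
    class_names: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))
    # run control
    out_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"

    def resolved_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "phantom" in raw and raw["phantom"] is not None:
            ph = dict(raw["phantom"])
            for key, sub_cls in (
                ("muscle", "MuscleParams"),
                ("scaffold", "ScaffoldParams"),
                ("interstitium", "InterstitiumParams"),
                ("vessel", "VesselParams"),
                ("noise", "NoiseParams"),
            ):
                if key in ph and isinstance(ph[key], dict):
                    from . import phantom as phantom_mod

                    ph[key] = getattr(phantom_mod, sub_cls)(**ph[key])
            raw["phantom"] = PhantomConfig(**ph)
        if "kmeans" in raw and isinstance(raw["kmeans"], dict):
            raw["kmeans"] = KMeansConfig(**raw["kmeans"])
        if "class_names" in raw and isinstance(raw["class_names"], dict):
            raw["class_names"] = {int(k): v for k, v in raw["class_names"].items()}
        return cls(**raw)


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive independent stage seeds (< 2**31) from the global seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setLevel(config.log_level)
    log.addHandler(fh)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    kmeans_seed = _stage_seeds(config.seed, 1)[0]

    # --- stage: input -----------------------------------------------------
    # The phantom keeps its own seed: a simulated input is a fixed dataset,
    # reproducible independently of the clustering seed.
    truth: LabelVolume | None = None
    try:
        if config.phantom is not None:
            ph_cfg = config.phantom
            log.info("simulating phantom %dx%dx%d (seed %d)",
                     ph_cfg.n_slices, ph_cfg.height, ph_cfg.width, ph_cfg.seed)
            ph = generate_phantom(ph_cfg)
            write_phantom(ph, out / "phantom")
            volume, truth = ph.intensity, ph.labels
        elif config.input_stack is not None:
            log.info("reading stack %s", config.input_stack)
            volume = read_stack(config.input_stack)
            if config.truth_labels:
                truth = read_label_volume(config.truth_labels)
        else:
            raise ValueError("config needs either input_stack or phantom")
    except Exception as e:
        raise StageError(f"input stage failed: {e}") from e

    # --- stage: normalization --------------------------------------------
    try:
        volume = normalize_intensity(volume, config.low_pct, config.high_pct)
        write_stack(volume, out / "normalized.tif", dtype="uint16")
    except Exception as e:
        raise StageError(f"normalization stage failed: {e}") from e

    # --- stage: features + segmentation per slice -------------------------
    nz, h, w = volume.shape
    wavelengths = config.wavelengths or default_wavelengths(w, h)
    bank = build_gabor_bank(wavelengths, np.deg2rad(config.orientations_deg))
    log.info("Gabor bank: %d filters (%d wavelengths x %d orientations)",
             len(bank), len(wavelengths), len(config.orientations_deg))
    km_cfg = dataclasses.replace(config.kmeans, seed=kmeans_seed)
    per_slice = []
    rows = []
    appearance_indices: list[int] | None = None
    for z in range(nz):
        try:
            feats = compute_features(
                volume.data[z],
                bank,
                smoothing_factor=config.smoothing_factor,
                include_intensity=config.include_intensity,
                include_spatial=config.include_spatial,
                spatial_weight=config.spatial_weight,
            )
            appearance_indices = feats.appearance_indices
            label_map, result = segment_slice(feats, km_cfg)
        except Exception as e:
            raise StageError(f"segmentation stage failed at slice {z}: {e}") from e
        per_slice.append((label_map, result))
        rows.append(
            {
                "slice": z,
                "objective": result.objective,
                "n_iter": result.n_iter,
                **{f"restart_{i}": o for i, o in enumerate(result.restart_objectives)},
            }
        )
        log.info("slice %d: objective %.4g after %d iterations", z,
                 result.objective, result.n_iter)
    pd.DataFrame(rows).to_csv(out / "kmeans_per_slice.csv", index=False)

    # --- stage: harmonization ---------------------------------------------
    try:
        labels = harmonize_volume(
            per_slice,
            appearance_indices=appearance_indices,
            class_names={k: f"cluster_{k}" for k in range(km_cfg.K)},
        )
        write_label_volume(labels, out / "labels.tif")
    except Exception as e:
        raise StageError(f"harmonization stage failed: {e}") from e

    # --- stage: evaluation -------------------------------------------------
    report: DiceReport | None = None
    if truth is not None:
        try:
            pairs = [(labels.data[z], truth.data[z]) for z in range(nz)]
            report = evaluate_images(pairs, km_cfg.K, config.class_names)
            report.to_csv(out / "dice_per_image.csv", out / "dice_summary.csv")
            report.plot_summary(out / "dice_summary.png")
            for name, m in report.per_class_mean.items():
                log.info("class %-13s mean Dice %.3f (SD %.3f)",
                         name, m, report.per_class_sd[name])
        except Exception as e:
            raise StageError(f"evaluation stage failed: {e}") from e

    manifest = {"config": config.resolved_dict(), "stage_seeds": {
        "kmeans": kmeans_seed}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("run complete: %s", out)
    return out
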