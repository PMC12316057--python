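"""Segmentation validation: cluster-to-class matching and Dice coefficients.

K-means cluster indices are arbitrary, so before scoring, each image's
clusters are matched one-to-one to the ground-truth classes by the
assignment that maximizes the summed Dice overlap (optimal bipartite
assignment on the K x K Dice matrix; a greedy mode exists for comparison).
Per-class Dice values are then aggregated as mean and sample SD (n-1
denominator) over the image set.

Dice of two masks A, B is ``2|A ∩ B| / (|A| + |B|)``.  When both masks are
empty the value is defined as 1 — perfect agreement on the absence of a
class — and the report flags every image/class where this was triggered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|); two empty masks give 1.0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class ClassMapping:
    """One-to-one table from cluster index to ground-truth class code."""

    cluster_to_class: dict[int, int]
    total_overlap: float  # summed Dice over the matched pairs

    def apply(self, pred: np.ndarray) -> np.ndarray:
        """Relabel a prediction map with ground-truth class codes."""
        lut = np.empty(max(self.cluster_to_class) + 1, dtype=np.int64)
        for c, t in self.cluster_to_class.items():
            lut[c] = t
        return lut[pred]


def dice_matrix(pred: np.ndarray, truth: np.ndarray, K: int) -> np.ndarray:
    """K x K matrix of Dice(pred cluster i, truth class j)."""
    out = np.empty((K, K), dtype=np.float64)
    for i in range(K):
        pi = pred == i
        for j in range(K):
            out[i, j] = dice(pi, truth == j)
    return out


def match_clusters_to_classes(
    pred: np.ndarray, truth: np.ndarray, K: int, method: str = "optimal"
) -> ClassMapping:
    """Best one-to-one cluster -> class assignment by summed Dice.

    ``method="optimal"`` solves the bipartite assignment exactly;
    ``method="greedy"`` repeatedly takes the largest remaining Dice entry
    (provided for comparison only).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shapes differ: {pred.shape} vs {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        vals = np.unique(arr)
        if vals.size and (vals.min() < 0 or vals.max() >= K):
            raise ValueError(f"{name} uses labels outside [0, {K})")
    D = dice_matrix(pred, truth, K)
    if method == "optimal":
        rows, cols = linear_sum_assignment(-D)
        mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    elif method == "greedy":
        mapping = {}
        M = D.copy()
        for _ in range(K):
            r, c = np.unravel_index(np.argmax(M), M.shape)
            mapping[int(r)] = int(c)
            M[r, :] = -1
            M[:, c] = -1
    else:
        raise ValueError(f"unknown matching method {method!r}")
    total = float(sum(D[r, c] for r, c in mapping.items()))
    return ClassMapping(cluster_to_class=mapping, total_overlap=total)


@dataclass
class DiceReport:
    """Per-image, per-class Dice plus mean/SD aggregation over the set."""

    per_image: pd.DataFrame  # columns: image_id, class, dice
    per_class_mean: dict[str, float]
    per_class_sd: dict[str, float]
    n_images: int
    flags: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        classes = list(self.per_class_mean)
        return pd.DataFrame(
            {
                "class": classes,
                "mean": [self.per_class_mean[c] for c in classes],
                "sd": [self.per_class_sd[c] for c in classes],
                "n": self.n_images,
            }
        )

    def to_csv(self, per_image_path: str | Path, summary_path: str | Path) -> None:
        self.per_image.to_csv(per_image_path, index=False)
        self.summary_frame().to_csv(summary_path, index=False)

    def plot_summary(self, path: str | Path) -> None:
        """Bar plot of mean Dice per class with SD error bars."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.summary_frame()
        fig, ax = plt.subplots(figsize=(5, 4))
        colors = {
            "muscle": "tab:red",
            "scaffold": "tab:green",
            "interstitium": "tab:blue",
            "vessel": "gold",
        }
        bar_colors = [colors.get(c, "tab:gray") for c in frame["class"]]
        ax.bar(frame["class"], frame["mean"], yerr=frame["sd"], capsize=4, color=bar_colors)
        ax.set_ylabel("Dice coefficient")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"Per-class Dice (mean ± SD, n={self.n_images})")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def evaluate_images(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    K: int,
    class_names: dict[int, str],
    matching: str = "optimal",
) -> DiceReport:
    """Match clusters to classes per image, score per-class Dice, aggregate.

    ``pairs`` holds ``(predicted label map, ground-truth label map)`` per
    image.  SD uses the n-1 denominator; with a single image the SD is
    reported as 0 and flagged.
    """
    if not pairs:
        raise ValueError("no image pairs to evaluate")
    rows = []
    flags: list[str] = []
    for img_id, (pred, truth) in enumerate(pairs):
        mapping = match_clusters_to_classes(pred, truth, K, method=matching)
        mapped = mapping.apply(pred)
        for code in range(K):
            name = class_names.get(code, str(code))
            pm = mapped == code
            tm = truth == code
            if not pm.any() and not tm.any():
                flags.append(f"image {img_id}, class {name}: empty/empty Dice=1")
            rows.append({"image_id": img_id, "class": name, "dice": dice(pm, tm)})
    frame = pd.DataFrame(rows)
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    n_images = len(pairs)
    for code in range(K):
        name = class_names.get(code, str(code))
        vals = frame.loc[frame["class"] == name, "dice"].to_numpy()
        means[name] = float(vals.mean())
        if n_images == 1:
            sds[name] = 0.0
        else:
            sds[name] = float(vals.std(ddof=1))
    if n_images == 1:
        flags.append("single image: SD undefined, reported as 0")
    return DiceReport(
        per_image=frame,
        per_class_mean=means,
        per_class_sd=sds,
        n_images=n_images,
        flags=flags,
    )
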