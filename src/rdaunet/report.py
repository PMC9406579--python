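"""Figure rendering: learning curves, per-case metric bars, overlay panels.

All rendering is best-effort (matplotlib Agg backend) and returns the list
of files written.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import MetricsReport
from .model import TrainingHistory
from .preprocessing import overlay_contour

__all__ = ["plot_learning_curves", "plot_case_metrics", "render_overlay_panel", "render_report"]


def plot_learning_curves(history: TrainingHistory, out_path: str | Path) -> Path:
    """Loss and pixel-accuracy vs epoch for training and validation."""
    out_path = Path(out_path)
    epochs = np.arange(1, len(history) + 1)
    fig, (ax_l, ax_a) = plt.subplots(1, 2, figsize=(10, 4))
    ax_l.plot(epochs, history.train_loss, label="train")
    ax_l.plot(epochs, history.val_loss, label="validation")
    ax_l.set(xlabel="epoch", ylabel="loss", title="Loss")
    ax_l.legend()
    ax_a.plot(epochs, history.train_acc, label="train")
    ax_a.plot(epochs, history.val_acc, label="validation")
    ax_a.set(xlabel="epoch", ylabel="pixel accuracy", title="Accuracy")
    ax_a.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def plot_case_metrics(
    cases: list[tuple[str, MetricsReport]], out_path: str | Path
) -> Path:
    """Grouped bars of ACC/DSC/IoU per case (one group per case)."""
    out_path = Path(out_path)
    names = [cid for cid, _ in cases]
    keys = ("acc", "dsc", "iou")
    width = 0.25
    xs = np.arange(len(names))
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(names)), 4))
    for i, key in enumerate(keys):
        vals = [getattr(r, key) for _, r in cases]
        ax.bar(xs + (i - 1) * width, vals, width, label=key.upper())
    ax.set_xticks(xs)
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def render_overlay_panel(
    image01: np.ndarray,
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    out_path: str | Path,
) -> Path:
    """Four panels: original | ground truth | prediction | superposition.

    The superposition draws the ground-truth contour in white and the
    predicted contour in red on the original image.
    """
    out_path = Path(out_path)
    both = overlay_contour(image01, gt_mask, color=(1.0, 1.0, 1.0))
    both = overlay_contour_rgb(both, pred_mask, color=(1.0, 0.0, 0.0))
    panels = [
        (image01, "original", "gray"),
        (gt_mask, "ground truth", "gray"),
        (pred_mask, "prediction", "gray"),
        (both, "superposition", None),
    ]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.8))
    for ax, (img, title, cmap) in zip(axes, panels):
        ax.imshow(img, cmap=cmap, vmin=0, vmax=1)
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def overlay_contour_rgb(rgb: np.ndarray, mask: np.ndarray, color) -> np.ndarray:
    from .preprocessing import boundary_pixels

    out = np.asarray(rgb, dtype=np.float64).copy()
    out[boundary_pixels(mask)] = np.asarray(color, dtype=np.float64)
    return out


def render_report(
    history: TrainingHistory,
    cases: list[tuple[str, MetricsReport]],
    overlays: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]],
    out_dir: str | Path,
) -> list[Path]:
    """Write the full figure set; ``overlays`` holds (id, image01, gt, pred)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = [
        plot_learning_curves(history, out_dir / "learning_curves.png"),
        plot_case_metrics(cases, out_dir / "case_metrics.png"),
    ]
    for cid, img, gt, pred in overlays:
        written.append(render_overlay_panel(img, gt, pred, out_dir / f"overlay_{cid}.png"))
    return written
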