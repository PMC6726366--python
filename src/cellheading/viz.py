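"""Overlay and figure writers for predictions and attribution maps."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .attribution import RelevanceMap, SaliencyMap
from .tracking import Trajectory

# direction -> RGB, matching the overlay-movie legend:
# red upper right, blue upper left, green lower left, yellow lower right
DIRECTION_COLORS: dict[int, tuple[float, float, float]] = {
    0: (1.0, 0.0, 0.0),
    1: (0.0, 0.3, 1.0),
    2: (0.0, 0.8, 0.0),
    3: (1.0, 0.9, 0.0),
}


def _draw_box(rgb: np.ndarray, cx: int, cy: int, half: int,
              color: tuple[float, float, float], thickness: int = 2) -> None:
    h, w, _ = rgb.shape
    y0, y1 = max(0, cy - half), min(h - 1, cy + half)
    x0, x1 = max(0, cx - half), min(w - 1, cx + half)
    c = np.asarray(color, dtype=rgb.dtype)
    rgb[y0:y0 + thickness, x0:x1 + 1] = c
    rgb[max(0, y1 - thickness + 1):y1 + 1, x0:x1 + 1] = c
    rgb[y0:y1 + 1, x0:x0 + thickness] = c
    rgb[y0:y1 + 1, max(0, x1 - thickness + 1):x1 + 1] = c


def overlay_predictions(
    movie: np.ndarray,
    trajs: Sequence[Trajectory],
    predictions: Mapping[tuple[int, int], int],
    box_px: int,
) -> np.ndarray:
    """Direction-colored patch boxes drawn on each frame.

    ``predictions`` maps (cell_id, frame) to a direction label; the box
    side is the patch crop size.  Returns an RGB float32 stack.
    """
    rgb = np.repeat(movie[..., None], 3, axis=-1).astype(np.float32)
    by_id = {tr.cell_id: tr for tr in trajs}
    for (cell_id, frame), label in predictions.items():
        tr = by_id[cell_id]
        x_um, y_um = tr.position(frame)
        _draw_box(
            rgb[frame],
            int(round(x_um / tr.pixel_size_um)),
            int(round(y_um / tr.pixel_size_um)),
            box_px // 2,
            DIRECTION_COLORS[int(label)],
        )
    return np.clip(rgb, 0.0, 1.0)


def attribution_figure(
    patch: np.ndarray,
    gbp_maps: Sequence[SaliencyMap],
    relevance: RelevanceMap,
    path: str | Path,
) -> None:
    """Composite panel: input patch, top GBP maps, DTD heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = 2 + len(gbp_maps)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3.2))
    axes[0].imshow(patch, cmap="gray", vmin=0, vmax=1)
    axes[0].set_title("input")
    for i, sm in enumerate(gbp_maps):
        v = np.abs(sm.values).max() or 1.0
        axes[1 + i].imshow(sm.values, cmap="gray", vmin=-v, vmax=v)
        axes[1 + i].set_title(f"GBP map {sm.target.feature_map}")
    axes[-1].imshow(relevance.values, cmap="hot")
    axes[-1].set_title(f"DTD (class {relevance.class_index})")
    for ax in axes:
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
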