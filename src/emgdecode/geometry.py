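"""Backtracking FC weights into electrode-grid topography ("geometry plots").

Each FC row W_i (192 weights for joint i) splits into six consecutive
32-long blocks, one per feature map, each aligned with the 32 electrode
channels. Summing the six blocks elementwise gives one signed weight per
channel: how strongly (and with what sign) that electrode's envelope drives
the joint's predicted angle. The 32-vector is normalized to [-1, 1] by its
own absolute maximum and arranged on the two 4 x 4 sleeve faces (flexor
panel left, extensor panel right) with a diverging blue-white-red colormap:
red regions push the joint toward its positive motions (WF, P, HG), blue
toward the negative ones (WE, S, HO).

"Superposition" of the six blocks defaults to a *gain-aligned* sum: each
block is multiplied by the sign of its filter's effective gain (the sum of
the filter's 60 taps, i.e. the feature's response to a uniform rise of the
channel envelope) before summing. A filter with negative gain responds to
muscle activity by *decreasing*, and the FC layer compensates with
negative weights; a plain sum of blocks lets these contributions cancel,
while the aligned sum reads every block in input space, so "positive map
value" always means "envelope rise pushes the joint positive". Plain sum,
mean and abs-sum are exposed for exploration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import List, Optional, Sequence  # noqa: F401

import numpy as np

from .containers import JOINT_NAMES
from .errors import ShapeError
from .layout import DEFAULT_LAYOUT, N_CHANNELS, ChannelLayout
from .model import ModelParams


@dataclass
class GeometryMap:
    """Per-joint signed weight topography on the two sleeve faces."""

    joint: str
    values: np.ndarray  # (32,) normalized to [-1, 1], index = channel_id - 1
    flexor_panel: np.ndarray  # (4, 4)
    extensor_panel: np.ndarray  # (4, 4)
    layout: ChannelLayout = DEFAULT_LAYOUT


def backtrack_fc_weights(
    w_row: np.ndarray, mode: str = "sum", filter_gains: Optional[np.ndarray] = None
) -> np.ndarray:
    """Collapse a 192-weight FC row to one signed value per channel.

    Splits the row into six consecutive 32-long blocks (the flatten order of
    the feature maps) and superposes them elementwise. Mode ``gain_sum``
    aligns each block by the sign of its filter's effective gain
    (``filter_gains``, typically the per-filter tap sums) before summing.
    """
    w = np.asarray(w_row, dtype=float).ravel()
    if w.size % N_CHANNELS != 0:
        raise ShapeError(f"FC row length {w.size} is not a multiple of {N_CHANNELS}")
    blocks = w.reshape(-1, N_CHANNELS)
    if mode == "sum":
        return blocks.sum(axis=0)
    if mode == "mean":
        return blocks.mean(axis=0)
    if mode == "abs_sum":
        return np.abs(blocks).sum(axis=0)
    if mode == "gain_sum":
        if filter_gains is None:
            raise ValueError("gain_sum mode requires filter_gains")
        gains = np.asarray(filter_gains, dtype=float)
        if gains.shape != (blocks.shape[0],):
            raise ShapeError(
                f"filter_gains must have length {blocks.shape[0]}, got {gains.shape}"
            )
        return (np.sign(gains)[:, None] * blocks).sum(axis=0)
    raise ValueError(f"unknown superposition mode {mode!r}")


def normalize_map(v: np.ndarray) -> np.ndarray:
    """Scale by the absolute maximum so values span [-1, 1]; zeros stay zero."""
    v = np.asarray(v, dtype=float)
    peak = np.abs(v).max()
    if peak == 0:
        return np.zeros_like(v)
    return v / peak


def arrange_panels(
    v: np.ndarray, layout: ChannelLayout = DEFAULT_LAYOUT, joint: str = ""
) -> GeometryMap:
    """Place a 32-vector of channel values onto the two 4 x 4 faces."""
    v = np.asarray(v, dtype=float)
    if v.shape != (N_CHANNELS,):
        raise ShapeError(f"expected a 32-vector, got shape {v.shape}")
    panels = {"flexor": np.empty((4, 4)), "extensor": np.empty((4, 4))}
    for ch in range(1, N_CHANNELS + 1):
        side, r, c = layout.position(ch)
        panels[side][r, c] = v[ch - 1]
    return GeometryMap(
        joint=joint,
        values=v,
        flexor_panel=panels["flexor"],
        extensor_panel=panels["extensor"],
        layout=layout,
    )


def panels_to_channels(gmap: GeometryMap) -> np.ndarray:
    """Inverse of :func:`arrange_panels`; lossless by bijectivity."""
    v = np.empty(N_CHANNELS)
    for side, panel in (("flexor", gmap.flexor_panel), ("extensor", gmap.extensor_panel)):
        grid = gmap.layout.grid(side)
        for r in range(4):
            for c in range(4):
                v[grid[r, c] - 1] = panel[r, c]
    return v


def geometry_maps_from_model(
    params: ModelParams,
    layout: ChannelLayout = DEFAULT_LAYOUT,
    mode: str = "gain_sum",
    joint_names: Sequence[str] = JOINT_NAMES,
) -> List[GeometryMap]:
    """One normalized GeometryMap per joint from a trained model's FC rows."""
    gains = params.conv_filters.sum(axis=1) if mode == "gain_sum" else None
    maps = []
    for i, name in enumerate(joint_names):
        v = normalize_map(
            backtrack_fc_weights(params.fc_weights[i], mode=mode, filter_gains=gains)
        )
        maps.append(arrange_panels(v, layout, joint=name))
    return maps


def top_channels(gmap: GeometryMap, n: int) -> set:
    """The n channels with largest absolute map value (1-based ids)."""
    order = np.argsort(-np.abs(gmap.values))
    return {int(i) + 1 for i in order[:n]}


def render_geometry_plot(maps: Sequence[GeometryMap], path, annotate: bool = True) -> None:
    """Render per-joint panel pairs to an image file.

    One row per joint, flexor panel left and extensor right, diverging
    blue-white-red colormap fixed to [-1, 1] with a shared colorbar.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(maps)
    if not 1 <= n <= 3:
        raise ValueError(f"expected 1-3 maps, got {n}")
    fig, axes = plt.subplots(n, 2, figsize=(6.5, 2.6 * n), squeeze=False)
    im = None
    for i, gmap in enumerate(maps):
        for j, (side, panel) in enumerate(
            (("flexor", gmap.flexor_panel), ("extensor", gmap.extensor_panel))
        ):
            ax = axes[i][j]
            im = ax.imshow(panel, cmap="bwr", vmin=-1.0, vmax=1.0)
            ax.set_title(f"{gmap.joint} — {side}")
            ax.set_xticks([])
            ax.set_yticks([])
            if annotate:
                grid = gmap.layout.grid(side)
                for r in range(4):
                    for c in range(4):
                        ax.text(c, r, str(grid[r, c]), ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=[a for row in axes for a in row], label="normalized weight")
    fig.savefig(path)
    plt.close(fig)


def export_geometry_csv(maps: Sequence[GeometryMap], path) -> None:
    """CSV export: channel_id, side, row, col, one value column per joint."""
    layout = maps[0].layout
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel_id", "side", "row", "col"] + [m.joint for m in maps])
        for ch in range(1, N_CHANNELS + 1):
            side, r, c = layout.position(ch)
            writer.writerow([ch, side, r, c] + [f"{m.values[ch - 1]:.8g}" for m in maps])
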