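"""Grad-CAM saliency maps for the dual-stream 3D CNN.

The heat-map is computed at the concatenate layer (the merge of the two
stream outputs): per-channel weights are the spatial average of the gradient
of the scalar loss with respect to the layer's activations; the map is the
rectified channel-weighted activation sum, trilinearly upsampled to the input
shape and max-normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import BinaryMask
from .nn.layers import DT
from .nn.network import CONCAT_LAYER, TMaskCNN, _sigmoid

__all__ = ["HeatMap", "grad_cam", "heat_region_contrast"]


@dataclass(frozen=True)
class HeatMap:
    """Non-negative saliency values in [0, 1] on the input grid."""

    grid: np.ndarray
    layer_name: str
    subject_id: str = ""

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=np.float64)
        if (g < 0).any() or g.max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("heat values must lie in [0, 1]")
        object.__setattr__(self, "grid", g)


def grad_cam(
    model: TMaskCNN,
    volume: np.ndarray,
    layer_name: str = CONCAT_LAYER,
    label: int | None = None,
    target: str = "loss",
    subject_id: str = "",
    upsampling: str = "trilinear",
) -> HeatMap:
    """Grad-CAM for a single 3D volume at the concatenate layer.

    ``target='loss'`` differentiates the cross-entropy at the (predicted or
    given) label; ``target='logit'`` differentiates the raw logit.  The model
    runs in inference mode, so repeated calls are deterministic.
    """
    if layer_name != CONCAT_LAYER:
        raise ValueError(
            f"unknown layer {layer_name!r}: saliency is exposed at {CONCAT_LAYER!r}"
        )
    if target not in ("loss", "logit"):
        raise ValueError("target must be 'loss' or 'logit'")
    if upsampling not in ("trilinear", "nearest"):
        raise ValueError("upsampling must be 'trilinear' or 'nearest'")

    x = np.asarray(volume, dtype=DT)
    if x.ndim == 3:
        x = x[None, None]
    elif x.ndim != 5 or x.shape[0] != 1:
        raise ValueError("volume must be a single 3D grid")

    logit = model.forward(x, training=False)
    p = _sigmoid(logit)
    if target == "logit":
        dlogit = np.ones(1, dtype=DT)
    else:
        y = float(label) if label is not None else float(p[0] > 0.5)
        dlogit = (p - y).astype(DT)  # d BCE / d logit
    model.backward(dlogit)

    acts = model.concat_activation[0]  # (C, d, h, w)
    grads = model.concat_gradient[0]
    weights = grads.mean(axis=(1, 2, 3))  # spatial average per channel
    cam = np.maximum((weights[:, None, None, None] * acts).sum(axis=0), 0.0)

    in_shape = x.shape[2:]
    zoom = [s / c for s, c in zip(in_shape, cam.shape)]
    order = 1 if upsampling == "trilinear" else 0
    up = ndimage.zoom(cam.astype(np.float64), zoom, order=order, mode="nearest")
    # zoom can over/undershoot the target shape by one voxel; crop/pad
    up = _fit_shape(up, in_shape)
    m = up.max()
    if m > 0:
        up = up / m
    up = np.clip(up, 0.0, 1.0)
    return HeatMap(grid=up, layer_name=layer_name, subject_id=subject_id)


def _fit_shape(arr: np.ndarray, shape) -> np.ndarray:
    out = arr[tuple(slice(0, s) for s in shape)]
    pads = [(0, s - o) for s, o in zip(shape, out.shape)]
    if any(p[1] for p in pads):
        out = np.pad(out, pads, mode="edge")
    return out


def heat_region_contrast(heat: HeatMap, region: BinaryMask) -> float:
    """(mean heat inside region) / (mean heat outside region); > 1 indicates
    focalization on the region.  All-outside-zero heat returns +inf."""
    sel = region.astype_bool()
    if heat.grid.shape != sel.shape:
        raise ValueError("heat map and region shapes differ")
    if not sel.any() or sel.all():
        raise ValueError("degenerate region: must be non-empty and not full")
    inside = heat.grid[sel].mean()
    outside = heat.grid[~sel].mean()
    if outside == 0:
        return float("inf") if inside > 0 else 1.0
    return float(inside / outside)
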