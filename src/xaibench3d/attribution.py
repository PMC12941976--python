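"""Post hoc attribution methods and intrinsic attention extraction.

Four post hoc methods — input-gradient saliency, integrated gradients,
sliding-window / point-cluster occlusion, and Grad-CAM with modality-specific
upsampling — plus extraction of a model's built-in attention masks.  Every
method returns a min-max normalized :class:`AttributionMap` aligned to its
sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .core import (
    AttributionMap,
    BaselineSpec,
    ConfigurationError,
    ModelAdapter,
    NumericalError,
    Sample3D,
    UnsupportedMethodError,
    ValidationError,
    normalize_attribution,
    resample_volume,
)


@dataclass
class GradCamConfig:
    """Target layer for Grad-CAM: the last 3D conv for grid models, the
    second set-abstraction level for point models."""

    layer_name: str = "conv1"
    upsample: str = "trilinear"  # "trilinear" grids | "nearest_neighbor_points"


@dataclass
class IGConfig:
    baseline: BaselineSpec = field(default_factory=lambda: BaselineSpec("zero"))
    n_steps: int = 50

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")


@dataclass
class OcclusionConfig:
    """Occlusion windows: integer triple for grids (voxel default (4,4,4),
    volumetric default dims/8), contiguous clusters of ``cluster_size``
    points for clouds.  ``stride`` defaults to the window (non-overlapping
    tiling); overlapping coverage is averaged per element."""

    window: tuple | None = None
    stride: tuple | None = None
    cluster_size: int = 10
    baseline: BaselineSpec | None = None

    def resolved_window(self, shape: tuple) -> tuple:
        if self.window is not None:
            w = tuple(int(v) for v in self.window)
        elif max(shape) <= 32:
            w = (4, 4, 4)
        else:
            w = tuple(max(1, s // 8) for s in shape)
        if any(wi < 1 or wi > si for wi, si in zip(w, shape)):
            raise ValidationError(f"occlusion window {w} invalid for grid {shape}")
        return w


def saliency(adapter: ModelAdapter, sample: Sample3D) -> AttributionMap:
    """Gradient-magnitude saliency for the predicted class.

    Grids take the absolute input gradient per voxel; point clouds take the
    per-point L2 norm across the three coordinate channels.
    """
    cls = sample.predicted_label if sample.predicted_label is not None else sample.true_label
    grad = np.asarray(adapter.gradient(sample.data, cls), dtype=float)
    if grad.shape != sample.data.shape:
        raise ValidationError(
            f"adapter gradient shape {grad.shape} != input shape {sample.data.shape}"
        )
    if sample.modality == "pointcloud":
        raw = np.linalg.norm(grad, axis=1)
    else:
        raw = np.abs(grad)
    if not raw.any():
        warnings.warn("all-zero gradient: saliency map is identically zero", stacklevel=2)
    return AttributionMap(normalize_attribution(raw), method="saliency", normalized=True)


def integrated_gradients(
    adapter: ModelAdapter, sample: Sample3D, cfg: IGConfig | None = None
) -> AttributionMap:
    """Path-integrated gradients from a baseline to the input.

    Uses a midpoint Riemann sum over ``n_steps`` interpolation points,
    which is exact for linear scores at any step count:
    attribution = (x - b) * mean_k grad(b + (k - 1/2)/n * (x - b)).
    The signed attributions (which satisfy the completeness identity
    sum = f(x) - f(b)) are kept under ``extras["signed"]``; the normalized
    map ranks by magnitude.
    """
    cfg = cfg or IGConfig()
    cls = sample.predicted_label if sample.predicted_label is not None else sample.true_label
    x = sample.data
    b = cfg.baseline.values(x)
    delta = x - b
    acc = np.zeros_like(x)
    for k in range(1, cfg.n_steps + 1):
        alpha = (k - 0.5) / cfg.n_steps
        g = np.asarray(adapter.gradient(b + alpha * delta, cls), dtype=float)
        if not np.all(np.isfinite(g)):
            raise NumericalError(f"non-finite gradient at integration step {k}")
        acc += g
    signed = delta * acc / cfg.n_steps
    if sample.modality == "pointcloud":
        # one value per point: L2 magnitude over the coordinate channels
        magnitude = np.linalg.norm(signed, axis=1)
    else:
        magnitude = np.abs(signed)
    values = normalize_attribution(magnitude)
    return AttributionMap(
        values, method="integrated_gradients", normalized=True, extras={"signed": signed}
    )


def _grid_windows(shape: tuple, window: tuple, stride: tuple):
    """Window start corners covering every element, clamped at the far edge."""
    starts = []
    for s, w, st in zip(shape, window, stride):
        ax = list(range(0, s - w + 1, st))
        if ax[-1] + w < s:
            ax.append(s - w)
        starts.append(ax)
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                yield (
                    slice(i, i + window[0]),
                    slice(j, j + window[1]),
                    slice(k, k + window[2]),
                )


def _part1by2(v: np.ndarray) -> np.ndarray:
    # spread 10 bits to every third position (Morton encoding helper)
    v = v.astype(np.uint64) & np.uint64(0x3FF)
    v = (v | (v << np.uint64(16))) & np.uint64(0x030000FF)
    v = (v | (v << np.uint64(8))) & np.uint64(0x0300F00F)
    v = (v | (v << np.uint64(4))) & np.uint64(0x030C30C3)
    v = (v | (v << np.uint64(2))) & np.uint64(0x09249249)
    return v


def morton_order(points: np.ndarray) -> np.ndarray:
    """Deterministic spatially coherent ordering of points by z-order code.

    Coordinates are quantized to a 10-bit lattice over the bounding box and
    bit-interleaved; ties break by point index.
    """
    pts = np.asarray(points, dtype=float)
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0
    q = np.clip((pts - lo) / span * 1023.0, 0, 1023).astype(np.uint64)
    code = (
        _part1by2(q[:, 0])
        | (_part1by2(q[:, 1]) << np.uint64(1))
        | (_part1by2(q[:, 2]) << np.uint64(2))
    )
    return np.argsort(code, kind="stable")


def occlusion(
    adapter: ModelAdapter, sample: Sample3D, cfg: OcclusionConfig | None = None
) -> AttributionMap:
    """Occlusion sensitivity: confidence drop when a region is set to baseline.

    Grids slide a 3D window (default non-overlapping tiling); each covered
    element receives the drop conf(x) - conf(x occluded), averaged where
    windows overlap.  Point clouds are partitioned into contiguous clusters
    of ``cluster_size`` points along the Morton (z-order) curve and each
    cluster is collapsed to the baseline in turn.
    """
    cfg = cfg or OcclusionConfig()
    baseline = cfg.baseline or (
        BaselineSpec("mean") if sample.modality == "volumetric" else BaselineSpec("zero")
    )
    cls = sample.predicted_label if sample.predicted_label is not None else sample.true_label
    x = sample.data
    base = baseline.values(x)
    conf0 = float(np.asarray(adapter.score(x))[cls])

    if sample.modality == "pointcloud":
        n = x.shape[0]
        if not (1 <= cfg.cluster_size <= n):
            raise ValidationError(
                f"cluster_size {cfg.cluster_size} invalid for {n} points"
            )
        order = morton_order(x)
        total = np.zeros(n)
        count = np.zeros(n)
        for start in range(0, n, cfg.cluster_size):
            idx = order[start : start + cfg.cluster_size]
            perturbed = x.copy()
            perturbed[idx] = base[idx]
            drop = conf0 - float(np.asarray(adapter.score(perturbed))[cls])
            total[idx] += drop
            count[idx] += 1
        raw = total / count
    else:
        window = cfg.resolved_window(x.shape)
        stride = tuple(int(v) for v in cfg.stride) if cfg.stride is not None else window
        total = np.zeros_like(x)
        count = np.zeros_like(x)
        for sl in _grid_windows(x.shape, window, stride):
            perturbed = x.copy()
            perturbed[sl] = base[sl]
            drop = conf0 - float(np.asarray(adapter.score(perturbed))[cls])
            total[sl] += drop
            count[sl] += 1
        raw = total / count
    return AttributionMap(normalize_attribution(raw), method="occlusion", normalized=True)


def _cam_from_layer(acts: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """ReLU(sum_c w_c A_c) with w_c the global average of the layer gradient."""
    acts = np.asarray(acts, dtype=float)
    grads = np.asarray(grads, dtype=float)
    if acts.shape != grads.shape or acts.ndim < 2:
        raise ConfigurationError(
            f"layer activations {acts.shape} and gradients {grads.shape} must match "
            "with a leading channel axis"
        )
    spatial_axes = tuple(range(1, acts.ndim))
    weights = grads.mean(axis=spatial_axes)
    cam = np.tensordot(weights, acts, axes=(0, 0))
    return np.maximum(cam, 0.0)


def grad_cam_grid(
    adapter: ModelAdapter, sample: Sample3D, cfg: GradCamConfig | None = None
) -> AttributionMap:
    """Grad-CAM for volumetric/voxel inputs at a named 3D conv layer,
    trilinearly upsampled to the input resolution."""
    if sample.modality == "pointcloud":
        raise ValidationError("grad_cam_grid requires a grid modality")
    cfg = cfg or GradCamConfig()
    cls = sample.predicted_label if sample.predicted_label is not None else sample.true_label
    acts, grads = adapter.layer_forward_backward(sample.data, cls, cfg.layer_name)
    cam = _cam_from_layer(acts, grads)
    cam = resample_volume(cam, sample.data.shape)
    return AttributionMap(normalize_attribution(cam), method="gradcam", normalized=True)


def grad_cam_points(
    adapter: ModelAdapter, sample: Sample3D, cfg: GradCamConfig | None = None
) -> AttributionMap:
    """Grad-CAM for point clouds at a set-abstraction layer.

    Per-centroid channel-weighted ReLU values are propagated to each
    original point from its nearest centroid (Euclidean distance, ties to
    the lowest centroid index).
    """
    if sample.modality != "pointcloud":
        raise ValidationError("grad_cam_points requires pointcloud modality")
    cfg = cfg or GradCamConfig(layer_name="sa2", upsample="nearest_neighbor_points")
    cls = sample.predicted_label if sample.predicted_label is not None else sample.true_label
    acts, grads = adapter.layer_forward_backward(sample.data, cls, cfg.layer_name)
    centroids = np.asarray(adapter.layer_coordinates(sample.data, cfg.layer_name), dtype=float)
    if centroids.ndim != 2 or centroids.shape[0] == 0:
        raise ConfigurationError("layer exposes zero centroids")
    cam = _cam_from_layer(acts, grads)  # (M,)
    if cam.shape != (centroids.shape[0],):
        raise ConfigurationError(
            f"per-centroid CAM shape {cam.shape} != centroid count {centroids.shape[0]}"
        )
    d2 = ((sample.data[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)  # argmin takes the lowest index on exact ties
    raw = cam[nearest]
    return AttributionMap(normalize_attribution(raw), method="gradcam", normalized=True)


def grad_cam(
    adapter: ModelAdapter, sample: Sample3D, cfg: GradCamConfig | None = None
) -> AttributionMap:
    """Dispatch Grad-CAM by modality."""
    if sample.modality == "pointcloud":
        return grad_cam_points(adapter, sample, cfg)
    return grad_cam_grid(adapter, sample, cfg)


def intrinsic_attention(
    adapter: ModelAdapter, sample: Sample3D, mask_name: str = "soft2"
) -> AttributionMap:
    """Extract a named attention mask (default the second soft stage) and
    trilinearly upsample it to input resolution.

    Point-cloud adapters do not carry dense attention modules; requesting
    intrinsic attribution for them raises :class:`UnsupportedMethodError`.
    """
    if sample.modality == "pointcloud":
        raise UnsupportedMethodError(
            "intrinsic attention is not available for point-cloud models"
        )
    masks = adapter.attention_masks(sample.data)
    if not masks:
        raise UnsupportedMethodError("adapter exposes no attention masks")
    if mask_name not in masks:
        raise ConfigurationError(
            f"no attention mask named {mask_name!r}; available: {sorted(masks)}"
        )
    mask = np.asarray(masks[mask_name], dtype=float)
    mask = resample_volume(mask, sample.data.shape)
    return AttributionMap(normalize_attribution(mask), method="intrinsic", normalized=True)


def compute_attribution(
    method: str,
    adapter: ModelAdapter,
    sample: Sample3D,
    *,
    gradcam: GradCamConfig | None = None,
    ig: IGConfig | None = None,
    occlusion_cfg: OcclusionConfig | None = None,
    mask_name: str = "soft2",
) -> AttributionMap:
    """Run one attribution method by name (pipeline entry point)."""
    if method == "saliency":
        return saliency(adapter, sample)
    if method == "integrated_gradients":
        return integrated_gradients(adapter, sample, ig)
    if method == "occlusion":
        return occlusion(adapter, sample, occlusion_cfg)
    if method == "gradcam":
        return grad_cam(adapter, sample, gradcam)
    if method == "intrinsic":
        return intrinsic_attention(adapter, sample, mask_name)
    raise ValidationError(f"unknown attribution method {method!r}")
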