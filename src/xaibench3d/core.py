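"""Shared data model for 3D explainability benchmarking.

Defines the three input modalities (dense volumes, binary occupancy voxel
grids, xyz point clouds), the attribution-map container, the model-adapter
contract through which every attribution method and metric queries a
classifier, perturbation baselines, min-max attribution normalization,
NPZ persistence, and trilinear volume resampling.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

MODALITIES = ("volumetric", "voxel", "pointcloud")
METHODS = ("gradcam", "saliency", "integrated_gradients", "occlusion", "intrinsic")


class ValidationError(ValueError):
    """Invalid input data or configuration value."""


class ConfigurationError(ValueError):
    """A method configuration refers to something the adapter does not provide."""


class UnsupportedMethodError(ValueError):
    """Requested attribution method is not applicable to this adapter/modality."""


class CorruptContainerError(IOError):
    """An attribution container is missing fields or internally inconsistent."""


class NumericalError(ArithmeticError):
    """A non-finite value appeared during a numeric computation."""


class MetricError(RuntimeError):
    """A metric computation failed mid-curve."""


@dataclass
class Sample3D:
    """One input instance in any of the three modalities.

    ``data`` is a (D, H, W) float array for volumetric inputs, a (D, H, W)
    {0,1} array for voxel occupancy grids, and an (N, 3) float array of xyz
    coordinates for point clouds.  ``predicted_label`` may be None until a
    classifier has been run on the sample.
    """

    sample_id: str
    modality: str
    data: np.ndarray
    true_label: int
    predicted_label: int | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        self.data = np.asarray(self.data, dtype=float)
        if self.modality == "pointcloud":
            if self.data.ndim != 2 or self.data.shape[1] != 3:
                raise ValidationError(
                    f"pointcloud data must be (N, 3), got {self.data.shape}"
                )
        else:
            if self.data.ndim != 3:
                raise ValidationError(
                    f"{self.modality} data must be (D, H, W), got {self.data.shape}"
                )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("sample data contains non-finite values")
        if self.modality == "voxel" and not np.isin(self.data, (0.0, 1.0)).all():
            raise ValidationError("voxel occupancy values must be 0 or 1")

    @property
    def correct(self) -> bool | None:
        if self.predicted_label is None:
            return None
        return self.predicted_label == self.true_label

    @property
    def n_elements(self) -> int:
        """Number of attribution elements: voxels for grids, points for clouds."""
        if self.modality == "pointcloud":
            return self.data.shape[0]
        return int(self.data.size)

    def with_data(self, data: np.ndarray) -> "Sample3D":
        """Copy of this sample carrying perturbed data, labels preserved."""
        return Sample3D(
            sample_id=self.sample_id,
            modality="volumetric" if self.modality == "voxel" else self.modality,
            data=data,
            true_label=self.true_label,
            predicted_label=self.predicted_label,
        )


@dataclass
class AttributionMap:
    """Per-element relevance values aligned to a :class:`Sample3D`.

    Grids carry one value per voxel on the same (D, H, W) lattice; point
    clouds carry a length-N vector.  ``extras`` holds method by-products such
    as the signed integrated-gradients attributions.
    """

    values: np.ndarray
    method: str
    normalized: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.method not in METHODS and self.method != "custom":
            raise ValidationError(f"unknown attribution method {self.method!r}")
        if self.normalized:
            v = self.values
            if v.size and (v.min() < 0.0 or v.max() > 1.0):
                raise ValidationError("normalized map has values outside [0, 1]")

    def check_matches(self, sample: Sample3D) -> None:
        expected = (
            (sample.data.shape[0],)
            if sample.modality == "pointcloud"
            else sample.data.shape
        )
        if self.values.shape != expected:
            raise ValidationError(
                f"attribution shape {self.values.shape} does not match "
                f"sample shape {expected}"
            )


class ModelAdapter(ABC):
    """Contract through which attribution methods and metrics query a classifier.

    ``score`` returns the per-class confidence vector used by the
    perturbation metrics; trained adapters report softmax probabilities,
    while analytic oracle adapters may report raw scores so closed-form
    identities hold exactly.  ``gradient`` differentiates the raw class
    score with respect to the input.
    """

    @property
    @abstractmethod
    def n_classes(self) -> int: ...

    @abstractmethod
    def score(self, x: np.ndarray) -> np.ndarray:
        """Per-class confidence vector of length ``n_classes``."""

    @abstractmethod
    def gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """d(score of class)/d(x), same shape as ``x``."""

    def layer_forward_backward(
        self, x: np.ndarray, class_index: int, layer_name: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """(activations, gradients) at a named internal layer, both (C, ...)."""
        raise ConfigurationError(f"adapter exposes no layer named {layer_name!r}")

    def layer_coordinates(self, x: np.ndarray, layer_name: str) -> np.ndarray:
        """(M, 3) spatial coordinates of a point model's abstraction layer."""
        raise ConfigurationError(f"adapter exposes no coordinates for {layer_name!r}")

    def attention_masks(self, x: np.ndarray) -> Mapping[str, np.ndarray] | None:
        """Named internal spatial attention masks, or None if unavailable."""
        return None

    def predict(self, x: np.ndarray) -> int:
        return int(np.argmax(self.score(x)))


@dataclass
class BaselineSpec:
    """Neutral replacement value used by perturbation: zero, the sample's own
    mean, or a Gaussian-blurred copy (``sigma`` in element units)."""

    kind: str = "zero"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "mean", "blurred"):
            raise ValidationError(f"unknown baseline kind {self.kind!r}")

    def values(self, data: np.ndarray) -> np.ndarray:
        """Baseline array with the same shape as ``data``."""
        data = np.asarray(data, dtype=float)
        if self.kind == "zero":
            return np.zeros_like(data)
        if self.kind == "mean":
            return np.full_like(data, float(data.mean()))
        return ndimage.gaussian_filter(data, sigma=self.sigma)


def default_baseline(modality: str) -> BaselineSpec:
    """Mean-intensity baseline for dense volumes, zero for geometric data."""
    if modality == "volumetric":
        return BaselineSpec("mean")
    return BaselineSpec("zero")


def normalize_attribution(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize a raw attribution array to [0, 1].

    A constant raw map normalizes to all zeros: when no element is
    distinguished, no element carries relevance.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValidationError("cannot normalize an empty attribution map")
    bad = ~np.isfinite(raw)
    if bad.any():
        idx = tuple(
            int(i) for i in np.unravel_index(int(np.flatnonzero(bad.ravel())[0]), raw.shape)
        )
        raise ValidationError(f"non-finite attribution value at index {idx}")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


_META_FIELDS = ("sample_id", "method", "modality", "true_label", "predicted_label")


def save_attribution(amap: AttributionMap, sample: Sample3D, path) -> None:
    """Persist one (sample, method) pair as an NPZ container.

    The container holds the named arrays ``values`` and ``data`` plus a JSON
    metadata record; signed extras are stored under ``extra_<name>``.
    """
    if not amap.normalized:
        raise ValidationError("only normalized attribution maps are persisted")
    amap.check_matches(sample)
    meta = {
        "sample_id": sample.sample_id,
        "method": amap.method,
        "modality": sample.modality,
        "true_label": int(sample.true_label),
        "predicted_label": (
            None if sample.predicted_label is None else int(sample.predicted_label)
        ),
    }
    arrays = {
        "values": amap.values,
        "data": sample.data,
        "metadata": np.array(json.dumps(meta, sort_keys=True)),
    }
    for name, arr in amap.extras.items():
        arrays[f"extra_{name}"] = np.asarray(arr)
    np.savez(path, **arrays)


def load_attribution(path) -> tuple[AttributionMap, dict]:
    """Load an NPZ attribution container; returns (map, metadata).

    Metadata includes the paired sample's raw ``data`` array under "data".
    """
    with np.load(path, allow_pickle=False) as npz:
        names = set(npz.files)
        if not {"values", "data", "metadata"} <= names:
            raise CorruptContainerError(
                f"container missing arrays: {sorted({'values', 'data', 'metadata'} - names)}"
            )
        try:
            meta = json.loads(str(npz["metadata"]))
        except json.JSONDecodeError as exc:
            raise CorruptContainerError("unreadable metadata record") from exc
        missing = [f for f in _META_FIELDS if f not in meta]
        if missing:
            raise CorruptContainerError(f"metadata missing fields: {missing}")
        values = npz["values"]
        data = npz["data"]
        extras = {
            n[len("extra_"):]: npz[n] for n in names if n.startswith("extra_")
        }
    modality = meta["modality"]
    expected = (data.shape[0],) if modality == "pointcloud" else data.shape
    if values.shape != expected:
        raise CorruptContainerError(
            f"values shape {values.shape} inconsistent with {modality} data "
            f"shape {data.shape}"
        )
    meta["data"] = data
    amap = AttributionMap(values=values, method=meta["method"], normalized=True,
                          extras=extras)
    return amap, meta


def resample_volume(grid: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear resampling of a 3D scalar grid onto a target lattice.

    Cell-center convention: target cell i along an axis of T cells samples
    source coordinate (i + 0.5) * S / T - 0.5, clamped at the boundary.
    Linear in intensities, so it preserves constants and commutes with
    global affine intensity changes.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 3 or grid.size == 0:
        raise ValidationError(f"expected a non-empty 3D grid, got shape {grid.shape}")
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ValidationError(f"invalid target shape {target_shape}")
    if target_shape == grid.shape:
        return grid.copy()
    axes = [
        (np.arange(t) + 0.5) * s / t - 0.5
        for s, t in zip(grid.shape, target_shape)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(grid, coords, order=1, mode="nearest")
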