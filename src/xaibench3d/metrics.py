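"""Perturbation-based faithfulness and compactness metrics.

Implements the removal/preservation perturbation engine and the three
benchmark metrics: AOPC (area over the confidence-drop curve under
progressive removal of top-attributed elements), AUPC (area under the
confidence curve when only top-attributed elements are kept), and
compactness at fixed absolute thresholds or an adaptive top-fraction
quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .core import (
    AttributionMap,
    BaselineSpec,
    MetricError,
    ModelAdapter,
    Sample3D,
    ValidationError,
    default_baseline,
)


@dataclass
class PerturbationSchedule:
    """K removal fractions k/K for k = 1..K (default 0.1, 0.2, ..., 1.0)."""

    K: int = 10

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError("K must be >= 1")

    @property
    def fractions(self) -> np.ndarray:
        return np.arange(1, self.K + 1) / self.K


@dataclass
class CompactnessConfig:
    fixed_thresholds: tuple = (0.5, 0.7, 0.9)
    adaptive_fraction: float = 0.1
    #: take the adaptive quantile over all elements (default) or only the
    #: elements that are non-zero in the input
    quantile_population: str = "all"

    def __post_init__(self) -> None:
        if any(not (0.0 < t <= 1.0) for t in self.fixed_thresholds):
            raise ValidationError("fixed thresholds must lie in (0, 1]")
        if not (0.0 < self.adaptive_fraction < 1.0):
            raise ValidationError("adaptive fraction must lie in (0, 1)")
        if self.quantile_population not in ("all", "nonzero"):
            raise ValidationError("quantile_population must be 'all' or 'nonzero'")


@dataclass
class MetricRecord:
    """AOPC/AUPC/compactness scores for one (sample, method) pair."""

    sample_id: str
    method: str
    aopc: float
    aupc: float
    compactness_fixed: dict
    compactness_adaptive: float
    drop_curve: np.ndarray
    preservation_curve: np.ndarray
    conf_init: float

    def __post_init__(self) -> None:
        self.drop_curve = np.asarray(self.drop_curve, dtype=float)
        self.preservation_curve = np.asarray(self.preservation_curve, dtype=float)
        if self.preservation_curve.size and self.preservation_curve[0] != 0.0:
            raise ValidationError("preservation curve must start at 0.0")


def rank_elements(amap: AttributionMap) -> np.ndarray:
    """Flat element indices sorted by attribution, highest first.

    Ties break by ascending flat index (stable sort), so the order is
    fully deterministic.
    """
    flat = amap.values.ravel()
    return np.argsort(-flat, kind="stable")


def _n_selected(fraction: float, m: int) -> int:
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction}")
    return ceil(fraction * m)


def _perturb(
    sample: Sample3D,
    order: np.ndarray,
    fraction: float,
    baseline: BaselineSpec,
    keep_selected: bool,
) -> Sample3D:
    data = sample.data
    base = baseline.values(data)
    if sample.modality == "pointcloud":
        m = data.shape[0]
        selected = order[: _n_selected(fraction, m)]
        if keep_selected:
            out = base.copy()
            out[selected] = data[selected]
        else:
            out = data.copy()
            out[selected] = base[selected]
    else:
        m = data.size
        selected = order[: _n_selected(fraction, m)]
        if keep_selected:
            out = base.copy().ravel()
            out[selected] = data.ravel()[selected]
        else:
            out = data.copy().ravel()
            out[selected] = base.ravel()[selected]
        out = out.reshape(data.shape)
    return sample.with_data(out)


def apply_removal(
    sample: Sample3D, order: np.ndarray, fraction: float, baseline: BaselineSpec
) -> Sample3D:
    """Replace the top ceil(fraction * M) elements of ``order`` by the baseline.

    M counts all elements of the sample (voxels of the full grid, or points).
    For point clouds the selected points' coordinates are replaced by the
    baseline constant (zero baseline collapses them to the origin); tensor
    shapes never change.
    """
    return _perturb(sample, order, fraction, baseline, keep_selected=False)


def apply_preservation(
    sample: Sample3D, order: np.ndarray, fraction: float, baseline: BaselineSpec
) -> Sample3D:
    """Keep only the top ceil(fraction * M) elements; everything else at baseline.

    Exact complement of :func:`apply_removal`: the kept set equals removal's
    replaced set at the same fraction.
    """
    return _perturb(sample, order, fraction, baseline, keep_selected=True)


def _confidence(adapter: ModelAdapter, data: np.ndarray, class_index: int, step: int) -> float:
    try:
        s = adapter.score(data)
    except Exception as exc:  # noqa: BLE001 - reported with curve position
        raise MetricError(f"adapter failed at perturbation step {step}") from exc
    return float(np.asarray(s)[class_index])


def _target_class(sample: Sample3D) -> int:
    # metrics always explain the model's actual decision
    return sample.predicted_label if sample.predicted_label is not None else sample.true_label


def compute_aopc(
    adapter: ModelAdapter,
    sample: Sample3D,
    amap: AttributionMap,
    schedule: PerturbationSchedule | None = None,
    baseline: BaselineSpec | None = None,
) -> tuple[float, np.ndarray, float]:
    """Area over the perturbation curve (correctness).

    drop_k = conf(x) - conf(x with top k/K removed); AOPC is the trapezoidal
    area of the drop-vs-fraction curve with an implicit (0, 0) origin.
    Returns (aopc, drop_curve, conf_init).
    """
    schedule = schedule or PerturbationSchedule()
    baseline = baseline or default_baseline(sample.modality)
    amap.check_matches(sample)
    cls = _target_class(sample)
    conf_init = _confidence(adapter, sample.data, cls, step=0)
    order = rank_elements(amap)
    drops = np.empty(schedule.K)
    for k, frac in enumerate(schedule.fractions, start=1):
        perturbed = apply_removal(sample, order, frac, baseline)
        drops[k - 1] = conf_init - _confidence(adapter, perturbed.data, cls, step=k)
    xs = np.concatenate([[0.0], schedule.fractions])
    ys = np.concatenate([[0.0], drops])
    aopc = float(np.trapezoid(ys, xs))
    return aopc, drops, conf_init


def compute_aupc(
    adapter: ModelAdapter,
    sample: Sample3D,
    amap: AttributionMap,
    schedule: PerturbationSchedule | None = None,
    baseline: BaselineSpec | None = None,
) -> tuple[float, np.ndarray]:
    """Area under the preservation curve (completeness).

    The curve starts at 0.0 (empty input) followed by conf(x with only the
    top k/K kept) at fractions 1/K..1; AUPC is its trapezoidal area.
    Returns (aupc, preservation_curve) with the curve of length K + 1.
    """
    schedule = schedule or PerturbationSchedule()
    baseline = baseline or default_baseline(sample.modality)
    amap.check_matches(sample)
    cls = _target_class(sample)
    order = rank_elements(amap)
    curve = np.zeros(schedule.K + 1)
    for k, frac in enumerate(schedule.fractions, start=1):
        preserved = apply_preservation(sample, order, frac, baseline)
        curve[k] = _confidence(adapter, preserved.data, cls, step=k)
    xs = np.concatenate([[0.0], schedule.fractions])
    aupc = float(np.trapezoid(curve, xs))
    return aupc, curve


def _n_nonzero(sample: Sample3D) -> int:
    # occupancy is meaningless for coordinates: every point counts
    if sample.modality == "pointcloud":
        return sample.data.shape[0]
    n = int(np.count_nonzero(sample.data))
    if n == 0:
        raise ValidationError("compactness undefined: sample has no non-zero elements")
    return n


def compute_compactness_fixed(
    amap: AttributionMap, sample: Sample3D, thresholds=(0.5, 0.7, 0.9)
) -> dict:
    """ratio(t) = #{a_i >= t} / #{x_i != 0} for each fixed threshold t.

    Ratios may exceed 1 on sparse grids where attributed elements outnumber
    occupied voxels.
    """
    amap.check_matches(sample)
    denom = _n_nonzero(sample)
    vals = amap.values.ravel()
    return {float(t): float(np.count_nonzero(vals >= t) / denom) for t in thresholds}


def compute_compactness_adaptive(
    amap: AttributionMap,
    sample: Sample3D,
    fraction: float = 0.1,
    quantile_population: str = "all",
) -> float:
    """Compactness at an adaptive top-``fraction`` quantile threshold.

    The threshold is the value of the ceil(fraction * M)-th largest
    attribution (the empirical (1 - fraction) quantile); the ratio counts
    elements at or above it against the non-zero elements of the input.
    """
    amap.check_matches(sample)
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"adaptive fraction must lie in (0, 1), got {fraction}")
    denom = _n_nonzero(sample)
    vals = amap.values.ravel()
    if quantile_population == "nonzero":
        if sample.modality == "pointcloud":
            pop = vals
        else:
            pop = vals[sample.data.ravel() != 0]
    else:
        pop = vals
    m = ceil(fraction * pop.size)
    threshold = np.sort(pop)[::-1][m - 1]
    return float(np.count_nonzero(vals >= threshold) / denom)


def evaluate_sample(
    adapter: ModelAdapter,
    sample: Sample3D,
    amap: AttributionMap,
    schedule: PerturbationSchedule | None = None,
    baseline: BaselineSpec | None = None,
    compactness: CompactnessConfig | None = None,
) -> MetricRecord:
    """All three metrics for one (sample, attribution) pair."""
    schedule = schedule or PerturbationSchedule()
    baseline = baseline or default_baseline(sample.modality)
    compactness = compactness or CompactnessConfig()
    aopc, drops, conf_init = compute_aopc(adapter, sample, amap, schedule, baseline)
    aupc, curve = compute_aupc(adapter, sample, amap, schedule, baseline)
    fixed = compute_compactness_fixed(amap, sample, compactness.fixed_thresholds)
    adaptive = compute_compactness_adaptive(
        amap, sample, compactness.adaptive_fraction, compactness.quantile_population
    )
    return MetricRecord(
        sample_id=sample.sample_id,
        method=amap.method,
        aopc=aopc,
        aupc=aupc,
        compactness_fixed=fixed,
        compactness_adaptive=adaptive,
        drop_curve=drops,
        preservation_curve=curve,
        conf_init=conf_init,
    )
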