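"""End-to-end benchmarking protocol.

Orchestrates the full evaluation: per-class balanced sample selection,
attribution generation for every requested method, AOPC/AUPC/compactness
scoring, per method-metric IQR outlier filtering, Kruskal-Wallis across
methods with Bonferroni-corrected pairwise Mann-Whitney follow-ups, and
emission of the CSV/NPZ/JSON artifact set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from itertools import combinations
from math import ceil, floor, sqrt
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import GradCamConfig, IGConfig, OcclusionConfig, compute_attribution
from .core import (
    BaselineSpec,
    ModelAdapter,
    Sample3D,
    ValidationError,
    default_baseline,
    save_attribution,
)
from .metrics import (
    CompactnessConfig,
    MetricRecord,
    PerturbationSchedule,
    evaluate_sample,
)
from .stats import bonferroni, iqr_filter, kruskal_wallis, mann_whitney

POSTHOC_METHODS = ("gradcam", "saliency", "integrated_gradients", "occlusion")
ALL_METHODS = POSTHOC_METHODS + ("intrinsic",)
#: metric columns entering the statistical comparison
STAT_METRICS = ("aopc", "aupc", "compactness_fixed_0.5", "compactness_adaptive")


@dataclass
class BenchmarkConfig:
    dataset: str = "fixture"
    modality: str = "volumetric"
    methods: tuple = ALL_METHODS
    samples_per_class: int = 5
    k_steps: int = 10
    ig_steps: int = 50
    fixed_thresholds: tuple = (0.5, 0.7, 0.9)
    adaptive_fraction: float = 0.1
    baseline: str | None = None  # override: "zero" | "mean" | "blurred"
    gradcam_layer: str | None = None  # default: conv1 grids, sa2 points
    seed: int = 0
    alpha: float = 0.05
    out_dir: str = "results"
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        self.fixed_thresholds = tuple(float(t) for t in self.fixed_thresholds)
        if self.samples_per_class < 1:
            raise ValidationError("samples_per_class must be >= 1")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValidationError(f"unknown methods {sorted(unknown)}")
        if self.modality == "pointcloud" and "intrinsic" in self.methods:
            raise ValidationError(
                "intrinsic attention is not supported for pointcloud"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        return cls(**d)


@dataclass
class BenchmarkReport:
    config: BenchmarkConfig
    records: pd.DataFrame
    summary: pd.DataFrame
    stats: pd.DataFrame
    failures: list
    n_selected: int


def select_samples(pool, samples_per_class: int, seed: int = 0):
    """Per-class balanced selection of correct/incorrect predictions.

    Within each class (ordered by sample_id) the correct stratum contributes
    ceil(s/2) samples and the incorrect stratum floor(s/2); a shortfall in
    one stratum is back-filled from the other.  Deterministic given the pool.
    """
    if not pool:
        raise ValidationError("empty sample pool")
    if any(s.predicted_label is None for s in pool):
        raise ValidationError("pool contains samples without predictions")
    by_class: dict[int, list[Sample3D]] = {}
    for s in sorted(pool, key=lambda s: s.sample_id):
        by_class.setdefault(s.true_label, []).append(s)
    selected = []
    for cls in sorted(by_class):
        members = by_class[cls]
        correct = [s for s in members if s.correct]
        incorrect = [s for s in members if not s.correct]
        n_cor = min(ceil(samples_per_class / 2), len(correct))
        n_inc = min(floor(samples_per_class / 2), len(incorrect))
        # back-fill shortfall from the other stratum
        short = samples_per_class - n_cor - n_inc
        if short > 0:
            extra_cor = min(short, len(correct) - n_cor)
            n_cor += extra_cor
            n_inc += min(short - extra_cor, len(incorrect) - n_inc)
        selected.extend(correct[:n_cor] + incorrect[:n_inc])
    return selected


def _record_row(rec: MetricRecord) -> dict:
    row = {
        "sample_id": rec.sample_id,
        "method": rec.method,
        "aopc": rec.aopc,
        "aupc": rec.aupc,
        "compactness_adaptive": rec.compactness_adaptive,
        "conf_init": rec.conf_init,
    }
    for t, v in rec.compactness_fixed.items():
        row[f"compactness_fixed_{t:g}"] = v
    return row


def run_benchmark(cfg: BenchmarkConfig, adapter: ModelAdapter, pool):
    """Execute the full protocol; returns (records DataFrame, BenchmarkReport).

    Stage failures are recorded per (sample, method) and the run continues.
    All artifacts are written under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    (out / "attributions").mkdir(parents=True, exist_ok=True)
    selected = select_samples(pool, cfg.samples_per_class, cfg.seed)

    schedule = PerturbationSchedule(cfg.k_steps)
    compactness = CompactnessConfig(
        fixed_thresholds=cfg.fixed_thresholds, adaptive_fraction=cfg.adaptive_fraction
    )
    baseline = (
        BaselineSpec(cfg.baseline) if cfg.baseline else default_baseline(cfg.modality)
    )
    layer = cfg.gradcam_layer or ("sa2" if cfg.modality == "pointcloud" else "conv1")

    records: list[MetricRecord] = []
    curves: dict[str, np.ndarray] = {}
    failures: list[dict] = []
    for sample in selected:
        for method in cfg.methods:
            try:
                amap = compute_attribution(
                    method,
                    adapter,
                    sample,
                    gradcam=GradCamConfig(layer_name=layer),
                    ig=IGConfig(n_steps=cfg.ig_steps),
                    occlusion_cfg=OcclusionConfig(baseline=baseline),
                )
                save_attribution(
                    amap, sample, out / "attributions" / f"{sample.sample_id}_{method}.npz"
                )
                rec = evaluate_sample(
                    adapter, sample, amap, schedule, baseline, compactness
                )
            except Exception as exc:  # noqa: BLE001 - per-sample isolation
                failures.append(
                    {"sample_id": sample.sample_id, "method": method,
                     "error": f"{type(exc).__name__}: {exc}"}
                )
                continue
            records.append(rec)
            curves[f"{sample.sample_id}|{method}|drop"] = rec.drop_curve
            curves[f"{sample.sample_id}|{method}|preservation"] = rec.preservation_curve

    df = pd.DataFrame([_record_row(r) for r in records])
    if not df.empty:
        df = df.sort_values(["sample_id", "method"], kind="stable").reset_index(drop=True)
    df.to_csv(out / "metrics.csv", index=False)
    if curves:
        np.savez(out / "curves.npz", **curves)

    stats_df = compute_stats(df, dataset=cfg.dataset, alpha=cfg.alpha)
    stats_df.to_csv(out / "stats.csv", index=False)
    summary = summarize(df)
    report = BenchmarkReport(
        config=cfg,
        records=df,
        summary=summary,
        stats=stats_df,
        failures=failures,
        n_selected=len(selected),
    )
    emit_report(report, out)
    return df, report


def compute_stats(df: pd.DataFrame, dataset: str = "fixture", alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Statistical comparison of methods per metric.

    Per method-metric pair the scores are IQR-filtered; a Kruskal-Wallis
    test across methods gates Bonferroni-corrected pairwise Mann-Whitney U
    tests (pairs are still reported, flagged exploratory, when the gate is
    not significant).  P-values are corrected per dataset-metric
    combination with m = number of method pairs.
    """
    rows: list[dict] = []
    if df.empty:
        return pd.DataFrame(
            columns=["dataset", "metric", "comparison", "test", "statistic",
                     "z_score", "p_raw", "p_corrected", "effect_size",
                     "effect_label", "n", "exploratory"]
        )
    methods = sorted(df["method"].unique())
    for metric in STAT_METRICS:
        if metric not in df.columns:
            continue
        groups, labels = [], []
        for m in methods:
            vals = df.loc[df["method"] == m, metric].to_numpy(dtype=float)
            if vals.size == 0:
                continue
            kept, _, _ = iqr_filter(vals) if vals.size >= 4 else (vals, None, None)
            groups.append(kept)
            labels.append(m)
        if len(groups) < 2:
            continue
        kw = kruskal_wallis(groups, labels)
        rows.append(
            {"dataset": dataset, "metric": metric, "comparison": "all",
             "test": "kruskal_wallis", "statistic": kw.statistic, "z_score": "",
             "p_raw": kw.p_raw, "p_corrected": kw.p_raw,
             "effect_size": kw.effect_size, "effect_label": kw.effect_label,
             "n": int(sum(kw.n_per_group)), "exploratory": False}
        )
        gate_significant = kw.p_raw < alpha
        pairs = list(combinations(range(len(groups)), 2))
        m_tests = len(pairs)
        raw_ps, pair_rows = [], []
        for i, j in pairs:
            mw = mann_whitney(groups[i], groups[j], mode="auto")
            raw_ps.append(mw.p_raw)
            pair_rows.append(
                {"dataset": dataset, "metric": metric,
                 "comparison": f"{labels[i]}_vs_{labels[j]}",
                 "test": "mann_whitney", "statistic": mw.statistic,
                 "z_score": mw.z_score, "p_raw": mw.p_raw,
                 "effect_size": mw.effect_size, "effect_label": mw.effect_label,
                 "n": int(sum(mw.n_per_group)),
                 "exploratory": not gate_significant}
            )
        corrected = bonferroni(raw_ps, m_tests)
        for row, pc in zip(pair_rows, corrected):
            row["p_corrected"] = float(pc)
            rows.append(row)
    cols = ["dataset", "metric", "comparison", "test", "statistic", "z_score",
            "p_raw", "p_corrected", "effect_size", "effect_label", "n",
            "exploratory"]
    return pd.DataFrame(rows, columns=cols)


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Per (method, metric) summary statistics; the IQR filter is applied
    per method-metric pair and both n before/after are reported."""
    rows = []
    if df.empty:
        return pd.DataFrame(
            columns=["method", "metric", "mean", "median", "q1", "q3",
                     "n_before", "n_after"]
        )
    metric_cols = [c for c in df.columns if c not in ("sample_id", "method", "conf_init")]
    for method in sorted(df["method"].unique()):
        sub = df[df["method"] == method]
        for metric in metric_cols:
            vals = sub[metric].to_numpy(dtype=float)
            kept = iqr_filter(vals)[0] if vals.size >= 4 else vals
            q1, med, q3 = np.quantile(kept, [0.25, 0.5, 0.75])
            rows.append(
                {"method": method, "metric": metric, "mean": float(kept.mean()),
                 "median": float(med), "q1": float(q1), "q3": float(q3),
                 "n_before": int(vals.size), "n_after": int(kept.size)}
            )
    return pd.DataFrame(rows)


def emit_report(report: BenchmarkReport, out_dir) -> None:
    """Write summary/stats CSVs, a provenance JSON, and optional boxplots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.records.empty:
        (out / "summary.csv").write_text("# no records\n")
    else:
        report.summary.to_csv(out / "summary.csv", index=False)
    provenance = {
        "config": report.config.to_dict(),
        "seed": report.config.seed,
        "n_selected": report.n_selected,
        "n_records": int(len(report.records)),
        "failures": report.failures,
        "versions": {
            "xaibench3d": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )
    if report.config.make_plots and not report.records.empty:
        _boxplots(report.records, out)


def _boxplots(df: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = sorted(df["method"].unique())
    for metric in STAT_METRICS:
        if metric not in df.columns:
            continue
        data = [df.loc[df["method"] == m, metric].dropna() for m in methods]
        fig, ax = plt.subplots(figsize=(1.2 * len(methods) + 2, 4))
        ax.boxplot(data, tick_labels=methods)
        ax.set_ylabel(metric)
        ax.set_title(f"{metric} by attribution method")
        fig.tight_layout()
        fig.savefig(out / f"boxplot_{metric}.png", dpi=100)
        plt.close(fig)
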