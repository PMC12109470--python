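"""Evaluation metrics, per-region ablation, and band-power group reports.

Accuracy, recall and F1 come straight from the confusion counts
(MDD = positive class); AUC is the rank statistic — the probability that a
random positive outscores a random negative, ties counting one half.
Region ablation reruns selection + stacking cross-validation on each scalp
region's feature columns alone and ranks regions by accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .core import (
    BANDS_STANDARD,
    BandScheme,
    ConfusionCounts,
    DEFAULT_REGION_MAP,
    FeatureTable,
    RegionMap,
)

__all__ = [
    "EvalReport",
    "confusion_metrics",
    "roc_auc",
    "region_ablation",
    "band_power_group_report",
]


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, recall, F1) from binary confusion counts.

    accuracy = (TP+TN)/total, recall = TP/(TP+FN), F1 = harmonic mean of
    precision and recall (0 when precision + recall = 0).  Recall with no
    actual positives is reported as NaN.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    accuracy = (c.tp + c.tn) / c.total
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    rec = 0.0 if np.isnan(recall) else recall
    f1 = (2 * precision * rec / (precision + rec)
          if (precision + rec) > 0 else 0.0)
    return accuracy, recall, f1


def roc_auc(scores, labels) -> float:
    """Rank-based AUC: P(score+ > score−) with ties counting ½.

    Equivalent to trapezoidal integration of the ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = spstats.rankdata(s)  # mid-ranks handle ties as ½
    r_pos = ranks[y == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Per-model (or per-region) metrics with fold-level detail."""

    models: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add_model(self, name: str, fold_counts: list[ConfusionCounts],
                  fold_aucs: list[float], pooled_auc: float,
                  extra: dict | None = None) -> None:
        pooled = ConfusionCounts(0, 0, 0, 0)
        fold_metrics = []
        for c in fold_counts:
            pooled = pooled + c
            acc, rec, f1 = confusion_metrics(c)
            fold_metrics.append({"accuracy": acc, "recall": rec, "f1": f1})
        acc, rec, f1 = confusion_metrics(pooled)
        self.models[name] = {
            "accuracy": acc,
            "recall": rec,
            "f1": f1,
            "auc": pooled_auc,
            "auc_mean_folds": float(np.mean(fold_aucs)),
            "confusion": {"tp": pooled.tp, "fp": pooled.fp,
                          "tn": pooled.tn, "fn": pooled.fn},
            "fold_metrics": fold_metrics,
            "fold_aucs": [float(a) for a in fold_aucs],
            **(extra or {}),
        }

    def metric(self, name: str, key: str = "accuracy") -> float:
        return float(self.models[name][key])

    def ranking(self, key: str = "accuracy") -> list[str]:
        return sorted(self.models, key=lambda m: self.models[m][key],
                      reverse=True)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.models.items():
            rows.append({
                "model": name, "accuracy": m["accuracy"],
                "recall": m["recall"], "f1": m["f1"], "auc": m["auc"],
                "auc_mean_folds": m["auc_mean_folds"],
                **{k: v for k, v in m["confusion"].items()},
            })
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {"models": self.models, "meta": self.meta}
        Path(path).write_text(json.dumps(payload, indent=1, default=float))

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        return cls(models=payload["models"], meta=payload.get("meta", {}))


def region_ablation(
    full_table: FeatureTable,
    regions: RegionMap = DEFAULT_REGION_MAP,
    alpha: float = 0.05,
    k: int = 5,
    grouping: str = "subject",
    seed: int = 0,
    stacking=None,
) -> EvalReport:
    """Selection + stacking CV restricted to each region's columns.

    Per region, Bonferroni selection runs over that region's feature
    family alone; if nothing survives, the region's raw (unselected)
    columns are used and flagged.  The report ranks regions by accuracy.
    """
    from .classify import StackedEEGClassifier, cross_validate
    from .selection import select_features

    report = EvalReport()
    report.meta.update({"kind": "region_ablation", "alpha": alpha, "k": k,
                        "grouping": grouping, "seed": seed})
    for region, _ in regions:
        cols = full_table.region_columns(region)
        if not cols:
            raise ValueError(f"no columns found for region {region!r}")
        sub = full_table.subset_columns(cols)
        sel, reduced = select_features(sub, alpha=alpha)
        no_features = reduced.n_features == 0
        use = sub if no_features else reduced
        proto = stacking if stacking is not None else StackedEEGClassifier(
            random_state=seed)
        sub_report = cross_validate(use, learners={"stacking": proto}, k=k,
                                    grouping=grouping, seed=seed,
                                    include_stacking=False)
        m = sub_report.models["stacking"]
        report.models[region] = {
            **m,
            "n_selected": sel.n_selected,
            "n_features_used": use.n_features,
            "no_selected_features": bool(no_features),
        }
    return report


def _relative_power_frame(
    table: FeatureTable,
    regions: RegionMap,
    bands: BandScheme,
) -> pd.DataFrame:
    """Long-format relative band powers per row × region × band.

    Relative power is the stored absolute band power divided by the
    stored total power of the same region.
    """
    recs = []
    for region, _ in regions:
        total = table.values[f"{region}__total_power"].to_numpy()
        for band in bands.band_names:
            col = f"{region}__{band}_power"
            rel = table.values[col].to_numpy() / total
            for i, v in enumerate(rel):
                recs.append({
                    "region": region, "band": band,
                    "group": table.labels.iloc[i], "relative_power": v,
                })
    return pd.DataFrame(recs)


def band_power_group_report(
    table: FeatureTable,
    regions: RegionMap = DEFAULT_REGION_MAP,
    bands: BandScheme = BANDS_STANDARD,
    figure_path=None,
):
    """Per region × band × group box-plot statistics with group p-values.

    Returns a DataFrame with median, Q1, Q3 (linear-interpolation
    quartiles), outliers beyond 1.5 IQR, and a two-sided Mann–Whitney
    p-value per region × band.  Optionally renders grouped box plots.
    """
    groups = set(table.labels)
    if not {"MDD", "HC"} <= groups:
        raise ValueError(f"need both groups, found {sorted(groups)}")
    long = _relative_power_frame(table, regions, bands)

    rows = []
    for (region, band), chunk in long.groupby(["region", "band"], sort=False):
        vals = {}
        for grp in ("HC", "MDD"):
            v = chunk.loc[chunk["group"] == grp, "relative_power"].to_numpy()
            q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interp
            iqr = q3 - q1
            outliers = v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]
            vals[grp] = (v, med, q1, q3, outliers)
        v_mdd, v_hc = vals["MDD"][0], vals["HC"][0]
        if np.ptp(np.concatenate([v_mdd, v_hc])) == 0:
            p = 1.0
        else:
            p = float(spstats.mannwhitneyu(
                v_mdd, v_hc, alternative="two-sided").pvalue)
        for grp in ("HC", "MDD"):
            v, med, q1, q3, outliers = vals[grp]
            rows.append({
                "region": region, "band": band, "group": grp,
                "median": med, "q1": q1, "q3": q3,
                "n": v.size, "n_outliers": outliers.size,
                "outliers": list(np.round(outliers, 6)),
                "mannwhitney_p": p,
                "quartile_method": "linear",
            })
    summary = pd.DataFrame(rows)

    if figure_path is not None:
        _render_band_boxplots(long, bands, figure_path)
    return summary


def _render_band_boxplots(long: pd.DataFrame, bands: BandScheme,
                          figure_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    band_names = bands.band_names
    fig, axes = plt.subplots(2, 3, figsize=(15, 8), sharey=False)
    for ax, band in zip(axes.ravel(), band_names):
        chunk = long[long["band"] == band]
        regions = chunk["region"].unique()
        data, positions, colors = [], [], []
        for ri, region in enumerate(regions):
            for gi, grp in enumerate(("HC", "MDD")):
                sel = chunk[(chunk["region"] == region) &
                            (chunk["group"] == grp)]
                data.append(sel["relative_power"].to_numpy())
                positions.append(ri * 2.5 + gi)
                colors.append("#7fbf7f" if grp == "HC" else "#e8c040")
        bp = ax.boxplot(data, positions=positions, widths=0.8,
                        patch_artist=True)
        for patch, color in zip(bp["boxes"], colors):
            patch.set_facecolor(color)
        ax.set_xticks([r * 2.5 + 0.5 for r in range(len(regions))])
        ax.set_xticklabels(regions, rotation=30, ha="right", fontsize=7)
        ax.set_title(band)
        ax.set_ylabel("relative power")
    fig.suptitle("Relative band power by region and group (green = HC, "
                 "yellow = MDD)")
    fig.tight_layout()
    fig.savefig(figure_path, dpi=120)
    plt.close(fig)
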