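"""Significance-routed two-group feature selection.

Each feature column is routed to a parametric or non-parametric two-group
test: Shapiro–Wilk normality in *both* groups and Levene variance
homogeneity (median-centered) must all hold at the gate level (0.05) for
one-way ANOVA; otherwise a two-sided Mann–Whitney U is used.  Raw p-values
are Bonferroni-adjusted over the tested family and a feature is selected
iff its adjusted p falls below alpha.

``SignificanceFeatureSelector`` wraps the same procedure as a
scikit-learn transformer so it can sit in a Pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .core import FeatureTable

__all__ = [
    "SelectionResult",
    "route_and_test",
    "bonferroni_adjust",
    "select_features",
    "SignificanceFeatureSelector",
]


@dataclass
class SelectionResult:
    """Per-feature routing decisions, p-values and selection flags."""

    table: pd.DataFrame  # one row per feature
    alpha: float
    n_tested: int

    COLUMNS = [
        "feature", "shapiro_p_mdd", "shapiro_p_hc", "levene_p",
        "test_used", "raw_p", "adjusted_p", "selected",
    ]

    @property
    def selected_features(self) -> list[str]:
        return self.table.loc[self.table["selected"], "feature"].tolist()

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def region_share(self) -> pd.DataFrame:
        """Share of selected features contributed by each region prefix."""
        sel = self.table[self.table["selected"]]
        if sel.empty:
            return pd.DataFrame(columns=["region", "n_selected", "share"])
        regions = sel["feature"].str.split("__").str[0]
        counts = regions.value_counts()
        out = pd.DataFrame({
            "region": counts.index,
            "n_selected": counts.values,
            "share": counts.values / counts.values.sum(),
        })
        return out.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, alpha: float = 0.05) -> "SelectionResult":
        t = pd.read_csv(path)
        return cls(table=t, alpha=alpha, n_tested=len(t))


def route_and_test(
    values_mdd: np.ndarray,
    values_hc: np.ndarray,
    alpha_assumption: float = 0.05,
) -> tuple[str, float]:
    """Choose ANOVA vs Mann–Whitney for one feature and return (test, p).

    The parametric branch requires Shapiro–Wilk p >= ``alpha_assumption``
    in both groups *and* Levene (median-centered) p >= it.  Degenerate
    (constant) groups fall through to Mann–Whitney.
    """
    a = np.asarray(values_mdd, dtype=float)
    b = np.asarray(values_hc, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    test, p, _ = _route_and_test_full(a, b, alpha_assumption)
    return test, p


def _route_and_test_full(
    a: np.ndarray, b: np.ndarray, gate: float
) -> tuple[str, float, tuple[float, float, float]]:
    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
    if degenerate:
        sw_a = sw_b = lev = np.nan
    else:
        sw_a = float(spstats.shapiro(a).pvalue)
        sw_b = float(spstats.shapiro(b).pvalue)
        lev = float(spstats.levene(a, b, center="median").pvalue)
    parametric = (not degenerate) and sw_a >= gate and sw_b >= gate and lev >= gate
    if parametric:
        p = float(spstats.f_oneway(a, b).pvalue)
        return "anova", p, (sw_a, sw_b, lev)
    if np.ptp(np.concatenate([a, b])) == 0:
        return "mann_whitney", 1.0, (sw_a, sw_b, lev)  # identical constants
    p = float(spstats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return "mann_whitney", p, (sw_a, sw_b, lev)


def bonferroni_adjust(raw_p: np.ndarray) -> np.ndarray:
    """Family-wise adjustment: adjusted_i = min(1, m · p_i)."""
    p = np.asarray(raw_p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    # statsmodels' bonferroni implements exactly min(1, m*p)
    return multipletests(p, method="bonferroni")[1] if p.size else p


def select_features(
    table: FeatureTable,
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
    method: str = "bonferroni",
    subject_mean: bool = False,
) -> tuple[SelectionResult, FeatureTable]:
    """Route-and-test every column, adjust, and keep the significant ones.

    ``subject_mean=True`` averages epochs within subject first, trading
    power for protection against pseudo-replication.  ``method`` may be
    ``"bonferroni"`` (default, family-wise) or ``"bh"``
    (Benjamini–Hochberg, off by default).
    """
    frame = table.values.copy()
    labels = table.labels.to_numpy()
    if subject_mean:
        df = frame.copy()
        df["__sid"] = table.subject_ids.to_numpy()
        df["__lab"] = labels
        agg = df.groupby("__sid").agg(
            {**{c: "mean" for c in frame.columns}, "__lab": "first"}
        )
        labels = agg["__lab"].to_numpy()
        frame = agg.drop(columns="__lab")
    groups = set(labels)
    if not {"MDD", "HC"} <= groups:
        raise ValueError(f"need both MDD and HC rows, found {sorted(groups)}")
    mdd = frame[labels == "MDD"]
    hc = frame[labels == "HC"]
    if len(mdd) < 3 or len(hc) < 3:
        raise ValueError("each group needs at least 3 rows")

    records = []
    for col in frame.columns:
        test, p, (sw_a, sw_b, lev) = _route_and_test_full(
            mdd[col].to_numpy(), hc[col].to_numpy(), gate_alpha
        )
        records.append((col, sw_a, sw_b, lev, test, p))
    raw = np.array([r[5] for r in records])
    if method == "bonferroni":
        adjusted = bonferroni_adjust(raw)
    elif method == "bh":
        adjusted = multipletests(raw, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    # alpha >= 1 is a vacuous threshold: keep everything, including
    # features whose adjusted p capped at exactly 1.0
    selected = adjusted < alpha if alpha < 1.0 else np.ones_like(
        adjusted, dtype=bool)

    result = SelectionResult(
        table=pd.DataFrame(
            [
                {
                    "feature": rec[0],
                    "shapiro_p_mdd": rec[1],
                    "shapiro_p_hc": rec[2],
                    "levene_p": rec[3],
                    "test_used": rec[4],
                    "raw_p": rec[5],
                    "adjusted_p": adj,
                    "selected": bool(sel),
                }
                for rec, adj, sel in zip(records, adjusted, selected)
            ]
        ),
        alpha=alpha,
        n_tested=len(records),
    )
    kept = [c for c, s in zip(frame.columns, selected) if s]
    reduced = table.subset_columns(kept) if kept else FeatureTable(
        table.values.iloc[:, :0], table.labels, table.subject_ids
    )
    return result, reduced


class SignificanceFeatureSelector(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer over the routing/Bonferroni selection.

    Parameters
    ----------
    alpha : float
        Significance level on the adjusted p-values.
    gate_alpha : float
        Gate level for the Shapiro–Wilk / Levene assumption tests.
    method : str
        ``"bonferroni"`` or ``"bh"``.

    Attributes (after ``fit``)
    --------------------------
    support_ : boolean mask of kept columns.
    pvalues_ : raw p-values per column.
    adjusted_pvalues_ : Bonferroni/BH-adjusted p-values.
    test_used_ : ``"anova"`` or ``"mann_whitney"`` per column.
    """

    def __init__(self, alpha: float = 0.05, gate_alpha: float = 0.05,
                 method: str = "bonferroni"):
        self.alpha = alpha
        self.gate_alpha = gate_alpha
        self.method = method

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("selector requires exactly two classes")
        a = X[y == classes.max()]
        b = X[y == classes.min()]
        tests, raw = [], []
        for j in range(X.shape[1]):
            t, p, _ = _route_and_test_full(a[:, j], b[:, j], self.gate_alpha)
            tests.append(t)
            raw.append(p)
        raw_arr = np.asarray(raw)
        if self.method == "bonferroni":
            adj = bonferroni_adjust(raw_arr)
        elif self.method == "bh":
            adj = multipletests(raw_arr, method="fdr_bh")[1]
        else:
            raise ValueError(f"unknown adjustment method {self.method!r}")
        self.n_features_in_ = X.shape[1]
        self.pvalues_ = raw_arr
        self.adjusted_pvalues_ = adj
        self.test_used_ = np.asarray(tests)
        self.support_ = (adj < self.alpha if self.alpha < 1.0
                         else np.ones_like(adj, dtype=bool))
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_.copy()
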