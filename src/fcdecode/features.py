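"""Per-series statistical features with FRESH-style relevance filtering.

A fixed, documented catalog of ten time-series statistics stands in for the
full tsfresh catalog: the selection machinery (per-feature hypothesis test
with Benjamini-Yekutieli FDR control) is the methodological content; the
catalog itself is kept small and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FEATURE_CATALOG = (
    "mean", "variance", "skewness", "kurtosis",
    "autocorr_lag1", "autocorr_lag2", "autocorr_lag3",
    "energy", "abs_sum_changes", "trend_slope",
)


def _autocorr(x: np.ndarray, lag: int) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x[lag:] @ x[:-lag]) / denom


def extract_features(series: np.ndarray) -> pd.DataFrame:
    """Catalog statistics for each row of ``series`` (n_samples, T)."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    rows = []
    for x in series:
        t = np.arange(x.size)
        slope = float(np.polyfit(t, x, 1)[0]) if x.size > 1 else 0.0
        rows.append({
            "mean": float(x.mean()),
            "variance": float(x.var(ddof=1)) if x.size > 1 else 0.0,
            "skewness": float(stats.skew(x)) if x.size > 2 else 0.0,
            "kurtosis": float(stats.kurtosis(x)) if x.size > 3 else 0.0,
            "autocorr_lag1": _autocorr(x, 1) if x.size > 1 else 0.0,
            "autocorr_lag2": _autocorr(x, 2) if x.size > 2 else 0.0,
            "autocorr_lag3": _autocorr(x, 3) if x.size > 3 else 0.0,
            "energy": float(x @ x),
            "abs_sum_changes": float(np.abs(np.diff(x)).sum()) if x.size > 1 else 0.0,
            "trend_slope": slope,
        })
    return pd.DataFrame(rows, columns=list(FEATURE_CATALOG))


@dataclass
class FreshSelection:
    """Outcome of FRESH-style relevance filtering."""

    table: pd.DataFrame  # feature, p, q, selected
    fdr_level: float
    empty: bool  # no feature survived

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "feature"])


def fresh_select(features: pd.DataFrame | np.ndarray, labels,
                 fdr_level: float = 0.05) -> FreshSelection:
    """Keep features whose Mann-Whitney relevance test survives
    Benjamini-Yekutieli FDR control at ``fdr_level`` (binary target)."""
    x = pd.DataFrame(features)
    y = np.asarray(labels)
    if x.shape[0] != y.size:
        raise ValueError("features and labels must have equal length")
    if x.shape[0] < 8:
        raise ValueError("relevance testing needs at least 8 samples")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class; relevance is undefined")
    if classes.size > 2:
        raise ValueError("fresh_select handles binary targets only")
    mask = y == classes[0]
    pvals = []
    for col in x.columns:
        a, b = x.loc[mask, col].to_numpy(), x.loc[~mask, col].to_numpy()
        if np.all(a == a[0]) and np.all(b == a[0]):
            pvals.append(1.0)  # constant feature carries no information
            continue
        try:
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        except ValueError:
            p = 1.0
        pvals.append(float(p))
    selected, q, _, _ = multipletests(pvals, alpha=fdr_level, method="fdr_by")
    table = pd.DataFrame({
        "feature": list(x.columns),
        "p": pvals,
        "q": q,
        "selected": selected,
    })
    if not selected.any():
        warnings.warn("no feature survived Benjamini-Yekutieli selection", stacklevel=2)
    return FreshSelection(table=table, fdr_level=fdr_level, empty=not selected.any())


def node_features_from_window(window_data: np.ndarray,
                              connectivity_row_profile: np.ndarray | None = None,
                              feature_subset: list[str] | None = None) -> np.ndarray:
    """Assemble the per-node feature matrix X for one graph sample.

    Each node gets the catalog statistics of its own window time-series,
    optionally restricted to a FRESH-selected subset, optionally concatenated
    with the node's connectivity profile (its row of the sample's
    connectivity matrix).
    """
    stats_df = extract_features(window_data.T)  # (N, 10)
    if feature_subset is not None:
        stats_df = stats_df[feature_subset]
    x = stats_df.to_numpy(dtype=float)
    if connectivity_row_profile is not None:
        x = np.concatenate([x, np.asarray(connectivity_row_profile, dtype=float)], axis=1)
    return x
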