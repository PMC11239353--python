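"""Shapley-value attribution of model predictions to input features.

The Shapley value of feature i is its marginal contribution to the model
output averaged over all feature subsets S with the combinatorial weight
|S|! (n - |S| - 1)! / n!. ``shap_exact`` enumerates all 2^n subsets (n <= 16);
``shap_sample`` is the Monte-Carlo permutation estimator for larger feature
sets. "Absent" features are handled by the caller's value function —
the helpers here build value functions that impute a background mean.

ROI-level aggregation follows the median-|phi| convention: edge attributions
are mapped to both endpoint ROIs and each ROI is ranked by the median of its
absolute scores across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .rois import RoiSet


@dataclass
class ShapAttribution:
    """Per-feature Shapley values with the efficiency bookkeeping."""

    phi: np.ndarray
    feature_names: list[str]
    baseline: float  # val(empty set)
    full_value: float  # val(all features)
    se: np.ndarray | None = None  # sampling standard errors (sampled mode)

    def efficiency_gap(self) -> float:
        return float(abs(self.phi.sum() - (self.full_value - self.baseline)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.feature_names, "phi": self.phi})
        if self.se is not None:
            df["se"] = self.se
        return df


def shap_exact(value_fn, n_features: int,
               feature_names: list[str] | None = None) -> ShapAttribution:
    """Exact Shapley values by subset enumeration.

    ``value_fn(mask)`` maps a boolean inclusion mask of length n to a scalar.
    """
    if n_features > 16:
        raise ValueError("n_features > 16: enumeration infeasible, use shap_sample")
    names = feature_names or [f"f{i}" for i in range(n_features)]
    all_idx = list(range(n_features))
    cache: dict[frozenset, float] = {}

    def val(subset: frozenset) -> float:
        if subset not in cache:
            mask = np.zeros(n_features, dtype=bool)
            mask[list(subset)] = True
            cache[subset] = float(value_fn(mask))
        return cache[subset]

    n_fact = factorial(n_features)
    phi = np.zeros(n_features)
    for i in all_idx:
        rest = [j for j in all_idx if j != i]
        for size in range(n_features):
            w = factorial(size) * factorial(n_features - size - 1) / n_fact
            for combo in combinations(rest, size):
                s = frozenset(combo)
                phi[i] += w * (val(s | {i}) - val(s))
    return ShapAttribution(phi=phi, feature_names=names,
                           baseline=val(frozenset()),
                           full_value=val(frozenset(all_idx)))


def shap_sample(value_fn, n_features: int, n_permutations: int = 200,
                seed: int = 0,
                feature_names: list[str] | None = None) -> ShapAttribution:
    """Monte-Carlo permutation estimate of the Shapley values.

    Each random feature ordering contributes one marginal per feature;
    the reported standard error is over orderings.
    """
    if n_permutations < 50:
        raise ValueError("use at least 50 permutations")
    names = feature_names or [f"f{i}" for i in range(n_features)]
    rng = np.random.default_rng(seed)
    mask = np.zeros(n_features, dtype=bool)
    baseline = float(value_fn(mask))
    full = float(value_fn(np.ones(n_features, dtype=bool)))
    marginals = np.zeros((n_permutations, n_features))
    for p in range(n_permutations):
        order = rng.permutation(n_features)
        mask[:] = False
        prev = baseline
        for i in order:
            mask[i] = True
            cur = float(value_fn(mask))
            marginals[p, i] = cur - prev
            prev = cur
    phi = marginals.mean(axis=0)
    se = marginals.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return ShapAttribution(phi=phi, feature_names=names, baseline=baseline,
                           full_value=full, se=se)


# ---------------------------------------------------------------------------
# value functions over connectivity inputs
# ---------------------------------------------------------------------------

def masked_matrix_value_fn(predict_fn, x: np.ndarray, background: np.ndarray,
                           roi_set: RoiSet, granularity: str = "roi"):
    """Value function over a single connectivity sample.

    Absent features are imputed with the background (training-set mean)
    matrix. granularity="roi": feature i masks every edge incident to ROI i
    (n features = N). granularity="edge": features are the upper-triangle
    edges (n = N(N-1)/2).
    """
    n = x.shape[0]
    iu = np.triu_indices(n, 1)

    if granularity == "roi":
        def value_fn(mask):
            xm = background.copy()
            keep = np.where(mask)[0]
            sub = np.ix_(keep, keep)
            xm[sub] = x[sub]
            return float(predict_fn(xm))
        return value_fn, list(roi_set.names)

    if granularity == "edge":
        names = [f"{roi_set.names[i]}--{roi_set.names[j]}" for i, j in zip(*iu)]

        def value_fn(mask):
            xm = background.copy()
            sel = np.where(mask)[0]
            ii, jj = iu[0][sel], iu[1][sel]
            xm[ii, jj] = x[ii, jj]
            xm[jj, ii] = x[jj, ii]
            return float(predict_fn(xm))
        return value_fn, names

    raise ValueError("granularity must be 'roi' or 'edge'")


def rank_rois(attributions: list[ShapAttribution], roi_set: RoiSet) -> pd.DataFrame:
    """Aggregate attributions to a ranked ROI table (median |phi|).

    Edge features contribute to both endpoint ROIs; rank ties are broken by
    ROI-table order (stable sort).
    """
    if not attributions:
        raise ValueError("no attributions supplied")
    scores: dict[str, list[float]] = {name: [] for name in roi_set.names}
    for att in attributions:
        for name, phi in zip(att.feature_names, att.phi):
            if "--" in name:
                a, b = name.split("--")
                scores[a].append(abs(phi))
                scores[b].append(abs(phi))
            else:
                scores[name].append(abs(phi))
    rows = [{"roi": name, "network": net,
             "median_abs_phi": float(np.median(scores[name])) if scores[name] else 0.0}
            for name, net in zip(roi_set.names, roi_set.networks)]
    df = pd.DataFrame(rows)
    df = df.sort_values("median_abs_phi", ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def dominant_rois(ranking: pd.DataFrame, per_network: int = 3) -> list[str]:
    """Top-k ROIs per network — the "dominant regions" of an analysis."""
    out = []
    for net in ("ToM", "Pain"):
        sub = ranking[ranking["network"] == net].head(per_network)
        out.extend(sub["roi"].tolist())
    return out
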