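"""FC and ISFC matrices per subject x window, and edge-level statistics.

FC is the within-subject Pearson correlation between ROI signals over an
event window. ISFC correlates one subject's ROI signal with the *average of
all other subjects'* signals over the same window (leave-one-out), then
symmetrizes; because only the stimulus-evoked component survives averaging
across brains, ISFC isolates stimulus-locked coupling and suppresses
intrinsic and noise coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import fisher_z
from .cohort import BoldTimeSeries
from .rois import EventWindow, RoiSet


class DegenerateSignalError(ValueError):
    """A ROI has zero variance inside the window."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """An N x N symmetric correlation matrix for one subject x window."""

    values: np.ndarray
    kind: str  # "FC" or "ISFC"
    subject_id: str
    window_label: str
    roi_set: RoiSet

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.roi_set)
        if v.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.max(np.abs(v)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        if self.kind not in ("FC", "ISFC"):
            raise ValueError("kind must be 'FC' or 'ISFC'")
        object.__setattr__(self, "values", v)

    def upper_values(self) -> np.ndarray:
        """The N(N-1)/2 unique off-diagonal edge values."""
        iu = np.triu_indices(self.values.shape[0], 1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_set.names,
                            columns=self.roi_set.names)


def edge_names(roi_set: RoiSet) -> list[str]:
    n = len(roi_set)
    iu = np.triu_indices(n, 1)
    return [f"{roi_set.names[i]}--{roi_set.names[j]}" for i, j in zip(*iu)]


def _zscore_window(x: np.ndarray, roi_set: RoiSet) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = [roi_set.names[i] for i in dead]
        raise DegenerateSignalError(f"zero-variance ROI(s) in window: {names}")
    return (x - x.mean(axis=0)) / sd


def compute_fc(ts: BoldTimeSeries, window: EventWindow) -> ConnectivityMatrix:
    """Pearson-correlation FC over one event window."""
    x = ts.window_data(window)
    if x.shape[0] < 3:
        raise ValueError("window must span at least 3 time points")
    z = _zscore_window(x, ts.roi_set)
    r = np.corrcoef(z, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, "FC", ts.subject_id, window.name, ts.roi_set)


def compute_isfc(cohort_ts: list[BoldTimeSeries],
                 window: EventWindow) -> list[ConnectivityMatrix]:
    """Leave-one-out ISFC for every subject over one window.

    For subject s, entry (i, j) is the Pearson correlation of s's ROI-i
    signal with the mean over all *other* subjects of their ROI-j signals;
    the resulting (generally asymmetric) matrix is symmetrized as
    (M + M^T) / 2.
    """
    if len(cohort_ts) < 2:
        raise ValueError("ISFC requires >=2 subjects")
    roi_set = cohort_ts[0].roi_set
    n = len(roi_set)
    for ts in cohort_ts:
        if ts.roi_set.names != roi_set.names:
            raise ValueError("all subjects must share the same ROI set")
    stack = np.stack([_zscore_window(ts.window_data(window), roi_set)
                      for ts in cohort_ts])  # (S, T, N)
    total = stack.sum(axis=0)
    out = []
    for s, ts in enumerate(cohort_ts):
        others = (total - stack[s]) / (len(cohort_ts) - 1)
        sd = others.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateSignalError("leave-one-out mean has a zero-variance ROI")
        a = stack[s]
        a = (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)
        b = (others - others.mean(axis=0)) / sd
        m = a.T @ b / (a.shape[0] - 1)
        m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
        out.append(ConnectivityMatrix(m, "ISFC", ts.subject_id, window.name, roi_set))
    return out


def average_matrices(matrices: list[ConnectivityMatrix],
                     fisher: bool = True) -> ConnectivityMatrix:
    """Entrywise mean, optionally through the Fisher z-transform."""
    if not matrices:
        raise ValueError("cannot average an empty list of matrices")
    stack = np.stack([m.values for m in matrices])
    if fisher:
        mean = np.tanh(np.mean(fisher_z(stack), axis=0))
    else:
        mean = stack.mean(axis=0)
    mean = (mean + mean.transpose()) / 2.0
    np.fill_diagonal(mean, 1.0)
    first = matrices[0]
    return ConnectivityMatrix(mean, first.kind, "group-mean",
                              first.window_label, first.roi_set)


def classify_edge_strength(value: float, band: float = 0.05) -> str:
    """Strong / moderate / weak connectivity relative to the 0.5 landmark."""
    if not -1.0 - 1e-9 <= value <= 1.0 + 1e-9:
        raise ValueError("correlation must lie in [-1, 1]")
    if band <= 0:
        raise ValueError("band must be positive")
    if abs(value - 0.5) <= band:
        return "moderate"
    return "strong" if value > 0.5 else "weak"


@dataclass
class EdgeStatTable:
    """Per-edge one-sample t statistics with FDR-adjusted decisions."""

    table: pd.DataFrame  # columns: edge, t, p, q, survives, strength_class
    alpha: float

    def n_surviving(self) -> int:
        return int(self.table["survives"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def edge_ttests(matrices: list[ConnectivityMatrix], alpha: float = 0.01,
                strength_band: float = 0.05) -> EdgeStatTable:
    """One-sample t-test of Fisher-z edge values against zero, per edge,
    with Benjamini-Hochberg FDR adjustment across the unique edges."""
    if len(matrices) < 3:
        raise ValueError("edge t-tests require at least 3 matrices")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    roi_set = matrices[0].roi_set
    z = fisher_z(np.stack([m.upper_values() for m in matrices]))  # (S, E)
    mean_r = np.tanh(z.mean(axis=0))
    sd = z.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_1samp(z, 0.0, axis=0)
    # constant nonzero edges: infinite evidence against the null
    t = np.where(degenerate, np.where(np.abs(z[0]) > 0, np.inf * np.sign(z[0]), 0.0), t)
    p = np.where(degenerate, np.where(np.abs(z[0]) > 0, 0.0, 1.0), p)
    survives, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    table = pd.DataFrame({
        "edge": edge_names(roi_set),
        "mean_r": mean_r,
        "t": t,
        "p": p,
        "q": q,
        "survives": q < alpha,
        "degenerate": degenerate,
        "strength_class": [classify_edge_strength(r, strength_band) for r in mean_r],
    })
    return EdgeStatTable(table=table, alpha=alpha)
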