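"""Synthetic movie-watching BOLD cohorts with the S + I + N structure.

Every subject's ROI signal inside an event window is a mixture

    x(t) = a * m_age * S(t)  +  b * I(t)  +  c * eps(t)

of three zero-mean components:

``S``   stimulus-evoked activity, drawn once per window from a multivariate
        normal whose covariance depends on the window's state (ToM or Pain)
        and *shared by every subject* — this is what inter-subject
        correlation methods lock onto;
``I``   intrinsic activity, drawn per subject with a correlation structure
        that carries the subject's false-belief performance group: the
        ToM<->Pain between-network block of the intrinsic correlation is set
        analytically so that the *observed* between-network correlation of
        the mixture lands on the group's coupling target (pass > 0.5,
        inconsistent ~ 0.5, fail < 0.5). Subject- and window-level Wishart
        jitter makes intrinsic coupling non-stationary, which corrupts FC
        but not ISFC;
``eps`` white measurement noise.

``m_age`` is an optional per-age-group multiplier on the stimulus weight,
modelling the weaker stimulus-locked responses of the youngest children.

The default cohort reproduces the study composition: 155 subjects, 122
children and 33 adults, with the children split 84 / 23 / 15 into
pass / inconsistent / fail false-belief groups. Adults are untested on the
task and carry the "pass" label as a placeholder; downstream performance
prediction excludes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._utils import (block_correlation, check_psd, nearest_correlation,
                     sample_wishart_correlation, spawn_rng)
from .rois import PAIN, TOM, EventWindow, RoiSet, default_rois, default_windows

GROUPS = ("pass", "inconsistent", "fail")

#: score range (correct answers out of 6 matched false-belief items) per group
GROUP_SCORES = {"pass": (5, 6), "inconsistent": (3, 4), "fail": (0, 2)}


class ConfigError(ValueError):
    """Inconsistent cohort configuration."""


class CovarianceError(ValueError):
    """A supplied covariance matrix is not symmetric PSD with unit diagonal."""


@dataclass(frozen=True)
class BoldTimeSeries:
    """One subject's T x N ROI signal with its event-window annotation."""

    subject_id: str
    data: np.ndarray  # (T, N)
    windows: tuple[EventWindow, ...]
    roi_set: RoiSet
    tr_seconds: float = 2.0

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("data must be a T x N matrix")
        if d.shape[1] != len(self.roi_set):
            raise ValueError(f"data has {d.shape[1]} columns but roi_set has {len(self.roi_set)}")
        if not np.all(np.isfinite(d)):
            raise ValueError("data contains missing/non-finite values")
        total = sum(w.length for w in self.windows)
        if self.windows and total != d.shape[0]:
            raise ValueError(f"windows span {total} time points but data has {d.shape[0]} rows")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "windows", tuple(self.windows))

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def window_data(self, window: EventWindow) -> np.ndarray:
        return self.data[window.start_tp:window.end_tp]


@dataclass(frozen=True)
class PerformanceLabel:
    """False-belief task outcome: group and (for children) the raw score."""

    group: str
    n_correct: int | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.n_correct is not None:
            lo, hi = GROUP_SCORES[self.group]
            if not (lo <= self.n_correct <= hi):
                raise ValueError(
                    f"n_correct={self.n_correct} outside the {self.group} range {lo}-{hi}")


class SubjectRecord(NamedTuple):
    timeseries: BoldTimeSeries
    label: PerformanceLabel
    age_group: str


def default_state_covariances(n_tom: int = 6, n_pain: int = 6) -> dict[str, np.ndarray]:
    """State-dependent stimulus covariances: the engaged network is tightly
    correlated (0.9), the other network weakly (0.1), between-network 0.05."""
    return {
        TOM: block_correlation(n_tom, n_pain, 0.9, 0.1, 0.05),
        PAIN: block_correlation(n_tom, n_pain, 0.1, 0.9, 0.05),
    }


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort (a pure function of this)."""

    n_subjects: int = 155
    #: children per false-belief group; adults are counted via age_groups
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"pass": 84, "inconsistent": 23, "fail": 15})
    age_groups: dict[str, int] = field(
        default_factory=lambda: {"3-4yr": 44, "5-12yr": 78, "adult": 33})
    #: (a, b, c) weights of stimulus / intrinsic / noise components
    mix_weights: tuple[float, float, float] = (0.40, 1.0, 0.2)
    state_covariances: dict[str, np.ndarray] | None = None
    intrinsic_covariance: np.ndarray | None = None
    #: observed ToM<->Pain correlation targets per group (None disables injection)
    group_coupling: dict[str, float] | None = field(
        default_factory=lambda: {"pass": 0.8, "inconsistent": 0.5, "fail": 0.2})
    #: stimulus-weight multiplier per age group (age effect on decodability)
    snr_multipliers: dict[str, float] = field(
        default_factory=lambda: {"3-4yr": 0.55, "5-12yr": 1.0, "adult": 1.0})
    #: Wishart degrees of freedom for subject- and window-level intrinsic jitter
    subject_df: int = 60
    window_df: int = 30
    roi_set: RoiSet = field(default_factory=default_rois)
    windows: tuple[EventWindow, ...] | None = None
    seed: int = 0

    def resolved_windows(self) -> tuple[EventWindow, ...]:
        return tuple(self.windows) if self.windows is not None else tuple(default_windows())

    def resolved_state_covariances(self) -> dict[str, np.ndarray]:
        n_tom = len(self.roi_set.indices(TOM))
        n_pain = len(self.roi_set.indices(PAIN))
        covs = self.state_covariances or default_state_covariances(n_tom, n_pain)
        for label, cov in covs.items():
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (len(self.roi_set),) * 2:
                raise CovarianceError(f"state covariance {label} has shape {cov.shape}")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise CovarianceError(f"state covariance {label} is not symmetric")
            if not np.allclose(np.diag(cov), 1.0, atol=1e-8):
                raise CovarianceError(f"state covariance {label} must have unit diagonal")
            if not check_psd(cov):
                raise CovarianceError(f"state covariance {label} is not PSD")
        return {k: np.asarray(v, dtype=float) for k, v in covs.items()}

    def resolved_intrinsic(self) -> np.ndarray:
        n = len(self.roi_set)
        if self.intrinsic_covariance is None:
            n_tom = len(self.roi_set.indices(TOM))
            return block_correlation(n_tom, n - n_tom, 0.5, 0.5, 0.3)
        cov = np.asarray(self.intrinsic_covariance, dtype=float)
        if cov.shape != (n, n):
            raise CovarianceError(f"intrinsic covariance has shape {cov.shape}, expected {(n, n)}")
        if not np.allclose(cov, cov.T, atol=1e-10) or not check_psd(cov):
            raise CovarianceError("intrinsic covariance must be symmetric PSD")
        return cov

    def validate(self) -> None:
        a, b, c = self.mix_weights
        if min(a, b, c) < 0:
            raise ConfigError("mix_weights must be non-negative")
        n_children = sum(self.group_sizes.values())
        n_adults = self.age_groups.get("adult", 0)
        if n_children + n_adults != self.n_subjects:
            raise ConfigError(
                f"group sizes ({n_children} children) + adults ({n_adults}) "
                f"!= n_subjects ({self.n_subjects})")
        if sum(self.age_groups.values()) != self.n_subjects:
            raise ConfigError("age_groups must sum to n_subjects")
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ConfigError(f"unknown performance group {g!r}")
        self.resolved_state_covariances()
        self.resolved_intrinsic()


def _coupled_intrinsic(base: np.ndarray, roi_set: RoiSet, target: float,
                       a_eff: float, b: float, c: float, s_between: float) -> np.ndarray:
    """Intrinsic correlation whose mixture with S and noise has the target
    observed ToM<->Pain correlation.

    Observed between-network correlation of the mixture is
    (a^2 s_bn + b^2 i_bn) / (a^2 + b^2 + c^2); solve for i_bn and rebuild the
    intrinsic matrix as a two-block compound-symmetric correlation with a
    within-network level high enough to stay PSD.
    """
    total = a_eff**2 + b**2 + c**2
    i_bn = (target * total - a_eff**2 * s_between) / b**2
    i_bn = float(np.clip(i_bn, -0.9, 0.95))
    n_tom = len(roi_set.indices(TOM))
    n_pain = len(roi_set) - n_tom
    tom_idx = roi_set.indices(TOM)
    base_within = float(np.mean(base[np.ix_(tom_idx, tom_idx)][np.triu_indices(n_tom, 1)]))
    # compound-symmetry PSD bound for the between-block level, with margin
    k = max(n_tom, n_pain)
    psd_floor = (k * abs(i_bn) - 1.0) / (k - 1.0) + 0.05
    i_wn = float(np.clip(max(base_within, psd_floor, i_bn + 0.05), 0.05, 0.97))
    return block_correlation(n_tom, n_pain, i_wn, i_wn, i_bn)


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw a full cohort; bitwise-deterministic in ``config.seed``."""
    config.validate()
    a, b, c = config.mix_weights
    roi_set = config.roi_set
    n = len(roi_set)
    windows = config.resolved_windows()
    state_cov = config.resolved_state_covariances()
    base_intrinsic = config.resolved_intrinsic()
    tom_idx = roi_set.indices(TOM)
    pain_idx = roi_set.indices(PAIN)
    s_between = (float(np.mean(state_cov[TOM][np.ix_(tom_idx, pain_idx)]))
                 if TOM in state_cov and tom_idx and pain_idx else 0.0)

    # shared stimulus component: one draw per window, common to all subjects
    stim_rng = spawn_rng(config.seed, "cohort", "stimulus")
    chol = {k: np.linalg.cholesky(v + 1e-10 * np.eye(n)) for k, v in state_cov.items()}
    shared_s = [stim_rng.standard_normal((w.length, n)) @ chol[w.label].T for w in windows]

    # deterministic group / age assignment, then shuffled independently
    groups = [g for g in GROUPS for _ in range(config.group_sizes.get(g, 0))]
    child_ages = [ag for ag, cnt in config.age_groups.items() if ag != "adult"
                  for _ in range(cnt)]
    assign_rng = spawn_rng(config.seed, "cohort", "assignment")
    assign_rng.shuffle(groups)
    assign_rng.shuffle(child_ages)
    ages = child_ages + ["adult"] * config.age_groups.get("adult", 0)
    groups = groups + ["pass"] * config.age_groups.get("adult", 0)

    total_tp = sum(w.length for w in windows)
    cohort: list[SubjectRecord] = []
    for s_idx, (group, age) in enumerate(zip(groups, ages)):
        rng = spawn_rng(config.seed, "cohort", f"subject-{s_idx}")
        a_eff = a * config.snr_multipliers.get(age, 1.0)
        if b > 0 and config.group_coupling and group in config.group_coupling:
            sigma_i = _coupled_intrinsic(base_intrinsic, roi_set,
                                         config.group_coupling[group],
                                         a_eff, b, c, s_between)
            sigma_i = sample_wishart_correlation(rng, sigma_i, config.subject_df)
        else:
            sigma_i = base_intrinsic
        data = np.empty((total_tp, n))
        for w, s_w in zip(windows, shared_s):
            x = a_eff * s_w
            if b > 0:
                sig_w = sample_wishart_correlation(rng, sigma_i, config.window_df)
                chol_w = np.linalg.cholesky(sig_w + 1e-10 * np.eye(n))
                x = x + b * (rng.standard_normal((w.length, n)) @ chol_w.T)
            if c > 0:
                x = x + c * rng.standard_normal((w.length, n))
            data[w.start_tp:w.end_tp] = x
        if age == "adult":
            n_correct = None
        else:
            lo, hi = GROUP_SCORES[group]
            n_correct = int(rng.integers(lo, hi + 1))
        cohort.append(SubjectRecord(
            BoldTimeSeries(f"sub-{s_idx:03d}", data, windows, roi_set),
            PerformanceLabel(group, n_correct),
            age,
        ))
    return cohort


def children(cohort: list[SubjectRecord]) -> list[SubjectRecord]:
    """The behaviourally tested subset (performance prediction uses these only)."""
    return [r for r in cohort if r.age_group != "adult"]


# ---------------------------------------------------------------------------
# on-disk format: one TSV per subject, metadata + window schedule + manifest
# ---------------------------------------------------------------------------

class CohortIOError(ValueError):
    pass


def write_cohort(cohort: list[SubjectRecord], directory: str | Path) -> Path:
    directory = Path(directory)
    (directory / "series").mkdir(parents=True, exist_ok=True)
    if not cohort:
        raise CohortIOError("cannot write an empty cohort")
    roi_set = cohort[0].timeseries.roi_set
    windows = cohort[0].timeseries.windows

    pd.DataFrame({
        "label": [w.label for w in windows],
        "start": [w.start_tp for w in windows],
        "end": [w.end_tp for w in windows],
        "description": [w.description for w in windows],
    }).to_csv(directory / "windows.tsv", sep="\t", index=False)

    meta = pd.DataFrame({
        "subject_id": [r.timeseries.subject_id for r in cohort],
        "age_group": [r.age_group for r in cohort],
        "group": [r.label.group for r in cohort],
        "n_correct": [r.label.n_correct if r.label.n_correct is not None else ""
                      for r in cohort],
    })
    meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)

    for r in cohort:
        df = pd.DataFrame(r.timeseries.data, columns=list(roi_set.names))
        # default float formatting is shortest-round-trip repr: exact reload
        df.to_csv(directory / "series" / f"{r.timeseries.subject_id}.tsv",
                  sep="\t", index=False)

    manifest = {
        "format": "fcdecode-cohort/1",
        "n_subjects": len(cohort),
        "tr_seconds": cohort[0].timeseries.tr_seconds,
        "roi_names": list(roi_set.names),
        "roi_networks": list(roi_set.networks),
        "roi_mni": [list(m) for m in roi_set.mni],
        "subjects": [r.timeseries.subject_id for r in cohort],
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_cohort(directory: str | Path) -> list[SubjectRecord]:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise CohortIOError(f"no cohort manifest found in {directory}")
    manifest = json.loads(manifest_path.read_text())
    roi_set = RoiSet(
        names=tuple(manifest["roi_names"]),
        networks=tuple(manifest["roi_networks"]),
        mni=tuple(tuple(m) for m in manifest["roi_mni"]),
    )
    wdf = pd.read_csv(directory / "windows.tsv", sep="\t", keep_default_na=False)
    windows = tuple(EventWindow(r.label, int(r.start), int(r.end), str(r.description))
                    for r in wdf.itertuples())
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t",
                       dtype={"subject_id": str}, keep_default_na=False)
    meta_ids = list(meta["subject_id"])
    if sorted(meta_ids) != sorted(manifest["subjects"]):
        raise CohortIOError("metadata subjects do not match the manifest subject list")
    cohort = []
    for row in meta.itertuples():
        series_path = directory / "series" / f"{row.subject_id}.tsv"
        if not series_path.exists():
            raise CohortIOError(f"series file missing for subject {row.subject_id}")
        try:
            df = pd.read_csv(series_path, sep="\t", float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise CohortIOError(f"malformed series file {series_path}: {exc}") from exc
        if list(df.columns) != list(roi_set.names):
            raise CohortIOError(f"{series_path}: columns do not match ROI names")
        n_correct = None if row.n_correct == "" else int(float(row.n_correct))
        cohort.append(SubjectRecord(
            BoldTimeSeries(row.subject_id, df.to_numpy(dtype=float), windows, roi_set,
                           tr_seconds=float(manifest["tr_seconds"])),
            PerformanceLabel(row.group, n_correct),
            row.age_group,
        ))
    return cohort
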