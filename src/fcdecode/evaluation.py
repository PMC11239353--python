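"""Validation protocols and end-to-end experiments.

Splits are *subject-level*: all event windows of a subject stay on one side
of every split, preventing leakage of subject-specific structure between
train and test. Repeated 80:20 shuffles (10 by default) follow the
floor(0.8 N) train-size rule; five-fold cross-validation partitions subjects
into disjoint folds; leave-one-out holds out one subject at a time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import KFold, StratifiedKFold, StratifiedShuffleSplit

from ._utils import spawn_rng
from .cohort import CohortConfig, SubjectRecord, children, generate_cohort
from .connectivity import ConnectivityMatrix, average_matrices, compute_fc, compute_isfc
from .decoder import ChebNetDecoder, DecoderConfig
from .features import node_features_from_window
from .graphs import BrainGraph, to_adjacency
from .rois import TOM, RoiSet
from .vae import ConnectivityVAE, VaeConfig, train_group_classifier

#: the eight regions with the highest median attribution scores across the
#: FC and ISFC analyses (union of three dominant ROIs per network per run)
DOMINANT_8 = ("LTPJ", "RTPJ", "PCC", "vmPFC", "LII", "RII", "LMFG", "RMFG")


@dataclass(frozen=True)
class SplitPlan:
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    repeat_index: int
    scheme: str
    seed: int

    def __post_init__(self):
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError("subject leakage: train and test overlap")


def make_splits(subject_ids, scheme: str = "repeated_8020", seed: int = 0,
                n_repeats: int = 10, labels=None) -> list[SplitPlan]:
    """Subject-level split plans for a scheme in {repeated_8020, kfold5, loo}."""
    ids = np.asarray(subject_ids)
    n = ids.size
    y = None if labels is None else np.asarray(labels)
    plans = []
    if scheme == "repeated_8020":
        if n < 2:
            raise ValueError("need at least 2 subjects")
        n_train = int(np.floor(0.8 * n))
        for rep in range(n_repeats):
            rng = spawn_rng(seed, "split", f"rep-{rep}")
            rs = int(rng.integers(0, 2**31 - 1))
            if y is not None:
                sss = StratifiedShuffleSplit(n_splits=1, train_size=n_train,
                                             random_state=rs)
                tr, te = next(sss.split(ids, y))
            else:
                perm = np.random.default_rng(rs).permutation(n)
                tr, te = perm[:n_train], perm[n_train:]
            plans.append(SplitPlan(tuple(ids[tr]), tuple(ids[te]), rep,
                                   scheme, seed))
    elif scheme == "kfold5":
        if n < 5:
            raise ValueError("five-fold CV needs at least 5 subjects")
        rs = int(spawn_rng(seed, "split", "kfold").integers(0, 2**31 - 1))
        splitter = (StratifiedKFold(5, shuffle=True, random_state=rs) if y is not None
                    else KFold(5, shuffle=True, random_state=rs))
        for rep, (tr, te) in enumerate(splitter.split(ids, y)):
            plans.append(SplitPlan(tuple(ids[tr]), tuple(ids[te]), rep, scheme, seed))
    elif scheme == "loo":
        if n < 2:
            raise ValueError("leave-one-out needs at least 2 subjects")
        for rep in range(n):
            mask = np.arange(n) != rep
            plans.append(SplitPlan(tuple(ids[mask]), (str(ids[rep]),), rep,
                                   scheme, seed))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return plans


@dataclass
class EvalReport:
    accuracy: float
    per_class: pd.DataFrame  # class, precision, recall, f1, support
    macro_f1: float
    macro_precision: float
    macro_recall: float
    confusion: np.ndarray
    classes: np.ndarray
    roc_points: pd.DataFrame | None = None
    pr_points: pd.DataFrame | None = None


def compute_metrics(predictions, truths, scores=None) -> EvalReport:
    """Accuracy, per-class and macro precision/recall/F1, confusion matrix;
    ROC and precision-recall curves when scores are supplied (one-vs-rest
    macro treatment for more than two classes)."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.size != true.size:
        raise ValueError("predictions and truths must have equal length")
    classes = np.unique(np.concatenate([true, pred]))
    conf = skm.confusion_matrix(true, pred, labels=classes)
    prec, rec, f1, supp = skm.precision_recall_fscore_support(
        true, pred, labels=classes, zero_division=0)
    per_class = pd.DataFrame({"class": classes, "precision": prec, "recall": rec,
                              "f1": f1, "support": supp})
    roc_df = pr_df = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        roc_rows, pr_rows = [], []
        if scores.ndim == 1:
            scores = np.column_stack([1 - scores, scores])
        if scores.shape[1] != classes.size:
            scores = None  # a class absent from this fold: curves undefined
    if scores is not None:
        for ci, cls in enumerate(classes):
            y_bin = (true == cls).astype(int)
            if y_bin.min() == y_bin.max():
                continue
            fpr, tpr, _ = skm.roc_curve(y_bin, scores[:, ci])
            p, r, _ = skm.precision_recall_curve(y_bin, scores[:, ci])
            roc_rows.append(pd.DataFrame({"class": cls, "fpr": fpr, "tpr": tpr}))
            pr_rows.append(pd.DataFrame({"class": cls, "precision": p[:-1],
                                         "recall": r[:-1]}))
        if roc_rows:
            roc_df = pd.concat(roc_rows, ignore_index=True)
            pr_df = pd.concat(pr_rows, ignore_index=True)
    return EvalReport(
        accuracy=float(np.trace(conf) / conf.sum()),
        per_class=per_class,
        macro_f1=float(f1.mean()),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        confusion=conf,
        classes=classes,
        roc_points=roc_df,
        pr_points=pr_df,
    )


# ---------------------------------------------------------------------------
# dataset builders
# ---------------------------------------------------------------------------

def _subset_cohort(cohort: list[SubjectRecord], roi_names) -> list[SubjectRecord]:
    if roi_names is None:
        return cohort
    roi_set = cohort[0].timeseries.roi_set
    idx = [roi_set.names.index(n) for n in roi_names]
    sub = roi_set.subset(list(roi_names))
    out = []
    for r in cohort:
        ts = r.timeseries
        out.append(SubjectRecord(
            type(ts)(ts.subject_id, ts.data[:, idx], ts.windows, sub,
                     ts.tr_seconds), r.label, r.age_group))
    return out


def connectivity_by_window(cohort: list[SubjectRecord],
                           kind: str = "ISFC") -> list[list[ConnectivityMatrix]]:
    """matrices[w][s]: window-w connectivity of subject s."""
    windows = cohort[0].timeseries.windows
    if kind == "FC":
        return [[compute_fc(r.timeseries, w) for r in cohort] for w in windows]
    if kind == "ISFC":
        ts = [r.timeseries for r in cohort]
        return [compute_isfc(ts, w) for w in windows]
    raise ValueError("kind must be 'FC' or 'ISFC'")


@dataclass
class DecodingDataset:
    """Graph samples (one per subject x window) for the state decoder."""

    graphs: list[BrainGraph]
    state_labels: np.ndarray  # window state per sample
    subject_ids: np.ndarray
    age_groups: np.ndarray
    kind: str
    roi_set: RoiSet

    def subject_index(self, subjects) -> np.ndarray:
        keep = set(subjects)
        return np.where([s in keep for s in self.subject_ids])[0]


def build_decoding_dataset(cohort: list[SubjectRecord], kind: str = "ISFC",
                           roi_subset=None, adjacency_mode: str = "abs",
                           standardize_features: bool = True) -> DecodingDataset:
    """Connectivity -> adjacency -> BrainGraph with node features.

    Node features concatenate the catalog statistics of each node's window
    time-series with the node's connectivity profile (its matrix row);
    feature columns are z-scored across samples (label-free).
    """
    cohort = _subset_cohort(cohort, roi_subset)
    windows = cohort[0].timeseries.windows
    roi_set = cohort[0].timeseries.roi_set
    mats = connectivity_by_window(cohort, kind)
    graphs, labels, subs, ages = [], [], [], []
    feats = []
    for wi, w in enumerate(windows):
        for si, r in enumerate(cohort):
            m = mats[wi][si]
            x = node_features_from_window(r.timeseries.window_data(w),
                                          m.values)
            feats.append(x)
            graphs.append((m, x))
            labels.append(w.label)
            subs.append(r.timeseries.subject_id)
            ages.append(r.age_group)
    feats = np.stack(feats)  # (n, N, F)
    if standardize_features:
        mu = feats.mean(axis=(0, 1))
        sd = feats.std(axis=(0, 1)) + 1e-12
        feats = (feats - mu) / sd
    built = [BrainGraph(to_adjacency(m, adjacency_mode), node_features=f)
             for (m, _), f in zip(graphs, feats)]
    return DecodingDataset(built, np.array(labels), np.array(subs),
                           np.array(ages), kind, roi_set)


def window_connectivity_stack(cohort: list[SubjectRecord], kind: str = "ISFC",
                              roi_subset=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All subject x window connectivity matrices as one stack.

    Returns (matrices (n_subj * n_windows, N, N), group labels, subject ids),
    ordered subject-major.
    """
    cohort = _subset_cohort(cohort, roi_subset)
    mats = connectivity_by_window(cohort, kind)
    out, groups, ids = [], [], []
    for si, r in enumerate(cohort):
        for wi in range(len(mats)):
            out.append(mats[wi][si].values)
            groups.append(r.label.group)
            ids.append(r.timeseries.subject_id)
    return np.stack(out), np.array(groups), np.array(ids)


def subject_mean_connectivity(cohort: list[SubjectRecord], kind: str = "ISFC",
                              roi_subset=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject Fisher-z mean connectivity across all windows.

    Returns (matrices (n, N, N), group labels, subject ids).
    """
    cohort = _subset_cohort(cohort, roi_subset)
    mats = connectivity_by_window(cohort, kind)
    out, groups, ids = [], [], []
    for si, r in enumerate(cohort):
        mean = average_matrices([mats[wi][si] for wi in range(len(mats))], fisher=True)
        out.append(mean.values)
        groups.append(r.label.group)
        ids.append(r.timeseries.subject_id)
    return np.stack(out), np.array(groups), np.array(ids)


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

ROI_PRESETS = {"all12": None, "dominant8": DOMINANT_8, "tom6": "tom"}


@dataclass
class ExperimentConfig:
    feature_kind: str = "ISFC"  # FC | ISFC
    roi_preset: str = "all12"  # all12 | dominant8 | tom6
    model: str = "stgcnn"  # stgcnn | cvae
    split_scheme: str = "repeated_8020"
    n_repeats: int = 10
    seed: int = 0
    cohort: CohortConfig | None = None
    decoder: DecoderConfig | None = None
    vae: VaeConfig | None = None
    out_dir: str | None = None

    def resolve_rois(self, roi_set: RoiSet):
        if self.roi_preset not in ROI_PRESETS:
            raise ValueError(f"unknown ROI preset {self.roi_preset!r}")
        preset = ROI_PRESETS[self.roi_preset]
        if preset == "tom":
            return tuple(n for n, net in zip(roi_set.names, roi_set.networks)
                         if net == TOM)
        return preset


def run_experiment(config: ExperimentConfig) -> dict:
    """generate -> features -> graphs -> train -> evaluate, per split.

    Returns a dict with per-repeat metrics and their mean +/- sd; writes a
    self-contained results directory when ``config.out_dir`` is set.
    """
    cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
    cohort = generate_cohort(cohort_cfg)
    roi_subset = config.resolve_rois(cohort_cfg.roi_set)

    per_repeat = []
    if config.model == "stgcnn":
        ds = build_decoding_dataset(cohort, config.feature_kind, roi_subset)
        subjects = np.unique(ds.subject_ids)
        subj_state = None  # state labels are within-subject; no stratification key
        plans = make_splits(subjects, config.split_scheme, config.seed,
                            config.n_repeats, labels=subj_state)
        for plan in plans:
            tr = ds.subject_index(plan.train_subjects)
            te = ds.subject_index(plan.test_subjects)
            dcfg = config.decoder or DecoderConfig()
            dcfg.seed = config.seed + plan.repeat_index
            model = ChebNetDecoder(ds.graphs, ds.state_labels, ds.subject_ids, dcfg)
            res = model.fit(train_idx=tr)
            probs = res.predict_proba(te)
            pred = res.predict(te)
            rep = compute_metrics(pred, ds.state_labels[te], scores=probs)
            per_repeat.append(rep)
    elif config.model == "cvae":
        kids = children(cohort)
        mats, groups, ids = window_connectivity_stack(kids, config.feature_kind,
                                                      roi_subset)
        subjects = np.unique(ids)
        subj_group = np.array([groups[ids == s][0] for s in subjects])
        plans = make_splits(subjects, config.split_scheme, config.seed,
                            config.n_repeats, labels=subj_group)
        for plan in plans:
            vcfg = config.vae or VaeConfig()
            vcfg.seed = config.seed + plan.repeat_index
            tr = np.where(np.isin(ids, plan.train_subjects))[0]
            vae = ConnectivityVAE(mats[tr], vcfg)
            fit = vae.fit()
            clf = train_group_classifier(fit.latent_means(), groups[tr],
                                         seed=config.seed + plan.repeat_index)
            # subject-level prediction: average window scores, then argmax
            pred, true, scores = [], [], []
            for s in plan.test_subjects:
                z = fit.latent_means(mats[ids == s])
                sc = clf.predict_scores(z).mean(axis=0)
                pred.append(clf.classes_[int(np.argmax(sc))])
                true.append(subj_group[subjects == s][0])
                scores.append(sc)
            scores = np.array(scores)
            # align score columns with compute_metrics' sorted class order
            order = np.argsort(clf.classes_)
            rep = compute_metrics(np.array(pred), np.array(true),
                                  scores=scores[:, order])
            per_repeat.append(rep)
    else:
        raise ValueError(f"unknown model {config.model!r}")

    accs = np.array([r.accuracy for r in per_repeat])
    f1s = np.array([r.macro_f1 for r in per_repeat])
    result = {
        "config": {
            "feature_kind": config.feature_kind,
            "roi_preset": config.roi_preset,
            "model": config.model,
            "split_scheme": config.split_scheme,
            "n_repeats": len(per_repeat),
            "seed": config.seed,
        },
        "per_repeat_accuracy": accs.tolist(),
        "per_repeat_macro_f1": f1s.tolist(),
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        "mean_macro_f1": float(f1s.mean()),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(result, indent=2))
        rows = [{"repeat": i, "accuracy": r.accuracy, "macro_f1": r.macro_f1,
                 "macro_precision": r.macro_precision, "macro_recall": r.macro_recall}
                for i, r in enumerate(per_repeat)]
        pd.DataFrame(rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
    result["reports"] = per_repeat
    return result
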