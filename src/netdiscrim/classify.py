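"""SVM classification of tumor phenotype from three signature types.

Per-sample features come from (1) raw expression of a differential-gene
signature, (2) mean z-scored activity of discovered subnetworks, or
(3) a per-sample hub co-expression score f_h(j) = mean over partners p
of z_h(j) * z_p(j), whose group means recover the group-wise hub-partner
correlations.  A linear-kernel SVM is evaluated either by repeated
random 2/3-1/3 splits (default, 50 repeats) or k-fold cross-validation,
with AUC from held-out decision values; features are standardized on
the training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ExpressionDataset
from .subnet import ScoredSubnetwork, subnetwork_activity

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "build_features",
    "evaluate",
    "cross_dataset_evaluate",
]


@dataclass
class FeatureMatrix:
    """Samples-by-features design matrix with binary phenotype labels."""

    values: np.ndarray  # samples x features
    feature_ids: list[str]
    sample_ids: list[str]
    y: np.ndarray  # 1 = case phenotype
    signature: str

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class ClassificationReport:
    signature: str
    aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    roc_points: pd.DataFrame  # fpr, tpr pooled over held-out predictions
    repeats: int
    train_frac: float
    rng_seed: int
    scheme: str = "mccv"


def _zscore_rows(ds: ExpressionDataset, genes: list[str]) -> np.ndarray:
    x = ds.values.loc[genes].to_numpy()
    sd = x.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def build_features(
    ds: ExpressionDataset,
    signature: str,
    *,
    de_genes: list[str] | None = None,
    subnetworks: list[ScoredSubnetwork] | None = None,
    hub_scores=None,
    graph=None,
) -> FeatureMatrix:
    """Assemble the per-sample design matrix for one signature type.

    ``signature`` is one of ``de_genes`` (raw expression rows),
    ``subnetworks`` (mean member z-score per subnetwork) or ``hubs``
    (mean partner-product of z-scores per hub).  Signature elements
    whose genes are absent from the dataset are dropped with a warning;
    if everything drops out this is an error.
    """
    import warnings

    measured = set(ds.values.index)
    if signature == "de_genes":
        if not de_genes:
            raise ValueError("empty differential-gene signature")
        kept = [g for g in de_genes if g in measured]
        if len(kept) < len(de_genes):
            warnings.warn(
                f"{len(de_genes) - len(kept)} signature gene(s) unmeasured, dropped",
                stacklevel=2,
            )
        if not kept:
            raise ValueError("no signature gene measured")
        x = ds.values.loc[kept].to_numpy().T
        ids = list(kept)
    elif signature == "subnetworks":
        if not subnetworks:
            raise ValueError("empty subnetwork signature")
        from .diffexpr import zscore_normalize

        zds = zscore_normalize(ds)
        cols, ids = [], []
        for sn in subnetworks:
            members = [m for m in sn.members if m in zds.values.index]
            if not members:
                warnings.warn(f"subnetwork {sn.seed} fully unmeasured, dropped",
                              stacklevel=2)
                continue
            cols.append(subnetwork_activity(zds, members))
            ids.append(f"subnet:{sn.seed}")
        if not cols:
            raise ValueError("no subnetwork with measured members")
        x = np.column_stack(cols)
    elif signature == "hubs":
        if not hub_scores:
            raise ValueError("empty hub signature")
        from .diffexpr import zscore_normalize

        zds = zscore_normalize(ds)
        cols, ids = [], []
        for hs in hub_scores:
            hub = hs.hub if hasattr(hs, "hub") else str(hs)
            partners = (
                list(hs.partners)
                if hasattr(hs, "partners")
                else sorted(graph.neighbors(hub))
            )
            if hub not in zds.values.index:
                warnings.warn(f"hub {hub} unmeasured, dropped", stacklevel=2)
                continue
            partners = [p for p in partners if p in zds.values.index]
            if not partners:
                warnings.warn(f"hub {hub} has no measured partners, dropped",
                              stacklevel=2)
                continue
            h = zds.values.loc[hub].to_numpy()
            pmat = zds.values.loc[partners].to_numpy()
            cols.append((pmat * h).mean(axis=0))
            ids.append(f"hub:{hub}")
        if not cols:
            raise ValueError("no usable hub feature")
        x = np.column_stack(cols)
    else:
        raise ValueError(f"unknown signature type {signature!r}")

    y = ds.case_mask.astype(int)
    return FeatureMatrix(
        values=np.asarray(x, dtype=float),
        feature_ids=ids,
        sample_ids=list(ds.values.columns),
        y=y,
        signature=signature,
    )


def _fit_score(
    x_tr: np.ndarray, y_tr: np.ndarray, x_te: np.ndarray, cost: float
) -> np.ndarray:
    scaler = StandardScaler().fit(x_tr)
    clf = SVC(kernel="linear", C=cost).fit(scaler.transform(x_tr), y_tr)
    return clf.decision_function(scaler.transform(x_te))


def evaluate(
    fm: FeatureMatrix,
    repeats: int = 50,
    train_frac: float = 2 / 3,
    rng_seed: int = 0,
    *,
    cost: float = 1.0,
    scheme: str = "mccv",
) -> ClassificationReport:
    """Repeated-random-split (or k-fold) evaluation of a linear SVM.

    Each repeat trains on a random ``train_frac`` of samples and scores
    AUC on the rest; splits lacking a class in training are redrawn.
    ``scheme='kfold'`` instead pools repeats of stratified 3-fold CV.
    """
    y = fm.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(rng_seed)
    n = len(y)
    aucs = []
    pooled_scores, pooled_y = [], []
    if scheme == "mccv":
        n_train = max(2, int(round(train_frac * n)))
        for _ in range(repeats):
            for _attempt in range(1000):
                perm = rng.permutation(n)
                tr, te = perm[:n_train], perm[n_train:]
                if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
                    break
            else:
                raise ValueError("could not draw a split with both classes")
            scores = _fit_score(fm.values[tr], y[tr], fm.values[te], cost)
            aucs.append(roc_auc_score(y[te], scores))
            pooled_scores.append(scores)
            pooled_y.append(y[te])
    elif scheme == "kfold":
        for rep in range(repeats):
            cv = StratifiedKFold(
                n_splits=3, shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            for tr, te in cv.split(fm.values, y):
                scores = _fit_score(fm.values[tr], y[tr], fm.values[te], cost)
                aucs.append(roc_auc_score(y[te], scores))
                pooled_scores.append(scores)
                pooled_y.append(y[te])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    aucs = np.asarray(aucs)
    all_scores = np.concatenate(pooled_scores)
    all_y = np.concatenate(pooled_y)
    fpr, tpr, _ = roc_curve(all_y, all_scores)
    return ClassificationReport(
        signature=fm.signature,
        aucs=aucs,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        repeats=repeats,
        train_frac=train_frac,
        rng_seed=rng_seed,
        scheme=scheme,
    )


def cross_dataset_evaluate(
    fm_train: FeatureMatrix,
    fm_test: FeatureMatrix,
    *,
    cost: float = 1.0,
) -> ClassificationReport:
    """Train on all of one dataset's features, score AUC on another's.

    Both matrices must carry the same feature ids (built from the same
    signature artifacts); features present in only one are dropped to
    the intersection, preserving train-matrix order.
    """
    common = [f for f in fm_train.feature_ids if f in set(fm_test.feature_ids)]
    if not common:
        raise ValueError("no shared features between train and test matrices")
    tr_idx = [fm_train.feature_ids.index(f) for f in common]
    te_idx = [fm_test.feature_ids.index(f) for f in common]
    scores = _fit_score(
        fm_train.values[:, tr_idx], fm_train.y, fm_test.values[:, te_idx], cost
    )
    auc = roc_auc_score(fm_test.y, scores)
    fpr, tpr, _ = roc_curve(fm_test.y, scores)
    return ClassificationReport(
        signature=fm_train.signature,
        aucs=np.array([auc]),
        mean_auc=float(auc),
        sd_auc=0.0,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        repeats=1,
        train_frac=1.0,
        rng_seed=0,
        scheme="cross-dataset",
    )
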