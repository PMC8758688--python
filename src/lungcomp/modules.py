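"""Cellular-composition module discovery, validation and survival analysis.

Samples are hierarchically clustered on their deconvoluted cell-type
weights (correlation distance, average linkage) into recurrent composition
groups, which are named after their dominant cell type ("Fib-high", ...)
by an explicit z-score rule. Group structure is validated by a linear SVM
under repeated stratified cross-validation (ROC AUC, one-vs-one), the cell
types most perturbed between conditions are ranked Augur-style
(subsample - classify - rank by AUC), and groups are linked to outcome by
Kaplan–Meier curves and the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .deconvolution import CompositionMatrix
from .normalize import log_normalize

__all__ = [
    "GroupAssignment",
    "ClassifierReport",
    "SurvivalResult",
    "composition_correlation",
    "discover_groups",
    "classify_subtypes",
    "prioritize_cell_types",
    "km_estimate",
    "logrank_test",
]


@dataclass
class GroupAssignment:
    group: pd.Series                    # per-sample integer group id (1..k)
    names: dict[int, str]               # id -> "<Type>-high" / hybrid name
    k: int
    linkage: str = "average"

    @property
    def named(self) -> pd.Series:
        """Per-sample human-readable group name."""
        return self.group.map(self.names)


@dataclass
class ClassifierReport:
    mean_auc: float
    sd_auc: float
    n_folds: int
    n_repeats: int
    seed: int
    per_pair: dict | None = None


@dataclass
class SurvivalResult:
    chi_square: float
    p_value: float
    curves: dict[str, pd.DataFrame]


def composition_correlation(comp: CompositionMatrix) -> pd.DataFrame:
    """Sample x sample Pearson correlation of composition vectors.

    Symmetric with unit diagonal; rows with constant composition are NaN
    off-diagonal and reported via a warning.
    """
    W = comp.weights
    if len(W) < 2:
        raise ValueError("need >= 2 samples")
    vals = W.to_numpy()
    constant = np.ptp(vals, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"constant composition rows: {list(W.index[constant])}", stacklevel=2
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(vals)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=W.index, columns=W.index)


def _name_group(mean_z: pd.Series, z_high: float = 1.0, z_close: float = 0.25) -> str:
    """Name a group from its mean z-scored weights.

    Dominant type with z > ``z_high`` gives "<T>-high"; a runner-up within
    ``z_close`` z gives "<T1>-<T2> hybrid"; no dominant type gives "hybrid".
    """
    ranked = mean_z.sort_values(ascending=False)
    if ranked.iloc[0] <= z_high:
        return "hybrid"
    if len(ranked) > 1 and ranked.iloc[0] - ranked.iloc[1] < z_close:
        t1, t2 = sorted([ranked.index[0], ranked.index[1]])
        return f"{t1}-{t2} hybrid"
    return f"{ranked.index[0]}-high"


def discover_groups(
    comp: CompositionMatrix,
    k: int | str = "auto",
    k_max: int = 8,
) -> GroupAssignment:
    """Cluster samples into composition groups and name them.

    Agglomerative clustering with correlation distance (1 - r) and average
    linkage; ``k='auto'`` selects 2..k_max by silhouette on the same
    distance. Group ids follow order of first appearance over samples
    sorted lexicographically, so the partition is sample-order invariant.
    """
    W = comp.weights.sort_index()
    n = len(W)
    dist = 1.0 - composition_correlation(CompositionMatrix(W)).to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)

    def cut(kk: int) -> np.ndarray:
        return AgglomerativeClustering(
            n_clusters=kk, metric="precomputed", linkage="average"
        ).fit_predict(dist)

    if k == "auto":
        best, best_score = 1, -np.inf
        for kk in range(2, min(k_max, n - 1) + 1):
            lab = cut(kk)
            s = silhouette_score(dist, lab, metric="precomputed")
            if s > best_score + 1e-12:
                best, best_score = kk, s
        k = best
    else:
        k = int(k)
        if k > n:
            raise ValueError(f"k={k} exceeds {n} samples")
    raw = cut(k) if k > 1 else np.zeros(n, dtype=int)
    remap, nxt = {}, 1
    ids = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        ids[i] = remap[lab]
    group = pd.Series(ids, index=W.index, name="group")

    mu = W.mean(axis=0)
    sd = W.std(axis=0, ddof=0).replace(0, 1.0)
    z = (W - mu) / sd
    names = {
        gid: _name_group(z[group == gid].mean(axis=0))
        for gid in sorted(set(ids))
    }
    return GroupAssignment(group=group, names=names, k=k)


def classify_subtypes(
    comp: CompositionMatrix,
    labels: pd.Series,
    n_folds: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
) -> ClassifierReport:
    """Linear-SVM separability of sample classes from composition weights.

    Stratified k-fold cross-validation repeated ``n_repeats`` times with
    distinct fold seeds; ROC AUC is computed one-vs-one per class pair from
    the decision function and macro-averaged. Reports the mean and SD of
    the per-repeat AUC.
    """
    labels = pd.Series(labels).loc[comp.weights.index]
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = labels.value_counts()
    small = counts[counts < n_folds]
    if len(small):
        raise ValueError(f"classes below fold count: {dict(small)}")
    X = comp.weights.to_numpy()
    y = labels.to_numpy()
    rep_aucs, per_pair = [], {pair: [] for pair in combinations(classes, 2)}
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        pair_scores = []
        for c1, c2 in combinations(classes, 2):
            mask = (y == c1) | (y == c2)
            Xp, yp = X[mask], (y[mask] == c2).astype(int)
            scores, truth = [], []
            for tr, te in skf.split(Xp, yp):
                clf = SVC(kernel="linear", C=1.0)
                clf.fit(Xp[tr], yp[tr])
                scores.append(clf.decision_function(Xp[te]))
                truth.append(yp[te])
            auc = roc_auc_score(np.concatenate(truth), np.concatenate(scores))
            pair_scores.append(auc)
            per_pair[(c1, c2)].append(auc)
        rep_aucs.append(float(np.mean(pair_scores)))
    return ClassifierReport(
        mean_auc=float(np.mean(rep_aucs)),
        sd_auc=float(np.std(rep_aucs, ddof=0)),
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
        per_pair={k: float(np.mean(v)) for k, v in per_pair.items()},
    )


def prioritize_cell_types(
    expr,
    condition: pd.Series,
    cell_types: pd.Series,
    n_subsamples: int = 20,
    cells_per_subsample: int = 50,
    seed: int = 0,
    n_hvg: int = 500,
    n_folds: int = 3,
) -> pd.Series:
    """Rank cell types by how separable their conditions are (Augur-style).

    Per type: repeatedly subsample ``cells_per_subsample`` cells per
    condition, train a cross-validated L2 logistic classifier on the top
    ``n_hvg`` highly-variable genes to predict condition, and record ROC
    AUC. Mean AUC over subsamples ranks the types (higher = more
    perturbed). Types lacking enough cells in any condition are excluded
    with a warning.
    """
    condition, cell_types = pd.Series(condition), pd.Series(cell_types)
    conds = sorted(pd.unique(condition))
    if len(conds) != 2:
        raise ValueError("need exactly 2 conditions")
    norm = log_normalize(expr, scale=1e4)
    rng = np.random.default_rng(seed)
    out = {}
    for t in sorted(pd.unique(cell_types)):
        mask = (cell_types == t).to_numpy()
        sub_cond = condition[mask]
        sizes = sub_cond.value_counts()
        if len(sizes) < 2 or (sizes < cells_per_subsample).any():
            warnings.warn(
                f"cell type {t} lacks {cells_per_subsample} cells per condition",
                stacklevel=2,
            )
            continue
        Xt = norm[mask]
        var = Xt.var(axis=0)
        hvg = np.argsort(var)[::-1][: min(n_hvg, Xt.shape[1])]
        Xt = Xt[:, hvg]
        yt = (sub_cond == conds[1]).to_numpy().astype(int)
        idx0 = np.flatnonzero(yt == 0)
        idx1 = np.flatnonzero(yt == 1)
        aucs = []
        for _ in range(n_subsamples):
            pick = np.concatenate([
                rng.choice(idx0, cells_per_subsample, replace=False),
                rng.choice(idx1, cells_per_subsample, replace=False),
            ])
            Xs, ys = Xt[pick], yt[pick]
            skf = StratifiedKFold(
                n_splits=n_folds, shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            scores, truth = [], []
            for tr, te in skf.split(Xs, ys):
                clf = LogisticRegression(C=1.0, max_iter=2000)
                clf.fit(Xs[tr], ys[tr])
                scores.append(clf.decision_function(Xs[te]))
                truth.append(ys[te])
            aucs.append(roc_auc_score(np.concatenate(truth), np.concatenate(scores)))
        out[t] = float(np.mean(aucs))
    if not out:
        raise ValueError("no cell type had enough cells in both conditions")
    return pd.Series(out, name="mean_auc").sort_values(ascending=False)


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit curve.

    Returns one row per distinct event/censoring time with the number at
    risk and the survival estimate just after that time; censored times
    reduce the risk set without a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) != len(events):
        raise ValueError("times and events differ in length")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table.iloc[1:] if 0 not in times else kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": tab.index.to_numpy(dtype=float),
        "at_risk": tab["at_risk"].to_numpy(dtype=int),
        "n_events": tab["observed"].to_numpy(dtype=int),
        "survival": surv.loc[tab.index].to_numpy(dtype=float),
    }).reset_index(drop=True)
    return out


def logrank_test(times, events, groups) -> SurvivalResult:
    """Two-group log-rank test with per-group Kaplan–Meier curves.

    Standard 1-df chi-square over pooled event times; with no events at all
    the test is vacuous and returns p = 1 with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("log-rank needs exactly 2 groups")
    m0, m1 = groups == levels[0], groups == levels[1]
    if not m0.any() or not m1.any():
        raise ValueError("both groups must be non-empty")
    curves = {
        str(lev): km_estimate(times[groups == lev], events[groups == lev])
        for lev in levels
    }
    if events.sum() == 0:
        warnings.warn("no events observed; log-rank test is vacuous", stacklevel=2)
        return SurvivalResult(chi_square=0.0, p_value=1.0, curves=curves)
    res = _ll_logrank(times[m0], times[m1], events[m0], events[m1])
    return SurvivalResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=curves,
    )
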