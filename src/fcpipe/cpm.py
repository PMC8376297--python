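"""Connectome predictive mapping (CPM).

CPM relates a behavioral score to the connectome through three steps:

1. **Edge selection** — every edge's Fisher-z values are correlated with
   the score across training subjects; edges with p below a threshold
   (default 0.01) are kept and split by the sign of r into a *positive
   tail* (stronger connectivity, higher score) and a *negative tail*.
2. **Network strength** — each subject is summarized by the mean z over
   a tail's edges.
3. **Prediction** — an ordinary least-squares line from strength to
   score, fit on training subjects and applied to held-out subjects
   under k-fold cross-validation (default fivefold).  Model quality is
   the Pearson correlation between pooled out-of-fold predictions and
   the observed scores.

Edges selected in *every* fold form the consensus network for a tail;
the union of the consensus tails across tasks (e.g. the DST-positive and
NCT-negative networks) defines a combined network whose strength can be
applied post hoc to independent cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from . import edges as edgemod

logger = logging.getLogger(__name__)

__all__ = [
    "TailSelection",
    "FoldModel",
    "CpmResult",
    "CombinedNetwork",
    "ApplyResult",
    "select_edges",
    "network_strength",
    "cpm_crossval",
    "cpm_permutation_p",
    "combine_networks",
    "apply_network",
]


@dataclass
class TailSelection:
    """Edges correlated with the score, split by sign of r."""

    positive_edges: np.ndarray  # flat edge indices, r > 0 and p < threshold
    negative_edges: np.ndarray  # flat edge indices, r < 0 and p < threshold
    r: np.ndarray
    p: np.ndarray
    threshold_p: float

    def tail(self, name: str) -> np.ndarray:
        if name == "positive":
            return self.positive_edges
        if name == "negative":
            return self.negative_edges
        raise ValueError("tail must be 'positive' or 'negative'")


@dataclass
class FoldModel:
    train_ids: np.ndarray
    test_ids: np.ndarray
    selection: TailSelection
    slope: float
    intercept: float
    used_train_mean: bool  # True when the tail was empty in this fold


@dataclass
class CpmResult:
    folds: list[FoldModel]
    predictions: np.ndarray  # out-of-fold prediction per subject
    observed: np.ndarray
    r_pred_obs: float
    p_pred_obs: float
    #: mean of the within-fold predicted-observed correlations.  Unlike the
    #: pooled ``r_pred_obs``, this statistic is free of the between-fold
    #: intercept variation (each fold's intercept embeds its training mean,
    #: which is anti-correlated with the held-out scores within a fixed
    #: sample), so it is centered on zero under the null and is the right
    #: quantity for calibration checks at small n.
    fold_average_r: float
    consensus_positive: np.ndarray
    consensus_negative: np.ndarray
    tail: str
    k: int
    threshold_p: float
    seed: int | None


@dataclass
class CombinedNetwork:
    """Union of two edge sets with per-edge provenance."""

    edge_index: np.ndarray  # sorted flat indices of the union
    provenance: dict[int, str]  # edge index -> "from-a" | "from-b" | "both"
    n_regions: int

    @property
    def size(self) -> int:
        return int(self.edge_index.size)

    def node_degrees(self) -> dict[int, int]:
        g = nx.Graph()
        g.add_edges_from(map(tuple, edgemod.index_to_pairs(self.edge_index, self.n_regions)))
        return dict(g.degree())

    @property
    def nodes(self) -> np.ndarray:
        return np.unique(edgemod.index_to_pairs(self.edge_index, self.n_regions))


@dataclass
class ApplyResult:
    """Fixed-network regression of score on strength."""

    r: float
    F: float
    df: tuple[int, int]
    p: float
    beta: float  # slope, score units per unit Fisher-z strength
    intercept: float
    strengths: np.ndarray


def _edge_score_corr(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r (and two-tailed p) of each edge column with the score.

    The p value equals that of the simple-regression slope, so edge-wise
    correlation and edge-wise linear regression select identical edges.
    """
    n = x.shape[0]
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    sy = np.sqrt((yc**2).sum())
    sx = np.sqrt((xc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    constant = sx == 0.0
    if constant.any():
        logger.info("skipping %d constant edge(s) in selection", int(constant.sum()))
    r = np.where(constant, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isfinite(r), np.where(np.isfinite(p), p, 0.0), np.nan)
    return r, p


def select_edges(
    train: np.ndarray, scores: np.ndarray, threshold_p: float = 0.01
) -> TailSelection:
    """Correlate every edge with the score; keep p < threshold, split by sign."""
    x = np.asarray(train, dtype=float)
    y = np.asarray(scores, dtype=float).ravel()
    if x.ndim != 2:
        raise ValueError("train must be a (subjects, edges) array")
    if x.shape[0] != y.size:
        raise ValueError("scores length must match subject count")
    if x.shape[0] < 4:
        raise ValueError("need at least 4 training subjects")
    if y.std() == 0.0:
        raise ValueError("scores have zero variance")
    r, p = _edge_score_corr(x, y)
    with np.errstate(invalid="ignore"):
        sig = np.isfinite(r) & (p < threshold_p)
        pos = np.flatnonzero(sig & (r > 0))
        neg = np.flatnonzero(sig & (r < 0))
    return TailSelection(pos, neg, r, p, threshold_p)


def network_strength(values, edge_index: np.ndarray) -> float | np.ndarray:
    """Mean Fisher-z over a fixed edge set.

    ``values`` may be one subject's edge vector (1-D), a cohort matrix
    ``(subjects, edges)`` (2-D; returns one strength per subject), or a
    :class:`~fcpipe.fc.ConnectivityMatrix` (its upper triangle is used).
    """
    edge_index = np.asarray(edge_index, dtype=np.int64).ravel()
    if edge_index.size == 0:
        raise ValueError("network strength is undefined for an empty edge set")
    if hasattr(values, "z"):  # ConnectivityMatrix
        vec = edgemod.vectorize(values.z, check=False)
        return float(vec[edge_index].mean())
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        return float(x[edge_index].mean())
    return x[:, edge_index].mean(axis=1)


def cpm_crossval(
    cohort: np.ndarray,
    scores: np.ndarray,
    k: int = 5,
    threshold_p: float = 0.01,
    tail: str = "positive",
    seed: int | None = None,
) -> CpmResult:
    """k-fold cross-validated CPM on a (subjects, edges) cohort.

    Per fold, edges are selected on the training split only, a line from
    train strength to train score is fit by OLS, and the held-out
    subjects are predicted.  A fold whose selected tail is empty predicts
    the training-mean score (logged loudly).  ``k == n`` gives
    leave-one-out.
    """
    x = np.asarray(cohort, dtype=float)
    y = np.asarray(scores, dtype=float).ravel()
    n = x.shape[0]
    if y.size != n:
        raise ValueError("scores length must match subject count")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} subjects into {k} folds")

    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.full(n, np.nan)
    folds: list[FoldModel] = []
    per_fold_edges: list[np.ndarray] = []
    for train_ids, test_ids in splitter.split(x):
        sel = select_edges(x[train_ids], y[train_ids], threshold_p)
        chosen = sel.tail(tail)
        per_fold_edges.append(chosen)
        if chosen.size == 0:
            logger.warning(
                "fold selected zero %s-tail edges; predicting the train mean", tail
            )
            slope, intercept = 0.0, float(y[train_ids].mean())
            preds[test_ids] = intercept
            folds.append(FoldModel(train_ids, test_ids, sel, slope, intercept, True))
            continue
        s_train = network_strength(x[train_ids], chosen)
        slope, intercept = np.polyfit(s_train, y[train_ids], 1)
        s_test = network_strength(x[test_ids], chosen)
        preds[test_ids] = slope * s_test + intercept
        folds.append(
            FoldModel(train_ids, test_ids, sel, float(slope), float(intercept), False)
        )

    if np.std(preds) == 0.0 or np.std(y) == 0.0:
        logger.warning("degenerate predictions or scores; reporting r = 0")
        r_po, p_po = 0.0, 1.0
    else:
        r_po, p_po = stats.pearsonr(preds, y)

    fold_rs = []
    for f in folds:
        pt, yt = preds[f.test_ids], y[f.test_ids]
        if pt.size >= 3 and np.std(pt) > 0.0 and np.std(yt) > 0.0:
            fold_rs.append(np.corrcoef(pt, yt)[0, 1])
    fold_average_r = float(np.mean(fold_rs)) if fold_rs else 0.0

    consensus_pos = _intersect_all([f.selection.positive_edges for f in folds])
    consensus_neg = _intersect_all([f.selection.negative_edges for f in folds])
    return CpmResult(
        folds=folds,
        predictions=preds,
        observed=y.copy(),
        r_pred_obs=float(r_po),
        p_pred_obs=float(p_po),
        fold_average_r=fold_average_r,
        consensus_positive=consensus_pos,
        consensus_negative=consensus_neg,
        tail=tail,
        k=k,
        threshold_p=threshold_p,
        seed=seed,
    )


def _intersect_all(sets: list[np.ndarray]) -> np.ndarray:
    out = sets[0]
    for s in sets[1:]:
        out = np.intersect1d(out, s, assume_unique=False)
    return out


def cpm_permutation_p(
    cohort: np.ndarray,
    scores: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    **cv_kwargs,
) -> tuple[float, np.ndarray]:
    """Permutation p for the cross-validated r, re-running the full CV.

    Cross-validated correlations violate the independence assumptions of
    the parametric t-based p value, so shuffling the scores and repeating
    the whole selection + fit + predict cycle gives an honest null.
    """
    rng = np.random.default_rng(seed)
    observed = cpm_crossval(cohort, scores, seed=seed, **cv_kwargs).r_pred_obs
    null = np.empty(n_perm)
    for k in range(n_perm):
        y_shuf = rng.permutation(scores)
        null[k] = cpm_crossval(cohort, y_shuf, seed=seed, **cv_kwargs).r_pred_obs
    p = (1.0 + (null >= observed).sum()) / (n_perm + 1.0)
    return float(p), null


def combine_networks(
    a: np.ndarray, b: np.ndarray, n_regions: int, mode: str = "union"
) -> CombinedNetwork:
    """Combine two consensus edge sets (e.g. DST-positive and NCT-negative).

    The default is the set union with per-edge provenance; disjoint sets
    of sizes 6 and 12 combine into an 18-edge network.  ``mode="intersection"``
    keeps only shared edges.
    """
    a = np.unique(np.asarray(a, dtype=np.int64))
    b = np.unique(np.asarray(b, dtype=np.int64))
    if mode == "union":
        combined = np.union1d(a, b)
    elif mode == "intersection":
        combined = np.intersect1d(a, b)
    else:
        raise ValueError("mode must be 'union' or 'intersection'")
    in_a, in_b = np.isin(combined, a), np.isin(combined, b)
    prov = {
        int(e): ("both" if ia and ib else "from-a" if ia else "from-b")
        for e, ia, ib in zip(combined, in_a, in_b)
    }
    return CombinedNetwork(edge_index=combined, provenance=prov, n_regions=n_regions)


def apply_network(
    cohort: np.ndarray, edge_index: np.ndarray, scores: np.ndarray
) -> ApplyResult:
    """Regress score on the strength of a fixed edge set (post hoc model).

    Reports the slope beta (score units per unit z), Pearson r, the F
    statistic on (1, n-2) degrees of freedom and its two-tailed p.  The
    identity ``F = (n-2) r^2 / (1 - r^2)`` ties the two views together.
    """
    x = np.asarray(cohort, dtype=float)
    y = np.asarray(scores, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("scores length must match subject count")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    s = network_strength(x, edge_index)
    if np.std(s) == 0.0:
        raise ValueError("network strength has zero variance across subjects")
    fit = stats.linregress(s, y)
    n = y.size
    r = float(fit.rvalue)
    if abs(r) >= 1.0:
        f_stat = np.inf
    else:
        f_stat = (n - 2) * r**2 / (1.0 - r**2)
    p = float(stats.f.sf(f_stat, 1, n - 2)) if np.isfinite(f_stat) else 0.0
    return ApplyResult(
        r=r,
        F=float(f_stat),
        df=(1, n - 2),
        p=p,
        beta=float(fit.slope),
        intercept=float(fit.intercept),
        strengths=np.asarray(s),
    )
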