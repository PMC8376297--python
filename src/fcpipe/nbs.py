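"""Network-based statistic (NBS) for family-wise-error-controlled edge inference.

Mass-univariate two-sample t tests are run on every included edge of the
connectome; edges surviving a stringent primary threshold (default
p < 1e-4, one-tailed) form a graph whose connected components are the
candidate effects.  Component size is measured in edges.  Significance is
assessed against an empirical null of the *maximal* component size
obtained by re-running the identical procedure under random relabelings
of the subjects (default 10,000 permutations), which controls the
family-wise error at the component level.

An edge-inclusion mask restricts testing to edges whose connectivity is
significantly nonzero (Bonferroni-corrected one-sample t test) in at
least one group; the mask is computed once on the observed grouping and
held fixed across permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import edges as edgemod

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeTestMap",
    "Component",
    "NbsResult",
    "edge_inclusion_mask",
    "edgewise_t",
    "suprathreshold_components",
    "nbs_test",
]

#: p-value sentinel stored at edges excluded by the inclusion mask.
EXCLUDED_P = np.nan


@dataclass
class Component:
    """A connected component of suprathreshold edges."""

    edge_pairs: np.ndarray  # (m, 2) node pairs, i < j
    nodes: np.ndarray  # sorted unique node indices

    @property
    def size(self) -> int:
        """Component size = number of edges (links), not nodes."""
        return int(self.edge_pairs.shape[0])


@dataclass
class EdgeTestMap:
    """Edge-wise t statistics and one-tailed p values under a mask."""

    t: np.ndarray
    p: np.ndarray
    tail: str  # "greater" (A > B) or "less" (A < B)
    df: float
    included: np.ndarray


@dataclass
class NbsResult:
    components: list[Component]
    corrected_p: np.ndarray
    null_max_sizes: np.ndarray
    tests: EdgeTestMap
    primary_p: float
    n_perm: int
    seed: int | None
    paper_literal: bool = False
    paired: bool = False

    def significant(self, alpha: float = 0.05) -> list[tuple[Component, float]]:
        return [
            (c, float(p))
            for c, p in zip(self.components, self.corrected_p)
            if p <= alpha
        ]


def _as_matrix(group: np.ndarray) -> np.ndarray:
    x = np.asarray(group, dtype=float)
    if x.ndim != 2:
        raise ValueError("each group must be a 2-D (subjects x edges) array")
    return x


def edge_inclusion_mask(
    groups: list[np.ndarray], alpha: float = 0.05
) -> np.ndarray:
    """Edges whose mean z is significantly nonzero in at least one group.

    Per group, a two-tailed one-sample t test against zero across that
    group's subjects; the threshold is Bonferroni-corrected over the E
    edges (``alpha / E``).  An edge passes if it is significant in any
    group.
    """
    mats = [_as_matrix(g) for g in groups]
    n_edges = mats[0].shape[1]
    for g in mats:
        if g.shape[0] < 2:
            raise ValueError("every group needs at least 2 subjects for the mask")
        if g.shape[1] != n_edges:
            raise ValueError("groups disagree on edge count")
    thresh = alpha / n_edges
    mask = np.zeros(n_edges, dtype=bool)
    for g in mats:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_1samp(g, 0.0, axis=0)
        p = np.where(np.isfinite(p), p, 1.0)  # constant-zero edges never pass
        mask |= p < thresh
    return mask


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    num = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    # zero pooled variance: t=0 for equal means, +/-inf otherwise
    degenerate = denom == 0.0
    if degenerate.any():
        logger.info("%d edge(s) with zero pooled variance", int(degenerate.sum()))
        with np.errstate(invalid="ignore"):
            t = np.where(
                degenerate, np.where(num == 0.0, 0.0, np.sign(num) * np.inf), t
            )
    return t, float(df)


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    num = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    bad = se2 == 0.0
    with np.errstate(invalid="ignore"):
        t = np.where(bad, np.where(num == 0.0, 0.0, np.sign(num) * np.inf), t)
    df = np.where(bad, na + nb - 2, df)
    return t, df


def _one_tailed_p(t: np.ndarray, df, tail: str) -> np.ndarray:
    if tail == "greater":
        return stats.t.sf(t, df)
    if tail == "less":
        return stats.t.cdf(t, df)
    raise ValueError("tail must be 'greater' or 'less'")


def edgewise_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    tail: str = "greater",
    mask: np.ndarray | None = None,
    variance: str = "pooled",
) -> EdgeTestMap:
    """Two-sample t test at every included edge.

    ``tail="greater"`` tests mean(A) > mean(B); ``"less"`` the reverse.
    Pooled-variance Student t by default; ``variance="welch"`` uses the
    Welch statistic with Satterthwaite degrees of freedom.
    """
    a, b = _as_matrix(group_a), _as_matrix(group_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups disagree on edge count")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if variance == "pooled":
        t, df = _pooled_t(a, b)
    elif variance == "welch":
        t, df = _welch_t(a, b)
    else:
        raise ValueError("variance must be 'pooled' or 'welch'")
    p = _one_tailed_p(t, df, tail)
    n_edges = a.shape[1]
    included = np.ones(n_edges, dtype=bool) if mask is None else np.asarray(mask, bool)
    if included.shape != (n_edges,):
        raise ValueError("mask length must equal the edge count")
    p = np.where(included, p, EXCLUDED_P)
    df_scalar = float(np.median(df)) if np.ndim(df) else float(df)
    return EdgeTestMap(t=t, p=p, tail=tail, df=df_scalar, included=included)


def _paired_t(diff: np.ndarray) -> tuple[np.ndarray, float]:
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    bad = sd == 0.0
    with np.errstate(invalid="ignore"):
        t = np.where(bad, np.where(m == 0.0, 0.0, np.sign(m) * np.inf), t)
    return t, float(n - 1)


class _UnionFind:
    """Array-backed union-find over node indices touched by edges."""

    def __init__(self, n_nodes: int) -> None:
        self.parent = np.arange(n_nodes)

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:  # path compression
            p[x], x = root, p[x]
        return root

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def _components_from_pairs(pairs: np.ndarray, n_regions: int) -> list[Component]:
    if pairs.shape[0] == 0:
        return []
    uf = _UnionFind(n_regions)
    for i, j in pairs:
        uf.union(int(i), int(j))
    roots: dict[int, list[int]] = {}
    for k, (i, j) in enumerate(pairs):
        roots.setdefault(uf.find(int(i)), []).append(k)
    comps = []
    for edge_ids in roots.values():
        ep = pairs[edge_ids]
        comps.append(Component(edge_pairs=ep, nodes=np.unique(ep)))
    comps.sort(key=lambda c: c.size, reverse=True)
    return comps


def suprathreshold_components(
    tests: EdgeTestMap, primary_p: float, n_regions: int
) -> list[Component]:
    """Connected components of the graph of edges with ``p < primary_p``.

    Components are sorted by size (edge count) descending; an empty edge
    set yields an empty list.
    """
    with np.errstate(invalid="ignore"):
        supra = np.flatnonzero(tests.included & (tests.p < primary_p))
    pairs = edgemod.index_to_pairs(supra, n_regions)
    return _components_from_pairs(pairs, n_regions)


def _max_component_size(pairs: np.ndarray, n_regions: int) -> int:
    if pairs.shape[0] == 0:
        return 0
    uf = _UnionFind(n_regions)
    for i, j in pairs:
        uf.union(int(i), int(j))
    counts: dict[int, int] = {}
    for i, _j in pairs:
        r = uf.find(int(i))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def _t_threshold(primary_p: float, df: float, tail: str) -> float:
    # p < primary_p one-tailed <=> t beyond the critical value in the tail
    crit = stats.t.isf(primary_p, df)
    return crit if tail == "greater" else -crit


def nbs_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    tail: str = "greater",
    primary_p: float = 1e-4,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha_mask: float | None = 0.05,
    mask: np.ndarray | None = None,
    variance: str = "pooled",
    paired: bool = False,
    paper_literal: bool = False,
    n_regions: int | None = None,
) -> NbsResult:
    """Full NBS: observed components plus a permutation null of max size.

    Parameters
    ----------
    group_a, group_b
        ``(subjects, edges)`` arrays of Fisher-z edge vectors.  In paired
        mode the rows must be matched subjects (pre/post sessions).
    tail
        ``"greater"`` tests A > B edge-wise.
    primary_p
        Edge-level one-tailed threshold defining suprathreshold links.
    alpha_mask
        Bonferroni level for the nonzero-in-at-least-one-group inclusion
        mask; ``None`` disables masking.  An explicit ``mask`` overrides.
    paired
        Use a one-sample t test on within-subject differences with a
        sign-flip permutation scheme instead of label shuffling.
    paper_literal
        Report the corrected p as the plain proportion of permutations
        whose maximum exceeds (strictly) the observed size, instead of
        the default add-one estimator ``(1 + #{max >= M}) / (n_perm + 1)``.

    Notes
    -----
    The inclusion mask is computed once from the observed grouping and
    reused for every permutation, matching the convention of testing "the
    same set of connections" throughout.
    """
    a, b = _as_matrix(group_a), _as_matrix(group_b)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        logger.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    n_edges = a.shape[1]
    if n_regions is None:
        n_regions = edgemod.regions_for_edge_count(n_edges)

    if mask is None and alpha_mask is not None:
        mask = edge_inclusion_mask([a, b], alpha=alpha_mask)
    if mask is None:
        mask = np.ones(n_edges, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    rng = np.random.default_rng(seed)

    if paired:
        if a.shape != b.shape:
            raise ValueError("paired mode requires matched (same-shape) groups")
        diff = a - b  # tail 'greater' => mean(A - B) > 0
        t_obs, df = _paired_t(diff)
        p_obs = _one_tailed_p(t_obs, df, tail)
        tests = EdgeTestMap(t=t_obs, p=np.where(mask, p_obs, EXCLUDED_P),
                            tail=tail, df=df, included=mask)
        components = suprathreshold_components(tests, primary_p, n_regions)
        t_crit = _t_threshold(primary_p, df, tail)
        null_max = np.empty(n_perm, dtype=np.int64)
        n = diff.shape[0]
        sq = np.sqrt(n)
        for k in range(n_perm):
            signs = rng.choice((-1.0, 1.0), size=n)
            d = diff * signs[:, None]
            m = d.mean(axis=0)
            sd = d.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = m / (sd / sq)
            t = np.where(sd == 0.0, 0.0, t)
            supra = _supra_indices(t, mask, t_crit, tail)
            null_max[k] = _max_component_size(
                edgemod.index_to_pairs(supra, n_regions), n_regions
            )
    else:
        tests = edgewise_t(a, b, tail=tail, mask=mask, variance=variance)
        components = suprathreshold_components(tests, primary_p, n_regions)
        na, nb = a.shape[0], b.shape[0]
        pooled = np.vstack([a, b])
        df = na + nb - 2
        t_crit = _t_threshold(primary_p, df, tail)
        null_max = np.empty(n_perm, dtype=np.int64)
        welch = variance == "welch"
        for k in range(n_perm):
            perm = rng.permutation(na + nb)
            pa, pb = pooled[perm[:na]], pooled[perm[na:]]
            if welch:
                t, dfw = _welch_t(pa, pb)
                pvals = _one_tailed_p(t, dfw, tail)
                supra = np.flatnonzero(mask & (pvals < primary_p))
            else:
                t, _ = _pooled_t(pa, pb)
                supra = _supra_indices(t, mask, t_crit, tail)
            null_max[k] = _max_component_size(
                edgemod.index_to_pairs(supra, n_regions), n_regions
            )

    sizes = np.array([c.size for c in components], dtype=np.int64)
    if paper_literal:
        corrected = np.array(
            [(null_max > m).sum() / n_perm for m in sizes], dtype=float
        )
    else:
        corrected = np.array(
            [(1.0 + (null_max >= m).sum()) / (n_perm + 1.0) for m in sizes],
            dtype=float,
        )
    return NbsResult(
        components=components,
        corrected_p=corrected,
        null_max_sizes=null_max,
        tests=tests,
        primary_p=primary_p,
        n_perm=n_perm,
        seed=seed,
        paper_literal=paper_literal,
        paired=paired,
    )


def _supra_indices(
    t: np.ndarray, mask: np.ndarray, t_crit: float, tail: str
) -> np.ndarray:
    if tail == "greater":
        return np.flatnonzero(mask & (t > t_crit))
    return np.flatnonzero(mask & (t < t_crit))
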