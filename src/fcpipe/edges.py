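"""Canonical upper-triangle edge indexing for symmetric connectivity matrices.

Every unordered region pair ``(i, j)`` with ``i < j`` is assigned a flat
index by row-major traversal of the strict upper triangle, i.e. the same
order as ``numpy.triu_indices(n, 1)``.  All modules in this package use
this single ordering, so an edge vector of length ``n(n-1)/2`` is an
unambiguous representation of a symmetric zero-diagonal matrix.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "edge_count",
    "regions_for_edge_count",
    "upper_tri_pairs",
    "pairs_to_index",
    "index_to_pairs",
    "vectorize",
    "matricize",
]


def edge_count(n_regions: int) -> int:
    """Number of unordered region pairs, ``n(n-1)/2``."""
    if n_regions < 2:
        raise ValueError(f"need at least 2 regions, got {n_regions}")
    return n_regions * (n_regions - 1) // 2


def regions_for_edge_count(n_edges: int) -> int:
    """Invert :func:`edge_count`; error if ``n_edges`` is not triangular."""
    n = int(round((1.0 + math.sqrt(1.0 + 8.0 * n_edges)) / 2.0))
    if n < 2 or edge_count(n) != n_edges:
        raise ValueError(
            f"{n_edges} is not a triangular number n(n-1)/2; "
            "cannot be an edge-vector length"
        )
    return n


def upper_tri_pairs(n_regions: int) -> np.ndarray:
    """All edges as an ``(E, 2)`` int array in canonical (row-major) order."""
    i, j = np.triu_indices(n_regions, k=1)
    return np.column_stack([i, j])


def pairs_to_index(pairs: np.ndarray, n_regions: int) -> np.ndarray:
    """Map ``(m, 2)`` node pairs (any order within a pair) to flat edge indices."""
    pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
    if pairs.size == 0:
        return np.empty(0, dtype=np.int64)
    if pairs.shape[1] != 2:
        raise ValueError("pairs must have shape (m, 2)")
    i = np.minimum(pairs[:, 0], pairs[:, 1])
    j = np.maximum(pairs[:, 0], pairs[:, 1])
    if (i < 0).any() or (j >= n_regions).any():
        raise ValueError(f"node index out of range for {n_regions} regions")
    if (i == j).any():
        raise ValueError("self-loops (i == j) are not edges")
    return i * (2 * n_regions - i - 1) // 2 + (j - i - 1)


def index_to_pairs(index: np.ndarray, n_regions: int) -> np.ndarray:
    """Map flat edge indices back to ``(m, 2)`` node pairs with ``i < j``."""
    index = np.atleast_1d(np.asarray(index, dtype=np.int64))
    e = edge_count(n_regions)
    if index.size and ((index < 0).any() or (index >= e).any()):
        raise ValueError(f"edge index out of range [0, {e})")
    all_pairs = upper_tri_pairs(n_regions)
    return all_pairs[index]


def vectorize(matrix: np.ndarray, *, check: bool = True, tol: float = 1e-12) -> np.ndarray:
    """Extract the strict upper triangle of a symmetric zero-diagonal matrix.

    The inverse of :func:`matricize`: the round trip is bit-exact.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if check:
        if not np.allclose(m, m.T, atol=tol, rtol=0.0):
            raise ValueError("matrix is not symmetric within tolerance 1e-12")
        if np.any(np.diag(m) != 0.0):
            raise ValueError("matrix diagonal must be exactly zero")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def matricize(vector: np.ndarray, n_regions: int | None = None) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    v = np.asarray(vector, dtype=float).ravel()
    if n_regions is None:
        n_regions = regions_for_edge_count(v.size)
    elif edge_count(n_regions) != v.size:
        raise ValueError(
            f"vector length {v.size} does not match {n_regions} regions "
            f"(expected {edge_count(n_regions)})"
        )
    m = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    m[iu] = v
    m.T[iu] = v
    return m
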