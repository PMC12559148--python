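"""Balanced colorings and polysynchrony subspaces.

A node coloring is *balanced* when any two same-colored nodes receive
the same multiset of input colors (counting arrow multiplicities).  Each
balanced coloring defines a *polysynchrony subspace* — the set of states
where same-colored cells are equal — which is flow-invariant for every
admissible ODE on the network.  Balanced colorings are therefore the
robust synchrony patterns a tissue can sustain, and the candidate
patterns emerging at a synchrony-breaking bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import RegularNetwork

__all__ = [
    "Coloring",
    "is_balanced",
    "coarsest_balanced_refinement",
    "coloring_from_vector",
    "subspace_intersection_dim",
    "monochrome",
]


@dataclass(frozen=True)
class Coloring:
    """Map node -> color, stored canonically (colors numbered 0..k-1 by
    first occurrence along the node order)."""

    colors: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "colors", _canonical(self.colors))

    @property
    def n_nodes(self) -> int:
        return len(self.colors)

    @property
    def n_colors(self) -> int:
        return max(self.colors) + 1 if self.colors else 0

    def classes(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_colors)]
        for node, c in enumerate(self.colors):
            out[c].append(node)
        return out

    def subspace_basis(self, node_dim: int = 1) -> np.ndarray:
        """Orthonormal basis of the polysynchrony subspace.

        With ``node_dim == 1`` the basis lives in node space (one
        normalized indicator column per color class); otherwise each
        indicator is tensored with the ``node_dim`` identity.
        """
        n, k = self.n_nodes, self.n_colors
        ind = np.zeros((n, k))
        for node, c in enumerate(self.colors):
            ind[node, c] = 1.0
        ind /= np.sqrt(ind.sum(axis=0, keepdims=True))
        if node_dim == 1:
            return ind
        return np.kron(ind, np.eye(node_dim))


def _canonical(colors) -> tuple[int, ...]:
    seen: dict[int, int] = {}
    out = []
    for c in colors:
        if c not in seen:
            seen[c] = len(seen)
        out.append(seen[c])
    return tuple(out)


def monochrome(n: int) -> Coloring:
    """The all-one-color coloring (fully synchronous pattern)."""
    return Coloring((0,) * n)


def _input_signature(network: RegularNetwork, colors: tuple[int, ...]) -> np.ndarray:
    """Row i = counts of input arrows to node i, summed by source color."""
    n = network.n_nodes
    k = max(colors) + 1
    sig = np.zeros((n, k), dtype=int)
    a = network.arrow_counts
    for j in range(n):
        sig[:, colors[j]] += a[:, j]
    return sig


def is_balanced(network: RegularNetwork, coloring: Coloring) -> bool:
    """True iff same-colored nodes have identical input-color multisets."""
    if coloring.n_nodes != network.n_nodes:
        raise ValueError("coloring does not cover the network's nodes")
    sig = _input_signature(network, coloring.colors)
    for members in coloring.classes():
        first = sig[members[0]]
        for node in members[1:]:
            if not np.array_equal(sig[node], first):
                return False
    return True


def coarsest_balanced_refinement(
    network: RegularNetwork, seed: Coloring
) -> Coloring:
    """Coarsest balanced coloring refining ``seed``.

    Standard partition refinement: repeatedly split color classes by
    their input-color count vectors until stable.  A balanced seed is a
    fixed point; the worst case is the discrete coloring.
    """
    if seed.n_nodes != network.n_nodes:
        raise ValueError("coloring does not cover the network's nodes")
    colors = seed.colors
    while True:
        sig = _input_signature(network, colors)
        keys = [(colors[i], tuple(sig[i])) for i in range(network.n_nodes)]
        new: dict[tuple, int] = {}
        refined = tuple(new.setdefault(k, len(new)) for k in keys)
        if max(refined) == max(colors):
            return Coloring(refined)
        colors = refined


def coloring_from_vector(vec, tol: float = 1e-6) -> Coloring:
    """Color nodes by (approximately) equal vector entries.

    Entries within ``tol * max|vec|`` of one another share a color;
    colors are numbered by first occurrence along the node order.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    v = np.asarray(vec, dtype=float).ravel()
    scale = float(np.max(np.abs(v), initial=0.0))
    band = tol * max(scale, 1e-300)
    order = np.argsort(v, kind="stable")
    colors = np.zeros(v.size, dtype=int)
    cluster_id = 0
    last = v[order[0]]
    for idx in order[1:]:
        if v[idx] - last > band:
            cluster_id += 1
        colors[idx] = cluster_id
        last = v[idx]
    return Coloring(tuple(int(c) for c in colors))


def subspace_intersection_dim(
    basis, coloring: Coloring, rank_tol: float = 1e-8
) -> int:
    """Dimension of span(basis) intersected with the polysynchrony subspace.

    Uses rank arithmetic, ``dim(U ∩ W) = dim U + dim W - dim(U + W)``.
    Basis vectors of length ``n`` are intersected with the node-space
    polysynchrony subspace; vectors of length ``n * s`` with its tensor
    extension to the full phase space.
    """
    arr = np.asarray(basis, dtype=float)
    if arr.ndim == 1:
        u = arr.reshape(-1, 1)
    elif arr.shape[0] % coloring.n_nodes == 0:
        u = arr  # columns are vectors (square arrays read column-wise)
    elif arr.shape[1] % coloring.n_nodes == 0:
        u = arr.T  # rows are vectors (e.g. a list of 1-D vectors)
    else:
        u = arr
    dim_total = u.shape[0]
    if dim_total % coloring.n_nodes:
        raise ValueError("basis length is not a multiple of the node count")
    node_dim = dim_total // coloring.n_nodes
    w = coloring.subspace_basis(node_dim)

    def rank(m: np.ndarray) -> int:
        if m.size == 0:
            return 0
        s = np.linalg.svd(m, compute_uv=False)
        return int(np.sum(s > rank_tol * max(1.0, s[0])))

    ru, rw = rank(u), rank(w)
    return ru + rw - rank(np.column_stack([u, w]))
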