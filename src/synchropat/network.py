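"""Regular cell-communication networks.

A *regular network* is a finite directed multigraph in which every node
receives the same number of input arrows (the *valence*, ``nu``).  Arrow
multiplicities are stored as an integer adjacency table ``arrow_counts``
whose entry ``(i, j)`` counts the arrows from node ``j`` to node ``i``
(inputs to ``i``).  Classification additionally assumes no self-arrows
(zero diagonal) — tissue cells do not signal to themselves through the
contact network — and builders here always satisfy that; a permissive
flag exists for pedagogical networks that violate it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RegularNetwork",
    "NetworkValidationError",
    "validate_regular",
    "is_strongly_connected",
    "build_line_lattice",
    "build_periodic_lattice_2d",
    "read_network",
    "write_network",
]


class NetworkValidationError(ValueError):
    """Raised when an adjacency table is not a valid regular network."""


@dataclass(frozen=True)
class RegularNetwork:
    """A regular directed network with integer arrow multiplicities.

    Attributes
    ----------
    arrow_counts:
        ``(n, n)`` integer array; entry ``(i, j)`` is the number of arrows
        from node ``j`` to node ``i``.
    valence:
        Common row sum ``nu`` (number of input arrows per node).
    node_labels:
        Optional human-readable node names.
    has_self_arrows:
        True when the diagonal is not identically zero (permissive mode).
    """

    arrow_counts: np.ndarray
    valence: int
    node_labels: tuple[str, ...] = field(default=())
    has_self_arrows: bool = False

    @property
    def n_nodes(self) -> int:
        return self.arrow_counts.shape[0]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "arrow_counts", np.ascontiguousarray(self.arrow_counts, dtype=int)
        )
        if not self.node_labels:
            object.__setattr__(
                self,
                "node_labels",
                tuple(f"v{i + 1}" for i in range(self.arrow_counts.shape[0])),
            )


def validate_regular(
    arrow_counts, *, allow_self_arrows: bool = False, node_labels: Sequence[str] = ()
) -> RegularNetwork:
    """Validate an integer adjacency table and wrap it as a RegularNetwork.

    Raises :class:`NetworkValidationError` when the table is non-square,
    has negative or non-integer entries, non-uniform row sums ("not
    regular"), or a nonzero diagonal ("self-arrow present") unless
    ``allow_self_arrows`` is set.
    """
    a = np.asarray(arrow_counts)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] == 0:
        raise NetworkValidationError("malformed adjacency: table must be square")
    if not np.issubdtype(a.dtype, np.integer):
        rounded = np.rint(a)
        if not np.array_equal(rounded, a):
            raise NetworkValidationError("malformed adjacency: non-integer entries")
        a = rounded.astype(int)
    if (a < 0).any():
        raise NetworkValidationError("malformed adjacency: negative entries")
    row_sums = a.sum(axis=1)
    if not (row_sums == row_sums[0]).all():
        raise NetworkValidationError(
            f"not regular: row sums {row_sums.tolist()} are not uniform"
        )
    has_self = bool(np.diag(a).any())
    if has_self and not allow_self_arrows:
        raise NetworkValidationError("self-arrow present: nonzero diagonal entry")
    return RegularNetwork(
        arrow_counts=a.astype(int),
        valence=int(row_sums[0]),
        node_labels=tuple(node_labels),
        has_self_arrows=has_self,
    )


def is_strongly_connected(network: RegularNetwork) -> bool:
    """True iff every ordered pair of nodes is joined by a directed path."""
    import networkx as nx

    g = nx.from_numpy_array(
        network.arrow_counts.T, create_using=nx.DiGraph
    )  # edge j->i when arrow_counts[i, j] > 0
    return nx.is_strongly_connected(g)


def build_line_lattice(n: int) -> RegularNetwork:
    """Line of ``n`` cells with doubled end arrows (valence 2).

    Interior cells receive one arrow from each neighbour; the two end
    cells receive two arrows from their single neighbour.  ``n = 6``
    gives the C. elegans vulval-precursor-cell network.
    """
    if n < 2:
        raise NetworkValidationError("line lattice requires n >= 2")
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        if i == 0:
            a[i, 1] = 2
        elif i == n - 1:
            a[i, n - 2] = 2
        else:
            a[i, i - 1] = 1
            a[i, i + 1] = 1
    return validate_regular(a)


_SHELL_OFFSETS: Mapping[str, tuple[tuple[int, int], ...]] = {
    "nearest": ((1, 0), (-1, 0), (0, 1), (0, -1)),
    "diagonal": ((1, 1), (1, -1), (-1, 1), (-1, -1)),
}


def build_periodic_lattice_2d(
    rows: int, cols: int, shell_weights: Mapping[str, int]
) -> RegularNetwork:
    """Torus lattice of ``rows x cols`` cells with weighted neighbour shells.

    ``shell_weights`` maps shell names (``"nearest"`` for the four
    axis-aligned offsets, ``"diagonal"`` for the four diagonal offsets)
    to positive integer connection strengths.  The resulting adjacency
    table is symmetric and valence equals ``sum(shell size * weight)``.
    """
    if rows < 3 or cols < 3:
        raise NetworkValidationError("degenerate wrap: rows and cols must be >= 3")
    if not shell_weights:
        raise NetworkValidationError("at least one neighbour shell is required")
    n = rows * cols
    a = np.zeros((n, n), dtype=int)
    labels = []
    for r in range(rows):
        for c in range(cols):
            labels.append(f"r{r}c{c}")
            i = r * cols + c
            for shell, weight in shell_weights.items():
                try:
                    offsets = _SHELL_OFFSETS[shell]
                except KeyError:
                    raise NetworkValidationError(f"unknown shell {shell!r}") from None
                if int(weight) <= 0:
                    raise NetworkValidationError("shell weights must be positive")
                for dr, dc in offsets:
                    j = ((r + dr) % rows) * cols + (c + dc) % cols
                    a[i, j] += int(weight)
    return validate_regular(a, node_labels=labels)


# ---------------------------------------------------------------------------
# File formats: CSV adjacency table and JSON arrow list.


def read_network(path, *, allow_self_arrows: bool = False) -> RegularNetwork:
    """Read a network from a ``.csv`` adjacency table or ``.json`` arrow list.

    CSV: header row of node labels, then integer rows.  JSON:
    ``{"nodes": [...], "arrows": [[target, source, count], ...]}`` with
    node indices 0-based.  Regularity is validated on load.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            doc = json.load(fh)
        nodes = doc["nodes"]
        n = len(nodes)
        a = np.zeros((n, n), dtype=int)
        for target, source, count in doc["arrows"]:
            a[int(target), int(source)] += int(count)
        return validate_regular(
            a, allow_self_arrows=allow_self_arrows, node_labels=[str(x) for x in nodes]
        )
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [row for row in reader if row]
    labels = [cell.strip() for cell in rows[0]]
    a = np.array([[int(cell) for cell in row] for row in rows[1:]], dtype=int)
    return validate_regular(a, allow_self_arrows=allow_self_arrows, node_labels=labels)


def write_network(network: RegularNetwork, path) -> None:
    """Write a network as CSV adjacency (``.csv``) or JSON arrows (``.json``)."""
    path = str(path)
    if path.endswith(".json"):
        arrows = [
            [i, j, int(c)]
            for (i, j), c in np.ndenumerate(network.arrow_counts)
            if c
        ]
        doc = {"nodes": list(network.node_labels), "arrows": arrows}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(network.node_labels)
        writer.writerows(network.arrow_counts.tolist())
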