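"""Adjacency spectra and block-Jacobian eigenstructure.

At a synchronous equilibrium of an admissible ODE on a regular network,
the full Jacobian decomposes over the adjacency spectrum: its
eigenvalues are the union, over adjacency eigenvalues ``mu_j``, of the
eigenvalues of the reduced ``s x s`` matrices ``Q + mu_j R``, and its
eigenvectors are Kronecker composites of a cell-level vector ``u`` (an
eigenvector of ``Q + mu_j R``) with a network-level vector ``v_j`` (an
adjacency eigenvector).  The network-level factors span the *critical
pattern space*, which carries the spatial shape of any emerging
pattern.

``assemble_full_jacobian`` provides the dense ``(n s) x (n s)`` oracle
against which the reduced decomposition is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from .network import RegularNetwork

__all__ = [
    "SpectralData",
    "Linearization",
    "JacobianEigenpair",
    "adjacency_spectrum",
    "jacobian_spectrum",
    "assemble_full_jacobian",
    "critical_pattern_space",
]


@dataclass(frozen=True)
class SpectralData:
    """Clustered adjacency spectrum of a regular network.

    ``eigenvalues`` holds the distinct (clustered) eigenvalues sorted by
    real part (ties by imaginary part); ``multiplicities`` the algebraic
    multiplicity of each; ``eigenvectors[i]`` an orthonormal basis of
    the real eigenspace ``P^{mu_i}`` (shape ``(n, g_i)``); and
    ``generalized_bases[i]`` an orthonormal basis of the real
    generalized eigenspace ``G^{mu_i}``.
    """

    eigenvalues: np.ndarray
    multiplicities: np.ndarray
    eigenvectors: tuple[np.ndarray, ...]
    generalized_bases: tuple[np.ndarray, ...]
    is_real_spectrum: bool
    spectral_radius: float
    n_nodes: int

    @property
    def n_clusters(self) -> int:
        return len(self.eigenvalues)

    @property
    def min_index(self) -> int:
        """Index of the smallest-real-part eigenvalue (``mu_1``): always 0."""
        return 0

    @property
    def max_index(self) -> int:
        """Index of the largest-real-part eigenvalue (``mu_k``)."""
        return self.n_clusters - 1


@dataclass(frozen=True)
class Linearization:
    """Internal (Q) and coupled (R) dynamics at a synchronous point.

    ``Q`` is the differential of the cell rate function with respect to
    the cell's own state; ``R`` with respect to any single input-cell
    state.  ``x0``/``lam0`` record where on the synchronous branch the
    blocks were evaluated (metadata only).
    """

    Q: np.ndarray
    R: np.ndarray
    x0: np.ndarray | None = None
    lam0: float | None = None

    def __post_init__(self) -> None:
        q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        r = np.atleast_2d(np.asarray(self.R, dtype=float))
        if q.shape != r.shape or q.shape[0] != q.shape[1]:
            raise ValueError("Q and R must be square matrices of equal size")
        object.__setattr__(self, "Q", q)
        object.__setattr__(self, "R", r)

    @property
    def node_dim(self) -> int:
        return self.Q.shape[0]


@dataclass(frozen=True)
class JacobianEigenpair:
    """One Jacobian eigenvalue with its Kronecker-factored eigenvector."""

    eigenvalue: complex
    cell_part: np.ndarray
    network_part: np.ndarray
    mu_index: int

    @property
    def full_vector(self) -> np.ndarray:
        """Eigenvector of the assembled Jacobian (node-major ordering)."""
        return np.kron(self.network_part, self.cell_part)


def _fix_phase(vec: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unit norm with the first significantly-nonzero component positive."""
    v = vec / np.linalg.norm(vec)
    nz = np.nonzero(np.abs(v) > tol * 10)[0]
    if nz.size and v[nz[0]].real < 0:
        v = -v
    return v


def _null_basis(m: np.ndarray, atol: float) -> np.ndarray:
    """Orthonormal kernel basis with an absolute singular-value cutoff."""
    u, s, vh = np.linalg.svd(m)
    rank = int(np.sum(s > atol))
    return vh[rank:].conj().T


def adjacency_spectrum(
    network: RegularNetwork, cluster_tol: float = 1e-8
) -> SpectralData:
    """Compute the clustered adjacency spectrum with eigenspace bases.

    Eigenvalues within ``cluster_tol * max(1, spectral radius)`` of each
    other are merged into one cluster whose algebraic multiplicity is
    the cluster size.  For integer adjacency tables, eigenvalues within
    1e-6 of an integer are snapped to it before clustering, so exact
    lattice spectra do not split spuriously.  Real eigenspaces are
    kernels of ``A - mu I`` (or of the real quadratic factor for a
    complex pair); generalized eigenspaces are kernels of the same
    operator raised to the algebraic multiplicity.
    """
    if cluster_tol <= 0:
        raise ValueError("cluster_tol must be positive")
    a = network.arrow_counts.astype(float)
    n = a.shape[0]
    symmetric = np.array_equal(a, a.T)
    if symmetric:
        raw = scipy.linalg.eigvalsh(a).astype(complex)
    else:
        raw = scipy.linalg.eigvals(a)
    rho = float(np.max(np.abs(raw))) if n else 0.0
    scale = max(1.0, rho)
    tol_abs = cluster_tol * scale

    # Snap near-integer eigenvalues of integer tables to exact integers.
    snapped = raw.copy()
    near_int = (np.abs(raw.real - np.rint(raw.real)) < 1e-6) & (np.abs(raw.imag) < 1e-6)
    snapped[near_int] = np.rint(raw.real[near_int])

    is_real = bool(np.max(np.abs(snapped.imag), initial=0.0) < max(tol_abs, 1e-9))
    if is_real:
        snapped = snapped.real.astype(complex)

    order = np.lexsort((snapped.imag, snapped.real))
    ordered = snapped[order]
    clusters: list[list[complex]] = [[ordered[0]]]
    for ev in ordered[1:]:
        if abs(ev - clusters[-1][-1]) <= max(tol_abs, 1e-9):
            clusters[-1].append(ev)
        else:
            clusters.append([ev])

    eigenvalues = np.array([np.mean(c) for c in clusters])
    mults = np.array([len(c) for c in clusters], dtype=int)

    kernel_tol = max(tol_abs * 100, 1e-9 * scale)
    p_bases: list[np.ndarray] = []
    g_bases: list[np.ndarray] = []
    for mu, alpha in zip(eigenvalues, mults):
        if abs(mu.imag) < max(tol_abs, 1e-9):
            op = a - mu.real * np.eye(n)
            p = _null_basis(op, kernel_tol)
            g = p if p.shape[1] == alpha else _null_basis(
                np.linalg.matrix_power(op, int(alpha)),
                kernel_tol * np.linalg.norm(op, 2) ** max(int(alpha) - 1, 0),
            )
        else:
            op = (a - mu * np.eye(n)) @ (a - np.conj(mu) * np.eye(n))
            op = op.real
            p = _null_basis(op, kernel_tol * max(1.0, np.linalg.norm(op, 2) / scale))
            g = p if p.shape[1] == 2 * alpha else _null_basis(
                np.linalg.matrix_power(op, int(alpha)), kernel_tol * scale ** alpha
            )
        p = np.column_stack([_fix_phase(p[:, i]) for i in range(p.shape[1])]) if p.size else p
        g = np.column_stack([_fix_phase(g[:, i]) for i in range(g.shape[1])]) if g.size else g
        p_bases.append(p)
        g_bases.append(g)

    return SpectralData(
        eigenvalues=eigenvalues,
        multiplicities=mults,
        eigenvectors=tuple(p_bases),
        generalized_bases=tuple(g_bases),
        is_real_spectrum=is_real,
        spectral_radius=rho,
        n_nodes=n,
    )


def jacobian_spectrum(
    lin: Linearization, spec: SpectralData
) -> list[JacobianEigenpair]:
    """Jacobian eigenpairs via the reduced matrices ``Q + mu_j R``.

    Returns ``n * s`` eigenpairs counted with multiplicity: for every
    clustered adjacency eigenvalue ``mu_j`` (multiplicity ``alpha_j``)
    and every eigenspace basis vector of ``P^{mu_j}``, the ``s``
    eigenvalues of ``Q + mu_j R`` with their cell-level eigenvectors.
    """
    pairs: list[JacobianEigenpair] = []
    s = lin.node_dim
    for j, (mu, alpha) in enumerate(zip(spec.eigenvalues, spec.multiplicities)):
        mu_s = mu.real if abs(mu.imag) < 1e-12 else mu
        reduced = lin.Q + mu_s * lin.R
        w, u = np.linalg.eig(reduced)
        basis = spec.eigenvectors[j]
        g = max(basis.shape[1], 1)
        for copy in range(int(alpha)):
            v = basis[:, copy % g] if basis.size else np.zeros(spec.n_nodes)
            for m in range(s):
                pairs.append(
                    JacobianEigenpair(
                        eigenvalue=complex(w[m]),
                        cell_part=np.array(u[:, m]),
                        network_part=v,
                        mu_index=j,
                    )
                )
    return pairs


def assemble_full_jacobian(lin: Linearization, network: RegularNetwork) -> np.ndarray:
    """Dense Jacobian: diagonal blocks ``Q``, block ``(i, j)`` adds
    ``arrow_counts[i, j] * R`` (self-arrow counts add to the diagonal)."""
    n = network.n_nodes
    a = network.arrow_counts.astype(float)
    return np.kron(np.eye(n), lin.Q) + np.kron(a, lin.R)


def critical_pattern_space(
    spec: SpectralData, critical_indices: Iterable[int]
) -> np.ndarray:
    """Orthonormal basis of the direct sum of the eigenspaces ``P^{mu_j}``
    over the critical index set."""
    idx = sorted(set(int(i) for i in critical_indices))
    if not idx:
        raise ValueError("critical index set must be nonempty")
    for i in idx:
        if not 0 <= i < spec.n_clusters:
            raise IndexError(f"eigenvalue index {i} out of range")
    stacked = np.column_stack([spec.eigenvectors[i] for i in idx])
    q, r = np.linalg.qr(stacked)
    keep = np.abs(np.diag(r)) > 1e-10
    return np.column_stack([_fix_phase(q[:, i]) for i in range(q.shape[1]) if keep[i]])
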