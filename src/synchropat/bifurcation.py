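"""Synchronous-branch continuation and first-bifurcation detection.

An *admissible* ODE on a regular network gives every cell the same rate
function of its own state and of the (arrow-weighted) sum of its input
states.  Along the fully synchronous branch the Jacobian spectrum is
carried by the reduced matrices ``Q + mu_i R``; as the bifurcation
parameter ramps, the first reduced eigenvalue to reach the imaginary
axis determines the critical pattern space and hence the preferred
tissue pattern.  This module locates that first crossing, classifies
it, and verifies the genericity hypotheses (trivial intersection of the
critical generalized eigenspace with the synchronous subspace, and a
one-dimensional intersection with the predicted polysynchrony
subspace) under which a unique patterned branch bifurcates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.optimize

from .classify import (
    ClassificationResult,
    classify_1d,
    classify_2d_detR0,
    criticality_tolerance,
)
from .colorings import (
    Coloring,
    coarsest_balanced_refinement,
    coloring_from_vector,
    is_balanced,
    monochrome,
    subspace_intersection_dim,
)
from .network import RegularNetwork
from .spectral import (
    Linearization,
    SpectralData,
    adjacency_spectrum,
    critical_pattern_space,
)

__all__ = [
    "AdmissibleODEFamily",
    "BifurcationReport",
    "BranchError",
    "synchronous_equilibrium",
    "find_first_bifurcation",
    "reduced_max_real_parts",
]


class BranchError(RuntimeError):
    """Continuation of the synchronous branch failed."""


@dataclass(frozen=True)
class AdmissibleODEFamily:
    """A parameterized admissible ODE on a regular network.

    ``cell_rate(u, neighbor_sum, lam)`` returns the rate of one cell
    given its own state ``u`` and the arrow-count-weighted *sum* of its
    input-cell states.  Accepting only the sum guarantees the symmetry
    over individual inputs that admissibility requires.  The function
    must broadcast over leading axes (it is called with ``(n, s)``
    stacks during integration).

    ``jacobian_blocks(u, lam) -> (Q, R)`` may supply analytic
    linearizations at synchronous points; otherwise they are obtained by
    central finite differences of ``cell_rate``.
    """

    network: RegularNetwork
    node_dim: int
    cell_rate: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    jacobian_blocks: Callable[[np.ndarray, float], tuple[np.ndarray, np.ndarray]] | None = None
    name: str = "custom"

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    def synchronous_rate(self, u: np.ndarray, lam: float) -> np.ndarray:
        """Cell rate on the synchronous subspace (every input equals u)."""
        u = np.asarray(u, dtype=float)
        return np.asarray(
            self.cell_rate(u, self.network.valence * u, lam), dtype=float
        )

    def vector_field(self, x: np.ndarray, lam: float) -> np.ndarray:
        """Full network vector field on node-major states of length n*s."""
        n, s = self.n_nodes, self.node_dim
        states = np.asarray(x, dtype=float).reshape(n, s)
        nbr = self.network.arrow_counts @ states
        return np.asarray(self.cell_rate(states, nbr, lam), dtype=float).reshape(-1)

    def linearization(self, u: np.ndarray, lam: float) -> Linearization:
        """Q and R at the synchronous point ``u`` (analytic or differenced)."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if self.jacobian_blocks is not None:
            q, r = self.jacobian_blocks(u, lam)
            return Linearization(Q=q, R=r, x0=u, lam0=lam)
        s = self.node_dim
        nu = self.network.valence
        q = np.empty((s, s))
        r = np.empty((s, s))
        nbr = nu * u
        for j in range(s):
            h = 1e-6 * (1.0 + abs(u[j]))
            e = np.zeros(s)
            e[j] = h
            q[:, j] = (
                np.asarray(self.cell_rate(u + e, nbr, lam), dtype=float)
                - np.asarray(self.cell_rate(u - e, nbr, lam), dtype=float)
            ) / (2 * h)
            r[:, j] = (
                np.asarray(self.cell_rate(u, nbr + e, lam), dtype=float)
                - np.asarray(self.cell_rate(u, nbr - e, lam), dtype=float)
            ) / (2 * h)
        return Linearization(Q=q, R=r, x0=u, lam0=lam)


@dataclass(frozen=True)
class BifurcationReport:
    """First crossing of the synchronous branch and its interpretation."""

    lambda0: float
    x0: np.ndarray
    critical_indices: tuple[int, ...]
    critical_adjacency_eigenvalues: tuple[float, ...]
    eigenvalue_type: str  # "real" or "imaginary_pair"
    hopf_frequency: float | None
    critical_pattern_basis: np.ndarray
    predicted_coloring: Coloring | None
    coloring_repaired: bool
    synchrony_breaking: bool
    classification: ClassificationResult | None
    g_cap_delta_trivial: bool
    dim_g_cap_delta_bowtie: int | None
    other_modes_nonnegative: bool
    notes: tuple[str, ...] = field(default=())


def synchronous_equilibrium(
    family: AdmissibleODEFamily,
    lam: float,
    guess,
    *,
    residual_tol: float = 1e-10,
) -> np.ndarray:
    """Solve ``f(u, nu * u, lam) = 0`` for the synchronous cell state.

    Damped root-finding (hybrid Powell) from ``guess``; the residual is
    polished to ``residual_tol`` or a BranchError is raised.
    """
    guess = np.atleast_1d(np.asarray(guess, dtype=float))
    sol = scipy.optimize.root(
        lambda u: family.synchronous_rate(u, lam), guess, method="hybr", tol=1e-13
    )
    res = np.linalg.norm(family.synchronous_rate(sol.x, lam))
    if res > residual_tol:
        raise BranchError(
            f"no synchronous equilibrium found from guess at lambda={lam:.6g} "
            f"(residual {res:.3g})"
        )
    return np.atleast_1d(sol.x)


def reduced_max_real_parts(
    lin: Linearization, spec: SpectralData
) -> np.ndarray:
    """Max real part of the eigenvalues of ``Q + mu_i R``, per cluster."""
    out = np.empty(spec.n_clusters)
    for i, mu in enumerate(spec.eigenvalues):
        mu_s = mu.real if abs(mu.imag) < 1e-12 else mu
        out[i] = np.max(np.linalg.eigvals(lin.Q + mu_s * lin.R).real)
    return out


def _select_pattern_coloring(
    basis: np.ndarray,
    gen_basis: np.ndarray,
    network: RegularNetwork,
    vec_tol: float,
) -> tuple[Coloring | None, bool, int | None]:
    """Choose the balanced coloring induced by the critical pattern space.

    Each basis vector induces a candidate coloring (equal entries share
    a color).  Among candidates that are balanced and meet the
    one-dimensional-intersection hypothesis, the one with fewest colors
    (ties by lexicographic color sequence) is preferred; otherwise the
    first vector's coloring is repaired by partition refinement.
    """
    candidates: list[tuple[int, tuple[int, ...], Coloring]] = []
    for i in range(basis.shape[1]):
        col = coloring_from_vector(basis[:, i], tol=vec_tol)
        if is_balanced(network, col):
            if subspace_intersection_dim(gen_basis, col) == 1:
                candidates.append((col.n_colors, col.colors, col))
    if candidates:
        candidates.sort(key=lambda t: (t[0], t[1]))
        col = candidates[0][2]
        return col, False, subspace_intersection_dim(gen_basis, col)
    col = coarsest_balanced_refinement(
        network, coloring_from_vector(basis[:, 0], tol=vec_tol)
    )
    return col, True, subspace_intersection_dim(gen_basis, col)


def find_first_bifurcation(
    family: AdmissibleODEFamily,
    lam_range: tuple[float, float],
    *,
    guess=None,
    n_grid: int = 200,
    refine_tol: float = 1e-9,
    cluster_tol: float = 1e-8,
    vec_tol: float = 1e-6,
) -> BifurcationReport:
    """Continue the synchronous branch and classify its first eigenvalue
    crossing.

    The branch is tracked over an evenly spaced ``lam`` grid (each
    solution seeding the next solve); the first sign change of the
    maximal reduced-spectrum real part is bracketed and refined by
    bisection until that real part is within ``refine_tol`` of zero.
    Raises BranchError when the branch is already unstable at the range
    start, no crossing occurs in range, or continuation fails while all
    eigenvalues are still negative (a fold is then suspected).
    """
    lam_lo, lam_hi = float(lam_range[0]), float(lam_range[1])
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    spec = adjacency_spectrum(family.network, cluster_tol=cluster_tol)
    s = family.node_dim
    u = np.zeros(s) if guess is None else np.atleast_1d(np.asarray(guess, dtype=float))

    def branch_point(lam: float, seed: np.ndarray) -> tuple[np.ndarray, Linearization, float]:
        ustar = synchronous_equilibrium(family, lam, seed)
        lin = family.linearization(ustar, lam)
        return ustar, lin, float(np.max(reduced_max_real_parts(lin, spec)))

    grid = np.linspace(lam_lo, lam_hi, n_grid)
    u, lin, m_prev = branch_point(grid[0], u)
    if m_prev >= 0:
        raise BranchError(
            f"synchronous branch is not stable at the start of the range "
            f"(max Re = {m_prev:.3g} at lambda={lam_lo:.6g})"
        )
    lam_prev, u_prev = grid[0], u
    bracket = None
    for lam in grid[1:]:
        try:
            u, lin, m = branch_point(lam, u_prev)
        except BranchError as err:
            raise BranchError(
                f"fold suspected: branch continuation failed at lambda={lam:.6g} "
                f"while all eigenvalues were still negative ({err})"
            ) from err
        if m >= 0:
            bracket = (lam_prev, lam, u_prev)
            break
        lam_prev, u_prev, m_prev = lam, u, m
    if bracket is None:
        raise BranchError(
            f"no eigenvalue crossing in lambda range [{lam_lo:.6g}, {lam_hi:.6g}]"
        )

    lo, hi, seed = bracket
    u_lo = u_prev
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        u_mid, lin_mid, m_mid = branch_point(mid, u_lo)
        if abs(m_mid) <= refine_tol:
            lam0, u0, lin0 = mid, u_mid, lin_mid
            break
        if m_mid < 0:
            lo, u_lo = mid, u_mid
        else:
            hi = mid
    else:
        lam0 = 0.5 * (lo + hi)
        u0, lin0, m_mid = branch_point(lam0, u_lo)

    tol = max(criticality_tolerance(lin0, spec), 10 * refine_tol)
    per_cluster = reduced_max_real_parts(lin0, spec)
    crit = tuple(int(i) for i in np.nonzero(per_cluster >= -tol)[0])
    if not crit:
        raise BranchError("internal error: refined point has no critical mode")
    other_nonneg = bool(
        np.any(per_cluster[[i for i in range(spec.n_clusters) if i not in crit]] >= 0)
    ) if len(crit) < spec.n_clusters else False

    # eigenvalue type at the critical modes
    hopf_freq = None
    etype = "real"
    for i in crit:
        mu = spec.eigenvalues[i]
        mu_s = mu.real if abs(mu.imag) < 1e-12 else mu
        w = np.linalg.eigvals(lin0.Q + mu_s * lin0.R)
        wc = w[np.argmax(w.real)]
        if abs(wc.imag) > tol:
            etype = "imaginary_pair"
            hopf_freq = float(abs(wc.imag))

    basis = critical_pattern_space(spec, crit)
    gen_basis = np.column_stack([spec.generalized_bases[i] for i in crit])

    # classification via the sign machinery where it applies
    classification: ClassificationResult | None = None
    cls_notes: list[str] = []
    try:
        if s == 1:
            classification = classify_1d(
                float(lin0.Q[0, 0]), float(lin0.R[0, 0]), spec,
                network=family.network, tol=tol,
            )
        elif s == 2:
            classification = classify_2d_detR0(
                lin0, spec, network=family.network, tol=tol
            )
        if classification is not None and classification.refused:
            cls_notes.extend(classification.notes)
            classification = None
    except ValueError as err:
        cls_notes.append(f"classification unavailable: {err}")

    synchrony_breaking = not (
        len(crit) == 1 and crit[0] == spec.max_index
    )
    predicted_coloring: Coloring | None = None
    repaired = False
    dim_bowtie: int | None = None
    if etype == "real" or synchrony_breaking:
        predicted_coloring, repaired, dim_bowtie = _select_pattern_coloring(
            basis, gen_basis, family.network, vec_tol
        )
        if etype == "imaginary_pair":
            cls_notes.append(
                "oscillatory: coloring describes the synchrony pattern of the "
                "predicted periodic branch"
            )

    g_cap_delta = subspace_intersection_dim(gen_basis, monochrome(family.n_nodes))

    return BifurcationReport(
        lambda0=float(lam0),
        x0=u0,
        critical_indices=crit,
        critical_adjacency_eigenvalues=tuple(
            float(spec.eigenvalues[i].real) for i in crit
        ),
        eigenvalue_type=etype,
        hopf_frequency=hopf_freq,
        critical_pattern_basis=basis,
        predicted_coloring=predicted_coloring,
        coloring_repaired=repaired,
        synchrony_breaking=synchrony_breaking,
        classification=classification,
        g_cap_delta_trivial=(g_cap_delta == 0),
        dim_g_cap_delta_bowtie=dim_bowtie,
        other_modes_nonnegative=other_nonneg,
        notes=tuple(cls_notes),
    )
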