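"""Classification of first bifurcations from the synchronous branch.

For one- and two-species cells, the critical pattern space of the first
bifurcation is determined by qualitative features of the internal (Q)
and coupled (R) dynamics together with the extreme adjacency
eigenvalues.  The key observation: the real part (trace) and, when
``det R = 0``, the determinant of ``Q + mu R`` are *linear* in ``mu``,
so as the bifurcation parameter moves they can first touch zero only at
the smallest eigenvalue ``mu_1``, the largest ``mu_k``, or everywhere
at once.  Enumerating which line vanishes where yields fifteen cases;
each maps to a critical pattern space, a critical-eigenvalue type
(real crossing vs. purely imaginary Hopf pair) and a multiplicity.

Two sufficient nondegeneracy certificates (in terms of the valence
``nu``) rule out one of the two lines entirely:

* ``det Q > |nu B|``  — the determinant line stays positive, so the
  criticality must be a single imaginary pair;
* ``tr Q < -|nu tr R|`` — the trace line stays negative, so the
  criticality must be a single real crossing.

Here ``B = tr(Q) tr(R) - tr(QR)`` is the slope of the determinant line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import RegularNetwork, is_strongly_connected
from .spectral import Linearization, SpectralData

__all__ = [
    "DegeneracyStatistics",
    "ClassificationResult",
    "NotAtBifurcationError",
    "stability_preconditions",
    "classify_1d",
    "degeneracy_statistics",
    "classify_2d_detR0",
    "ndg_conditions",
    "theorem13_feasible_spaces",
    "PATTERN_LABELS",
]

PATTERN_LABELS = ("P_mu1", "P_muk", "P_mu1_plus_P_muk", "full_space", "refused")


class NotAtBifurcationError(ValueError):
    """No reduced matrix has a critical eigenvalue at the given tolerance."""


@dataclass(frozen=True)
class DegeneracyStatistics:
    """Scalar statistics of a 2x2 linearization used by the classifier.

    ``trace_line`` holds the coefficients of ``p1(mu) = tr Q + mu tr R``;
    ``det_line`` those of ``p2(mu) = det Q + mu B``, which represents
    ``det(Q + mu R)`` only when ``det R = 0`` (it is None otherwise).
    """

    tr_Q: float
    tr_R: float
    det_Q: float
    det_R: float
    B: float
    trace_line: tuple[float, float]
    det_line: tuple[float, float] | None


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of a first-bifurcation classification."""

    pattern_space_label: str
    eigenvalue_type: str  # "real", "imaginary_pair", "mixed", or "none"
    critical_multiplicity: str
    synchrony_breaking: bool
    critical_indices: tuple[int, ...]
    table1_row: int | None = None
    degenerate: bool = False
    hopf_frequency: float | None = None
    notes: tuple[str, ...] = field(default=())

    @property
    def refused(self) -> bool:
        return self.pattern_space_label == "refused"


def _refusal(reason: str) -> ClassificationResult:
    return ClassificationResult(
        pattern_space_label="refused",
        eigenvalue_type="none",
        critical_multiplicity="0",
        synchrony_breaking=False,
        critical_indices=(),
        notes=(reason,),
    )


def _check_assumptions(
    spec: SpectralData, network: RegularNetwork | None
) -> str | None:
    """Return a refusal reason when a classification assumption fails."""
    if not spec.is_real_spectrum:
        return "refused: adjacency spectrum is not real"
    if network is not None:
        if network.has_self_arrows:
            return "refused: network has self-arrows (no-self-arrow assumption)"
        if not is_strongly_connected(network):
            return "refused: network is not strongly connected"
    return None


def stability_preconditions(lin: Linearization) -> list[str]:
    """Necessary conditions for a stable synchronous branch; empty if met.

    One-species cells need ``Q < 0``; two-species cells need
    ``tr Q < 0``.  Both follow from stability because the adjacency
    matrix of a no-self-arrow regular network always has eigenvalues of
    both signs, so ``Q + mu R`` (resp. its trace) is squeezed below zero
    at ``mu = 0`` regardless of the sign of ``R``.
    """
    s = lin.node_dim
    if s == 1:
        return [] if lin.Q[0, 0] < 0 else ["Q >= 0: synchronous branch cannot be stable"]
    if s == 2:
        return (
            []
            if np.trace(lin.Q) < 0
            else ["tr(Q) >= 0: synchronous branch cannot be stable"]
        )
    raise ValueError("stability preconditions are stated for 1- or 2-species cells")


def criticality_tolerance(lin: Linearization, spec: SpectralData) -> float:
    """Absolute band within which an eigenvalue real part counts as zero."""
    mu_k = spec.eigenvalues[spec.max_index].real
    reduced = lin.Q + mu_k * lin.R
    rho = float(np.max(np.abs(np.linalg.eigvals(reduced)))) if reduced.size else 0.0
    return 1e-7 * max(1.0, rho)


def classify_1d(
    q_scalar: float,
    r_scalar: float,
    spec: SpectralData,
    *,
    network: RegularNetwork | None = None,
    tol: float | None = None,
) -> ClassificationResult:
    """First-bifurcation trichotomy for one-species cells.

    At a critical point (``Q + mu_j R = 0`` for some adjacency
    eigenvalue), the sign of the coupling derivative ``R`` alone decides
    the critical pattern space: ``R < 0`` (lateral inhibition) breaks
    synchrony with pattern space ``P^{mu_1}``; ``R > 0`` preserves it
    (``P^{mu_k}``, the uniform direction); ``R = 0`` is fully
    degenerate (every eigenspace is critical at once).
    """
    lin = Linearization(Q=[[float(q_scalar)]], R=[[float(r_scalar)]])
    reason = _check_assumptions(spec, network)
    if reason is not None:
        return _refusal(reason)
    if tol is None:
        tol = criticality_tolerance(lin, spec)
    mus = spec.eigenvalues.real
    values = float(q_scalar) + mus * float(r_scalar)
    critical = np.nonzero(np.abs(values) <= tol)[0]
    if critical.size == 0:
        raise NotAtBifurcationError(
            "not at a bifurcation: no reduced matrix Q + mu R is critical"
        )
    alpha = spec.multiplicities
    k = spec.max_index
    if abs(r_scalar) <= tol:
        return ClassificationResult(
            pattern_space_label="full_space",
            eigenvalue_type="real",
            critical_multiplicity=f"{int(alpha.sum())} (all alpha_i, real)",
            synchrony_breaking=True,
            critical_indices=tuple(range(spec.n_clusters)),
            degenerate=True,
            notes=("R = 0: coupling-independent criticality in every eigenspace",),
        )
    if r_scalar < 0:
        return ClassificationResult(
            pattern_space_label="P_mu1",
            eigenvalue_type="real",
            critical_multiplicity=f"{int(alpha[0])} (alpha_1, real)",
            synchrony_breaking=True,
            critical_indices=(0,),
            notes=("R < 0: synchrony-breaking crossing at mu_1",),
        )
    return ClassificationResult(
        pattern_space_label="P_muk",
        eigenvalue_type="real",
        critical_multiplicity="1 (real)",
        synchrony_breaking=False,
        critical_indices=(k,),
        notes=("R > 0: synchrony-preserving crossing at mu_k",),
    )


def degeneracy_statistics(
    lin: Linearization, det_r_tol: float = 1e-9
) -> DegeneracyStatistics:
    """Traces, determinants and the determinant-line slope B for s = 2."""
    if lin.node_dim != 2:
        raise ValueError("degeneracy statistics are defined for 2-species cells")
    q, r = lin.Q, lin.R
    tr_q, tr_r = float(np.trace(q)), float(np.trace(r))
    det_q, det_r = float(np.linalg.det(q)), float(np.linalg.det(r))
    b = tr_q * tr_r - float(np.trace(q @ r))
    scale = max(1.0, float(np.abs(r).max()) ** 2)
    det_line = (det_q, b) if abs(det_r) <= det_r_tol * scale else None
    return DegeneracyStatistics(
        tr_Q=tr_q,
        tr_R=tr_r,
        det_Q=det_q,
        det_R=det_r,
        B=b,
        trace_line=(tr_q, tr_r),
        det_line=det_line,
    )


def ndg_conditions(lin: Linearization, valence: float) -> dict[str, bool]:
    """Sufficient nondegeneracy certificates for 2-species cells.

    ``imaginary_pair_certified``: ``det Q > |nu B|`` keeps the
    determinant line positive on the whole spectrum (spectral radius is
    the valence), so criticality can only be an imaginary pair from one
    reduced matrix.  ``single_real_certified``: ``tr Q < -|nu tr R|``
    keeps the trace line negative, so criticality can only be a single
    real crossing.
    """
    stats = degeneracy_statistics(lin)
    nu = float(valence)
    return {
        "imaginary_pair_certified": stats.det_Q > abs(nu * stats.B),
        "single_real_certified": stats.tr_Q < -abs(nu * stats.tr_R),
    }


# (p1 root category, p2 root category) -> Table-1 row and its report.
# Categories: where each line vanishes on the adjacency spectrum —
# nowhere, at mu_1 only, at mu_k only, or identically.
_TABLE1: dict[tuple[str, str], dict] = {
    ("none", "mu1"): dict(row=1, label="P_mu1", etype="real", mult="alpha_1 (real)"),
    ("mu1", "none"): dict(
        row=2, label="P_mu1", etype="imaginary_pair", mult="2*alpha_1 (imaginary)"
    ),
    ("none", "muk"): dict(row=3, label="P_muk", etype="real", mult="1 (real)"),
    ("muk", "none"): dict(
        row=4, label="P_muk", etype="imaginary_pair", mult="2 (imaginary)"
    ),
    ("mu1", "mu1"): dict(row=5, label="P_mu1", etype="real", mult="2*alpha_1 (real)"),
    ("muk", "muk"): dict(row=6, label="P_muk", etype="real", mult="2 (real)"),
    ("muk", "mu1"): dict(
        row=7,
        label="P_mu1_plus_P_muk",
        etype="mixed",
        mult="alpha_1 (real) + 2 (imaginary)",
    ),
    ("mu1", "muk"): dict(
        row=8,
        label="P_mu1_plus_P_muk",
        etype="mixed",
        mult="2*alpha_1 (imaginary) + 1 (real)",
    ),
    ("all", "mu1"): dict(
        row=9,
        label="full_space",
        etype="mixed",
        mult="2*alpha_1 (real) + sum_{j!=1} 2*alpha_j (imaginary)",
    ),
    ("all", "muk"): dict(
        row=10,
        label="full_space",
        etype="mixed",
        mult="2 (real) + sum_{j!=k} 2*alpha_j (imaginary)",
    ),
    ("mu1", "all"): dict(
        row=11,
        label="full_space",
        etype="real",
        mult="2*alpha_1 (real) + sum_{j!=1} alpha_j (real)",
    ),
    ("muk", "all"): dict(
        row=12,
        label="full_space",
        etype="real",
        mult="2 (real) + sum_{j!=k} alpha_j (real)",
    ),
    ("all", "none"): dict(
        row=13, label="full_space", etype="imaginary_pair", mult="sum_j 2*alpha_j (imaginary)"
    ),
    ("none", "all"): dict(
        row=14, label="full_space", etype="real", mult="sum_j alpha_j (real)"
    ),
    ("all", "all"): dict(
        row=15, label="full_space", etype="real", mult="sum_j 2*alpha_j (real)"
    ),
}


def _root_category(values: np.ndarray, tol: float) -> str:
    """Where a line vanishes on the ordered spectrum: none/mu1/muk/all."""
    roots = set(np.nonzero(np.abs(values) <= tol)[0].tolist())
    k = values.size - 1
    if not roots:
        return "none"
    if len(roots) == values.size:
        return "all"
    if roots == {0}:
        return "mu1"
    if roots == {k}:
        return "muk"
    raise NotAtBifurcationError(
        f"inconsistent root set {sorted(roots)}: the synchronous branch cannot "
        "have been stable up to this point (interior or partial roots of a line)"
    )


def classify_2d_detR0(
    lin: Linearization,
    spec: SpectralData,
    *,
    network: RegularNetwork | None = None,
    tol: float | None = None,
) -> ClassificationResult:
    """Classify a first bifurcation for two-species cells with ``det R = 0``.

    Evaluates the trace line ``p1`` and determinant line ``p2`` at every
    clustered adjacency eigenvalue, maps their root locations to the
    fifteen enumerated cases, and reports the critical pattern space,
    eigenvalue type and (symbolic) multiplicity.  Rows 5-15 are
    degenerate; for rows 1-4 the notes record whether nondegeneracy was
    certified by the valence inequalities or by direct evaluation.

    Pass ``network`` to enforce the no-self-arrow and strong-connectivity
    assumptions; a violation (or a non-real spectrum) yields a refusal
    result rather than an exception.
    """
    if lin.node_dim != 2:
        raise ValueError("this classifier handles 2-species cells only")
    reason = _check_assumptions(spec, network)
    if reason is not None:
        return _refusal(reason)
    stats = degeneracy_statistics(lin)
    if stats.det_line is None:
        return _refusal(
            f"refused: det R = {stats.det_R:.3g} != 0; the determinant of "
            "Q + mu R is not linear in mu and this enumeration does not apply"
        )
    if tol is None:
        tol = criticality_tolerance(lin, spec)
    mus = spec.eigenvalues.real
    p1 = stats.tr_Q + mus * stats.tr_R
    p2 = stats.det_Q + mus * stats.B
    cat1 = _root_category(p1, tol)
    cat2 = _root_category(p2, tol)
    if (cat1, cat2) == ("none", "none"):
        raise NotAtBifurcationError(
            "not at a bifurcation: neither the trace line nor the determinant "
            "line vanishes at any adjacency eigenvalue"
        )
    entry = _TABLE1[(cat1, cat2)]
    row = entry["row"]
    degenerate = row >= 5

    crit: set[int] = set()
    k = spec.max_index
    for cat in (cat1, cat2):
        if cat == "mu1":
            crit.add(0)
        elif cat == "muk":
            crit.add(k)
        elif cat == "all":
            crit.update(range(spec.n_clusters))

    notes = [f"p1 roots: {cat1}; p2 roots: {cat2}"]
    hopf_freq = None
    if entry["etype"] in ("imaginary_pair", "mixed"):
        # frequency of the imaginary pair: sqrt(det) of the Hopf-side matrix
        hopf_idx = 0 if cat1 == "mu1" else k
        det_at = stats.det_Q + mus[hopf_idx] * stats.B
        if det_at > 0:
            hopf_freq = float(np.sqrt(det_at))
    if not degenerate:
        valence = mus[k] if network is None else network.valence
        cert = ndg_conditions(lin, valence)
        if row in (1, 3) and cert["single_real_certified"]:
            notes.append("NDG certified: tr(Q) < -|nu tr(R)| (valence inequality)")
        elif row in (2, 4) and cert["imaginary_pair_certified"]:
            notes.append("NDG certified: det(Q) > |nu B| (valence inequality)")
        else:
            notes.append("NDG certified numerically: the other line has no root")

    return ClassificationResult(
        pattern_space_label=entry["label"],
        eigenvalue_type=entry["etype"],
        critical_multiplicity=entry["mult"],
        synchrony_breaking=entry["label"] != "P_muk",
        critical_indices=tuple(sorted(crit)),
        table1_row=row,
        degenerate=degenerate,
        hopf_frequency=hopf_freq,
        notes=tuple(notes),
    )


def theorem13_feasible_spaces(det_r: float) -> set[str]:
    """Critical pattern spaces feasible for two-species cells given det R.

    With ``det R <= 0`` the determinant of ``Q + mu R`` is concave in
    ``mu`` (downward parabola) and positive on the spectrum before the
    bifurcation, so it can first vanish only at an extreme eigenvalue:
    the pattern space is restricted to ``P^{mu_1}``, ``P^{mu_k}``,
    their sum, or the full space.  ``det R > 0`` imposes no restriction
    (any interior eigenspace can be selected first).
    """
    restricted = {"P_mu1", "P_muk", "P_mu1_plus_P_muk", "full_space"}
    if det_r <= 0:
        return restricted
    return restricted | {"P_mu_interior"}
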