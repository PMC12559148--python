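"""Inferring sign constraints on biochemical interactions from patterns.

Forward, the classification machinery maps signs of the internal (Q)
and coupled (R) linearizations to the first bifurcation's outcome.
Backward, an observed tissue-level outcome (homogeneous steady state,
synchronous oscillation, oscillating pattern, or steady pattern)
restricts the admissible signs: every sign assignment to the unknown
entries is enumerated, kept only if some numeric instantiation is
jointly consistent with synchronous-branch stability and with the
outcome's necessary conditions, and the conclusions are whatever signs
and pairwise sign relations hold across *all* survivors.

Sign semantics: ``+`` is (0, inf), ``-`` is (-inf, 0), ``0`` is exactly
zero, ``?`` is unknown.  The necessary conditions used (two-species
cells, ``det R = 0``) are those of the nondegenerate first-crossing
enumeration: a steady pattern needs determinant-line slope ``B > 0``, a
homogeneous steady outcome ``B < 0``, an oscillating pattern
``tr R < 0``, a synchronous oscillation ``tr R > 0``.  Degenerate
crossings are excluded by default (they are unlikely in biological
systems); ``include_degenerate`` restores the multi-eigenvalue cases,
which weakens the conclusions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .spectral import SpectralData

__all__ = [
    "SignSkeleton",
    "ObservedOutcome",
    "InferenceConclusion",
    "infer_signs",
    "infer_from_pattern_space",
    "OUTCOME_CATEGORIES",
]

OUTCOME_CATEGORIES = (
    "homogeneous_steady",
    "synchronous_oscillation",
    "oscillating_pattern",
    "steady_pattern",
)

_SIGNS = ("+", "-", "0")
_DEFAULT_Q_NAMES = (("a", "b"), ("c", "d"))
_DEFAULT_R_NAMES = (("kappa11", "kappa12"), ("kappa21", "kappa22"))


@dataclass(frozen=True)
class SignSkeleton:
    """Sign tables for Q and R with entries in {+, -, 0, ?}.

    ``variable_names`` give reporting labels for the entries; defaults
    are a, b, c, d for Q and kappa_ij for R (a single unknown coupling
    is conventionally called ``kappa``).
    """

    Q_signs: tuple[tuple[str, ...], ...]
    R_signs: tuple[tuple[str, ...], ...]
    Q_names: tuple[tuple[str, ...], ...] | None = None
    R_names: tuple[tuple[str, ...], ...] | None = None

    def __post_init__(self) -> None:
        q = tuple(tuple(row) for row in self.Q_signs)
        r = tuple(tuple(row) for row in self.R_signs)
        s = len(q)
        if s not in (1, 2) or any(len(row) != s for row in q) or len(r) != s or any(
            len(row) != s for row in r
        ):
            raise ValueError("skeleton must be square 1x1 or 2x2, Q and R matching")
        for table in (q, r):
            for row in table:
                for entry in row:
                    if entry not in ("+", "-", "0", "?"):
                        raise ValueError(f"invalid sign entry {entry!r}")
        object.__setattr__(self, "Q_signs", q)
        object.__setattr__(self, "R_signs", r)
        if self.Q_names is None:
            names = _DEFAULT_Q_NAMES if s == 2 else (("Q",),)
            object.__setattr__(self, "Q_names", names)
        if self.R_names is None:
            if s == 1:
                names = (("R",),)
            else:
                # a single unknown coupling gets the conventional name kappa
                unknown = [(i, j) for i in range(2) for j in range(2) if r[i][j] != "0"]
                if len(unknown) == 1:
                    names = [["0", "0"], ["0", "0"]]
                    names[unknown[0][0]][unknown[0][1]] = "kappa"
                    names = tuple(tuple(row) for row in names)
                else:
                    names = _DEFAULT_R_NAMES
            object.__setattr__(self, "R_names", names)

    @property
    def node_dim(self) -> int:
        return len(self.Q_signs)


@dataclass(frozen=True)
class ObservedOutcome:
    """An observed tissue-level outcome, optionally with the identity of
    the adjacency eigenspace carrying the pattern."""

    category: str
    pattern_space_id: int | None = None

    def __post_init__(self) -> None:
        if self.category not in OUTCOME_CATEGORIES:
            raise ValueError(
                f"unknown outcome {self.category!r}; one of {OUTCOME_CATEGORIES}"
            )


@dataclass(frozen=True)
class InferenceConclusion:
    """Signs and relations forced by an observation, with provenance."""

    forced_signs: tuple[tuple[str, str], ...]
    forced_relations: tuple[str, ...]
    contradictions: tuple[str, ...]
    provenance: tuple[str, ...]
    n_survivors: int = 0
    notes: tuple[str, ...] = field(default=())

    @property
    def consistent(self) -> bool:
        return not self.contradictions


def _entries(skeleton: SignSkeleton):
    """Flatten skeleton entries as (matrix, i, j, sign, name)."""
    out = []
    for mat, signs, names in (
        ("Q", skeleton.Q_signs, skeleton.Q_names),
        ("R", skeleton.R_signs, skeleton.R_names),
    ):
        for i, row in enumerate(signs):
            for j, sign in enumerate(row):
                out.append((mat, i, j, sign, names[i][j]))
    return out


def _sample_matrices(assignment, s, rng, n_draws):
    """Random instantiations honouring a full sign assignment."""
    q = np.zeros((n_draws, s, s))
    r = np.zeros((n_draws, s, s))
    for (mat, i, j), sign in assignment.items():
        if sign == "0":
            continue
        mags = rng.uniform(0.1, 3.0, n_draws)
        vals = mags if sign == "+" else -mags
        (q if mat == "Q" else r)[:, i, j] = vals
    return q, r


# outcome -> list of (name, condition) alternatives in the nondegenerate case
def _outcome_conditions(category: str, s: int, include_degenerate: bool):
    if s == 1:
        # one-species cells: the reduced matrices are real scalars, so no
        # oscillatory outcome is possible at all
        table = {
            "steady_pattern": [
                (
                    "synchrony-breaking real crossing at mu_1 requires R < 0 "
                    "(negative coupling slope)",
                    lambda st: st["R"] < 0,
                )
            ],
            "homogeneous_steady": [
                (
                    "synchrony-preserving real crossing at mu_k requires R > 0",
                    lambda st: st["R"] > 0,
                )
            ],
            "synchronous_oscillation": [],
            "oscillating_pattern": [],
        }
        return table[category]

    nondeg = {
        "steady_pattern": [
            (
                "nondegenerate synchrony-breaking steady crossing requires "
                "determinant-line slope B > 0",
                lambda st: st["B"] > 0,
            )
        ],
        "homogeneous_steady": [
            (
                "nondegenerate synchrony-preserving steady crossing requires B < 0",
                lambda st: st["B"] < 0,
            )
        ],
        "oscillating_pattern": [
            (
                "nondegenerate synchrony-breaking Hopf requires tr(R) < 0",
                lambda st: st["trR"] < 0,
            )
        ],
        "synchronous_oscillation": [
            (
                "nondegenerate synchrony-preserving Hopf requires tr(R) > 0",
                lambda st: st["trR"] > 0,
            )
        ],
    }
    conds = list(nondeg[category])
    if include_degenerate:
        deg = {
            "steady_pattern": [
                ("degenerate double real crossing at mu_1 (B > 0, tr(R) < 0)",
                 lambda st: (st["B"] > 0) & (st["trR"] < 0)),
                ("degenerate mixed crossing with real part at mu_1 (B > 0, tr(R) > 0)",
                 lambda st: (st["B"] > 0) & (st["trR"] > 0)),
            ],
            "oscillating_pattern": [
                ("degenerate mixed crossing with Hopf pair at mu_1 (B < 0, tr(R) < 0)",
                 lambda st: (st["B"] < 0) & (st["trR"] < 0)),
            ],
            "synchronous_oscillation": [
                ("degenerate mixed crossing with Hopf pair at mu_k (B > 0, tr(R) > 0)",
                 lambda st: (st["B"] > 0) & (st["trR"] > 0)),
            ],
            "homogeneous_steady": [
                ("degenerate double real crossing at mu_k (B < 0, tr(R) > 0)",
                 lambda st: (st["B"] < 0) & (st["trR"] > 0)),
                ("degenerate mixed crossing with real part at mu_k (B < 0, tr(R) < 0)",
                 lambda st: (st["B"] < 0) & (st["trR"] < 0)),
            ],
        }
        conds += deg[category]
    return conds


def infer_signs(
    skeleton: SignSkeleton,
    outcome: ObservedOutcome,
    *,
    include_degenerate: bool = False,
    n_draws: int = 200,
    rng_seed: int = 12345,
) -> InferenceConclusion:
    """Derive sign constraints forced by an observed outcome.

    Enumerates sign assignments to the ``?`` entries, keeps those for
    which some numeric instantiation satisfies synchronous-branch
    stability together with the outcome's necessary conditions, and
    reports the signs and pairwise product signs common to every
    survivor.  An empty survivor set yields contradictions instead.
    """
    s = skeleton.node_dim
    rng = np.random.default_rng(rng_seed)
    entries = _entries(skeleton)
    unknowns = [(m, i, j) for (m, i, j, sign, _name) in entries if sign == "?"]
    fixed = {(m, i, j): sign for (m, i, j, sign, _name) in entries if sign != "?"}
    names = {(m, i, j): name for (m, i, j, _sign, name) in entries}

    provenance: list[str] = []
    notes: list[str] = []
    if s == 1:
        provenance.append(
            "stability of the synchronous branch requires Q < 0 "
            "(the adjacency spectrum straddles zero)"
        )
    else:
        provenance.append(
            "stability of the synchronous branch requires tr(Q) < 0 "
            "(the adjacency spectrum straddles zero)"
        )

    if s == 1 and outcome.category in (
        "synchronous_oscillation",
        "oscillating_pattern",
    ):
        return InferenceConclusion(
            forced_signs=(),
            forced_relations=(),
            contradictions=(
                "one-species cells have real reduced spectra Q + mu R; "
                "no oscillatory outcome is possible",
            ),
            provenance=tuple(provenance),
            n_survivors=0,
        )

    conditions = _outcome_conditions(outcome.category, s, include_degenerate)

    # does the skeleton force det R = 0 structurally (two-species route)?
    table1_route = True
    if s == 2:
        for combo in itertools.product(_SIGNS, repeat=len(unknowns)):
            assignment = dict(fixed)
            assignment.update(dict(zip(unknowns, combo)))
            _q, r = _sample_matrices(assignment, s, rng, 8)
            if np.max(np.abs(np.linalg.det(r))) > 1e-12:
                table1_route = False
                break
        if not table1_route:
            notes.append(
                "det(R) is not structurally zero: the linear determinant-line "
                "enumeration does not apply; only stability constraints and the "
                "det(R) bound on extreme-eigenvalue patterns are used"
            )
            conditions = []
    if conditions:
        provenance.extend(name for name, _cond in conditions)

    survivors: list[dict] = []
    for combo in itertools.product(_SIGNS, repeat=len(unknowns)):
        assignment = dict(fixed)
        assignment.update(dict(zip(unknowns, combo)))
        q, r = _sample_matrices(assignment, s, rng, n_draws)
        if s == 1:
            stats = {"Q": q[:, 0, 0], "R": r[:, 0, 0]}
            stable = stats["Q"] < 0
        else:
            tr_q = np.trace(q, axis1=1, axis2=2)
            tr_r = np.trace(r, axis1=1, axis2=2)
            b = tr_q * tr_r - np.trace(q @ r, axis1=1, axis2=2)
            stats = {"trQ": tr_q, "trR": tr_r, "B": b}
            stable = tr_q < 0
        if not conditions:
            ok = stable
        else:
            ok = np.zeros_like(stable)
            for _name, cond in conditions:
                ok |= stable & cond(stats)
        if np.any(ok):
            survivors.append(assignment)

    if not survivors:
        msgs = [
            f"the outcome '{outcome.category}' is impossible under this skeleton"
        ]
        if s == 2 and outcome.category in (
            "oscillating_pattern",
            "synchronous_oscillation",
        ):
            # the common biological case: tr(R) structurally zero kills Hopf
            all_tr_zero = all(
                skeleton.R_signs[i][i] == "0" for i in range(2)
            )
            if all_tr_zero:
                msgs.append(
                    "tr(R) = 0 structurally, so only a steady-state crossing "
                    "can occur (no oscillatory outcome)"
                )
        return InferenceConclusion(
            forced_signs=(),
            forced_relations=(),
            contradictions=tuple(msgs),
            provenance=tuple(provenance),
            n_survivors=0,
            notes=tuple(notes),
        )

    # signs common to every survivor (for originally unknown entries)
    forced: list[tuple[str, str]] = []
    for key in unknowns:
        signs = {srv[key] for srv in survivors}
        if len(signs) == 1:
            forced.append((names[key], signs.pop()))

    # pairwise product signs common to every survivor
    relations: list[str] = []
    forced_keys = {name for name, _ in forced}
    nonzero_unknowns = [k for k in unknowns if names[k] not in forced_keys]
    for k1, k2 in itertools.combinations(nonzero_unknowns, 2):
        prods = set()
        for srv in survivors:
            s1, s2 = srv[k1], srv[k2]
            if s1 == "0" or s2 == "0":
                prods.add("0")
            else:
                prods.add("+" if s1 == s2 else "-")
        if prods == {"+"}:
            relations.append(f"{names[k1]}*{names[k2]} > 0")
        elif prods == {"-"}:
            relations.append(f"sgn({names[k1]}) != sgn({names[k2]})")

    return InferenceConclusion(
        forced_signs=tuple(forced),
        forced_relations=tuple(relations),
        contradictions=(),
        provenance=tuple(provenance),
        n_survivors=len(survivors),
        notes=tuple(notes),
    )


def infer_from_pattern_space(
    outcome: ObservedOutcome, spec: SpectralData
) -> InferenceConclusion:
    """Constrain det R from the identity of an observed pattern space.

    A steady pattern carried by an *interior* adjacency eigenspace
    (neither the smallest nor the largest eigenvalue) is impossible when
    ``det R <= 0`` — barring the fully degenerate case — so observing
    one forces ``det R > 0`` by contraposition.  A pattern at the
    smallest eigenvalue is consistent with ``det R <= 0`` (no sign
    forced); the largest eigenvalue's eigenspace is the synchronous
    direction and carries no spatial pattern at all.
    """
    if not spec.is_real_spectrum:
        raise ValueError("pattern-space inference requires a real adjacency spectrum")
    i = outcome.pattern_space_id
    if i is None:
        raise ValueError("pattern_space_id is required for this inference")
    if not 0 <= i < spec.n_clusters:
        raise IndexError(f"pattern_space_id {i} out of range")
    if i == spec.max_index:
        return InferenceConclusion(
            forced_signs=(),
            forced_relations=(),
            contradictions=(),
            provenance=(
                "the largest eigenvalue's eigenspace is spanned by the all-ones "
                "vector: synchrony-preserving, no spatial pattern",
            ),
            n_survivors=1,
            notes=("synchrony_preserving",),
        )
    if i == spec.min_index:
        return InferenceConclusion(
            forced_signs=(),
            forced_relations=(),
            contradictions=(),
            provenance=(
                "a pattern at the smallest eigenvalue is the generic "
                "synchrony-breaking case; consistent with det(R) <= 0, "
                "no sign of det(R) is forced",
            ),
            n_survivors=1,
        )
    return InferenceConclusion(
        forced_signs=(("det(R)", "+"),),
        forced_relations=("det(R) > 0",),
        contradictions=(),
        provenance=(
            "an interior-eigenspace pattern is impossible when det(R) <= 0 "
            "(the determinant of Q + mu R is then concave and first vanishes "
            "at an extreme eigenvalue); by contraposition det(R) > 0",
        ),
        n_survivors=1,
    )
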