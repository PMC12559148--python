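"""Integration of admissible ODEs and pattern scoring.

Trajectories are integrated with a stiff-capable adaptive solver under
a fixed or quasistatically ramped bifurcation parameter.  The emergent
pattern is scored spectrally: the final deviation from the synchronous
mean is decomposed over the adjacency eigenspaces, and the dominant
eigenspace index is compared with the classifier's prediction.  For
symmetric adjacency matrices the eigenspace projections are orthogonal,
so the projection fractions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.integrate

from .bifurcation import AdmissibleODEFamily, find_first_bifurcation, synchronous_equilibrium, BranchError
from .colorings import Coloring, coarsest_balanced_refinement, coloring_from_vector
from .models import build_model
from .network import RegularNetwork
from .spectral import SpectralData, adjacency_spectrum

__all__ = ["SimulationResult", "integrate", "run_pattern_experiment"]


@dataclass(frozen=True)
class SimulationResult:
    """A trajectory with spectral pattern diagnostics.

    ``projection_fractions[i]`` is the fraction of the squared final
    deviation captured by the adjacency eigenspace ``P^{mu_i}``;
    ``best_index``/``projection_fraction`` report the dominant one.
    ``invariance_drift`` is the maximal distance from the polysynchrony
    subspace the trajectory started in (None when the initial state was
    not polysynchronous beyond the discrete coloring).
    """

    times: np.ndarray
    states: np.ndarray  # (len(times), n*s), node-major
    final_deviation: np.ndarray  # (n, s)
    best_index: int
    projection_fraction: float
    projection_fractions: np.ndarray
    matched_coloring: Coloring
    invariance_drift: float | None
    lambda_final: float
    notes: tuple[str, ...] = field(default=())


def _pattern_diagnostics(
    family: AdmissibleODEFamily,
    spec: SpectralData,
    x_final: np.ndarray,
    coloring_tol: float = 0.1,
) -> tuple[np.ndarray, int, float, np.ndarray, Coloring]:
    n, s = family.n_nodes, family.node_dim
    final = x_final.reshape(n, s)
    deviation = final - final.mean(axis=0, keepdims=True)
    total = float(np.sum(deviation**2))
    fractions = np.zeros(spec.n_clusters)
    if total > 0:
        for i, basis in enumerate(spec.eigenvectors):
            if basis.size:
                proj = basis @ (basis.T @ deviation)
                fractions[i] = float(np.sum(proj**2)) / total
    best = int(np.argmax(fractions)) if total > 0 else spec.max_index
    # colour by the deviation of the species deviating most; repair to a
    # balanced coloring (tolerance is relative to the pattern amplitude,
    # and a numerically-zero deviation is the monochrome pattern)
    amp = float(np.max(np.abs(deviation)))
    if amp < 1e-8 * max(1.0, float(np.max(np.abs(final)))):
        matched = coarsest_balanced_refinement(
            family.network, coloring_from_vector(np.zeros(n))
        )
    else:
        sp = int(np.argmax(np.sum(deviation**2, axis=0)))
        raw = coloring_from_vector(deviation[:, sp], tol=coloring_tol)
        matched = coarsest_balanced_refinement(family.network, raw)
    return deviation, best, float(fractions[best]), fractions, matched


def _initial_polysynchrony(family: AdmissibleODEFamily, x0: np.ndarray) -> Coloring | None:
    """Balanced coloring whose subspace contains the initial state."""
    n, s = family.n_nodes, family.node_dim
    states = x0.reshape(n, s)
    # nodes share a color iff their full state vectors agree
    key: dict[tuple, int] = {}
    colors = tuple(
        key.setdefault(tuple(np.round(states[i], 12)), len(key)) for i in range(n)
    )
    col = coarsest_balanced_refinement(family.network, Coloring(colors))
    return None if col.n_colors == n else col


def integrate(
    family: AdmissibleODEFamily,
    x_init,
    lam_schedule,
    t_end: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_samples: int = 201,
    coloring_tol: float = 0.1,
    notes: tuple[str, ...] = (),
) -> SimulationResult:
    """Integrate the admissible ODE and score the final pattern.

    ``lam_schedule`` is a number (fixed parameter) or a callable
    ``t -> lam``.  Integration uses LSODA; a step-size collapse raises
    RuntimeError reporting the time reached.
    """
    x0 = np.asarray(x_init, dtype=float).ravel()
    if x0.size != family.n_nodes * family.node_dim:
        raise ValueError("x_init has wrong length for this network/model")
    if callable(lam_schedule):
        lam_of_t = lam_schedule
    else:
        lam_const = float(lam_schedule)
        lam_of_t = lambda t: lam_const  # noqa: E731

    sol = scipy.integrate.solve_ivp(
        lambda t, x: family.vector_field(x, lam_of_t(t)),
        (0.0, float(t_end)),
        x0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(0.0, float(t_end), n_samples),
        dense_output=False,
    )
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(
            f"integration failed at t={reached:.6g}: {sol.message}"
        )

    spec = adjacency_spectrum(family.network)
    deviation, best, frac, fractions, matched = _pattern_diagnostics(
        family, spec, sol.y[:, -1], coloring_tol
    )

    drift: float | None = None
    start_col = _initial_polysynchrony(family, x0)
    if start_col is not None:
        proj = start_col.subspace_basis(family.node_dim)
        resid = sol.y - proj @ (proj.T @ sol.y)
        drift = float(np.max(np.linalg.norm(resid, axis=0)))

    return SimulationResult(
        times=sol.t,
        states=sol.y.T,
        final_deviation=deviation,
        best_index=best,
        projection_fraction=frac,
        projection_fractions=fractions,
        matched_coloring=matched,
        invariance_drift=drift,
        lambda_final=float(lam_of_t(float(t_end))),
        notes=tuple(notes),
    )


def run_pattern_experiment(
    model_name: str,
    network: RegularNetwork,
    lam_ramp: tuple[float, float] | tuple[float, float, float],
    *,
    noise_amplitude: float = 1e-3,
    seed: int = 0,
    model_params: dict | None = None,
    equilibrium_guess=None,
    settle_tol: float = 1e-8,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    coloring_tol: float = 0.1,
) -> SimulationResult:
    """Ramp a model through its first bifurcation and score the pattern.

    The state starts at the synchronous equilibrium of ``lam_start``
    plus a seeded uniform perturbation of amplitude ``noise_amplitude``
    per component.  ``lam`` ramps linearly from ``lam_start`` to
    ``lam_end`` at ``rate`` per unit time (default ``1e-3`` of the
    range, i.e. a quasistatic sweep over 1000 time units), then holds at
    ``lam_end`` until the rate norm drops below ``settle_tol``.  A
    warning note is recorded when the ramp does not cross the predicted
    first-bifurcation parameter.
    """
    if noise_amplitude < 0:
        raise ValueError("noise_amplitude must be nonnegative")
    lam_start, lam_end = float(lam_ramp[0]), float(lam_ramp[1])
    rate = (
        float(lam_ramp[2])
        if len(lam_ramp) > 2
        else 1e-3 * abs(lam_end - lam_start)
    )
    if rate <= 0:
        raise ValueError("ramp rate must be positive")
    family = build_model(model_name, network, **(model_params or {}))
    n, s = family.n_nodes, family.node_dim

    guess = (
        np.full(s, 0.5) if equilibrium_guess is None else np.asarray(equilibrium_guess)
    )
    u0 = synchronous_equilibrium(family, lam_start, guess)

    notes: list[str] = []
    try:
        report = find_first_bifurcation(
            family, (lam_start, lam_end), guess=u0, n_grid=100
        )
        if not (min(lam_start, lam_end) <= report.lambda0 <= max(lam_start, lam_end)):
            notes.append("warning: ramp range excludes the predicted bifurcation")
        else:
            notes.append(f"predicted first bifurcation at lambda0={report.lambda0:.6g}")
    except BranchError as err:
        notes.append(f"warning: no bifurcation predicted in ramp range ({err})")

    rng = np.random.default_rng(seed)
    x0 = np.tile(u0, n) + rng.uniform(-noise_amplitude, noise_amplitude, n * s)

    t_ramp = abs(lam_end - lam_start) / rate
    direction = 1.0 if lam_end >= lam_start else -1.0

    def lam_of_t(t):
        return lam_start + direction * rate * min(t, t_ramp)

    rhs = lambda t, x: family.vector_field(x, lam_of_t(t))  # noqa: E731
    sol = scipy.integrate.solve_ivp(
        rhs, (0.0, t_ramp), x0, method="LSODA", rtol=rtol, atol=atol,
        t_eval=np.linspace(0.0, t_ramp, 101),
    )
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.6g}: {sol.message}")
    times = [sol.t]
    states = [sol.y]
    x = sol.y[:, -1]
    t_now = t_ramp

    def deviation_amp(state):
        grid = state.reshape(n, s)
        return float(np.max(np.abs(grid - grid.mean(axis=0, keepdims=True))))

    spec = adjacency_spectrum(network)
    try:
        u_end = synchronous_equilibrium(family, lam_end, x.reshape(n, s).mean(axis=0))
        lin_end = family.linearization(u_end, lam_end)
        from .bifurcation import reduced_max_real_parts

        sync_stable = float(np.max(reduced_max_real_parts(lin_end, spec))) < 0
    except BranchError:
        sync_stable = False
    # an exactly synchronous start has nothing to regrow: the ideal
    # trajectory stays in the invariant subspace even past the crossing
    if noise_amplitude == 0:
        sync_stable = True

    # Hold at lam_end until the state is both stationary (small rate norm)
    # and pattern-settled: the deviation amplitude has stopped changing.
    # The second condition matters because the synchronous equilibrium just
    # past the crossing is stationary but unstable — a decayed perturbation
    # must be given time to regrow and saturate before the pattern is scored.
    amp_prev = deviation_amp(x)
    settled = False
    for _ in range(60):
        rate_ok = np.max(np.abs(family.vector_field(x, lam_end))) <= settle_tol
        amp_floor = amp_prev <= 1e-9 * max(1.0, float(np.max(np.abs(x))))
        if rate_ok and amp_floor and sync_stable:
            settled = True
            break
        chunk = scipy.integrate.solve_ivp(
            lambda t, y: family.vector_field(y, lam_end),
            (t_now, t_now + 200.0), x, method="LSODA", rtol=rtol, atol=atol,
            t_eval=np.linspace(t_now, t_now + 200.0, 21),
        )
        if not chunk.success:
            raise RuntimeError(
                f"integration failed at t={chunk.t[-1]:.6g}: {chunk.message}"
            )
        times.append(chunk.t[1:])
        states.append(chunk.y[:, 1:])
        x = chunk.y[:, -1]
        t_now += 200.0
        amp = deviation_amp(x)
        rate_ok = np.max(np.abs(family.vector_field(x, lam_end))) <= settle_tol
        grown = amp > 1e-9 * max(1.0, float(np.max(np.abs(x))))
        if rate_ok and abs(amp - amp_prev) <= 1e-6 * max(amp, 1e-12) and (
            grown or sync_stable
        ):
            settled = True
            amp_prev = amp
            break
        amp_prev = amp
    if not settled:
        notes.append("warning: settling window exhausted before rate norm tolerance")

    all_t = np.concatenate(times)
    all_y = np.concatenate(states, axis=1)
    deviation, best, frac, fractions, matched = _pattern_diagnostics(
        family, spec, x, coloring_tol
    )
    return SimulationResult(
        times=all_t,
        states=all_y.T,
        final_deviation=deviation,
        best_index=best,
        projection_fraction=frac,
        projection_fractions=fractions,
        matched_coloring=matched,
        invariance_drift=None,
        lambda_final=lam_end,
        notes=tuple(notes),
    )
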