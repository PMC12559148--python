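"""Built-in admissible cell models.

Each builder returns an :class:`~synchropat.bifurcation.AdmissibleODEFamily`
for a given network.  Rate functions are written with numpy broadcasting
(states may be ``(s,)`` vectors or ``(n, s)`` stacks).  Unless noted,
models *average* neighbour signals (arrow-weighted sum divided by the
valence), reflecting cells that sense mean ligand exposure.

``delta_notch`` is a two-species lateral-inhibition model with the
canonical Notch sign structure: Delta decays and is Hill-inhibited by
Notch within the cell; Notch decays and is Hill-activated by
neighbour-averaged Delta, with the bifurcation parameter ``lam``
scaling the activation strength.  Its linearization has
``Q = [[-, -], [0, -]]`` and ``R = [[0, 0], [+, 0]]`` (species order
(Delta, Notch)), hence ``det R = 0``, ``tr R = 0`` and ``B > 0``: the
first bifurcation is a synchrony-breaking real crossing at the smallest
adjacency eigenvalue.
"""

from __future__ import annotations

import numpy as np

from .bifurcation import AdmissibleODEFamily
from .network import RegularNetwork

__all__ = ["build_model", "MODEL_NAMES"]


def _example1(network: RegularNetwork) -> AdmissibleODEFamily:
    """Linear one-species worked example: du/dt = -3u - 2*lam*(input sum).

    Uses the raw input sum (no averaging) so the printed equations are
    reproduced literally; Q = -3 and R = -2*lam analytically.
    """

    def rate(u, nsum, lam):
        return -3.0 * u - 2.0 * lam * nsum

    def blocks(u, lam):
        return np.array([[-3.0]]), np.array([[-2.0 * lam]])

    return AdmissibleODEFamily(
        network=network, node_dim=1, cell_rate=rate, jacobian_blocks=blocks,
        name="example1",
    )


def _single_chem(
    network: RegularNetwork, threshold: float = 0.5, hill: float = 2.0
) -> AdmissibleODEFamily:
    """One-species lateral inhibition: neighbour signal represses production.

    ``du/dt = 1 / (1 + (lam * ubar / threshold)^hill) - u`` with ``ubar``
    the neighbour average.  R < 0 for lam > 0, so the first crossing is
    synchrony-breaking with pattern space ``P^{mu_1}``.
    """
    nu = network.valence

    def rate(u, nsum, lam):
        ubar = nsum / nu
        x = np.maximum(lam * ubar / threshold, 0.0)
        return 1.0 / (1.0 + x**hill) - u

    return AdmissibleODEFamily(
        network=network, node_dim=1, cell_rate=rate, name="single_chem"
    )


def _delta_notch(
    network: RegularNetwork,
    hill: float = 2.0,
    k_notch: float = 0.5,
    k_delta: float = 0.5,
) -> AdmissibleODEFamily:
    """Two-species Delta-Notch lateral inhibition (species order (D, N)).

    ``dD/dt = 1 / (1 + (N / k_notch)^hill) - D``
    ``dN/dt = lam * Dbar^hill / (k_delta^hill + Dbar^hill) - N``

    with ``Dbar`` the neighbour-averaged Delta.  Hill exponents default
    to 2 and thresholds to the synchronous equilibrium scale.
    """
    nu = network.valence

    def rate(u, nsum, lam):
        u = np.asarray(u, dtype=float)
        d = u[..., 0]
        n = np.maximum(u[..., 1], 0.0)
        dbar = np.maximum(np.asarray(nsum, dtype=float)[..., 0] / nu, 0.0)
        ddot = 1.0 / (1.0 + (n / k_notch) ** hill) - d
        ndot = lam * dbar**hill / (k_delta**hill + dbar**hill) - u[..., 1]
        return np.stack([ddot, ndot], axis=-1)

    return AdmissibleODEFamily(
        network=network, node_dim=2, cell_rate=rate, name="delta_notch"
    )


def _cross_coupling(
    network: RegularNetwork,
    a: float = -1.0,
    b: float = -0.5,
    c: float = 1.0,
    d: float = -1.0,
    kappa: float = 1.0,
) -> AdmissibleODEFamily:
    """Linear two-species model where chemical u activates v in neighbours.

    ``Q = [[a, b], [c, d]]``, ``R = [[0, 0], [lam * kappa / nu, 0]]``
    (neighbour-averaged).  With the defaults, tr R = 0, det R = 0 and
    B = -b * lam * kappa > 0, so the first crossing is a real
    synchrony-breaking bifurcation at mu_1.
    """
    nu = network.valence
    q = np.array([[a, b], [c, d]])

    def rate(u, nsum, lam):
        u = np.asarray(u, dtype=float)
        ubar = np.asarray(nsum, dtype=float)[..., 0] / nu
        udot = a * u[..., 0] + b * u[..., 1]
        vdot = c * u[..., 0] + d * u[..., 1] + lam * kappa * ubar
        return np.stack([udot, vdot], axis=-1)

    def blocks(u, lam):
        return q, np.array([[0.0, 0.0], [lam * kappa / nu, 0.0]])

    return AdmissibleODEFamily(
        network=network, node_dim=2, cell_rate=rate, jacobian_blocks=blocks,
        name="cross_coupling",
    )


_REGISTRY = {
    "example1": _example1,
    "single_chem": _single_chem,
    "delta_notch": _delta_notch,
    "collier": _delta_notch,  # lateral-inhibition alias
    "cross_coupling": _cross_coupling,
}

MODEL_NAMES = tuple(sorted(_REGISTRY))


def build_model(name: str, network: RegularNetwork, **params) -> AdmissibleODEFamily:
    """Instantiate a registered model on a network."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
        ) from None
    return builder(network, **params)
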