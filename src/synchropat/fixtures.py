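"""Deterministic generation of the bundled worked-object fixtures."""

from __future__ import annotations

import json
import os

import numpy as np

from .network import (
    build_line_lattice,
    build_periodic_lattice_2d,
    validate_regular,
    write_network,
)

__all__ = ["generate_fixture", "FIXTURE_NAMES", "example1_network"]

FIXTURE_NAMES = ("example1", "vpc6", "torus16", "collier_params", "fig8_skeletons")


def example1_network():
    """The 3-node worked-example network (has a self-arrow; permissive)."""
    return validate_regular(
        [[1, 1, 0], [2, 0, 0], [1, 1, 0]], allow_self_arrows=True
    )


def _write_json(path: str, doc) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def generate_fixture(name: str, outdir: str) -> list[str]:
    """Write the named fixture's files into ``outdir``; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: list[str] = []

    def out(fname: str) -> str:
        p = os.path.join(outdir, fname)
        paths.append(p)
        return p

    if name == "example1":
        write_network(example1_network(), out("example1_network.csv"))
        _write_json(
            out("example1_model.json"),
            {
                "model": "example1",
                "node_dim": 1,
                "Q": "-3",
                "R": "-2*lambda",
                "rate": "du/dt = -3 u - 2 lambda (input sum)",
            },
        )
    elif name == "vpc6":
        write_network(build_line_lattice(6), out("vpc6_network.csv"))
    elif name == "torus16":
        net = build_periodic_lattice_2d(16, 16, {"nearest": 3, "diagonal": 1})
        write_network(net, out("torus16_network.csv"))
    elif name == "collier_params":
        _write_json(
            out("collier_params.json"),
            {
                "model": "delta_notch",
                "hill": 2.0,
                "k_notch": 0.5,
                "k_delta": 0.5,
                "species": ["Delta", "Notch"],
            },
        )
    elif name == "fig8_skeletons":
        _write_json(
            out("skeleton_single_chemical.json"),
            {"Q": [["?"]], "R": [["?"]], "names": {"Q": [["Q"]], "R": [["R"]]}},
        )
        _write_json(
            out("skeleton_same_chemical_coupling.json"),
            {
                "Q": [["?", "?"], ["?", "?"]],
                "R": [["?", "0"], ["0", "0"]],
                "names": {
                    "Q": [["a", "b"], ["c", "d"]],
                    "R": [["kappa", "0"], ["0", "0"]],
                },
            },
        )
        _write_json(
            out("skeleton_cross_chemical_coupling.json"),
            {
                "Q": [["?", "?"], ["?", "?"]],
                "R": [["0", "0"], ["?", "0"]],
                "names": {
                    "Q": [["a", "b"], ["c", "d"]],
                    "R": [["0", "0"], ["kappa", "0"]],
                },
            },
        )
    else:
        raise KeyError(f"unknown fixture {name!r}; one of {FIXTURE_NAMES}")
    return paths
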