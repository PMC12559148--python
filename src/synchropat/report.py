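"""JSON report serialization with deterministic key ordering."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass

import numpy as np

from . import __version__

__all__ = ["to_jsonable", "render_report", "validate_report"]


def to_jsonable(obj):
    """Recursively convert package objects to JSON-serializable data."""
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, np.ndarray):
        if np.iscomplexobj(obj):
            return [to_jsonable(complex(v)) for v in obj.ravel()] if obj.ndim == 1 \
                else [to_jsonable(row) for row in obj]
        return obj.tolist()
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [to_jsonable(v) for v in obj]
    return str(obj)


def render_report(kind: str, payload, config: dict | None = None) -> str:
    """Aggregate a subcommand result into a versioned JSON document."""
    doc = {
        "kind": kind,
        "version": __version__,
        "config": to_jsonable(config or {}),
        "result": to_jsonable(payload),
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


_REQUIRED = {"kind", "version", "config", "result"}


def validate_report(text: str) -> dict:
    """Round-trip check: parse a report and verify the document schema."""
    doc = json.loads(text)
    missing = _REQUIRED - set(doc)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    if not isinstance(doc["kind"], str) or not isinstance(doc["config"], dict):
        raise ValueError("report fields have wrong types")
    return doc
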