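"""Deterministic consolidated reports of the analysis stages."""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["build_report"]

from . import __version__


def _jsonable(x):
    import numpy as np

    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, set)):
        items = [_jsonable(v) for v in x]
        return sorted(items, key=repr) if isinstance(x, set) else items
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    return x


def build_report(
    stage_outputs: dict,
    out_path: str | Path | None = None,
    config: dict | None = None,
    seed: int | None = None,
    artifacts: list[str | Path] | None = None,
) -> dict:
    """Assemble stage outputs into one deterministic JSON document.

    Keys are sorted and numpy scalars coerced, so identical inputs yield
    byte-identical JSON.  ``artifacts`` paths referenced by the report are
    checked for existence; missing ones raise with the offending path.
    Empty optional sections are omitted.
    """
    if not stage_outputs:
        raise ValueError("need at least one stage output")
    missing = [
        str(p) for p in (artifacts or []) if not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(
            "missing referenced artifact(s): " + ", ".join(missing)
        )
    doc = {
        "tool": "wormquant",
        "version": __version__,
        "stages": {k: _jsonable(v) for k, v in stage_outputs.items() if v},
    }
    if config:
        doc["config"] = _jsonable(config)
    if seed is not None:
        doc["seed"] = int(seed)
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        Path(out_path).write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n"
        )
    return doc
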