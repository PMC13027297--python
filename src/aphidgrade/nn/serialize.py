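"""Checkpoint save/load as ``.npz`` archives of flat state dicts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .modules import Module

__all__ = ["save_checkpoint", "load_state", "load_into"]


def save_checkpoint(module: Module, path: str | Path,
                    meta: dict | None = None) -> None:
    state = dict(module.state_dict())
    if meta is not None:
        state["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8).copy()
    np.savez(path, **state)


def load_state(path: str | Path) -> tuple[dict[str, np.ndarray], dict | None]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"checkpoint file is empty: {path}")
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    meta = None
    if "__meta__" in state:
        meta = json.loads(state.pop("__meta__").tobytes().decode())
    return state, meta


def load_into(module: Module, path: str | Path,
              strict: bool = False) -> dict[str, list[str]]:
    """Load a checkpoint into ``module``; returns a match report."""
    state, _ = load_state(path)
    own = module.state_dict()
    loadable = {k: v for k, v in state.items()
                if k in own and own[k].shape == np.asarray(v).shape}
    missing, unexpected = module.load_state_dict(loadable, strict=False)
    report = {
        "matched": sorted(loadable),
        "missing": sorted(set(own) - set(loadable)),
        "unmatched": sorted(set(state) - set(loadable)),
    }
    if strict and (report["missing"] or report["unmatched"]):
        raise KeyError(f"strict load failed: {report}")
    return report
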