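"""Checkpoint files: named parameter arrays plus a JSON metadata block."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .nn import Module

__all__ = ["save_checkpoint", "load_checkpoint"]

_META_KEY = "__meta__"


def save_checkpoint(path: str | Path, model: Module,
                    meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    arrays = {name.replace(".", "/"): value for name, value in state.items()}
    arrays[_META_KEY] = np.frombuffer(
        json.dumps(meta or {}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as data:
        meta = {}
        state = {}
        for key in data.files:
            if key == _META_KEY:
                meta = json.loads(bytes(data[key]).decode())
            else:
                state[key.replace("/", ".")] = data[key]
    return state, meta
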