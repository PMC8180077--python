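"""Single-file model checkpoints: a JSON header plus the weight arrays."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Module


def save_checkpoint(path: str | Path, header: dict, model: Module) -> None:
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    with open(path, "wb") as fh:
        np.savez(fh, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict, list[np.ndarray]]:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        keys = sorted(k for k in z.files if k.startswith("arr_"))
        arrays = [z[k] for k in keys]
    return header, arrays
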