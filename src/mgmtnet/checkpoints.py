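"""Model checkpoint save/load (npz weights + embedded JSON config)."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .classification_model import ClsConfig, MethylationCNN
from .segmentation_model import SegConfig, SegmentationNet

__all__ = ["save_checkpoint", "load_checkpoint"]

_KINDS = {"segmentation": (SegmentationNet, SegConfig),
          "classifier": (MethylationCNN, ClsConfig)}


def save_checkpoint(model, path) -> None:
    if isinstance(model, SegmentationNet):
        kind = "segmentation"
    elif isinstance(model, MethylationCNN):
        kind = "classifier"
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    meta = json.dumps({"kind": kind,
                       "config": dataclasses.asdict(model.config)})
    np.savez(path, __meta__=np.array(meta), **model.state_dict())


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model_cls, cfg_cls = _KINDS[meta["kind"]]
    cfg = meta["config"]
    for key in ("conv_filters",):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    model = model_cls(cfg_cls(**cfg))
    model.load_state_dict(state)
    model.eval()
    return model
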