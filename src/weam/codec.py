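"""Linear quantizer between real feature vectors and discrete functions.

In the full memory system a trained encoder maps a concrete image to ``n``
real features which are then sampled into ``m`` discrete levels (the rows of
the register), and a decoder maps features back to an image.  This module is
the level-2 <-> level-3 half of that pipeline: a per-argument equal-width
linear binning fitted to a corpus.  Any external encoder can plug in by
emitting the same n-column feature table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import UNDEFINED, DiscreteFunction

__all__ = ["QuantizerModel", "fit_quantizer", "quantize", "dequantize",
           "save_quantizer", "load_quantizer"]


@dataclass(frozen=True)
class QuantizerModel:
    """Per-argument linear real <-> level mapping.

    ``lo``/``hi`` are the per-argument bounds of the fitted range; values
    outside clip to the boundary level.  Quantize -> dequantize -> quantize
    is level-stable (bin midpoints land in their own bin).
    """

    m: int
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lo", np.asarray(self.lo, dtype=float))
        object.__setattr__(self, "hi", np.asarray(self.hi, dtype=float))
        if self.m < 1:
            raise ValueError("m must be positive")
        if self.lo.shape != self.hi.shape or self.lo.ndim != 1:
            raise ValueError("lo and hi must be 1-D arrays of equal length")
        if not (self.hi > self.lo).all():
            raise ValueError("hi must exceed lo for every argument")

    @property
    def n(self) -> int:
        return self.lo.size


def fit_quantizer(
    vectors: np.ndarray, m: int, *, epsilon: float = 1e-9
) -> QuantizerModel:
    """Fit per-argument bounds as the min/max over a corpus.

    Degenerate arguments (constant over the corpus) are widened by
    ``epsilon`` so every value maps to level 0.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("vectors must be a non-empty 2-D array")
    if not np.isfinite(x).all():
        raise ValueError("vectors must be finite")
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    flat = hi <= lo
    hi = np.where(flat, lo + epsilon, hi)
    return QuantizerModel(m=int(m), lo=lo, hi=hi)


def quantize(model: QuantizerModel, x: np.ndarray) -> DiscreteFunction:
    """Map a real vector to levels: floor(m * (x - lo) / (hi - lo)), clipped.

    NaN entries mark undefined arguments and yield a partial function.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n,):
        raise ValueError(f"expected vector of length {model.n}, got {x.shape}")
    defined = np.isfinite(x)
    span = model.hi - model.lo
    with np.errstate(invalid="ignore"):
        raw = np.floor(model.m * (x - model.lo) / span)
    levels = np.full(model.n, UNDEFINED, dtype=np.int64)
    levels[defined] = np.clip(raw[defined], 0, model.m - 1).astype(np.int64)
    return DiscreteFunction(levels)


def dequantize(model: QuantizerModel, f: DiscreteFunction) -> np.ndarray:
    """Map levels back to bin midpoints; NaN where the function is undefined."""
    if f.n != model.n:
        raise ValueError(f"expected arity {model.n}, got {f.n}")
    width = (model.hi - model.lo) / model.m
    out = model.lo + (f.levels + 0.5) * width
    return np.where(f.defined, out, np.nan)


def save_quantizer(model: QuantizerModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "n": model.n,
        "m": model.m,
        "lo": model.lo.tolist(),
        "hi": model.hi.tolist(),
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def load_quantizer(path: str | Path) -> QuantizerModel:
    payload = json.loads(Path(path).read_text())
    model = QuantizerModel(
        m=payload["m"], lo=np.array(payload["lo"]), hi=np.array(payload["hi"])
    )
    if model.n != payload["n"]:
        raise ValueError("inconsistent quantizer file")
    return model
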