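"""Synthetic Gaussian-cluster corpus emulating encoder-output geometry.

The memory experiments assume a labelled corpus of real feature vectors with
class structure: each of ``c`` classes is an isotropic Gaussian cluster in
``n`` dimensions, the corpus is balanced, and it is partitioned into a
training set (for fitting the codec and classifier stand-ins), a remembered
set (for filling the memory) and a test set (for cueing it).  A nearest
centroid classifier plays the role of the external classifier, and
``corrupt`` produces noisy cues by replacing a fraction of the feature
values with uniform draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "DomainSpec",
    "Partition",
    "Domain",
    "generate_domain",
    "corrupt",
    "nearest_centroid_classify",
    "save_corpus",
    "load_corpus",
]


@dataclass(frozen=True)
class DomainSpec:
    """Parameters of the synthetic corpus and its partition.

    Defaults: 10 balanced classes of 64-dimensional features, 7000 objects,
    split 70/20/10 into train / remember / test.  Class centroids have
    coordinates drawn from N(0, separation**2); objects scatter around their
    centroid with isotropic sd ``noise_sd``.
    """

    n: int = 64
    c: int = 10
    separation: float = 1.0
    noise_sd: float = 0.3
    size: int = 7000
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self):
        if self.c < 2:
            raise ValueError("need at least two classes")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.size < self.c or self.size % self.c != 0:
            raise ValueError("size must be a positive multiple of c (balanced corpus)")
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be three non-negative numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.separation <= 0 or self.noise_sd < 0:
            raise ValueError("separation must be > 0 and noise_sd >= 0")

    def per_class_partition(self) -> tuple[int, int, int]:
        """Objects per class in each partition (largest-remainder rounding)."""
        per_class = self.size // self.c
        raw = [f * per_class for f in self.fractions]
        base = [int(np.floor(r)) for r in raw]
        short = per_class - sum(base)
        order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder
        for j in order[:short]:
            base[j] += 1
        return tuple(base)

    def partition_sizes(self) -> tuple[int, int, int]:
        """Total sizes of (train, remember, test)."""
        return tuple(k * self.c for k in self.per_class_partition())


class Partition(NamedTuple):
    """A labelled slice of the corpus."""

    features: np.ndarray  # (N, n)
    labels: np.ndarray  # (N,)


class Domain(NamedTuple):
    """Generated corpus: three disjoint partitions plus the true centroids."""

    train: Partition
    remember: Partition
    test: Partition
    centroids: np.ndarray  # (c, n)
    spec: DomainSpec


def generate_domain(spec: DomainSpec) -> Domain:
    """Draw the corpus: balanced, disjoint, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    centroids = rng.normal(0.0, spec.separation, size=(spec.c, spec.n))
    sizes = spec.per_class_partition()
    parts: list[list[np.ndarray]] = [[], [], []]
    labels: list[list[np.ndarray]] = [[], [], []]
    for k in range(spec.c):
        x = centroids[k] + rng.normal(0.0, spec.noise_sd, size=(spec.size // spec.c, spec.n))
        offsets = np.cumsum((0,) + sizes)
        for p in range(3):
            chunk = x[offsets[p]: offsets[p + 1]]
            parts[p].append(chunk)
            labels[p].append(np.full(len(chunk), k, dtype=np.int64))
    out = []
    for p in range(3):
        feats = np.concatenate(parts[p])
        labs = np.concatenate(labels[p])
        perm = rng.permutation(len(labs))
        out.append(Partition(feats[perm], labs[perm]))
    return Domain(train=out[0], remember=out[1], test=out[2],
                  centroids=centroids, spec=spec)


def corrupt(
    x: np.ndarray,
    fraction: float,
    value_range: tuple[np.ndarray | float, np.ndarray | float],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Replace round(fraction * n) positions with uniform draws.

    Positions are chosen uniformly without replacement; replacement values
    are uniform on the (per-argument) ``value_range``.  Untouched positions
    are copied verbatim.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    out = x.copy()
    k = int(round(fraction * x.size))
    if k == 0:
        return out
    pos = rng.choice(x.size, size=k, replace=False)
    lo = np.broadcast_to(np.asarray(value_range[0], dtype=float), x.shape)
    hi = np.broadcast_to(np.asarray(value_range[1], dtype=float), x.shape)
    out[pos] = rng.uniform(lo[pos], hi[pos])
    return out


def nearest_centroid_classify(centroids: np.ndarray, x: np.ndarray) -> int:
    """Class of the nearest centroid (Euclidean); ties break to the lowest id.

    NaN entries of ``x`` (undefined arguments of a partial retrieval) are
    ignored in the distance.
    """
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(x)
    if not mask.any():
        raise ValueError("cannot classify a vector with no defined entries")
    d = ((centroids[:, mask] - x[mask]) ** 2).sum(axis=1)
    return int(np.argmin(d))


def save_corpus(path: str | Path, part: Partition) -> Path:
    """Write a partition as CSV: columns f0..f{n-1} plus 'label'."""
    n = part.features.shape[1]
    df = pd.DataFrame(part.features, columns=[f"f{i}" for i in range(n)])
    df["label"] = part.labels
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_corpus(path: str | Path) -> Partition:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("corpus CSV must have a 'label' column")
    labels = df.pop("label").to_numpy(dtype=np.int64)
    return Partition(df.to_numpy(dtype=float), labels)
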