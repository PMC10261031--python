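"""Desk-scale experiment protocols over a synthetic domain.

Four protocols mirror the way a single-register entropic memory is studied:

- ``run_fill_sweep``: fill fresh registers with growing fractions of the
  remembered corpus and score retrieval of every test cue — the entropy
  trade-off curve (precision/recall/accuracy vs fill level and row count).
- ``run_sigma_sweep``: retrieve every cue at a ladder of sigma values
  (optionally corrupting cues first) and tabulate how often the retrieval
  keeps the cue's class, is reassigned, or is rejected.
- ``run_chain``: feed each retrieval back as the next cue, producing an
  association chain that stops at the first rejection.
- ``run_kfold``: repeat a fill protocol under k-fold rotation of the
  remember/test pools and report mean and sd per metric.

All randomness flows through seeds derived deterministically from a single
master seed.  Results are tidy DataFrames (one row per grid cell, per sigma,
or per fold) carrying the raw outcome counts alongside every percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codec import QuantizerModel, dequantize, fit_quantizer, quantize
from .core import (
    AMRegister,
    DiscreteFunction,
    RecognitionParams,
    entropy,
    register,
    retrieve,
)
from .metrics import OutcomeCounts, score
from .synthetic import Domain, Partition, corrupt, nearest_centroid_classify

__all__ = [
    "DEFAULT_FILL_FRACTIONS",
    "DEFAULT_SIGMAS",
    "ChainStep",
    "ChainResult",
    "fill_register",
    "evaluate_cues",
    "run_fill_sweep",
    "run_sigma_sweep",
    "run_chain",
    "run_kfold",
]

#: Fill levels of the remembered corpus swept in the trade-off protocol.
DEFAULT_FILL_FRACTIONS = (0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64, 1.00)

#: Sigma ladder for the retrieval-variability protocol.
DEFAULT_SIGMAS = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def _child_seeds(seed: int, k: int) -> list[int]:
    """k deterministic sub-seeds (< 2**31) derived from a master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(k) % (2 ** 31)]


def _balanced_subset(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a class-balanced random subset of the given fraction."""
    take: list[np.ndarray] = []
    for k in np.unique(labels):
        idx = np.nonzero(labels == k)[0]
        cnt = int(round(fraction * idx.size))
        if cnt:
            take.append(rng.choice(idx, size=cnt, replace=False))
    if not take:
        raise ValueError(f"fraction {fraction} yields zero objects")
    return np.concatenate(take)


def fill_register(
    amr: AMRegister, quantizer: QuantizerModel, features: np.ndarray
) -> AMRegister:
    """Quantize and register every row of ``features`` into ``amr``."""
    for x in features:
        register(amr, quantize(quantizer, x))
    return amr


def evaluate_cues(
    amr: AMRegister,
    quantizer: QuantizerModel,
    part: Partition,
    centroids: np.ndarray,
    *,
    sigma: float,
    params: RecognitionParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> OutcomeCounts:
    """Retrieve each cue, classify the retrieval, and tally outcomes."""
    rng = np.random.default_rng(rng)
    right = wrong = none = 0
    for x, y in zip(part.features, part.labels):
        f = retrieve(amr, quantize(quantizer, x), sigma, params, rng)
        if f is None:
            none += 1
        elif nearest_centroid_classify(centroids, dequantize(quantizer, f)) == y:
            right += 1
        else:
            wrong += 1
    return OutcomeCounts(right, wrong, none)


def run_fill_sweep(
    domain: Domain,
    m_rows_list=(4,),
    fractions=DEFAULT_FILL_FRACTIONS,
    *,
    sigma: float = 0.1,
    params: RecognitionParams | None = None,
    max_weight: int = 65535,
    seed: int = 0,
) -> pd.DataFrame:
    """Entropy trade-off protocol: one row per (rows, fill fraction) cell.

    For each cell a fresh register is filled with a balanced random subset
    of the remembered corpus, and every test object is retrieved (at the
    given sigma) and classified against its true label.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    n = domain.spec.n
    rows: list[dict] = []
    seeds = _child_seeds(seed, len(m_rows_list) * len(fractions))
    si = 0
    for m in m_rows_list:
        quantizer = fit_quantizer(domain.train.features, m)
        for frac in fractions:
            rng = np.random.default_rng(seeds[si]); si += 1
            amr = AMRegister(n, m, max_weight)
            subset = _balanced_subset(domain.remember.labels, frac, rng)
            fill_register(amr, quantizer, domain.remember.features[subset])
            counts = evaluate_cues(
                amr, quantizer, domain.test, domain.centroids,
                sigma=sigma, params=params, rng=rng,
            )
            rows.append({
                "n_columns": n,
                "m_rows": m,
                "fill_fraction": frac,
                "n_registered": subset.size,
                "entropy": entropy(amr),
                **score(counts),
                "right": counts.right,
                "wrong": counts.wrong,
                "none": counts.none,
            })
    return pd.DataFrame(rows)


def run_sigma_sweep(
    amr: AMRegister,
    quantizer: QuantizerModel,
    part: Partition,
    centroids: np.ndarray,
    sigmas=DEFAULT_SIGMAS,
    *,
    corrupt_fraction: float | None = None,
    params: RecognitionParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Class preservation vs sigma; one row per sigma value.

    With ``corrupt_fraction`` set, each cue is first corrupted in feature
    space (replacement values uniform on the quantizer's range).
    """
    rows: list[dict] = []
    for s, sub in zip(sigmas, _child_seeds(seed, len(sigmas))):
        rng = np.random.default_rng(sub)
        preserved = reassigned = rejected = 0
        for x, y in zip(part.features, part.labels):
            if corrupt_fraction:
                x = corrupt(x, corrupt_fraction, (quantizer.lo, quantizer.hi), rng)
            f = retrieve(amr, quantize(quantizer, x), s, params, rng)
            if f is None:
                rejected += 1
            elif nearest_centroid_classify(centroids, dequantize(quantizer, f)) == y:
                preserved += 1
            else:
                reassigned += 1
        total = len(part.labels)
        rows.append({
            "sigma": s,
            "corrupt_fraction": corrupt_fraction or 0.0,
            "preserved": preserved,
            "reassigned": reassigned,
            "rejected": rejected,
            "preserved_pct": 100.0 * preserved / total,
            "reassigned_pct": 100.0 * reassigned / total,
            "rejected_pct": 100.0 * rejected / total,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChainStep:
    """One link of an association chain."""

    function: DiscreteFunction
    class_id: int


@dataclass(frozen=True)
class ChainResult:
    """An association chain; stops at the first rejection."""

    steps: tuple[ChainStep, ...]
    rejected: bool
    sigma: float
    requested_length: int
    initial_class: int

    @property
    def length(self) -> int:
        return len(self.steps)


def run_chain(
    amr: AMRegister,
    quantizer: QuantizerModel,
    cue: np.ndarray,
    centroids: np.ndarray,
    *,
    sigma: float = 0.15,
    length: int = 6,
    params: RecognitionParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> ChainResult:
    """Recurrent retrieval: each retrieved object becomes the next cue."""
    rng = np.random.default_rng(rng)
    x = np.asarray(cue, dtype=float)
    initial = nearest_centroid_classify(centroids, x)
    steps: list[ChainStep] = []
    rejected = False
    for _ in range(length):
        f = retrieve(amr, quantize(quantizer, x), sigma, params, rng)
        if f is None:
            rejected = True
            break
        x = dequantize(quantizer, f)
        steps.append(ChainStep(f, nearest_centroid_classify(centroids, x)))
    return ChainResult(
        steps=tuple(steps),
        rejected=rejected,
        sigma=sigma,
        requested_length=length,
        initial_class=initial,
    )


def run_kfold(
    domain: Domain,
    k: int = 10,
    *,
    m_rows: int = 4,
    sigma: float = 0.1,
    fill_fraction: float = 1.0,
    params: RecognitionParams | None = None,
    max_weight: int = 65535,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """k-fold rotation of the remember/test pools.

    The remembered and test partitions are pooled and split into ``k``
    balanced folds; each fold serves once as the test set while the rest
    fills the register.  The quantizer is fitted on the training partition
    throughout.  Returns per-fold rows and a mean/sd summary.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    feats = np.concatenate([domain.remember.features, domain.test.features])
    labs = np.concatenate([domain.remember.labels, domain.test.labels])
    rng = np.random.default_rng(_child_seeds(seed, 1)[0])
    fold_of = np.empty(labs.size, dtype=np.int64)
    for c in np.unique(labs):  # balanced folds: round-robin within each class
        idx = rng.permutation(np.nonzero(labs == c)[0])
        fold_of[idx] = np.arange(idx.size) % k
    quantizer = fit_quantizer(domain.train.features, m_rows)
    rows: list[dict] = []
    for f, sub in zip(range(k), _child_seeds(seed + 1, k)):
        frng = np.random.default_rng(sub)
        rem = fold_of != f
        amr = AMRegister(domain.spec.n, m_rows, max_weight)
        if fill_fraction < 1.0:
            subset = _balanced_subset(labs[rem], fill_fraction, frng)
            fill_register(amr, quantizer, feats[rem][subset])
        else:
            fill_register(amr, quantizer, feats[rem])
        counts = evaluate_cues(
            amr, quantizer, Partition(feats[~rem], labs[~rem]),
            domain.centroids, sigma=sigma, params=params, rng=frng,
        )
        rows.append({"fold": f, "entropy": entropy(amr), **score(counts),
                     "right": counts.right, "wrong": counts.wrong,
                     "none": counts.none})
    per_fold = pd.DataFrame(rows)
    metrics = ["entropy", "precision", "recall", "accuracy"]
    summary = per_fold[metrics].agg(["mean", "std"])
    return {"per_fold": per_fold, "summary": summary}
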