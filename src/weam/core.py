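"""Associative memory register and the three memory operations.

The memory medium is a single table with ``n`` columns (function arguments)
and ``m`` rows (quantized values).  An object is a discrete function mapping
each argument to a row, and is stored by incrementing the weight of one cell
per column.  The three operations are:

``register``
    Hebbian-style reinforcement: add 1 to every cell used by the cue.
``recognize``
    A logical acceptance test — material implication over columns, relaxed by
    a tolerance ``xi``, plus a cue-weight threshold ``rho >= kappa * Omega``.
``retrieve``
    Constructive recall: per column, sample a row from the normalized product
    of the column weight distribution (prior, Psi) and a discretized normal
    kernel centered at the cue (likelihood, zeta).

Entropy plays a functional role: the Shannon entropy of each column measures
the indeterminacy of the stored content, and ``2**(entropy * n)`` counts the
functions (registered plus emerging) the table holds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "UNDEFINED",
    "AMRegister",
    "DiscreteFunction",
    "RecognitionParams",
    "RecognitionReport",
    "ColumnDistribution",
    "register",
    "recognize",
    "retrieve",
    "column_entropy",
    "entropy",
    "capacity_log2",
    "exact_capacity",
    "emerging_objects",
    "column_distribution",
    "cue_kernel",
    "posterior_distribution",
    "save_amr",
    "load_amr",
]

#: Sentinel level for an undefined argument of a partial function.
UNDEFINED = -1

_FORMAT_VERSION = 1


class DiscreteFunction:
    """A (possibly partial) map from argument index to row level.

    Parameters
    ----------
    levels
        Either a sequence of length ``n`` with ``UNDEFINED`` (-1) marking
        undefined arguments, or a mapping ``{argument_index: level}`` (in
        which case ``n`` is required).
    n
        Arity; required when ``levels`` is a mapping.
    """

    __slots__ = ("_levels",)

    def __init__(self, levels, n: int | None = None):
        if isinstance(levels, Mapping):
            if n is None:
                raise ValueError("arity n is required when levels is a mapping")
            arr = np.full(int(n), UNDEFINED, dtype=np.int64)
            for i, j in levels.items():
                arr[int(i)] = int(j)
        else:
            arr = np.array(levels, dtype=np.int64)
            if n is not None and arr.size != n:
                raise ValueError(f"expected arity {n}, got {arr.size}")
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("a discrete function needs at least one argument")
        if (arr < UNDEFINED).any():
            raise ValueError("levels must be >= 0, or -1 for undefined")
        if not (arr >= 0).any():
            raise ValueError("at least one argument must be defined")
        self._levels = arr
        self._levels.setflags(write=False)

    @property
    def levels(self) -> np.ndarray:
        """Read-only level array; ``UNDEFINED`` marks undefined arguments."""
        return self._levels

    @property
    def n(self) -> int:
        return self._levels.size

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of defined arguments."""
        return self._levels >= 0

    @property
    def complete(self) -> bool:
        return bool(self.defined.all())

    def items(self):
        """Iterate ``(argument, level)`` over defined arguments."""
        for i in np.nonzero(self.defined)[0]:
            yield int(i), int(self._levels[i])

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiscreteFunction):
            return NotImplemented
        return np.array_equal(self._levels, other._levels)

    def __hash__(self):
        return hash(self._levels.tobytes())

    def __repr__(self) -> str:
        pairs = ", ".join(f"{i}:{j}" for i, j in self.items())
        return f"DiscreteFunction(n={self.n}, {{{pairs}}})"


class AMRegister:
    """The n-column x m-row non-negative-integer weight table.

    ``n`` and ``m`` are immutable after construction.  Cell weights saturate
    at ``max_weight`` (default 65535, two-byte cells).
    """

    __slots__ = ("_weights", "_max_weight")

    def __init__(self, n: int, m: int, max_weight: int = 65535):
        if n < 1 or m < 1:
            raise ValueError("n and m must be positive")
        if max_weight < 1:
            raise ValueError("max_weight must be positive")
        self._weights = np.zeros((int(n), int(m)), dtype=np.int64)
        self._max_weight = int(max_weight)

    @property
    def n(self) -> int:
        """Number of columns (arguments)."""
        return self._weights.shape[0]

    @property
    def m(self) -> int:
        """Number of rows (levels)."""
        return self._weights.shape[1]

    @property
    def cells(self) -> int:
        return self.n * self.m

    @property
    def max_weight(self) -> int:
        return self._max_weight

    @property
    def weights(self) -> np.ndarray:
        """Read-only view of the (n, m) weight grid."""
        view = self._weights.view()
        view.setflags(write=False)
        return view

    def copy(self) -> "AMRegister":
        out = AMRegister(self.n, self.m, self._max_weight)
        out._weights[...] = self._weights
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, AMRegister):
            return NotImplemented
        return (
            self._max_weight == other._max_weight
            and np.array_equal(self._weights, other._weights)
        )

    def __repr__(self) -> str:
        return (
            f"AMRegister(n={self.n}, m={self.m}, max_weight={self._max_weight},"
            f" entropy={entropy(self):.3f})"
        )


@dataclass(frozen=True)
class RecognitionParams:
    """Sensitivity parameters of the recognition test.

    ``iota`` scales the minimum weight a cell must carry relative to its
    column mean to count as "on"; ``kappa`` scales the minimum mean cue
    weight ``rho`` relative to the register mean ``Omega``; ``xi`` is the
    number of columns allowed to fail the implication.  The defaults impose
    no constraint.
    """

    iota: float = 0.0
    kappa: float = 0.0
    xi: int = 0

    def __post_init__(self):
        if self.iota < 0 or self.kappa < 0:
            raise ValueError("iota and kappa must be non-negative")
        if int(self.xi) != self.xi or self.xi < 0:
            raise ValueError("xi must be a non-negative integer")


@dataclass(frozen=True)
class RecognitionReport:
    """Verdict of the recognition test plus its diagnostic quantities."""

    accepted: bool
    failing_columns: tuple[int, ...]
    omega: np.ndarray = field(repr=False)  # per-column mean nonzero weight
    Omega: float
    rho: float


@dataclass(frozen=True)
class ColumnDistribution:
    """A normalized distribution over the m levels of one column.

    ``empty`` flags an all-zero column (no support; ``probs`` is all zero).
    """

    probs: np.ndarray
    empty: bool = False


def _check_cue(amr: AMRegister, cue: DiscreteFunction) -> None:
    if cue.n != amr.n:
        raise ValueError(f"cue arity {cue.n} != register columns {amr.n}")
    if (cue.levels >= amr.m).any():
        bad = int(cue.levels.max())
        raise ValueError(f"cue level {bad} out of range for {amr.m} rows")


def register(amr: AMRegister, cue: DiscreteFunction) -> AMRegister:
    """Add the cue into the register (in place) and return it.

    Every cell used by the cue is incremented by 1, saturating at
    ``max_weight``; cells of undefined arguments are untouched.
    """
    _check_cue(amr, cue)
    idx = np.nonzero(cue.defined)[0]
    w = amr._weights
    w[idx, cue.levels[idx]] = np.minimum(
        w[idx, cue.levels[idx]] + 1, amr.max_weight
    )
    return amr


def _column_means(amr: AMRegister) -> np.ndarray:
    """Per-column mean weight over nonzero cells (0 for empty columns)."""
    w = amr._weights
    counts = (w > 0).sum(axis=1)
    sums = w.sum(axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def recognize(
    amr: AMRegister,
    cue: DiscreteFunction,
    params: RecognitionParams | None = None,
) -> RecognitionReport:
    """Acceptance test for a cue.

    A defined column fails when its cue cell has zero weight or weight below
    ``iota * omega_i``.  The cue is accepted when at most ``xi`` columns fail
    and the mean cue weight ``rho`` is at least ``kappa * Omega``.  For
    partial cues, failing columns and ``rho`` range over defined arguments
    only; ``Omega`` always averages over all columns.
    """
    _check_cue(amr, cue)
    if params is None:
        params = RecognitionParams()
    omega = _column_means(amr)
    Omega = float(omega.mean())
    idx = np.nonzero(cue.defined)[0]
    w_cue = amr._weights[idx, cue.levels[idx]]
    # Zero-weight cells are always "off": with iota=0 the threshold alone
    # would accept unsupported cells.
    fails = (w_cue == 0) | (w_cue < params.iota * omega[idx])
    failing = tuple(int(i) for i in idx[fails])
    rho = float(w_cue.mean())
    accepted = len(failing) <= params.xi and rho >= params.kappa * Omega
    return RecognitionReport(
        accepted=accepted,
        failing_columns=failing,
        omega=omega,
        Omega=Omega,
        rho=rho,
    )


def column_distribution(amr: AMRegister, i: int) -> ColumnDistribution:
    """Psi_i: the probability distribution defined by column i's weights."""
    if not 0 <= i < amr.n:
        raise IndexError(f"column {i} out of range for {amr.n} columns")
    w = amr._weights[i].astype(float)
    s = w.sum()
    if s == 0:
        return ColumnDistribution(probs=np.zeros(amr.m), empty=True)
    return ColumnDistribution(probs=w / s, empty=False)


def cue_kernel(m: int, level: int, sigma: float) -> np.ndarray:
    """zeta: normal density with sd ``sigma * m`` evaluated at levels 0..m-1.

    Centered at the cue level and normalized over the grid.  ``sigma = 0``
    degenerates to a point mass at the cue level.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not 0 <= level < m:
        raise ValueError(f"level {level} out of range for {m} rows")
    if sigma == 0:
        z = np.zeros(m)
        z[level] = 1.0
        return z
    grid = np.arange(m, dtype=float)
    z = np.exp(-0.5 * ((grid - level) / (sigma * m)) ** 2)
    return z / z.sum()


def posterior_distribution(
    amr: AMRegister, i: int, level: int, sigma: float
) -> ColumnDistribution:
    """Phi_i: normalized product of Psi_i and the cue kernel zeta.

    When the product has no mass (a point-mass kernel on a zero-weight cell)
    the column prior Psi_i is returned instead, so retrieval of an accepted
    cue stays defined.
    """
    psi = column_distribution(amr, i)
    if psi.empty:
        return psi
    phi = psi.probs * cue_kernel(amr.m, level, sigma)
    s = phi.sum()
    if s == 0:
        return psi
    return ColumnDistribution(probs=phi / s, empty=False)


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one level per row of a (k, m) row-stochastic matrix."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    lvl = (cum < u[:, None]).sum(axis=1)
    return np.minimum(lvl, probs.shape[1] - 1)


def retrieve(
    amr: AMRegister,
    cue: DiscreteFunction,
    sigma: float,
    params: RecognitionParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> DiscreteFunction | None:
    """Constructive retrieval; returns None when the cue is rejected.

    For each defined argument the output level is drawn from
    ``Phi_i \\propto Psi_i * zeta_i``; undefined arguments are drawn from the
    column prior ``Psi_i`` alone.  Arguments whose column is all-zero stay
    undefined (the result is then partial).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    _check_cue(amr, cue)
    rng = np.random.default_rng(rng)
    if not recognize(amr, cue, params).accepted:
        return None

    w = amr._weights.astype(float)
    col_sums = w.sum(axis=1)
    supported = col_sums > 0
    psi = np.zeros_like(w)
    psi[supported] = w[supported] / col_sums[supported, None]

    phi = psi.copy()
    idx = np.nonzero(cue.defined)[0]
    if idx.size:
        m = amr.m
        lv = cue.levels[idx]
        if sigma == 0:
            zeta = np.zeros((idx.size, m))
            zeta[np.arange(idx.size), lv] = 1.0
        else:
            grid = np.arange(m, dtype=float)
            zeta = np.exp(-0.5 * ((grid[None, :] - lv[:, None]) / (sigma * m)) ** 2)
        phi[idx] *= zeta
        # Point-mass kernel on a zero-weight cell (possible only in
        # xi-relaxed columns): fall back to the column prior.
        dead = idx[(phi[idx].sum(axis=1) == 0) & supported[idx]]
        phi[dead] = psi[dead]

    out = np.full(amr.n, UNDEFINED, dtype=np.int64)
    live = np.nonzero(supported)[0]
    if live.size == 0:
        return None
    rows = phi[live]
    rows = rows / rows.sum(axis=1, keepdims=True)
    out[live] = _sample_rows(rows, rng)
    return DiscreteFunction(out)


def column_entropy(amr: AMRegister, i: int) -> float:
    """Shannon entropy (bits) of column i's weight distribution.

    An all-zero column has entropy 0 by convention.
    """
    psi = column_distribution(amr, i)
    if psi.empty:
        return 0.0
    p = psi.probs[psi.probs > 0]
    return float(-(p * np.log2(p)).sum())


def entropy(amr: AMRegister) -> float:
    """Memory entropy: the mean of the column entropies, in bits."""
    w = amr._weights.astype(float)
    sums = w.sum(axis=1)
    ok = sums > 0
    if not ok.any():
        return 0.0
    p = w[ok] / sums[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    col_ent = terms.sum(axis=1)
    return float(col_ent.sum() / amr.n)  # empty columns contribute 0


def capacity_log2(amr: AMRegister) -> float:
    """Base-2 log of the number of representable functions: entropy * n."""
    return entropy(amr) * amr.n


def exact_capacity(log2_count: float, *, atol: float = 1e-6) -> int:
    """Exact big-integer ``2**log2_count`` when the exponent is integral."""
    k = round(log2_count)
    if abs(log2_count - k) > atol:
        raise ValueError(f"log2 count {log2_count} is not integral within {atol}")
    if k < 0:
        raise ValueError("log2 count must be non-negative")
    return 1 << k


def emerging_objects(log2_count: float, n_registered: int) -> int:
    """Count of emerging (never explicitly registered) functions.

    ``2**log2_count - n_registered``, evaluated exactly.
    """
    return exact_capacity(log2_count) - int(n_registered)


def save_amr(amr: AMRegister, path: str | Path) -> Path:
    """Persist a register as a directory: meta.json + weights.csv.

    weights.csv holds m rows x n columns of integers; row 0 is level 0.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "n": amr.n,
        "m": amr.m,
        "l": amr.max_weight,
        "format_version": _FORMAT_VERSION,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    np.savetxt(path / "weights.csv", amr._weights.T, fmt="%d", delimiter=",")
    return path


def load_amr(path: str | Path) -> AMRegister:
    """Load a register saved by :func:`save_amr` (bit-exact round trip)."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported format_version {meta.get('format_version')}")
    grid = np.loadtxt(path / "weights.csv", dtype=np.int64, delimiter=",", ndmin=2)
    if grid.shape != (meta["m"], meta["n"]):
        raise ValueError(
            f"weights shape {grid.shape} does not match meta ({meta['m']}, {meta['n']})"
        )
    if (grid < 0).any() or (grid > meta["l"]).any():
        raise ValueError("weights outside [0, max_weight]")
    amr = AMRegister(meta["n"], meta["m"], meta["l"])
    amr._weights[...] = grid.T
    return amr
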