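"""Motif models and biophysical affinity scoring.

This module covers the motif arm of the variant screen:

* :class:`PositionFrequencyMatrix` (PFM) — per-column base counts, read from
  JASPAR flat files or MEME minimal files (via Bio.motifs) or built in code.
* :class:`PositionWeightMatrix` (PWM) — the log-odds form against a background
  model, with per-column extremes so that window scores can be reported on the
  JASPAR-style *relative* scale (0 for the anti-consensus word, 1 for the
  consensus word).
* TRAP-style biophysical occupancy: each sequence window contributes a
  Fermi-type term ``R0 * exp(-E) / (1 + R0 * exp(-E))`` where ``E`` is the
  mismatch energy of the window relative to the motif consensus, and the
  expected occupancy of a sequence is the sum over all windows on both
  strands.  ``R0`` scales with motif width as ``exp(slope * W + intercept)``.
* Empirical p-value calibration: occupancies of background-sampled sequences
  form the null; the p-value of an observed occupancy is its (add-one
  corrected) right-tail rank in that null.

Log conventions: log-odds use base 2; the mismatch energy uses the natural
logarithm scaled by ``1 / lambda``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import BASES, BASE_INDEX, InvalidSequenceError, decode, encode

__all__ = [
    "PositionFrequencyMatrix",
    "BackgroundModel",
    "PositionWeightMatrix",
    "TrapParams",
    "MotifHit",
    "NullDistribution",
    "DegenerateMatrixError",
    "build_pwm",
    "scan",
    "trap_affinity",
    "calibrate_null",
    "affinity_pvalue",
]


class DegenerateMatrixError(ValueError):
    """Raised when every PFM column is flat and relative scores are undefined."""


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Motif base counts: a 4 x W matrix with rows in fixed order A, C, G, T."""

    tf_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x W matrix with W >= 1")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError("every column must have a positive total")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus_codes(self) -> np.ndarray:
        # argmax ties break toward the first row, i.e. fixed base order A<C<G<T
        return self.counts.argmax(axis=0).astype(np.int8)

    def consensus(self) -> str:
        return decode(self.consensus_codes())

    def probabilities(self, pseudocount: float = 0.0) -> np.ndarray:
        totals = self.counts.sum(axis=0)
        return (self.counts + pseudocount / 4.0) / (totals + pseudocount)

    def information_content(self) -> float:
        """Total information in bits against a uniform background."""
        p = self.probabilities(pseudocount=1e-9)
        return float((p * np.log2(p / 0.25)).sum())


@dataclass(frozen=True)
class BackgroundModel:
    """Order-0 or order-1 Markov background over A/C/G/T.

    For order 1, ``base_freqs`` is the stationary distribution and
    ``transition[i, j]`` the probability of base ``j`` following base ``i``.
    Log-odds scoring always uses ``base_freqs`` (the stationary vector).
    """

    order: int = 0
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    transition: np.ndarray | None = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs <= 0).any():
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        object.__setattr__(self, "base_freqs", freqs)
        if self.order == 0:
            if self.transition is not None:
                raise ValueError("order-0 background takes no transition matrix")
        elif self.order == 1:
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (4, 4) or (t <= 0).any():
                raise ValueError("order-1 background needs a positive 4x4 transition matrix")
            if np.abs(t.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("transition rows must sum to 1")
            object.__setattr__(self, "transition", t)
        else:
            raise ValueError("order must be 0 or 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls()

    @classmethod
    def promoter_like(cls) -> "BackgroundModel":
        """GC-rich, CpG-depleted order-1 preset standing in for a human
        promoter background (the exact composition of such tables varies by
        tool and is configurable here)."""
        stationary = np.array([0.22, 0.28, 0.28, 0.22])
        transition = np.tile(stationary, (4, 1))
        # deplete the C->G step by 4x and renormalise that row
        transition[1, 2] *= 0.25
        transition[1] /= transition[1].sum()
        return cls(order=1, base_freqs=stationary, transition=transition)

    def sample_codes(self, length: int, rng: np.random.Generator) -> np.ndarray:
        if self.order == 0:
            return rng.choice(4, size=length, p=self.base_freqs).astype(np.int8)
        out = np.empty(length, dtype=np.int8)
        out[0] = rng.choice(4, p=self.base_freqs)
        cum = np.cumsum(self.transition, axis=1)
        u = rng.random(length)
        for i in range(1, length):
            out[i] = np.searchsorted(cum[out[i - 1]], u[i])
        return out

    def sample_many(self, n: int, length: int, rng: np.random.Generator) -> np.ndarray:
        """Sample ``n`` sequences as an (n, length) code matrix (vectorised
        across sequences for the order-1 case)."""
        if self.order == 0:
            return rng.choice(4, size=(n, length), p=self.base_freqs).astype(np.int8)
        out = np.empty((n, length), dtype=np.int8)
        out[:, 0] = rng.choice(4, size=n, p=self.base_freqs)
        cum = np.cumsum(self.transition, axis=1)
        for j in range(1, length):
            u = rng.random(n)
            prev = out[:, j - 1]
            out[:, j] = (u[:, None] > cum[prev]).sum(axis=1)
        return out

    def sample_seq(self, length: int, rng: np.random.Generator) -> str:
        return decode(self.sample_codes(length, rng))


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log-odds form of a PFM with per-column and summed score extremes."""

    source: PositionFrequencyMatrix
    pseudocount: float
    log_odds: np.ndarray
    probs: np.ndarray
    col_max: np.ndarray
    col_min: np.ndarray
    s_max: float
    s_min: float
    anchor_col: int

    @property
    def tf_id(self) -> str:
        return self.source.tf_id

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]


@dataclass(frozen=True)
class TrapParams:
    """Biophysical occupancy parameters.

    ``lambda_`` scales mismatch energies; ``R0 = exp(slope * W + intercept)``
    unless ``r0_override`` is given.  ``pseudocount`` regularises the count
    ratios inside the energy term.
    """

    lambda_: float = 0.7
    ln_r0_slope: float = 0.584
    ln_r0_intercept: float = -5.66
    r0_override: float | None = None
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.r0_override is not None and self.r0_override <= 0:
            raise ValueError("r0_override must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def r0(self, width: int) -> float:
        if self.r0_override is not None:
            return self.r0_override
        return math.exp(self.ln_r0_slope * width + self.ln_r0_intercept)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif window; coordinates are 1-based on the plus strand."""

    tf_id: str
    start: int
    strand: str
    score: float
    rel_score: float
    anchor_pos: int


@dataclass(frozen=True)
class NullDistribution:
    """Sorted occupancies of background-sampled sequences."""

    tf_id: str
    values: np.ndarray
    seq_len: int
    seed: int

    @property
    def n(self) -> int:
        return len(self.values)


def build_pwm(
    pfm: PositionFrequencyMatrix,
    bg: BackgroundModel,
    pseudocount: float = 0.8,
) -> PositionWeightMatrix:
    """Turn counts into a log2-odds PWM against the background.

    Column probabilities are ``(counts + pc * bg_b) / (total + pc)`` — the
    pseudocount is distributed over bases by background frequency, the common
    JASPAR-ecosystem convention.  Raises :class:`DegenerateMatrixError` when
    all columns are flat, in which case the relative score is undefined.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = pfm.counts
    totals = counts.sum(axis=0)
    bg_freqs = bg.base_freqs
    probs = (counts + pseudocount * bg_freqs[:, None]) / (totals + pseudocount)
    log_odds = np.log2(probs / bg_freqs[:, None])
    col_max = log_odds.max(axis=0)
    col_min = log_odds.min(axis=0)
    s_max = float(col_max.sum())
    s_min = float(col_min.sum())
    if s_max - s_min <= 1e-12:
        raise DegenerateMatrixError(
            f"degenerate matrix {pfm.tf_id!r}: all columns flat, relative score undefined"
        )
    # anchor column: the most informative column (max KL to background)
    info = (probs * np.log2(probs / bg_freqs[:, None])).sum(axis=0)
    anchor_col = int(info.argmax())
    return PositionWeightMatrix(
        source=pfm,
        pseudocount=pseudocount,
        log_odds=log_odds,
        probs=probs,
        col_max=col_max,
        col_min=col_min,
        s_max=s_max,
        s_min=s_min,
        anchor_col=anchor_col,
    )


def _window_codes(codes: np.ndarray, width: int) -> np.ndarray:
    if len(codes) < width:
        raise ValueError(f"sequence shorter ({len(codes)}) than motif width ({width})")
    return np.lib.stride_tricks.sliding_window_view(codes, width)


def _rc_matrix(mat: np.ndarray) -> np.ndarray:
    """Score matrix for the reverse-complement strand: complement rows,
    reverse columns.  Scoring plus-strand windows with this matrix equals
    scoring the reverse complement of each window with the original."""
    return mat[::-1, ::-1]


def scan(
    pwm: PositionWeightMatrix,
    seq: str,
    both_strands: bool = True,
    rel_threshold: float = 0.8,
    anchor_col: int | None = None,
) -> list[MotifHit]:
    """Report every window with relative score >= ``rel_threshold``.

    Minus-strand windows are scored on the reverse complement but reported
    with plus-strand start coordinates; ties are kept.  ``anchor_pos`` marks
    the plus-strand position of the designated motif column (by default the
    PWM's most informative column) within each hit.
    """
    codes = encode(seq)
    width = pwm.width
    windows = _window_codes(codes, width)
    cols = np.arange(width)
    anchor = pwm.anchor_col if anchor_col is None else anchor_col
    if not 0 <= anchor < width:
        raise ValueError("anchor column outside motif")
    span = pwm.s_max - pwm.s_min

    hits: list[MotifHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        lo = pwm.log_odds if strand == "+" else _rc_matrix(pwm.log_odds)
        scores = lo[windows, cols].sum(axis=1)
        rel = (scores - pwm.s_min) / span
        for idx in np.flatnonzero(rel >= rel_threshold):
            start = int(idx) + 1
            offset = anchor if strand == "+" else width - 1 - anchor
            hits.append(
                MotifHit(
                    tf_id=pwm.tf_id,
                    start=start,
                    strand=strand,
                    score=float(scores[idx]),
                    rel_score=float(rel[idx]),
                    anchor_pos=start + offset,
                )
            )
    hits.sort(key=lambda h: (-h.rel_score, h.start, h.strand))
    return hits


def _energy_matrix(pfm: PositionFrequencyMatrix, params: TrapParams) -> np.ndarray:
    """Per-base, per-column mismatch energies: zero for the column's best base."""
    counts = pfm.counts
    cmax = counts.max(axis=0)
    return np.log((cmax + params.pseudocount) / (counts + params.pseudocount)) / params.lambda_


def _occupancy_from_codes(
    codes: np.ndarray, pfm: PositionFrequencyMatrix, params: TrapParams
) -> float:
    width = pfm.width
    windows = _window_codes(codes, width)
    cols = np.arange(width)
    eng = _energy_matrix(pfm, params)
    r0 = params.r0(width)
    total = 0.0
    for mat in (eng, _rc_matrix(eng)):
        e = mat[windows, cols].sum(axis=1)
        k = r0 * np.exp(-e)
        total += float((k / (1.0 + k)).sum())
    return total


def trap_affinity(
    seq: str,
    pfm: PositionFrequencyMatrix,
    params: TrapParams | None = None,
    bg: BackgroundModel | None = None,
) -> float:
    """Expected TF occupancy of a sequence under the biophysical model.

    Each window ``i`` (both strands) contributes
    ``R0 * exp(-E_i) / (1 + R0 * exp(-E_i))`` where
    ``E_i = (1/lambda) * sum_j ln[(count(best_j) + pc) / (count(b_ij) + pc)]``.
    The background model does not enter the energy term; the parameter is
    accepted for interface symmetry with the scoring functions.
    """
    params = params or TrapParams()
    return _occupancy_from_codes(encode(seq), pfm, params)


def calibrate_null(
    pfm: PositionFrequencyMatrix,
    bg: BackgroundModel,
    seq_len: int,
    n_null: int,
    seed: int,
    params: TrapParams | None = None,
) -> NullDistribution:
    """Occupancy null from ``n_null`` background sequences of ``seq_len``."""
    if n_null < 100:
        raise ValueError("n_null must be at least 100 for a usable null")
    if seq_len < pfm.width:
        raise ValueError("seq_len shorter than motif width")
    params = params or TrapParams()
    rng = np.random.default_rng(seed)
    mat = bg.sample_many(n_null, seq_len, rng)
    values = np.array(
        [_occupancy_from_codes(mat[i], pfm, params) for i in range(n_null)]
    )
    values.sort()
    return NullDistribution(tf_id=pfm.tf_id, values=values, seq_len=seq_len, seed=seed)


def affinity_pvalue(occupancy: float, null: NullDistribution) -> float:
    """Right-tail empirical p-value with add-one correction.

    ``p = (1 + #{null >= occupancy}) / (n_null + 1)``; never exactly zero.
    """
    if null.n == 0:
        raise ValueError("empty null distribution")
    # values are sorted ascending: count >= occupancy via searchsorted
    n_ge = null.n - int(np.searchsorted(null.values, occupancy, side="left"))
    return (1 + n_ge) / (null.n + 1)
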