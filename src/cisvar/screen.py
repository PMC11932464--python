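"""Allele-differential TF-binding screen.

For every motif x SNP pair, the two allelic sequences are scored with the
biophysical occupancy model, each occupancy is converted to an empirical
p-value against a background null, and the two per-allele p-values are
summarised as

* ``p_combined`` — Bonferroni over the two allele sequences,
  ``min(2 * min(p_ref, p_alt), 1)``;
* ``dlogp`` — ``log10(p_alt) - log10(p_ref)``, positive when the reference
  allele is the stronger predicted binder;
* ``best_rel_score`` — the best relative PWM score of any scanned window
  overlapping the SNP on either allele;
* a congruence flag — whether the SNP sits inside the motif hit at a column
  whose base preference is decisive between the two alleles.

Across the whole screen the combined p-values are Benjamini-Hochberg
adjusted; rows are ranked by q-value, then |dlogp|, then factor id.  A raw
p-value pre-filter (the exploratory fixed cut used alongside FDR control)
can be supplied in the config.

``spacing_analysis`` reports pairwise gaps between motif anchor coordinates
and every maximal arithmetic progression of length >= 3 — the pattern behind
equally spaced binding-site arrangements on an enhancer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log10
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .motif import (
    BackgroundModel,
    MotifHit,
    NullDistribution,
    PositionFrequencyMatrix,
    PositionWeightMatrix,
    TrapParams,
    affinity_pvalue,
    build_pwm,
    calibrate_null,
    scan,
    trap_affinity,
)

__all__ = [
    "AlleleEffect",
    "ScreenConfig",
    "ScreenReport",
    "SpacingResult",
    "Progression",
    "score_allele_pair",
    "bh_adjust",
    "run_screen",
    "congruence_check",
    "spacing_analysis",
]


@dataclass(frozen=True)
class AlleleEffect:
    """Predicted allele-specific binding effect of one TF at one SNP."""

    tf_id: str
    snp_id: str
    p_ref: float
    p_alt: float
    p_combined: float
    dlogp: float
    best_rel_score: float
    congruent: bool
    preferred_allele: str  # "ref" | "alt" | "none"


@dataclass(frozen=True)
class ScreenConfig:
    """Screen-wide settings.

    ``raw_p_threshold`` is an optional fixed pre-filter on ``p_combined``
    applied in addition to the q-value cut; ``min_rel_score`` requires a
    motif window of that relative score over the SNP before a row can be
    flagged (no motif, no call).
    """

    n_null: int = 2000
    seed: int = 0
    q_threshold: float = 0.05
    raw_p_threshold: float | None = None
    min_rel_score: float = 0.8
    min_pref_ratio: float = 2.0
    pseudocount: float = 0.8
    bg: BackgroundModel = field(default_factory=BackgroundModel.uniform)
    trap: TrapParams = field(default_factory=TrapParams)


@dataclass(frozen=True)
class Progression:
    start_anchor: int
    common_difference: int
    length: int


@dataclass(frozen=True)
class SpacingResult:
    anchors: tuple[int, ...]
    pairwise_gaps: tuple[int, ...]
    progressions: tuple[Progression, ...]


@dataclass
class ScreenReport:
    rows: list[AlleleEffect]
    q_values: np.ndarray
    significant: np.ndarray
    significance_threshold: float

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "tf_id": [r.tf_id for r in self.rows],
                "snp_id": [r.snp_id for r in self.rows],
                "p_ref": [r.p_ref for r in self.rows],
                "p_alt": [r.p_alt for r in self.rows],
                "p_combined": [r.p_combined for r in self.rows],
                "q": self.q_values,
                "dlogp": [r.dlogp for r in self.rows],
                "rel_score": [r.best_rel_score for r in self.rows],
                "congruent": [r.congruent for r in self.rows],
                "preferred_allele": [r.preferred_allele for r in self.rows],
                "significant": self.significant,
            }
        )
        return df


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _hits_over_snp(
    pwm: PositionWeightMatrix, seq: str, snp_index: int
) -> list[MotifHit]:
    hits = scan(pwm, seq, both_strands=True, rel_threshold=0.0)
    w = pwm.width
    return [h for h in hits if h.start <= snp_index <= h.start + w - 1]


def congruence_check(
    pwm: PositionWeightMatrix,
    seq: str,
    snp_index: int,
    hit: MotifHit,
    other_base: str,
    min_pref_ratio: float = 2.0,
) -> tuple[bool, str]:
    """Is the SNP decisive inside the motif hit, and which allele matches?

    Congruent iff the SNP falls inside the hit window and the probability of
    the PWM column's top base exceeds the probability of the *other* allele's
    base by ``min_pref_ratio``.  The preferred allele is whichever allele
    (the one in ``seq`` = "ref" by caller convention, or ``other_base``)
    carries the column's top base; "none" when neither does.
    """
    if not 1 <= snp_index <= len(seq):
        raise ValueError("snp_index outside sequence")
    w = pwm.width
    if not hit.start <= snp_index <= hit.start + w - 1:
        return False, "none"
    offset = snp_index - hit.start
    col = offset if hit.strand == "+" else w - 1 - offset
    probs = pwm.probs[:, col]
    top = int(probs.argmax())
    # map the column's top base into sequence-strand space
    top_seq_base = "ACGT"[top] if hit.strand == "+" else "TGCA"[top]
    this_base = seq[snp_index - 1]
    if this_base == top_seq_base:
        preferred = "this"
    elif other_base == top_seq_base:
        preferred = "other"
    else:
        return False, "none"
    # probability ratio between the top base and the non-preferred allele
    loser = other_base if preferred == "this" else this_base
    loser_idx = "ACGT".index(loser) if hit.strand == "+" else "TGCA".index(loser)
    ratio = probs[top] / probs[loser_idx]
    if ratio >= min_pref_ratio:
        return True, preferred
    return False, "none"


def score_allele_pair(
    pfm: PositionFrequencyMatrix,
    seq_ref: str,
    seq_alt: str,
    snp_index: int,
    null: NullDistribution,
    params: TrapParams | None = None,
    snp_id: str = "",
    bg: BackgroundModel | None = None,
    pseudocount: float = 0.8,
    min_pref_ratio: float = 2.0,
    pwm: PositionWeightMatrix | None = None,
) -> AlleleEffect:
    """Allele-differential affinity of one motif at one SNP.

    A pre-built ``pwm`` (for the same pfm/background/pseudocount) may be
    passed to avoid rebuilding it per SNP.
    """
    if len(seq_ref) != len(seq_alt):
        raise ValueError("allele sequences must have equal length")
    diffs = [i for i, (a, b) in enumerate(zip(seq_ref, seq_alt), start=1) if a != b]
    if diffs != [snp_index]:
        raise ValueError(
            f"sequences must differ exactly at snp_index {snp_index}, differ at {diffs}"
        )
    params = params or TrapParams()
    bg = bg or BackgroundModel.uniform()
    occ_ref = trap_affinity(seq_ref, pfm, params)
    occ_alt = trap_affinity(seq_alt, pfm, params)
    p_ref = affinity_pvalue(occ_ref, null)
    p_alt = affinity_pvalue(occ_alt, null)
    dlogp = log10(p_alt) - log10(p_ref)
    p_combined = min(2.0 * min(p_ref, p_alt), 1.0)

    if pwm is None:
        pwm = build_pwm(pfm, bg, pseudocount=pseudocount)
    best_hit: MotifHit | None = None
    best_from_ref = True
    for is_ref, seq in ((True, seq_ref), (False, seq_alt)):
        for h in _hits_over_snp(pwm, seq, snp_index):
            if best_hit is None or h.rel_score > best_hit.rel_score:
                best_hit, best_from_ref = h, is_ref
    best_rel = best_hit.rel_score if best_hit is not None else 0.0

    congruent, preferred = False, "none"
    if best_hit is not None:
        seq, other = (seq_ref, seq_alt) if best_from_ref else (seq_alt, seq_ref)
        congruent, which = congruence_check(
            pwm, seq, snp_index, best_hit, other[snp_index - 1], min_pref_ratio
        )
        if which == "this":
            preferred = "ref" if best_from_ref else "alt"
        elif which == "other":
            preferred = "alt" if best_from_ref else "ref"
    return AlleleEffect(
        tf_id=pfm.tf_id,
        snp_id=snp_id,
        p_ref=p_ref,
        p_alt=p_alt,
        p_combined=p_combined,
        dlogp=dlogp,
        best_rel_score=best_rel,
        congruent=congruent,
        preferred_allele=preferred,
    )


def run_screen(
    snps: Sequence[tuple[str, str, str, int]],
    pfm_library: Sequence[PositionFrequencyMatrix],
    config: ScreenConfig | None = None,
    nulls: dict[tuple[str, int], NullDistribution] | None = None,
) -> ScreenReport:
    """Score every TF x SNP pair, BH-adjust, rank and flag.

    ``snps`` holds ``(snp_id, seq_ref, seq_alt, snp_index)`` tuples.  Null
    distributions are calibrated once per (motif, sequence length) and can be
    passed in pre-calibrated via ``nulls`` for reuse across runs.
    """
    config = config or ScreenConfig()
    if not pfm_library:
        raise ValueError("pfm_library must not be empty")
    nulls = dict(nulls) if nulls else {}
    seeds = np.random.SeedSequence(config.seed).generate_state(len(pfm_library))
    effects: list[AlleleEffect] = []
    for k, pfm in enumerate(pfm_library):
        pwm = build_pwm(pfm, config.bg, pseudocount=config.pseudocount)
        for snp_id, seq_ref, seq_alt, snp_index in snps:
            key = (pfm.tf_id, len(seq_ref))
            if key not in nulls:
                nulls[key] = calibrate_null(
                    pfm,
                    config.bg,
                    seq_len=len(seq_ref),
                    n_null=config.n_null,
                    seed=int(seeds[k]) % (2**31),
                    params=config.trap,
                )
            effects.append(
                score_allele_pair(
                    pfm,
                    seq_ref,
                    seq_alt,
                    snp_index,
                    nulls[key],
                    params=config.trap,
                    snp_id=snp_id,
                    bg=config.bg,
                    pseudocount=config.pseudocount,
                    min_pref_ratio=config.min_pref_ratio,
                    pwm=pwm,
                )
            )
    q = bh_adjust([e.p_combined for e in effects])
    order = sorted(
        range(len(effects)),
        key=lambda i: (q[i], -abs(effects[i].dlogp), effects[i].tf_id, effects[i].snp_id),
    )
    rows = [effects[i] for i in order]
    q_sorted = q[order]
    significant = q_sorted < config.q_threshold
    if config.raw_p_threshold is not None:
        significant &= np.array([r.p_combined < config.raw_p_threshold for r in rows])
    significant &= np.array([r.best_rel_score >= config.min_rel_score for r in rows])
    return ScreenReport(
        rows=rows,
        q_values=q_sorted,
        significant=significant,
        significance_threshold=config.q_threshold,
    )


def spacing_analysis(
    anchors: Sequence[int], tolerance_bp: int = 0
) -> SpacingResult:
    """Pairwise gaps and maximal equal-spacing runs among anchor coordinates.

    Reports every maximal arithmetic progression of length >= 3 whose
    successive gaps deviate from the progression's first gap by at most
    ``tolerance_bp``; unsorted input is sorted with a warning.
    """
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors")
    a = list(anchors)
    if a != sorted(a):
        warnings.warn("anchors were not sorted ascending; sorting", stacklevel=2)
        a = sorted(a)
    arr = np.asarray(a)
    gaps = tuple(
        int(arr[j] - arr[i]) for i in range(len(arr)) for j in range(i + 1, len(arr))
    )

    def find_near(value: float) -> int | None:
        """Index of the anchor closest to value within tolerance, else None."""
        k = int(np.searchsorted(arr, value))
        best, best_dev = None, None
        for idx in (k - 1, k, k + 1):
            if 0 <= idx < len(arr):
                dev = abs(int(arr[idx]) - value)
                if dev <= tolerance_bp and (best_dev is None or dev < best_dev):
                    best, best_dev = idx, dev
        return best

    found: dict[tuple[int, int, int], Progression] = {}
    n = len(arr)
    for i in range(n):
        for j in range(i + 1, n):
            d = int(arr[j] - arr[i])
            if d == 0:
                continue
            if find_near(int(arr[i]) - d) is not None:
                continue  # extendable backwards: not a maximal start
            length = 2
            expected = float(arr[j])
            while True:
                nxt = find_near(expected + d)
                if nxt is None:
                    break
                expected = float(arr[nxt])
                length += 1
            if length >= 3:
                key = (int(arr[i]), d, length)
                found.setdefault(key, Progression(*key))
    progressions = tuple(
        sorted(found.values(), key=lambda p: (p.start_anchor, p.common_difference))
    )
    return SpacingResult(anchors=tuple(int(x) for x in arr), pairwise_gaps=gaps, progressions=progressions)
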