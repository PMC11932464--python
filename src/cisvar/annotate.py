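"""Chromatin-element annotation of candidate variants.

Variants (1-based positions) are intersected with chromatin tracks held in
0-based half-open intervals — open chromatin (DHS), enhancer histone marks
(H3K27ac, H3K4me1), TF ChIP-seq clusters (``TF-ChIP:<factor>``) and
chromatin-state segmentations (``ChromHMM:<state>``) — and classified into a
regulatory context.

The default classification rule formalises the usual biochemical reading of
these marks (the underlying descriptive practice leaves it implicit, so the
rule is explicit and overridable here):

* ``strong_enhancer`` — a ChromHMM strong-enhancer state, or DHS together
  with at least one enhancer histone mark;
* ``weak_enhancer`` — a ChromHMM weak-enhancer state, or exactly one of
  {DHS, H3K27ac, H3K4me1};
* ``promoter_proximal`` — otherwise, when a configured promoter interval
  overlaps;
* ``none`` — no qualifying overlap.

Chromosome naming is normalised so that "chr17" and "17" match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Variant",
    "VariantAnnotation",
    "ClassificationRule",
    "intersect_variants",
    "classify_regulatory",
    "ucsc_span_to_interval",
]

logger = logging.getLogger(__name__)

ENHANCER_MARKS = ("DHS", "H3K27ac", "H3K4me1")


@dataclass(frozen=True)
class GenomicInterval:
    """Labelled interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    label: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    id: str


@dataclass(frozen=True)
class VariantAnnotation:
    variant: Variant
    overlapping: tuple[GenomicInterval, ...]
    regulatory_class: str

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(iv.label for iv in self.overlapping)


@dataclass(frozen=True)
class ClassificationRule:
    """Configurable mapping from overlap labels to a regulatory class."""

    strong_states: tuple[str, ...] = ("ChromHMM:strong_enhancer",)
    weak_states: tuple[str, ...] = ("ChromHMM:weak_enhancer",)
    enhancer_marks: tuple[str, ...] = ENHANCER_MARKS
    promoter_labels: tuple[str, ...] = ("promoter",)


def normalize_chrom(chrom: str) -> str:
    """Treat UCSC-style ('chr17') and Ensembl-style ('17') names as equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def ucsc_span_to_interval(
    chrom: str, start_1based: int, end_1based: int, label: str
) -> GenomicInterval:
    """Convert a printed 1-based fully-closed span (UCSC browser convention,
    e.g. chr17:41810335-41810590) to internal 0-based half-open coordinates."""
    return GenomicInterval(chrom=chrom, start=start_1based - 1, end=end_1based, label=label)


def classify_labels(labels: Iterable[str], rule: ClassificationRule | None = None) -> str:
    """Pure classification of an overlap label set (same set, same class)."""
    rule = rule or ClassificationRule()
    labels = set(labels)
    known = (
        set(rule.strong_states)
        | set(rule.weak_states)
        | set(rule.enhancer_marks)
        | set(rule.promoter_labels)
    )
    for lab in sorted(labels):
        if lab not in known and not lab.startswith(("TF-ChIP:", "ChromHMM:")):
            logger.warning("ignoring unknown track label %r", lab)
    marks = [m for m in rule.enhancer_marks if m in labels]
    has_dhs = "DHS" in labels and "DHS" in rule.enhancer_marks
    histone = [m for m in marks if m != "DHS"]
    if labels & set(rule.strong_states) or (has_dhs and histone):
        return "strong_enhancer"
    if labels & set(rule.weak_states) or len(marks) == 1:
        return "weak_enhancer"
    if labels & set(rule.promoter_labels):
        return "promoter_proximal"
    return "none"


def classify_regulatory(
    annotation: VariantAnnotation, rule: ClassificationRule | None = None
) -> str:
    return classify_labels(annotation.labels, rule)


def intersect_variants(
    variants: Sequence[Variant | tuple],
    tracks: Sequence[GenomicInterval],
    rule: ClassificationRule | None = None,
) -> list[VariantAnnotation]:
    """Annotate each variant with every overlapping track interval.

    A variant at 1-based position p overlaps [s, e) iff s <= p - 1 < e.
    Overlaps are reported sorted by (label, start, end); the regulatory class
    is filled in with the (possibly overridden) classification rule.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in tracks:
        trees.setdefault(normalize_chrom(iv.chrom), IntervalTree()).addi(
            iv.start, iv.end, iv
        )
    out: list[VariantAnnotation] = []
    for v in variants:
        if not isinstance(v, Variant):
            v = Variant(*v)
        tree = trees.get(normalize_chrom(v.chrom))
        overlaps: list[GenomicInterval] = (
            [hit.data for hit in tree.at(v.pos - 1)] if tree is not None else []
        )
        overlaps.sort(key=lambda iv: (iv.label, iv.start, iv.end))
        ann = VariantAnnotation(
            variant=v,
            overlapping=tuple(overlaps),
            regulatory_class=classify_labels((iv.label for iv in overlaps), rule),
        )
        out.append(ann)
    return out
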