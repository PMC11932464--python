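"""Synthetic inputs with known ground truth for every pipeline stage.

The generators here define the bench conditions the rest of the package is
tested under:

* haplotype panels with block-wise LD — within a block every site is a copy
  of a founder column (pairwise r² = 1 before shuffling); between blocks a
  configurable fraction of haplotype labels is permuted independently per
  block, which destroys LD across block boundaries;
* background DNA with motif consensus words planted at controlled positions
  and strands, including allelic sequence pairs where a single SNP replaces
  the consensus base of a chosen motif column with the column's
  least-favoured base;
* qPCR Ct tables with a programmed true fold change and per-well Gaussian
  noise.

All generators are seed-deterministic: the same arguments and seed reproduce
byte-identical output.  Sequences are uppercase A/C/G/T only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import BASES, decode, revcomp_codes
from .assays import CtRecord
from .motif import BackgroundModel, PositionFrequencyMatrix

__all__ = [
    "Site",
    "HaplotypePanel",
    "MotifPlantSpec",
    "CtTableSpec",
    "simulate_haplotype_panel",
    "plant_motifs",
    "plant_truth_intervals",
    "make_allelic_pair",
    "simulate_ct_table",
    "synthetic_cebpb_like_pfm",
    "synthetic_gfi1_like_pfm",
    "random_pfm",
]


@dataclass(frozen=True)
class Site:
    """Biallelic site metadata; ``pos`` is 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix (n_haplotypes x n_sites) with site metadata.

    Haplotype count must be even (a phased diploid panel contributes two rows
    per sample); site positions are strictly increasing per chromosome.
    """

    alleles: np.ndarray
    sites: list[Site]
    seed: int | None = None

    def __post_init__(self) -> None:
        alleles = np.asarray(self.alleles, dtype=np.int8)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if not np.isin(alleles, (0, 1)).all():
            raise ValueError("allele entries must be 0 or 1")
        if alleles.shape[0] % 2 != 0:
            raise ValueError("n_haplotypes must be even (phased diploid panel)")
        if alleles.shape[1] != len(self.sites):
            raise ValueError("site metadata does not match allele matrix width")
        by_chrom: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in by_chrom and s.pos <= by_chrom[s.chrom]:
                raise ValueError("site positions must be strictly increasing per chromosome")
            by_chrom[s.chrom] = s.pos
        self.alleles = alleles

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def site_index(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.id == site_id:
                return i
        raise KeyError(f"site {site_id!r} not in panel")


@dataclass(frozen=True)
class MotifPlantSpec:
    """Where to write motif consensus words into a background sequence.

    Positions are 1-based starts; planted windows must fit inside the
    sequence and may not overlap one another.
    """

    motif: PositionFrequencyMatrix
    positions: tuple[int, ...]
    strands: tuple[str, ...]
    background: BackgroundModel
    length: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.strands):
            raise ValueError("positions and strands must have equal length")
        if any(s not in "+-" for s in self.strands):
            raise ValueError("strands must be '+' or '-'")
        w = self.motif.width
        if w > self.length:
            raise ValueError("motif wider than sequence")
        for p in self.positions:
            if not 1 <= p <= self.length - w + 1:
                raise ValueError(f"planted window at {p} extends outside [1, {self.length}]")
        occupied = sorted((p, p + w - 1) for p in self.positions)
        for (s1, e1), (s2, _) in zip(occupied, occupied[1:]):
            if s2 <= e1:
                raise ValueError("planted windows may not overlap")


@dataclass(frozen=True)
class CtTableSpec:
    """Programmed truth for a simulated qPCR experiment."""

    true_fold_change: float
    baseline_ct_target: float = 26.0
    baseline_ct_reference: float = 18.0
    noise_sd: float = 0.3
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fold_change <= 0:
            raise ValueError("true_fold_change must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


def simulate_haplotype_panel(
    n_haplotypes: int,
    block_sizes: Sequence[int],
    between_block_shuffle: float,
    maf_range: tuple[float, float],
    seed: int,
    chrom: str = "chr17",
    start_pos: int = 41_800_000,
    spacing_bp: int = 500,
) -> HaplotypePanel:
    """Blocky-LD haplotype panel.

    Each block draws a founder column with allele frequency uniform in
    ``maf_range`` (resampled until polymorphic) and copies it to every site
    in the block, giving within-block pairwise r² of exactly 1.  Afterwards,
    for each block independently, ``between_block_shuffle`` of the haplotype
    rows are permuted among themselves, decoupling blocks; at 1.0 the blocks
    are fully independent in expectation.
    """
    if n_haplotypes < 4 or n_haplotypes % 2 != 0:
        raise ValueError("n_haplotypes must be even and at least 4")
    if not block_sizes or any(b < 1 for b in block_sizes):
        raise ValueError("every block size must be at least 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not 0 <= between_block_shuffle <= 1:
        raise ValueError("between_block_shuffle must be in [0, 1]")

    rng = np.random.default_rng(seed)
    columns: list[np.ndarray] = []
    for size in block_sizes:
        maf = rng.uniform(lo, hi)
        founder = (rng.random(n_haplotypes) < maf).astype(np.int8)
        while founder.min() == founder.max():  # keep every block polymorphic
            founder = (rng.random(n_haplotypes) < maf).astype(np.int8)
        block = np.tile(founder[:, None], (1, size))
        k = int(round(between_block_shuffle * n_haplotypes))
        if k >= 2:
            rows = rng.choice(n_haplotypes, size=k, replace=False)
            block[rows] = block[rows[rng.permutation(k)]]
        columns.append(block)
    alleles = np.concatenate(columns, axis=1)

    sites = []
    for i in range(alleles.shape[1]):
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            Site(
                chrom=chrom,
                pos=start_pos + i * spacing_bp,
                ref=BASES[ref],
                alt=BASES[alt],
                id=f"snp{i:04d}",
            )
        )
    return HaplotypePanel(alleles=alleles, sites=sites, seed=seed)


def plant_motifs(spec: MotifPlantSpec) -> str:
    """Background sequence with motif consensus words written at the planted
    positions (reverse-complemented on the minus strand)."""
    rng = np.random.default_rng(spec.seed)
    codes = spec.background.sample_codes(spec.length, rng)
    consensus = spec.motif.consensus_codes()
    for pos, strand in zip(spec.positions, spec.strands):
        word = consensus if strand == "+" else revcomp_codes(consensus)
        codes[pos - 1 : pos - 1 + spec.motif.width] = word
    return decode(codes)


def plant_truth_intervals(spec: MotifPlantSpec, chrom: str = "synthetic"):
    """Planted windows as 0-based half-open labelled intervals (for BED)."""
    from .annotate import GenomicInterval

    w = spec.motif.width
    return [
        GenomicInterval(chrom=chrom, start=p - 1, end=p - 1 + w, label=spec.motif.tf_id)
        for p in sorted(spec.positions)
    ]


def make_allelic_pair(
    motif: PositionFrequencyMatrix,
    flank: int,
    snp_offset_in_motif: int,
    ref_is_consensus: bool = True,
    seed: int = 0,
    background: BackgroundModel | None = None,
) -> tuple[str, str, int]:
    """Allelic sequence pair differing at one motif column.

    Both sequences carry the motif consensus flanked by ``flank`` background
    bases on each side; at ``snp_offset_in_motif`` (0-based column) one
    sequence keeps the consensus base and the other carries the column's
    minimum-count base.  ``ref_is_consensus`` decides which is labelled ref.
    Returns ``(seq_ref, seq_alt, snp_index)`` with a 1-based ``snp_index``.
    """
    w = motif.width
    if not 0 <= snp_offset_in_motif < w:
        raise ValueError("snp_offset_in_motif outside motif")
    col = motif.counts[:, snp_offset_in_motif]
    if np.allclose(col, col[0]):
        raise ValueError("non-informative column: all bases equally counted")
    background = background or BackgroundModel.uniform()
    rng = np.random.default_rng(seed)
    consensus = motif.consensus_codes()
    top = int(col.argmax())
    worst = int(col.argmin())
    left = background.sample_codes(flank, rng)
    right = background.sample_codes(flank, rng)
    seq_cons = np.concatenate([left, consensus, right])
    seq_min = seq_cons.copy()
    seq_min[flank + snp_offset_in_motif] = worst
    snp_index = flank + snp_offset_in_motif + 1
    if ref_is_consensus:
        return decode(seq_cons), decode(seq_min), snp_index
    return decode(seq_min), decode(seq_cons), snp_index


def simulate_ct_table(
    spec: CtTableSpec,
    conditions: tuple[str, str] = ("treated", "control"),
    genes: tuple[str, str] = ("target", "reference"),
) -> list[CtRecord]:
    """Ct wells for a two-condition, target+reference qPCR design.

    The treated-condition target mean is shifted down by
    ``log2(true_fold_change)`` cycles; the reference gene is unaffected by
    condition.  Per-well Gaussian noise with ``noise_sd`` cycles is added.
    """
    treated, control = conditions
    target_gene, reference_gene = genes
    rng = np.random.default_rng(spec.seed)
    shift = float(np.log2(spec.true_fold_change))
    means = {
        (treated, target_gene): spec.baseline_ct_target - shift,
        (control, target_gene): spec.baseline_ct_target,
        (treated, reference_gene): spec.baseline_ct_reference,
        (control, reference_gene): spec.baseline_ct_reference,
    }
    records = []
    for condition in (treated, control):
        for gene in (target_gene, reference_gene):
            for rep in range(1, spec.n_replicates + 1):
                ct = means[(condition, gene)] + rng.normal(0.0, spec.noise_sd)
                records.append(
                    CtRecord(
                        sample_id=f"{condition}_{rep}",
                        condition=condition,
                        gene=gene,
                        replicate=rep,
                        ct=float(ct),
                    )
                )
    return records


def synthetic_cebpb_like_pfm() -> PositionFrequencyMatrix:
    """Synthetic CEBPB-like motif (not the JASPAR matrix).

    Width-10 matrix around the palindromic CEBP consensus ATTGCGCAAT
    (~11.7 bits).  The central C/G pair the bZIP dimer anchors on is
    near-invariant while the flanking columns are only moderately sharp, so
    a SNP that replaces the anchoring C removes far more binding energy —
    on both strands of the palindrome — than any single background mismatch
    elsewhere.  That anchor-column dominance is the allele-specific
    behaviour the screen is designed to detect.
    """
    consensus = "ATTGCGCAAT"
    counts = np.full((4, 10), 667.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 8000.0
    for anchor_col in (4, 5):  # the critical central C/G dimer contact
        counts[:, anchor_col] = 10.0
        counts["ACGT".index(consensus[anchor_col]), anchor_col] = 999_970.0
    return PositionFrequencyMatrix(tf_id="CEBPB_like_synthetic", counts=counts)


def synthetic_gfi1_like_pfm() -> PositionFrequencyMatrix:
    """Synthetic GFI1-like motif (not the JASPAR matrix); AATC-core repressor
    site used as a decoy/second factor in screen fixtures."""
    consensus = "AAATCACTGC"
    counts = np.full((4, 10), 600.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 8200.0
    return PositionFrequencyMatrix(tf_id="GFI1_like_synthetic", counts=counts)


def random_pfm(
    tf_id: str, width: int, sharpness: float, seed: int
) -> PositionFrequencyMatrix:
    """Random motif: each column puts ``sharpness`` of the mass on one base
    drawn at random and spreads the rest evenly (fixture plumbing)."""
    if not 0.25 < sharpness < 1:
        raise ValueError("sharpness must be in (0.25, 1)")
    rng = np.random.default_rng(seed)
    counts = np.full((4, width), (1 - sharpness) / 3 * 1000.0)
    tops = rng.integers(0, 4, size=width)
    counts[tops, np.arange(width)] = sharpness * 1000.0
    return PositionFrequencyMatrix(tf_id=tf_id, counts=counts)
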