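"""Readers and writers for the pipeline's standard file formats.

Haplotypes come in as phased VCF (GT fields with '|', via cyvcf2) or as the
package's plain-TSV haplotype matrix; chromatin tracks as BED3/4/6; motifs as
JASPAR flat files or MEME minimal files (parsed with Bio.motifs); sequences
as FASTA (Bio.SeqIO); Ct and reporter tables as headed TSV.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GenomicInterval, Variant
from .assays import CtRecord, ReporterRecord
from .ld import ProxySet
from .motif import MotifHit, PositionFrequencyMatrix
from .simulate import HaplotypePanel, Site

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_haplotypes_tsv",
    "write_haplotypes_tsv",
    "read_phased_vcf",
    "read_bed",
    "write_bed",
    "write_proxies_tsv",
    "read_jaspar",
    "write_jaspar",
    "read_meme_minimal",
    "read_ct_tsv",
    "write_ct_tsv",
    "read_reporter_tsv",
    "write_hits_tsv",
    "write_hits_bed",
    "write_allele_pairs_fasta",
    "read_allele_pairs_fasta",
]

CT_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct"]
REPORTER_COLUMNS = ["construct", "firefly", "renilla"]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seq_records, str(path), "fasta")


def write_allele_pairs_fasta(
    path: str | Path, pairs: dict[str, tuple[str, str]]
) -> None:
    """Pairs as ``{rsid: (seq_ref, seq_alt)}`` -> records `<rsid>_ref` / `<rsid>_alt`."""
    records = []
    for rsid, (seq_ref, seq_alt) in pairs.items():
        records.append((f"{rsid}_ref", seq_ref))
        records.append((f"{rsid}_alt", seq_alt))
    write_fasta(path, records)


def read_allele_pairs_fasta(path: str | Path) -> dict[str, tuple[str, str]]:
    seqs = read_fasta(path)
    pairs: dict[str, tuple[str, str]] = {}
    for name in seqs:
        if name.endswith("_ref"):
            rsid = name[: -len("_ref")]
            alt_name = f"{rsid}_alt"
            if alt_name not in seqs:
                raise ValueError(f"missing {alt_name} for {name}")
            pairs[rsid] = (seqs[name], seqs[alt_name])
    return pairs


# ----------------------------------------------------------- haplotypes

def write_haplotypes_tsv(path: str | Path, panel: HaplotypePanel) -> None:
    """Sites as rows: chrom, pos, id, ref, alt, then one 0/1 column per haplotype."""
    hap_cols = [f"h{i}" for i in range(panel.n_haplotypes)]
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in panel.sites],
            "pos": [s.pos for s in panel.sites],
            "id": [s.id for s in panel.sites],
            "ref": [s.ref for s in panel.sites],
            "alt": [s.alt for s in panel.sites],
        }
    )
    for i, col in enumerate(hap_cols):
        df[col] = panel.alleles[i, :]
    df.to_csv(path, sep="\t", index=False)


def read_haplotypes_tsv(path: str | Path) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t")
    meta = ["chrom", "pos", "id", "ref", "alt"]
    hap_cols = [c for c in df.columns if c not in meta]
    sites = [
        Site(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt, id=r.id)
        for r in df.itertuples()
    ]
    alleles = df[hap_cols].to_numpy(dtype=np.int8).T
    return HaplotypePanel(alleles=alleles, sites=sites)


def read_phased_vcf(path: str | Path, samples: Sequence[str] | None = None) -> HaplotypePanel:
    """Phased biallelic SNVs from a VCF into a haplotype panel.

    Raises on unphased genotypes; multi-allelic and non-SNV records are
    skipped.  ``samples`` optionally restricts the panel to a sample subset
    (treated as one pooled panel).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=list(samples) if samples else None)
    rows: list[list[int]] = []
    sites: list[Site] = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        haps: list[int] = []
        for g in var.genotypes:
            a0, a1, phased = g[0], g[1], g[2]
            if not phased:
                raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
            if a0 < 0 or a1 < 0:
                raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
            haps.extend([a0, a1])
        rows.append(haps)
        sites.append(
            Site(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                id=var.ID or f"{var.CHROM}:{var.POS}",
            )
        )
    if not sites:
        raise ValueError("no biallelic SNVs found in VCF")
    alleles = np.array(rows, dtype=np.int8).T
    return HaplotypePanel(alleles=alleles, sites=sites)


# ------------------------------------------------------------------ BED

def read_bed(path: str | Path, label: str | None = None) -> list[GenomicInterval]:
    """BED3/4/6; the label comes from the name column when present, else from
    the ``label`` argument (required for BED3)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else label
            if name is None:
                raise ValueError("BED3 input needs an explicit label")
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            out.append(
                GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    label=name,
                    score=score,
                )
            )
    return out


def write_bed(path: str | Path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{score}\n")


# ------------------------------------------------------------------ LD

def write_proxies_tsv(path: str | Path, proxy_set: ProxySet, panel: HaplotypePanel) -> None:
    site_by_id = {s.id: s for s in panel.sites}
    rows = []
    for sid, stats in proxy_set.proxies:
        s = site_by_id[sid]
        rows.append(
            {"id": sid, "chrom": s.chrom, "pos": s.pos, "r2": stats.r2, "d_prime": stats.d_prime}
        )
    pd.DataFrame(rows, columns=["id", "chrom", "pos", "r2", "d_prime"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------- motifs

def _from_bio_motif(m) -> PositionFrequencyMatrix:
    counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
    tf_id = m.matrix_id if getattr(m, "matrix_id", None) else (m.name or "motif")
    return PositionFrequencyMatrix(tf_id=tf_id, counts=counts)


def read_jaspar(path: str | Path) -> list[PositionFrequencyMatrix]:
    with open(path) as fh:
        return [_from_bio_motif(m) for m in bio_motifs.parse(fh, "jaspar")]


def write_jaspar(path: str | Path, pfms: Sequence[PositionFrequencyMatrix]) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.tf_id} {pfm.tf_id}\n")
            for i, base in enumerate("ACGT"):
                row = " ".join(f"{v:g}" for v in pfm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


def read_meme_minimal(path: str | Path) -> list[PositionFrequencyMatrix]:
    with open(path) as fh:
        return [_from_bio_motif(m) for m in bio_motifs.parse(fh, "minimal")]


def write_hits_tsv(path: str | Path, hits: Sequence[MotifHit], seq_id: str = "") -> None:
    pd.DataFrame(
        {
            "seq_id": [seq_id] * len(hits),
            "tf_id": [h.tf_id for h in hits],
            "start": [h.start for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
            "rel_score": [h.rel_score for h in hits],
            "anchor_pos": [h.anchor_pos for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)


def write_hits_bed(path: str | Path, hits: Sequence[MotifHit], chrom: str, width: int) -> None:
    """BED6 with the relative score scaled to the 0-1000 BED score range."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{chrom}\t{h.start - 1}\t{h.start - 1 + width}\t{h.tf_id}"
                f"\t{round(h.rel_score * 1000)}\t{h.strand}\n"
            )


# ------------------------------------------------------------- assays

def read_ct_tsv(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing required columns: {sorted(missing)}")
    return [
        CtRecord(
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            gene=str(r.gene),
            replicate=int(r.replicate),
            ct=float(r.ct),
        )
        for r in df.itertuples()
    ]


def write_ct_tsv(path: str | Path, records: Sequence[CtRecord]) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "condition": [r.condition for r in records],
            "gene": [r.gene for r in records],
            "replicate": [r.replicate for r in records],
            "ct": [r.ct for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_reporter_tsv(path: str | Path) -> list[ReporterRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(REPORTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reporter table missing required columns: {sorted(missing)}")
    return [
        ReporterRecord(construct=str(r.construct), firefly=float(r.firefly), renilla=float(r.renilla))
        for r in df.itertuples()
    ]
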