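"""Linkage disequilibrium from phased haplotypes and proxy-SNP selection.

Works directly on phased 0/1 haplotype matrices (no EM from unphased
genotypes): with p_a and p_b the alt-allele frequencies at two sites and
p_ab the frequency of haplotypes carrying both alt alleles,

    D  = p_ab - p_a * p_b
    r² = D² / (p_a (1 - p_a) p_b (1 - p_b))
    D' = |D| / D_max

where D_max is min(p_a (1 - p_b), (1 - p_a) p_b) for D > 0 and
min(p_a p_b, (1 - p_a)(1 - p_b)) for D < 0.  Monomorphic sites make LD
undefined and raise rather than silently returning zero.

Proxy selection mirrors the reference-panel workflow used to expand a GWAS
lead SNP into its haplotype block: every polymorphic site within a window
whose r² with the lead meets the threshold is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .simulate import HaplotypePanel

__all__ = [
    "LDStats",
    "ProxySet",
    "UndefinedLDError",
    "pairwise_ld",
    "select_proxies",
    "allele_freq_from_genotype_freqs",
    "round_half_up",
]


class UndefinedLDError(ValueError):
    """LD is undefined at a monomorphic site."""


@dataclass(frozen=True)
class LDStats:
    r2: float
    d_prime: float
    p_a: float
    p_b: float
    p_ab: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")
        if not -1e-12 <= self.d_prime <= 1 + 1e-12:
            raise ValueError("d_prime must lie in [0, 1]")
        if self.p_ab > min(self.p_a, self.p_b) + 1e-12:
            raise ValueError("p_ab cannot exceed min(p_a, p_b)")


@dataclass(frozen=True)
class ProxySet:
    lead_id: str
    proxies: list[tuple[str, LDStats]]
    threshold: float


def pairwise_ld(panel: HaplotypePanel, i: int, j: int) -> LDStats:
    """r² and D' between two sites of a phased panel."""
    if i == j:
        raise ValueError("site indices must differ")
    a = panel.alleles[:, i].astype(float)
    b = panel.alleles[:, j].astype(float)
    p_a = float(a.mean())
    p_b = float(b.mean())
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedLDError(f"monomorphic site among indices ({i}, {j}); LD undefined")
    p_ab = float((a * b).mean())
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = d * d / denom
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = 1.0
    d_prime = abs(d) / d_max
    return LDStats(
        r2=min(r2, 1.0), d_prime=min(d_prime, 1.0), p_a=p_a, p_b=p_b, p_ab=p_ab
    )


def select_proxies(
    panel: HaplotypePanel,
    lead_id: str,
    r2_threshold: float = 0.8,
    window_bp: int = 500_000,
) -> ProxySet:
    """All sites within ``window_bp`` of the lead with r² >= threshold.

    The lead itself is excluded; monomorphic candidate sites are skipped with
    a warning (a monomorphic *lead* is an error).  Proxies are returned in
    genomic-position order.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    lead_idx = panel.site_index(lead_id)
    lead_site = panel.sites[lead_idx]
    lead_col = panel.alleles[:, lead_idx]
    if lead_col.min() == lead_col.max():
        raise UndefinedLDError(f"lead SNP {lead_id!r} is monomorphic")
    proxies: list[tuple[str, LDStats]] = []
    for idx, site in enumerate(panel.sites):
        if idx == lead_idx or site.chrom != lead_site.chrom:
            continue
        if abs(site.pos - lead_site.pos) > window_bp:
            continue
        try:
            stats = pairwise_ld(panel, lead_idx, idx)
        except UndefinedLDError:
            warnings.warn(f"skipping monomorphic site {site.id}", stacklevel=2)
            continue
        if stats.r2 >= r2_threshold:
            proxies.append((site.id, stats))
    order = {s.id: s.pos for s in panel.sites}
    proxies.sort(key=lambda item: order[item[0]])
    return ProxySet(lead_id=lead_id, proxies=proxies, threshold=r2_threshold)


def allele_freq_from_genotype_freqs(f_AA: float, f_Aa: float, f_aa: float) -> float:
    """Allele frequency of A from the three genotype frequencies."""
    if min(f_AA, f_Aa, f_aa) < 0:
        raise ValueError("genotype frequencies must be nonnegative")
    total = f_AA + f_Aa + f_aa
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"genotype frequencies sum to {total}, expected 1")
    return f_AA + f_Aa / 2.0


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.3975 -> 0.398 at 3 digits), matching how
    population allele frequencies are conventionally printed.

    Binary float noise below 10^-(ndigits+6) is absorbed first, so a value
    that is exactly 0.3975 in decimal arithmetic rounds up even when its
    float representation is 0.39749999999999996.
    """
    snapped = Decimal(repr(x)).quantize(Decimal(1).scaleb(-(ndigits + 6)))
    return float(snapped.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
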