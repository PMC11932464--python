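"""Chromatin-element annotation of candidate variants.

Intersects variants with chromatin tracks (here: the two CEBPB ChIP-seq peak
spans printed for the SOST enhancer, plus toy DHS/H3K27ac intervals) and
classifies each variant's regulatory context.
"""

import cisvar as cv

# Printed 1-based fully-closed browser spans, converted to 0-based half-open.
peak1 = cv.ucsc_span_to_interval("chr17", 41_810_335, 41_810_590, "TF-ChIP:CEBPB")
peak2 = cv.ucsc_span_to_interval("chr17", 41_811_788, 41_812_043, "TF-ChIP:CEBPB")
dhs = cv.GenomicInterval("chr17", 41_810_300, 41_813_500, "DHS")
k27 = cv.GenomicInterval("chr17", 41_810_400, 41_812_200, "H3K27ac")

variants = [
    cv.Variant("chr17", 41_810_515, "anchor_peak1"),   # inside ChIP peak 1
    cv.Variant("chr17", 41_813_369, "rs9783823"),      # between/after the peaks
    cv.Variant("chr17", 41_900_000, "rs_outside"),     # outside every track
]

for ann in cv.intersect_variants(variants, [peak1, peak2, dhs, k27]):
    labels = ", ".join(iv.label for iv in ann.overlapping) or "-"
    print(f"{ann.variant.id:>14}: overlaps [{labels}] -> {ann.regulatory_class}")
# anchor_peak1 overlaps the ChIP peak plus DHS+H3K27ac -> strong_enhancer;
# rs9783823 sits in open chromatin only (no ChIP peak in these cells, which
# carry the motif-destroying allele) -> weak_enhancer; the distal variant
# overlaps nothing -> none.
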