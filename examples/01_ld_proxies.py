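"""LD proxy selection on a simulated haplotype block.

Builds a phased panel whose first ten sites form one perfect-LD block and a
second, shuffled block that is independent of it, then expands a lead SNP
into its proxy set at the conventional r² > 0.8 cut.  Also shows the
genotype-frequency arithmetic used to report population allele frequencies.
"""

import cisvar as cv

panel = cv.simulate_haplotype_panel(
    n_haplotypes=200,
    block_sizes=[10, 5],
    between_block_shuffle=1.0,
    maf_range=(0.2, 0.4),
    seed=11,
)
proxies = cv.select_proxies(panel, lead_id="snp0000", r2_threshold=0.8, window_bp=500_000)

print(f"lead snp0000 has {len(proxies.proxies)} proxies at r2 >= {proxies.threshold}:")
for sid, stats in proxies.proxies:
    print(f"  {sid}: r2 = {stats.r2:.3f}, D' = {stats.d_prime:.3f}")
# Expect exactly the 9 other block-1 sites at r2 = 1.0: within a block every
# site is a copy of the founder column, while block 2 was fully shuffled.

cross = cv.pairwise_ld(panel, 0, 12)
print(f"cross-block r2 (site 0 vs 12) = {cross.r2:.4f}  (shuffling removed the LD)")

# Population allele frequency from printed genotype frequencies: with EUR
# genotype frequencies C|C = 0.155, C|T = 0.485, T|T = 0.360, the C allele
# frequency is 0.155 + 0.485/2 = 0.3975, printed as 0.398.
f_c = cv.allele_freq_from_genotype_freqs(0.155, 0.485, 0.360)
print(f"f(C) from EUR genotype frequencies = {cv.round_half_up(f_c, 3)}")
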