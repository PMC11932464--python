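# cisvar

In-silico screening of cis-regulatory variants inside an associated
haplotype block.

GWAS associations rarely point at the causal base pair: the lead SNP drags
along dozens of proxies in strong linkage disequilibrium, and only a few of
them sit in regulatory DNA where an allele can change transcription-factor
binding. `cisvar` implements the desk-side half of that triage as a tested,
reusable library:

1. **LD proxies** (`cisvar.ld`) — expand a lead SNP into its haplotype block
   from phased haplotypes: r² = D²/(p_A(1−p_A)p_B(1−p_B)) with
   D = p_AB − p_A·p_B, D′ = |D|/D_max, proxy selection at a configurable r²
   cut (default 0.8), plus genotype-to-allele frequency arithmetic.
2. **Chromatin annotation** (`cisvar.annotate`) — intersect variants with
   DHS, H3K27ac/H3K4me1, TF ChIP-seq and ChromHMM tracks (0-based half-open
   BED semantics) and classify each variant's regulatory context
   (strong/weak enhancer, promoter-proximal, none) with an explicit,
   overridable rule.
3. **Allele-specific binding affinity** (`cisvar.motif`, `cisvar.screen`) —
   biophysical occupancy of a sequence for a motif: every window *i* on both
   strands contributes a Fermi-type term R₀e^(−E_i)/(1 + R₀e^(−E_i)), where
   E_i is the window's mismatch energy
   E_i = (1/λ) Σ_j ln[(n(b*_j)+pc)/(n(b_ij)+pc)] and R₀ = e^(0.584·W−5.66)
   by default. Occupancies are converted to empirical p-values against a
   seeded background null; allele pairs are summarised by
   p_combined = min(2·min(p_ref, p_alt), 1) and
   Δlog p = log₁₀ p_alt − log₁₀ p_ref (positive = reference binds more
   strongly), Benjamini–Hochberg adjusted across the screen, and checked for
   motif congruence at the SNP column. JASPAR-style relative PWM scores
   ((score − min)/(max − min), 1.0 = consensus) accompany every call.
   `spacing_analysis` finds equal-spacing (arithmetic-progression)
   arrangements among motif anchor coordinates.
4. **Assay quantification** (`cisvar.assays`) — 2^−ΔΔCt relative expression
   with replicate statistics and Welch t-tests, and firefly/renilla
   dual-luciferase normalisation.
5. **Synthetic data** (`cisvar.simulate`) — seed-deterministic generators
   for haplotype panels with block LD structure, background DNA with planted
   motifs, allelic sequence pairs with a motif-destroying SNP, and qPCR Ct
   tables with programmed fold changes — every downstream stage is testable
   with known ground truth.

File formats go through the usual libraries: phased VCF (cyvcf2), FASTA
(biopython), JASPAR/MEME motifs (Bio.motifs), BED and headed TSV tables.

## Worked example

```python
import cisvar as cv

pfm = cv.synthetic_cebpb_like_pfm()          # palindromic bZIP-like motif, ~11.7 bits
bg = cv.BackgroundModel.uniform()

# allele pair: ref carries the consensus, alt destroys the anchoring C column
seq_ref, seq_alt, snp_index = cv.make_allelic_pair(
    pfm, flank=21, snp_offset_in_motif=4, ref_is_consensus=True, seed=5)

null = cv.calibrate_null(pfm, bg, seq_len=len(seq_ref), n_null=2000, seed=17)
effect = cv.score_allele_pair(pfm, seq_ref, seq_alt, snp_index, null, snp_id="rs_demo")
print(effect.p_ref, effect.p_alt, round(effect.dlogp, 2), effect.preferred_allele)
# 0.0004997501249375312 0.08845577211394302 2.25 ref

res = cv.spacing_analysis([41_810_515, 41_811_942, 41_813_369])
print(res.progressions[0])
# Progression(start_anchor=41810515, common_difference=1427, length=3)
```

The consensus-bearing reference allele out-scores every sequence in the
2,000-draw background null (p at the 1/(n+1) floor of 5.0×10⁻⁴) while the
disrupted allele falls into the null bulk (p ≈ 0.09), a separation of ~2.2
orders of magnitude in favour of the reference allele; the motif anchor
coordinates on the enhancer form a single arithmetic progression with a
1,427 bp common difference. The scripts under `examples/` walk through each
capability (LD proxies, annotation, affinity, the full screen, assay
arithmetic) and print the numbers they compute.

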