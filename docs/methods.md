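# Methods

`cisvar` prioritises candidate cis-regulatory variants inside a haplotype
block by combining linkage-disequilibrium expansion, chromatin-context
annotation, allele-differential biophysical binding-affinity prediction and
assay arithmetic. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic-data generators do and
do not emulate.

## LD statistics and proxy selection

LD is computed from *phased* haplotypes only. With alt-allele frequencies
p_A and p_B at two sites and p_AB the joint alt-haplotype frequency:

    D  = p_AB − p_A·p_B
    r² = D² / (p_A(1−p_A) · p_B(1−p_B))
    D′ = |D| / D_max,  D_max = min(p_A(1−p_B), (1−p_A)p_B)      if D > 0
                       D_max = min(p_A·p_B, (1−p_A)(1−p_B))     if D < 0

Monomorphic sites raise `UndefinedLDError` rather than returning a silent
zero — monomorphism in a panel is a data problem, not evidence of linkage
equilibrium. Proxy selection reports all polymorphic sites within a window
(default 500 kb, covering a typical enhancer-to-gene block) with r² at or
above the threshold (default 0.8, the conventional proxy cut), ordered by
position; a monomorphic *candidate* is skipped with a warning because it
cannot be a proxy, while a monomorphic *lead* is an error. No EM estimation
from unphased genotypes is attempted; reference panels are phased, and
restricting to phased input keeps the computation exact. A multi-population
sample subset is treated as one pooled panel.

Population allele frequencies reported from genotype frequencies use
f(A) = f_AA + f_Aa/2 and are printed with decimal half-up rounding
(`round_half_up`), which also absorbs binary float noise below
10^−(digits+6) so that a decimally exact .5 boundary rounds up.

## Chromatin annotation

Tracks are held as 0-based half-open intervals; a 1-based variant position
p overlaps [s, e) iff s ≤ p−1 < e. Printed browser spans (1-based, fully
closed) are converted by `ucsc_span_to_interval`. Chromosome names are
normalised so "chr17" and "17" match. Strand is ignored: the element types
consumed here (open chromatin, histone marks, ChIP clusters, state
segmentations) are unstranded.

The classification rule is an explicit formalisation of the usual
biochemical reading — descriptive practice in the field leaves it implicit,
so it is spelled out and config-overridable:

* strong_enhancer: ChromHMM strong-enhancer state, or DHS together with at
  least one of H3K27ac/H3K4me1;
* weak_enhancer: ChromHMM weak-enhancer state, or exactly one of
  {DHS, H3K27ac, H3K4me1};
* promoter_proximal: otherwise, when a configured promoter interval
  overlaps;
* none: no qualifying overlap.

Unknown labels are ignored with a logged warning. Classification is a pure
function of the overlap label set.

## Motif model and biophysical affinity

PFMs hold per-column base counts (rows fixed A, C, G, T). The PWM uses
background-distributed pseudocounts,
p(b, j) = (n(b, j) + pc·q_b) / (N_j + pc) with pc = 0.8 by default (the
common JASPAR-ecosystem choice, kept so relative scores are comparable with
values reported by JASPAR-style scanners), and log₂ odds against the
background frequencies. Window scores are reported on the relative scale
(score − s_min)/(s_max − s_min): 1.0 is the consensus word, 0.0 the
anti-consensus. A matrix whose columns are all flat has no defined relative
score and raises `DegenerateMatrixError`. Each PWM designates an anchor
column (default: the most informative column, override per motif) whose
position inside a hit is reported as `anchor_pos` — this is the coordinate
the spacing analysis consumes.

Binding affinity follows the biophysical occupancy model: for each window i
on each strand, the mismatch energy relative to the consensus is

    E_i = (1/λ) Σ_j ln[(n(b*_j) + pc) / (n(b_ij) + pc)]

with λ = 0.7 and pc = 1.0, and the expected occupancy of a sequence is
Σ_i R₀e^(−E_i)/(1 + R₀e^(−E_i)) with ln R₀ = 0.584·W − 5.66 (W = motif
width) unless overridden. These defaults are the published parameterisation
of the occupancy model this scoring follows; all of them are exposed on
`TrapParams` because different deployments of the model have shipped
different constants. Log conventions: base-2 for log-odds, natural log
inside the energy. The energy term depends only on the counts, not on the
background model.

P-values are empirical: `calibrate_null` draws n_null background sequences
(seeded), scores their occupancies, and
p = (1 + #{null ≥ observed}) / (n_null + 1). This add-one correction makes
p-values super-uniform by at most 1/(n_null+1) and bounds them away from
zero — the smallest attainable p is 1/(n_null+1), which also bounds how far
apart two allele p-values can be pushed. The alternative — pre-fitted
extreme-value tail tables per matrix — is not reproducible from published
material, so exact p-values printed by web deployments of the model are
matched in ordering and order of magnitude, not digit-for-digit.

Backgrounds are order-0 or order-1 Markov models. The shipped default is
uniform; `BackgroundModel.promoter_like()` provides a GC-rich, CpG-depleted
order-1 preset standing in for a human-promoter background whose exact
composition is not published. Order-0 log-odds use the base frequencies;
order-1 uses the stationary vector.

## Allele-differential screen

For each motif × SNP pair (sequences must differ at exactly the SNP):

* p_ref, p_alt — empirical affinity p-values of the two allele sequences;
* p_combined = min(2·min(p_ref, p_alt), 1) — Bonferroni over the two allele
  sequences. The combination rule used by the original multiple-sequence
  web module is unpublished; Bonferroni is conservative and documented as a
  stand-in, not a claim about that tool.
* Δlog p = log₁₀ p_alt − log₁₀ p_ref, positive when the reference allele is
  the stronger predicted binder (log base 10 throughout);
* best_rel_score — the best relative PWM score among scanned windows
  overlapping the SNP on either allele;
* congruence — the SNP must fall inside the best motif window at a column
  whose top-base probability exceeds that of the *other* allele's base by a
  factor ≥ 2 (`min_pref_ratio`); the preferred allele is the one carrying
  the column's top base. This automates the manual "does the motif letter
  at the SNP actually discriminate the alleles" check.

Across the screen, p_combined values are Benjamini–Hochberg adjusted
(step-up, via statsmodels); rows are ranked by q, then |Δlog p| descending,
then factor id (deterministic ties). A row is flagged significant when
q < `q_threshold` (default 0.05) *and* its best relative score reaches
`min_rel_score` (default 0.8 — no motif over the SNP, no call); an optional
fixed raw-p pre-filter (e.g. the exploratory 5×10⁻⁶ cut used in screening
practice) can be applied on top. Null distributions are calibrated once per
(motif, sequence length) and reused.

`spacing_analysis` reports all pairwise gaps between anchor coordinates and
every maximal arithmetic progression of length ≥ 3, with per-step deviation
from the progression's first gap bounded by `tolerance_bp` (default 0,
i.e. exact spacing); unsorted input is sorted with a warning. Maximality is
enforced by refusing starts that extend backwards; results agree with
exhaustive 3-subset enumeration (tested).

## Assay arithmetic

`ddct_fold_change` implements the classical 2^−ΔΔCt model with
amplification efficiency fixed at 2 (efficiency-corrected variants are out
of scope): per condition ΔCt = Ct(target) − Ct(reference), computed
per-replicate when replicate indices align between the two genes and as a
condition-mean fallback otherwise (logged); ΔΔCt = ΔCt(treated) −
ΔCt(control); fold change = 2^−ΔΔCt. The p-value is a two-sided t-test on
the per-replicate ΔCt values, Welch by default (the unequal-variance choice
is the safer default when the plain "t-test" is unspecified; switchable via
`equal_var`). With a single replicate in either condition — or a fully
degenerate (zero-variance) table, where a t-test is meaningless — the fold
change is returned without a p-value. The estimator is exactly invariant to
adding a constant to all Ct values, and fold changes are exactly
reciprocal under swapping the conditions.

`reporter_normalize` divides firefly by renilla per record and expresses
per-construct mean ratios relative to a control construct (which therefore
maps to 1.0). Zero renilla is rejected.

## Synthetic data: what it emulates, what it does not

The generators define the conditions the test-suite and acceptance runs are
performed under. All are deterministic given their seed, and all sequences
are uppercase A/C/G/T (no N handling is needed downstream).

* **Haplotype panels** copy a founder column (allele frequency uniform in
  `maf_range`, resampled until polymorphic) across each block, then permute
  a fraction of haplotype rows independently per block. This produces exact
  within-block r² = 1 and, at full shuffle, independent blocks — sufficient
  because the screen consumes only r². It does **not** model coalescent
  genealogies, recombination gradients, mutation or population structure;
  real blocks have noisy internal r² and decaying edges.
* **Motif plants** write the consensus word (column argmax; ties broken by
  the fixed base order A<C<G<T for reproducibility) verbatim at
  non-overlapping positions, reverse-complemented on the minus strand.
  Real binding sites are rarely perfect-consensus; recovery rates measured
  on plants are upper bounds for degenerate real sites.
* **Allelic pairs** flank the consensus with 21 bp of background on each
  side — the probe geometry conventional for allele-specific binding-assay
  oligos — and set one motif column to its minimum-count base. A column
  with all-equal counts is refused ("non-informative column").
* **Ct tables** shift the treated-condition target mean by
  −log₂(fold change) cycles, leave the reference gene untouched, and add
  per-well Gaussian noise (the standard desk-scale qPCR error model;
  default 0.3 cycles, triplicates). Pipetting outliers, plate effects and
  efficiency drift are not modelled.

The shipped demonstration motifs are synthetic. `synthetic_cebpb_like_pfm`
(width 10, ~11.7 bits, consensus ATTGCGCAAT) mimics a bZIP dimer site: the
consensus is reverse-complement palindromic and the central C/G contact is
near-invariant while flanking columns are moderately sharp. Both central
columns must be sharp — with only one, the palindrome's minus-strand
reading would rescue a disrupted anchor. This concentration of information
at the anchor is what lets a single SNP drop the motif's occupancy into the
background null; passing tests therefore demonstrate the screen's behaviour
for factors whose binding hinges on a critical contact, not for motifs with
evenly spread information, where a single SNP moves the affinity much less.

## Problem sizes and numerical choices

Defaults used by the test-suite and the acceptance script: nulls of
n = 2,000 sequences (p-value floor 1/2001 ≈ 5×10⁻⁴), 52 bp allele
sequences (21 + 10 + 21), screens of 3 motifs × 4 SNPs, 20 seeded
end-to-end recovery runs and 100 null-screen runs, 200-seed Monte-Carlo for
ΔΔCt recovery. These sizes give stable Monte-Carlo estimates at desk scale;
all of them are arguments, not constants. Thresholds frozen after one
calibration pass (and not revisited): destroying-SNP Δlog p over the fixed
20-seed set has min 1.5/median 2.7; background-SNP |Δlog p| has median
≈ 4×10⁻⁴ with occasional excursions to ≈ 1.0 when a chance partial motif
match moves through a sparse null region — the frozen bounds are min ≥ 1 /
median ≥ 2 and median < 0.1 / max < 1.5 respectively. The noisy ΔΔCt
median-recovery interval is [20, 31] at fc = 25, noise 0.3, n = 3.

Degenerate inputs are errors, not silent defaults: monomorphic LD, all-flat
matrices, non-ACGT sequences, overlapping plants, zero renilla, Ct tables
with missing condition × gene cells, p-values outside (0, 1].

## Known limitations

* Empirical nulls bound attainable p-values at 1/(n_null+1); screens needing
  smaller p-values need larger nulls (cost is linear).
* The Bonferroni two-allele combination is conservative; a Fisher or
  min-p permutation combination would be sharper but less transparent.
* The annotation rule is a formalisation; real enhancer calls weigh signal
  strength and cell-type provenance, which BED labels alone do not carry.
* LD from phased panels only; no unphased-genotype EM, no multi-allelic
  sites.
* Scanning handles A/C/G/T only and zeroth/first-order backgrounds;
  dinucleotide-weight motif models and motif discovery are out of scope.
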