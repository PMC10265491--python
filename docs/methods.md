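# Methods

`genefam` reimplements, as one tested library, the standard desk-analysis
battery applied to a plant gene family after genome-wide identification:
who the members are, how they duplicated and when, what regulatory signals
sit around them, and how they are expressed. The watermelon HSP70 family is
the motivating use case; every stage is generic over family and genome.
This note records the models, the defaults and why, and what the synthetic
benchmark does and does not demonstrate.

## Coordinate and sequence conventions

All genomic coordinates are 1-based inclusive, as printed in GFF3: a gene
at `start..end` spans `end − start + 1` bases, and an intronless gene's
span equals its CDS length. IUPAC ambiguity codes pass through I/O
unchanged but count as mismatches in every downstream scoring step —
explicit failure or a conservative mismatch beats a silently imputed base.

## Family identification (profile scan)

The seed domain alignment is compiled into a position-specific score
matrix: columns with >50% gaps are dropped, and the column score for amino
acid *a* is `log2((count_a + κ·bg_a) / (n + κ) / bg_a)` with pseudocount
κ = 1 and a uniform background. Each candidate protein is scored by its
best ungapped window. Significance is empirical: `n_decoys` (default
1,000) decoy proteins are sampled with the query proteome's residue
composition and length distribution, and

    E(s) = (1 + #decoys ≥ s) / n_decoys × proteome size.

The default retention rule keeps a protein only when *no* decoy reaches
its score, i.e. E ≤ proteome_size/n_decoys — the desk-scale analogue of a
stringent homology-search E-value threshold. Decoys match the proteome
composition (not the uniform scoring background) so that composition bias
alone cannot pass the filter; this is what makes shuffled family members
fail the scan. Ungapped scanning is deliberate: it keeps the exhaustive
window-maximum oracle exact. A full profile HMM with insert/delete states
is out of scope.

## Physicochemistry and naming

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da), reported in kDa at 2 decimals. The isoelectric point solves
the Henderson–Hasselbalch net charge for zero by bisection on pH ∈ [0, 14]
to |charge| < 1e−4; the pK set is Bjellqvist's (the ProtParam convention),
swappable via the module constants. The charge is strictly decreasing in
pH, so bisection always converges. GRAVY is the mean Kyte–Doolittle index.
Ambiguous residues (B/Z/X) are rejected rather than averaged. Families are
named `<prefix>-1..n` by ascending molecular weight, ties broken by
(chromosome, start) so naming is a deterministic permutation.

## Duplicate pairs, Ka/Ks and dating

A pair of family CDS is a duplicate when a global nucleotide alignment
(match +2, mismatch −1, gap open −4, gap extend −1) covers >70% of the
longer sequence and shows >70% identity over columns where both sequences
have residues — identity, not similarity groups, because the criterion
speaks of the gene sequence. Classification: tandem iff same chromosome,
≤5 intervening genes (counted over *all* annotated genes via chromosome
rank) and ≤100 kb start-to-start; otherwise segmental. The 100 kb anchor
is start-to-start because no anchor is standard.

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions averaged over both sequences; codons differing at k positions
averaged over all k! substitution orders, excluding orders that pass
through a stop codon (all orders are used if every one is blocked);
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3), with p ≥ 3/4 reported as
a saturated, undated pair rather than a number. A mutation that would
create a stop counts as nonsynonymous, so each codon contributes exactly
3 sites and N + S = 3 × codons — the invariant the tests check. For NG86
the pair is codon-aligned by aligning the translations (BLOSUM62) and
mapping residue columns back to codons; any codon opposite a gap is
dropped whole, keeping site counts integral.

Dates come from the molecular clock T = Ks/(2λ) × 10⁻⁶ Mya with
λ = 6.1 × 10⁻⁹ synonymous substitutions per site per year, a standard
rate for cucurbit lineages. NG86 was chosen over ML codon models
because it is the method behind the "simple" Ka/Ks calculators used in
gene-family surveys, and because it admits an exact brute-force oracle.

## SSR mining

Perfect di-/tri-/tetranucleotide repeats with minimum repeat counts
6/5/5, over the gene body plus 2 kb of flank each side, strand-oriented.
Detection reports leftmost-maximal runs; units that are themselves
periodic (e.g. ATAT) are suppressed in favour of the shorter class, and
mononucleotide runs are not searched. Overlaps resolve longest-first,
then leftmost, then shortest unit. Motifs are reported as found (a
`canonical_motif` helper exists for statistics but is off by default,
matching MISA's output style). Consecutive SSRs ≤100 bp apart merge into
a compound SSR (MISA's documented default). An SSR straddling a region
boundary belongs to the region containing its start. Statistics report
two denominators — occurrences and distinct motif types — because
published summaries percentage over types.

## Promoter cis-elements

Promoters are the 2,000 bp immediately 5′ of the start codon,
strand-oriented and truncated (with a warning) at chromosome edges. The
packaged dictionary is a curated ~20-entry table of IUPAC consensus
motifs with category (hormone/stress/development) and response labels,
covering the element families commonly reported for stress-responsive
plant genes (ABRE, CGTCA/TGACG, TCA-element, P-box/GARE/TATC, ARE, MBS,
LTR, TC-rich repeats, CAT-box, O2-site, circadian, …). It is a compact,
user-extensible stand-in for a full database whose matrices are not
redistributable; absolute element counts on real genomes are therefore
not a supported comparison — planted-truth recovery is. No heat-shock
element ships by default (none was found in the motivating family's
promoters), but the TSV format accepts one. Both strands are scanned and
overlapping hits are all reported.

## Expression

2^−ΔΔCT with one or two reference genes: the reference signal is the
arithmetic mean of the reference Cts (equivalent to the geometric mean of
linear quantities — the combination rule is otherwise unspecified in
practice); ΔΔCt subtracts the calibrator sample, so the calibrator is
exactly 1 by construction. Significance is an equal-variance two-tailed
t-test on replicate-level ΔCt values (not on RQ, where normality is
implausible), flagged `*`/`**` at 0.05/0.01; a degenerate zero-variance
equal-means comparison reports p = 1. RNA-seq matrices are displayed as
log2(FPKM) hard-clipped to display bounds (defaults −4..10), with
FPKM = 0 mapped to the floor instead of −∞. The clip is monotone, and
back-transforming (2^value) and re-applying reproduces the matrix.

## Phylogeny and subfamilies

p-distances over a supplied protein MSA (computing the MSA is out of
scope) feed a neighbor-joining agglomeration with the Saitou–Nei
Q-criterion. Ties in Q break by the smallest taxon label in each cluster;
a negative branch length is floored at zero with the deficit moved to its
sister, preserving path lengths. NJ is consistent on additive matrices —
the tests verify exact recovery of 100 random additive trees. For
subfamily assignment the unrooted NJ output is midpoint-rooted first
(otherwise a subfamily straddling the arbitrary trifurcation dissolves
into the root); each query then takes the majority label of the
references in its smallest reference-containing clade, ties and
reference-free lineages staying unassigned. Bootstrap support by column
resampling is available (`bootstrap_splits`) but off by default.
Maximum-likelihood inference is out of scope.

## miRNA target scoring

Each transcript window of miRNA length is paired antiparallel (miRNA
5′→3′ vs target 3′→5′) and scored: Watson–Crick 0, G:U wobble 0.5,
mismatch 1.0, penalties doubled at miRNA positions 2–13, summed into an
*expectation*; sites ≤ cutoff (default 5.0) are reported many-to-many.
This is the default convention of the widely used plant target
predictors, made explicit and configurable. Ungapped mode is the default
so the all-window enumeration oracle is exact. Diagrams render the
canonical three-line dot format (`:` pair, `.` wobble, blank mismatch).

## The synthetic benchmark (what it shows and what it does not)

`synthetic_data.forge_genome` builds a genome in which every downstream
call has a known answer: family members embed a seed domain (planted at
~88% identity, well above the 60% contract); background genes are sampled
from a smoothed order-3 Markov model fitted to the seed consensus, so
decoys share its composition but not its order; duplicate pairs are
created by `mutate_codons`, which applies single-nucleotide substitutions
(never creating stops) until NG86 counting against the original hits the
target (pS, pN) within ±0.01; SSRs, cis-elements and miRNA sites are
planted at recorded positions with guard bases so a planted repeat cannot
silently extend into background. Free members are rejection-sampled so no
unplanted pair passes the 70/70 rule: the planted pair list is the
complete duplicate truth. Genic SSRs are placed inside a generated intron
so the reading frame is untouched.

Default conditions mirror a typical family-characterization study at
desk scale: 12 family
members; one tandem event with 2 intervening genes and a 37 kb
start-to-start gap (a realistic tandem-pair spacing) plus two
segmental events on different chromosomes; event (pS, pN) targets
back-computed via the Jukes–Cantor inversion from Ks/Ka values typical
of ancient plant duplicates
(pS 0.695/0.649/0.660, pN 0.0375/0.0355/0.0310 — giving Ks ≈ 1.4–2.0 and
Ka/Ks ≪ 1, i.e. purifying selection); qPCR with 3 biological replicates
and 0.2-cycle noise; FPKM with log-normal dispersion 0.2. The genome is
6 chromosomes × 400 kb with 48 background genes — large enough for every
placement constraint, small enough that the full suite runs in about a
minute.

What passing these tests shows: the algorithms implement their contracts
exactly (oracle equivalence), and the pipeline is internally consistent
end to end. What it does not show: performance on real genomes — the
forge has no indels, no alternative splicing, no repeat-rich intergenic
background, no GC heterogeneity, uniform codon usage, and its decoy genes
are far more benign than a real proteome's partial-domain paralogs.
Published absolute counts that depend on proprietary databases or on the
real genome (the 12-member identification itself, per-promoter element
totals, the 66-SSR census, miRNA/target counts) are treated as
non-reproducible and replaced by planted-truth recovery.

## Numerical choices and degenerate inputs

- pI bisection: 200 iterations max, |charge| < 1e−4 stop; charge strict
  monotonicity guarantees convergence.
- NG86 saturation (p ≥ 3/4) raises and the pair is reported undated, not
  silently clamped.
- `mutate_codons` bounds its attempts (400 per codon + 4,000) and raises
  on unreachable targets, e.g. any pS > 0 on a sequence with no
  synonymous degrees of freedom (a lone ATG).
- Empty SSR/hit sets produce zero-filled tables with all labels present.
- Zero-variance t-tests: p = 1 for equal means, p = 0 otherwise.
- All stochastic components take an explicit seed; fixed seeds give
  byte-identical forged files.

## Problem sizes used by the test suite

Oracle comparisons run at the sizes where the oracles are exact: NG86 vs
path enumeration on ≤10-codon pairs (≤3 differences), alignment vs affine
DP on ≤20-nt pairs, SSR detector vs regex scan on 50 × 10 kb fuzzed
sequences, NJ vs 100 random additive matrices of ≤12 taxa, ΔΔCT type-I
calibration over 1,000 simulated experiments, pI over 1,000 random
proteins. Pipeline-level checks run on the default forged genome.
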