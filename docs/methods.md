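# Methods

This note documents the models, parameter choices and numerical decisions
behind `nudimine`, and what the synthetic validation does and does not show
about real data.

## Problem setting

Large circular dsDNA viruses of arthropods (nudiviruses and relatives) have
genomes of roughly 97–232 kb encoding ~93–154 proteins, including a
conserved core gene set shared with baculoviruses (dnapol, the lef genes,
p47, vlf-1, p74, the pif genes, 38k, vp91, ...). When an infected insect
population is shotgun-sequenced, viral reads co-assemble with the host and
the viral genome surfaces as a handful of contigs. The pipeline recovers
those contigs by translated protein homology, annotates them, reconstructs
the circular fragment order, and places the virus phylogenetically.

## Search engine and E-values

The aligner is affine-gap Smith–Waterman under BLOSUM62 (gap open 11,
extend 1, NCBI convention: a gap of length g costs open + g·extend),
executed through Bio.Align.PairwiseAligner. Characters outside the 20
standard amino acids are remapped to X, which scores 0 against everything.

The search is word-seeded: a subject is examined only if it shares at least
one exact 4-mer with the query. Instead of the classical per-seed x-drop
extension, every seeded subject is screened with an exact computation of
its best *ungapped* diagonal segment score (a Kadane recurrence run down
all diagonals simultaneously, vectorized); subjects whose best ungapped
segment falls below the score whose ungapped E-value is 1000× looser than
the final cutoff cannot plausibly produce a passing hit and are skipped.
Survivors get the full gapped alignment. This filter is deterministic,
strictly more sensitive than heuristic x-drop extension, and exact for the
substitution-only divergence model of the synthetic data (where optimal
alignments are ungapped).

E-values use E = K·m·n·exp(−λS) with m the query length and n the total
database residues. The constants are deliberately conservative: λ = 0.20,
K = 0.10. The ungapped BLOSUM62 constants (λ = 0.3176, K = 0.134) are
calibrated for ungapped alignments between standard-composition proteins;
applied to gapped scores of six-frame translations of AT-rich DNA — whose
biased amino-acid composition inflates chance similarity — they understate
E and let random alignments through the 10⁻³ screen. Setting λ below the
standard gapped value (0.267 for 11/1 gaps) absorbs both effects. The
cost is reduced sensitivity only for very short, very diverged proteins
(< ~70 aa below ~40% identity), far outside the regime the screen targets;
the benefit is a high-precision screen: across seeded synthetic studies,
zero host contigs pass at E ≤ 10⁻³ while every gene-bearing viral fragment
is recovered at the 40% divergence working point.

Thresholds follow the published protocol: E ≤ 10⁻³ for the viral screen and
annotation, E ≤ 10⁻⁴ for inter-proteome homolog counting. Homolog counts
are one-directional ordered-pair counts (protein of genome i with ≥ 1 hit
in genome j); reciprocality is not required, and group means exclude the
diagonal.

## ORF calling

ORFs are predicted in all six frames under the standard genetic code.
A complete ORF runs from the first in-frame ATG after the previous stop to
a stop codon; contig edges waive the missing start (5′ partial) or stop
(3′ partial). The length filter (default ≥ 50 aa) applies to the translated
protein excluding the stop, including the initial methionine. "Limited
overlap" is implemented as greedy longest-first retention with a 60 nt
(≈ 20 codon) pairwise overlap ceiling — a common tolerance for nested or
slightly overlapping viral genes — with ties broken by leftmost start, then
'+' strand. Ambiguous bases translate to X and never act as stops. Names
follow linear order within each fragment (`PREFIX_F3_ORF12`).

## Redundancy merging

Candidate contigs are depleted with a greedy overlap-layout merger rather
than a full assembler: exact 16-mer anchors vote on a relative offset
between two contigs (both orientations), the implied overlap is verified
base-by-base, and overlaps of ≥ 40 bp at ≥ 95% identity are merged longest
first, the longer contig's base winning at disagreements. Contained contigs
are absorbed. The output is idempotent (no qualifying overlap remains) and
anchored overlaps that fail identity verification are reported rather than
merged.

## Scaffolding by split genes and synteny

Fragment orientation is resolved first: a fragment is flipped when the
majority of its reference-mapped ORFs run opposite to their reference
genes. Split-gene links — the last ORF of one fragment and the first of
another hitting the same reference gene with complementary missing ends —
are hard constraints; a gene terminal on three or more fragments is
ambiguous and reported unresolved. Because a truncated gene can present an
internal ATG and look structurally complete, partiality is also inferred
from the alignment: if the hit leaves more than max(15 aa, 15%) of the
reference protein uncovered at one end, that end is considered missing.

Remaining junctions are scored by synteny: score(A→B) = N − gap, with N the
reference gene count and gap the smallest forward circular distance from
the reference index of A's last two mapped ORFs to B's first two (terminal
ORFs only, mirroring how a curator reasons from fragment ends). Junctions
are selected greedily by descending score subject to in/out degree 1 and a
single Hamiltonian cycle; ties break lexicographically. Layouts are
canonicalized up to rotation and reflection, and layout comparison also
treats a global orientation flip as equal — a circular dsDNA reconstruction
has no intrinsic forward strand. Genomic rearrangements relative to the
reference are not modelled: they degrade synteny scores gracefully but the
method assumes conserved gene order, and the recovery guarantees below are
conditional on that assumption.

## Coverage and composition summaries

Read mapping is substitution-only (default ≤ 2 mismatches; the underlying
protocol's mapper is unspecified, and 100-nt single-end reads rarely need
indels), using pigeonhole seeding — a read with ≤ k mismatches contains an
exact segment of length ⌊L/(k+1)⌋ — and deterministic tie-breaking (lowest
fragment id, leftmost position, '+' strand). Coverage arithmetic matches
the published table's conventions exactly: bases mapped = reads × read
length (100 nt default; terminal partial alignments are not pro-rated),
fold coverage rounded half-up to 1 decimal, GC% to 2 decimals over
unambiguous bases only, and *unweighted* means across fragments (1 decimal
for coverage, 3 for GC) — the printed means are consistent only with
unweighted averaging. N50 is the largest L such that contigs ≥ L hold at
least half the total bases.

## Phylogeny

Per-gene protein alignments are progressive: single-linkage guide order on
3-mer Jaccard distances, profile-profile global DP under BLOSUM62 with a
linear gap penalty of −8 (affine gaps add little for the within-gene
divergences involved and linear gaps keep the profile DP exactly
vectorizable). Genes are concatenated into a supermatrix; taxa missing a
gene are all-gap in that partition — standard practice when endogenous
viral elements retain only a core-gene subset. Distances are corrected
p-distances, d = −ln(1 − p − 0.2 p²) (scoredist-style), computed over
columns where both taxa are non-gap and capped at 10; the correction is
within ~10% of the true expected substitution load for d ≲ 0.5. Trees are
neighbor-joining with lexicographic tie-breaking and negative branch
lengths clamped to zero; bootstrap resamples columns with replacement and
reports the percentage of replicates containing each original bipartition.
Full maximum-likelihood inference (JTT/WAG) is intentionally out of scope:
the claim this stage carries is clade-structure recovery — which lineages
group together and with what support — which NJ on corrected distances
delivers at desk scale, as the additive-matrix and two-clade recovery tests
verify.

## Synthetic data model

The generator emulates the discovery scenario end to end with analytic
ground truth:

* **Reference virus** — default 100 genes on a 130 kb circle, 20% core,
  GC 0.28 (the AT-rich end of the family's range, where composition bias
  stresses the search statistics most). Coding sequences are built
  codon-by-codon from bases drawn i.i.d. at the target GC with stop codons
  rejected, so base *and* amino-acid composition follow the target
  naturally; gene lengths are lognormal (median ≈ 260 aa, clipped to
  60–1400), strands random, protein lengths and intergenic gaps sized to
  tile the circle exactly.
* **Novel virus** — i.i.d. residue substitution at the target divergence
  (default 0.4, matching the ~40–60% identity regime in which related
  nudiviruses are found), uniform over the 19 alternatives, start
  methionine preserved; uniform synonymous back-translation; no indels, so
  truth identities are analytic. Lost genes (default rate 0.05) are
  replaced by background sequence and recorded.
* **Fragmentation** — fragments tile the circle separated by gaps
  (uniform in [min_gap, 3·min_gap]); each fragment is independently
  reverse-complemented with probability 0.5, exercising the scaffolder's
  orientation logic. Truth tables record layout, orientations and which
  gene pieces are edge-truncated.
* **Reads** — round(coverage × length / read length) single-end reads per
  fragment, uniform positions and strands, substitution errors at 0.002
  (HiSeq-like substitution-dominated error), qualities Phred 40 with
  errors at Phred 10 so end-trimming is exercised without a full quality
  model. Default coverage 18.5×, read length 100 nt — the depth regime of
  the motivating assembly.
* **Host background** — random contigs at GC 0.33 with no planted viral
  genes (the screen-specificity fixture).

What passing tests on this generator do **not** show: robustness to indels
and frameshifts, repeat-induced misassembly, chimeric contigs, realistic
Illumina error/quality profiles, composition heterogeneity along real
genomes, or genomic rearrangements between virus and reference. The
generator's truth is exact precisely because its evolution model is
simple; results on real data depend on how far those assumptions hold.

## Validation problem sizes

The test suite and acceptance script run at sizes chosen to exercise every
code path at full fidelity while staying desk-scale: oracle comparisons on
50 random 2-kb contigs (ORF calling) and 50-protein databases (search);
layout recovery over 50–100 fragmentations of a 100-gene, 130-kb genome;
screen sensitivity/specificity over 10–20 seeded studies of a 15-gene,
20-kb virus against 20 host contigs each; an 8-gene, 9-taxon two-clade
supermatrix with 100 bootstrap replicates. The published-assembly
arithmetic (coverage table, GC means, fold reduction, fragment order) is
recomputed from the packaged input tables at its original size.

## Known limitations

* Substitution-only alignment statistics: the conservative E-value
  constants are a design point, not a calibration; absolute E-values should
  not be compared with other tools'.
* The six-frame screen does not join HSPs across frameshifts; a contig is
  flagged by its best single-frame evidence.
* The scaffolder assumes conserved gene order and emits "synteny" evidence
  labels so that downstream users can distinguish hard (split-gene) from
  soft (synteny) junctions.
* The merger is a redundancy depleter, not an assembler: no quality-aware
  consensus, no repeat resolution.
* Adapter trimming is not implemented (no adapter sequences are assumed);
  quality trimming is end-trimming only.
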