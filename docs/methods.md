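# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the simulator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structural detection

Detection is a seeded self-comparison of each contig ≥ 10 kb (shorter
contigs are skipped with a warning — full-length elements plus flanks
rarely fit in less). Exact k-mer matches (k = 13) between positions
spaced compatibly with the element-length bounds are grouped by
diagonal (tolerance ± 20 nt, chain gap ≤ 300 nt) and each chain is
verified and extended by local alignment (match +2, mismatch −3, gap
open −8, extend −1) between the two repeat neighbourhoods. A candidate
survives if both repeats are 100–3,500 nt, the span is 1–16 kb, and the
repeat identity is ≥ 0.80. Candidates whose 5′ *and* 3′ repeats both
overlap a better candidate are suppressed; candidates overlapping in
only one repeat are kept separately, so two-element loci and tandem
arrangements are reported individually.

Defaults (LTR 100–3,500 nt, element 1–16 kb, identity ≥ 0.80, k = 13)
bracket the LTR and element lengths typical of plant Copia/Gypsy
elements (LTR means ≈ 540–650 nt; elements ≈ 5.6–7.6 kb); the upstream
tools this stage replaces publish no parameter set, so exact element
counts on real data are parameter-sensitive. All values are
configurable.

**Boundary refinement.** The repeat neighbourhoods are re-aligned by
Smith–Waterman, then the termini are snapped onto TG (start) / CA (end)
dinucleotides within ± 25 nt. A snap target must satisfy three
conditions: the motif is present at a compatible offset in *both* LTRs
(offsets may differ by ≤ 6 nt to absorb alignment wobble); the 6 nt just
*outside* the proposed terminus differ between the two loci (≥ 1
mismatch — at a true terminus the flank and the internal region are
unrelated, whereas inside an identical repeat they match, which is what
a spurious internal TG/CA pair would look like); and the 6 nt just
*inside* match (≤ 2 mismatches). Refinement never discards a candidate;
it only adjusts coordinates and records `has_tg_ca`.

**Features.** TSD: longest exact 4–6-mer shared by the immediate
flanks, ties broken toward the longest then the element-proximal copy.
PBS: a 15–18-mer within 30 nt downstream of the 5′ LTR matching the
reverse complement of a bundled tRNA 3′-end oligo with ≤ 2 mismatches
(best = fewest mismatches, then closest to the LTR, then longest). PPT:
the highest-purine 20–25-nt window within 40 nt upstream of the 3′ LTR,
requiring A+G fraction ≥ 0.80. Elements missing ≥ 2 of {TG...CA, TSD,
PBS, PPT} are dropped; the analysed element class is defined by intact
ends, and one missing feature is tolerated. If the forward orientation
of a candidate misses too many features, the mirrored candidate on the
reverse complement is evaluated and reported on the minus strand when it
scores better.

The bundled tRNA oligo set (`data/trna_oligos_synthetic.fasta`) is a
synthetic stand-in (random 18-mers ending in CCA) for a curated plant
tRNA library and is user-replaceable; on real data a genuine tRNA set
should be supplied.

## Superfamily classification

The internal region is translated in six frames and searched with local
alignment (BLOSUM62, gap open 11 / extend 1) against a bundled protein
library whose record ids begin with the domain label
(GAG/PR/INT/RT/RH/CHD). Hits below a raw score of 55 are discarded —
a deterministic replacement for database E-values; random ~1,000-aa
translations against this library score well below it (asserted in the
tests). Overlapping same-label hits keep the best score.

Order is read along the coding strand (a score-weighted majority of hit
frame signs), making calls strand-invariant. INT upstream of RT ⇒
Copia; INT downstream of RH (or RT if no RH) ⇒ Gypsy; CHD downstream of
INT on a Gypsy ⇒ chromodomain subgroup. With no RT *and* no INT hit the
element is Unknown. An element with exactly one of the two anchors is
also reported Unknown (with a warning): the defining character of the
superfamilies is the relative order, and a single anchor cannot exhibit
it. Unknowns are reclassified by nucleotide similarity to classified
elements when a local alignment spans ≥ 400 nt at ≥ 0.80 identity.

The bundled domain library is likewise a synthetic stand-in
(`data/domain_proteins_synthetic.fasta`, random sequences of plausible
lengths); the simulator back-translates the same proteins, which keeps
the planted-ORF search realistic in structure, but per-element calls on
real genomic data require a genuine curated library.

## Insertion dating

LTR pairs are aligned globally (match +2, mismatch −1, gap open −10,
extend −0.5) and *every* column containing a gap is removed (complete
deletion) before computing p = mismatches / remaining columns. The
Jukes–Cantor correction K = −(3/4)·ln(1 − (4/3)·p) is applied; p ≥ 0.75
is a saturation error, never silently clamped.

**Nei–Gojobori (1986) Ks.** Per codon, each position contributes
(number of synonymous single-base changes)/3 synonymous sites; changes
to stop codons are never synonymous, so they fall on the nonsynonymous
side — this is the original site definition and keeps S + N = 3 per
codon. Differences in multi-hit codons are averaged over all orderings
of the single changes, excluding pathways that pass through a stop codon
(all orderings are used only if every one does). Ks applies the
Jukes–Cantor correction to ps = Sd/S, with S averaged over the two
sequences. The implementation is cross-checked in the tests against an
independent enumeration oracle and against Biopython's NG86 (the latter
on single-difference codons only, since Biopython averages
stop-traversing pathways instead of excluding them).

**Calibration.** r_syn = mean(per-gene Ks) / T with T = 42.5 MY by
default (the midpoint of the 40–45 MY divergence of the two Oleaceae
lineages used for calibration), and r_ltr = 2·r_syn, LTRs evolving at
about twice the synonymous rate of genes. Rates are reported to 2
significant figures, ages to 0.01 MY.

**Age convention.** Default age = K / r_ltr. The published
zero-divergence upper bounds for this analysis (0.387 and 1.760 MY)
imply aligned LTR lengths of ≈ 718 and ≈ 158 nt under K / r_ltr but an
implausible ≈ 79 nt under K / (2·r_ltr), so K / r_ltr is the default;
the alternative convention remains available (`age_convention =
K_over_2r`) and every age table records which was used. For K = 0 the
age is 0 and the upper bound jc(1/aligned_length) / denominator is
reported.

## Read mapping and solo-LTR screening

Reads are truncated to 75 nt (prefix kept) for constant length. The
mapper is an exact-k-mer-seeded (k = 15), ungapped extender: a read is
assigned if its best placement covers ≥ 0.9 of the read at ≥ 0.9
identity; placements clipped at reference edges count only the
overlapping part. Both orientations are tried; ties among best-scoring
placements across references are broken uniformly at random from the
seeded per-stage stream, so identical seeds give identical assignments.
Reads with no seed hit anywhere fall back to an exhaustive diagonal
scan, which makes the mapper provably equivalent to the all-positions
oracle used in the tests. Substitution errors only — the simulator
plants no indels in reads, and the ungapped extender mirrors that.

**Solo-LTR ratio.** Each element is mapped as two references — the 5′
LTR and the inter-LTR region, the 3′ LTR excluded. Reads from both LTRs
of every intact genomic copy then land on the single reference LTR, so
an intact-only family has expected ratio 2, and S solo-LTRs per N
intact copies raise it to (2N+S)/N. Per-partition reads/kb in *this
statistic* are normalized by the effective number of admissible read
start positions, L − 2·⌈0.9·75⌉ + 75 + 1 = L − 60, rather than raw
length: a read must have ≥ 68 of its 75 bases inside a partition to be
accepted, so raw-length normalization deflates short partitions (the
LTR) more than long ones and biases the ratio low by ~5–10 % at typical
LTR lengths; the effective-length correction makes the estimator
unbiased (verified against the closed form in the acceptance tests).
The global redundancy table keeps the conventional reads/kb over raw
reference length. Ratios > 2.5 flag solo-LTR-rich families; an
inter-LTR partition with zero reads yields an `inf` sentinel, never a
silent drop.

## Phylogeny

RT regions from classified elements are translated and kept if ≥ 80 aa.
Distances are p-distances over the gap-free columns of pairwise global
alignments (BLOSUM62) — a deliberate simplification of a multiple
alignment that is deterministic and sufficient for NJ input; the
`protein_distances` step is the plug-in point for a real MSA. NJ is the
standard Saitou–Nei agglomeration with the Q-criterion; ties break
toward the lexicographically smallest label pair, negative branch-length
estimates are clamped to 0, and the last three nodes join at an unrooted
trifurcation. NJ provably reproduces any additive matrix exactly; the
tests verify this against an exhaustive-topology least-squares oracle up
to 6 taxa and against an independent NJ implementation on non-additive
matrices.

Bootstrap supports resample columns of an anchor-projected
pseudo-alignment (every sequence aligned to the longest one; insertions
relative to the anchor are ignored). Family delimitation — published
family boundaries for this kind of analysis are visual/bootstrap-based
with no numeric rule — is implemented as single-linkage clusters at
distance ≤ 0.25 (configurable).

## Reporting

Group statistics are mean ± SE (SE = sd/√n, ddof = 1; n = 1 groups
report SE = 0, n = 0 groups report blanks). Percentages are exact
divisions to 2 decimals; where a published tabulation is internally
inconsistent with exact division the exact value is reported, not the
published rounding. `genome_equivalents` truncates (floors) to one
decimal — the only convention consistent with the published value of
the worked BAC-library example (quotient 3.377 printed as 3.3). Age
histograms use half-open 1-MY bins by default. The age-vs-redundancy
table reports Spearman rank correlation, with 0 and a warning when
either variable is constant.

## Simulator

The simulator is the package's stated world: element templates with
TG...CA termini, a TSD duplicated from the insertion site (4–6 nt), a
PBS placed 1 nt after the 5′ LTR (reverse complement of a bundled tRNA
oligo), a 22-nt purine PPT directly upstream of the 3′ LTR, and a
single-frame internal ORF back-translated (most-frequent plant codons)
from the bundled domain proteins in the superfamily's canonical order.
Solo-LTRs are a single LTR between one TSD pair — the recombination
signature. Insertions are uniform without overlap (optionally with a
minimum spacing); each intact copy's LTR pair is aged independently
under JC69 at per-LTR rate μ = r_ltr/2 (so the expected between-LTR
distance is r_ltr·age under the default dating convention; μ = r_ltr
under `K_over_2r`). Reads have uniform starts on both strands with
i.i.d. substitution errors. Ortholog pairs mutate synonymous positions
with probability ps·f (f = the position's synonymous fraction), making
E[Sd]/S equal the target ps under NG86 counting.

What the simulator does **not** emulate: nested insertions (off by
default — the sampled element class in this kind of BAC-based survey
under-represents them), tandem-repeat landscapes, indel mutation in
LTRs (optionality reserved), quality-score error profiles, paired-end
structure, and inter-family sharing of internal regions. A green test
therefore establishes correctness of the algorithms under the stated
model, not performance on the full complexity of real genomic data.

## Known limitations

- The bundled tRNA and protein-domain FASTA files are synthetic
  stand-ins; real analyses should replace them.
- The detector does not resolve nested elements; outer and inner
  candidates at one locus are both reported.
- Old elements can lose their true TG...CA termini to mutation; a
  nearby spurious dinucleotide pair inside the snap window can then
  shift a boundary by up to ~25 nt (observed rarely in the aged
  simulations; clean simulations recover boundaries within 5 nt).
- The mapper is ungapped; indel-rich reads would be under-mapped.
- Genome-fraction estimates (mapped/total reads) are only meaningful
  with genuine whole-genome read sets, not with simulated or targeted
  reads.
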