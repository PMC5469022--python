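# Methods

This note documents the models, parameter choices and numerical
conventions of `genefamscan`, and what the synthetic study system does
and does not establish about real data.

## Family identification

Membership is defined by deterministic signature matching rather than
database homology search: a candidate is accepted iff its protein
carries both catalytic-domain motifs — the ATP-binding region
`[IL]GXGXFGVA` (the lysine anchoring ATP sits immediately downstream)
and the activation-loop active site `[VI]CHRDLKLENTLL` (whose aspartate
is the catalytic residue) — with the ATP motif upstream of the active
site.  These two motifs are exactly what defines a complete Ser/Thr
kinase catalytic domain in this family; BLASTP/profile-HMM searches
remain useful as *pre-filters* on very large proteomes but are not part
of this artifact, which trades their sensitivity model for a
self-contained, exactly testable rule.

Pattern syntax: one-letter amino acids; `X` matches anything; `[AB]`
matches either letter and is strict (mismatches are only tolerated at
literal positions).  The default mismatch tolerance is **1 per
signature** — real family members drift slightly from the consensus —
while the synthetic closure tests use tolerance 0, where recovery of
the planted membership is exact by construction.  Identical duplicate
sequences are collapsed to one representative (first seen, logged).

Names are assigned in chromosome order: subgenome letter (A before D),
chromosome number, placed chromosomes before scaffolds anchored to the
same chromosome (`scaffoldNNNN_A11` sorts after `A11` genes, before
`A12`), start position, then gene id lexicographically as the logged
tie-break.

## Coordinates and gene length

Everything internal is 1-based inclusive (GFF3 native).  The family
tables this pipeline reproduces print gene length as `end − start`
(verifiable from their printed coordinates), not the inclusive
`end − start + 1`; the API therefore exposes both `paper_gene_length`
and `span_length` rather than silently "fixing" either convention.

## Protein descriptors

* **Translation** uses the standard genetic code; the terminal stop is
  stripped, an internal stop is an error, codons containing `N`
  translate to `X`.  The bookkeeping relation `residues = CDS/3 − 1`
  holds for every stop-terminated model.
* **Molecular mass** is the sum of average (not monoisotopic) residue
  masses plus one water, the protein-parameter convention; the mass
  table is embedded in `protein_props.py`.  `X` is an error here — a
  sum is not robust to exclusion.
* **GRAVY** is the mean Kyte–Doolittle hydropathy; `X` residues are
  excluded from numerator and denominator (a mean is robust to
  exclusion) and logged.  Negative scores classify a protein
  hydrophilic.
* **pI** solves net charge = 0 by bisection on (0, 14) over the
  ionizable groups D, E, C, Y, H, K, R and both termini.  The net
  charge is strictly decreasing in pH, so the root is unique; bisection
  stops at |charge| < 1e-4 (results stable to 1e-3 under tolerance
  halving).  Two pKa sets ship: `bjellqvist` (default) and `emboss`.
  Published pI values computed with other tools may differ in the
  second decimal because the pKa set behind them is rarely stated —
  for this reason no test asserts third-party pI values to more than
  qualitative accuracy.

## Promoters and cis-elements

The promoter is the 2000 bp (configurable) immediately upstream of the
first CDS base, strand-aware, truncated with a warning at chromosome
edges.  Elements are exact strings (IUPAC codes expanded): ABRE
`CACGTG`, LTR `CCGAAA`, TC-rich `ATTTTCTTCA`, TCA `GAGAAGAATA`, HSE
`AAAAAATTTC`, TGACG `TGACG`, MBS `CAACTG`.  Scanning counts overlapping
occurrences on the forward strand plus, by default, reverse-complement
occurrences; palindromes (ABRE) are counted once per site; `N` never
matches.  Both-strand scanning matches the convention of the common
promoter-annotation databases; a forward-only flag exists and the choice
is recorded in output metadata.

## Gene structure

Intron phase is defined on coding sequence: phase of intron *i* is the
cumulative CDS length 5′ of it, mod 3.  This is the standard convention
(exon-based definitions differ when UTR-containing first exons exist);
UTR bp are skipped in the phase computation.  The per-group report
gives modal exon count, gene-length range and members deviating from
the group mode.

## Alignment and phylogeny

Pairwise alignment is global Needleman–Wunsch with affine gaps
(BLOSUM62; gap of length L costs `open + (L−1)·extend`, defaults
open 10, extend 0.5 — classic protein settings).  Traceback ties prefer
match/mismatch over a gap in the first sequence over a gap in the
second, making reported alignments deterministic.  The implementation
is verified against exhaustive alignment enumeration on short
sequences.

The multiple alignment is **center-star**: the center is the sequence
minimizing the total pairwise distance (1 − identity), all others are
merged against it under "once a gap, always a gap".  This is a
deterministic, dependency-free stand-in for progressive aligners; it is
adequate for the highly similar members of one family (the use case
here) but is *not* accurate for deeply diverged sequence sets — a known
limitation, and the reason tree topology against published figures is
out of testable scope.

Distances are p-distances with pairwise deletion; a Poisson-corrected
option (−ln(1 − p)) is available by flag.  **UPGMA** (chosen over
neighbor joining because the analysis this package re-implements names
UPGMA as its tree method) joins the minimal-distance pair — ties broken
by the lexicographically smallest sorted id pair — at height d/2 with
size-weighted arithmetic means for merged distances.  Output is
ultrametric by construction (tested to 1e-9) and cross-checked against
SciPy average-linkage cophenetic distances.

Bootstrap: columns resampled with replacement per replicate, distance
and tree recomputed, support of an internal edge = fraction of
replicates containing the same leaf bipartition.  1000 replicates is
the conventional default; pipeline tests use fewer (25–200) to keep the
suite fast — support values are the statistic being estimated, and
their sampling error at n replicates is binomial.  Replicates in which
a sequence pair loses all shared columns are discarded and logged.

## Group classification

Tree-based assignment is primary: each member takes the majority group
of the reference leaves in its smallest reference-containing clade
(ties → unassigned, warned).  C-terminal typing is the cross-check:
the maximal D+E window (width 30, configurable) in the C-terminal
third gives the acidic patch (poly-D vs poly-E, requiring D+E ≥ 6,
else indeterminate), and the two C-terminal boxes are detected by
pattern matching (tolerance 2) — the family-specific box (16 residues,
Gln…Pro) in all members and the ABA-specific box (30 residues, Leu…Met,
aspartate-rich) only in Group III.  The box consensus strings ship as
editable configuration because the source analyses report alignment
*coordinates*, not consensus sequences; pattern matching transfers the
concept to arbitrary members where fixed coordinates would not.
Conflicts (Group III without an ABA box; Group I without a poly-E
patch) are flagged, never silently overridden.

## Duplication and dS/dN

Pairs are scored by global protein alignment; a pair is a duplicate
when coverage (aligned columns / longer sequence) ≥ 0.80 and identity
(matches / aligned columns) ≥ 0.70.  Same chromosome ⇒ tandem,
different ⇒ segmental — a deliberately literal reading of the standard
criterion, with no adjacency window.

dS/dN uses **NG86** on a codon alignment back-threaded from the protein
alignment (each residue ↔ its source codon; gaps ↔ `---`; a
translation mismatch is an error naming the codon index):

* synonymous sites per codon: for each position, the fraction of the
  possible single-nucleotide changes (changes producing stop codons
  excluded from the denominator) that preserve the amino acid, summed
  over the three positions; `S` averages the two codons and sums over
  columns; `N = 3·columns − S`;
* differences per codon: all mutational pathways between the two
  codons, pathways through stop codons discarded and the remainder
  re-weighted equally (if every pathway is blocked — possible only for
  rare 2–3-difference pairs — all pathways are used unrestricted);
* Jukes–Cantor correction `d = −(3/4)·ln(1 − (4/3)p)`; `p ≥ 3/4` is a
  saturation error; ω = dN/dS, flagged undefined when dS = 0.  Codons
  containing a gap or `N` in either sequence are skipped entirely.

The implementation is verified against an independent exhaustive
enumeration over all sense-codon pairs, and recovers planted
(n_syn, n_nonsyn) counts exactly when planted changes hit distinct
codons at single positions.  NG86 + JC was chosen over ML codon models
(codeml-style) because it is deterministic and oracle-verifiable;
published values computed with ML tools are treated as cross-checks
only.

## Expression

FPKM matrices (genes × `condition_timepoint` samples, 0 h control
required per condition) are scaled as log2(FPKM + 1) or per-gene
z-scores of those values.  A gene is called responsive when
|log2 fold-change vs control| ≥ 1 at any stressed timepoint; the
source heatmaps state no cutoff, so this rule is the package's own and
is configurable.

2^−ΔΔCt: technical replicates are averaged first; ΔCt = mean Ct(target)
− mean Ct(reference) per sample; ΔΔCt subtracts the 0 h control; fold
= 2^−ΔΔCt, so the control fold is exactly 1.  Replicate SD is combined
in Ct space (target and reference SDs in quadrature) and exponentiated
to a fold-scale factor.  When biological replicate structure exists,
technical replicates are averaged before biological statistics.

## Synthetic study system

The generator's defaults mirror the study conditions the pipeline is
designed around: 20 family members as 10 homoeologous pairs split over
A- and D-subgenome chromosomes (one pair on unplaced scaffolds,
reproducing the scaffold-ordering rule), nine exons per gene, 2-kb
promoters, 10 kinase-like decoys carrying exactly one signature and 10
non-kinase decoys, 0.40 GC background.  Groups follow the published
family structure (2 × Group I, 8 × II, 10 × III).

Construction details that make the truth exact:

* **Motif-free background** everywhere outside planted sites (rejection
  sampling on both strands), so planted cis-element counts are exact
  and count-equality tests are meaningful.
* **Shared template lineage**: one family background (residues *and*
  codons) → group bases (~25 substitutions + 20 silent codon swaps and
  the group tail) → pair founders (8 + 10) → the D-subgenome paralog by
  exactly (n_syn, n_nonsyn) single-nucleotide changes at distinct
  background codons, never creating stops.  Family-wide identity lands
  around 74–96 %, as in a real kinase family, and synonymous distances
  stay far from Jukes–Cantor saturation within the family.
* Signatures and boxes sit at fixed template offsets and every derived
  protein is re-verified (exactly one hit of each planted signature at
  tolerance 1, correct box content at tolerance 2); candidates that
  accidentally gain or lose a motif are resampled.
* Expression: Group III members are the responsive set, induced
  `fold`-fold (default 4) at 3 h and 6 h over a log-normal baseline
  (σ = 0.2 log2 units; closure tests use σ = 0); Ct tables carry a
  constant reference gene and three technical replicates.

What passing these tests shows — and does not.  The closures prove the
pipeline's logic end-to-end: exact membership recovery, exact planted
cis-element counts, exact (Sd, Nd) recovery, correct group assignment.
They do not establish sensitivity to the messiness of real data:
pseudogenes, alternative isoforms, signature drift beyond one mismatch,
promoter motif variants outside the fixed table, homoeolog expression
bias, or intron evolution.  The generator deliberately omits all of
these.

## Problem sizes and determinism

Default test/acceptance sizes: 20-member family (+ decoys), 360-residue
proteins, ~1 kb CDS, 300-codon dS/dN simulations over 20 seeds,
5-taxon UPGMA oracle matrices, 25–200 bootstrap replicates in tests.
A full pipeline run at these sizes takes seconds.  One global seed is
fanned out per stage (seed + stage index); identical seed and
configuration reproduce byte-identical outputs.

## Known limitations

* Center-star MSA and p-distances are first-order tools; deep
  divergences need a progressive aligner and model-based distances.
* The signature filter's tolerance-1 default has not been calibrated
  against real proteome-scale variation.
* NG86 underestimates dS/dN at high divergence relative to ML codon
  models; saturated pairs are reported as NA rather than estimated.
* Tandem classification by "same chromosome" can over-call tandem
  duplication on large chromosomes.
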