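# Methods

This note documents the models and procedures implemented in `rgenescape`,
the parameters that matter, what the synthetic data emulate (and do not),
and the numerical and design choices made where the procedure left room.

## Identification triage

Candidate R genes are found in four stages per genome.

1. **Motif scan.** The bundled NB-ARC position-weight model scores every
   window of each protein (+2 per agreeing residue, −1 otherwise, over a
   40-residue canonical block); one best hit per protein is kept at a
   default cutoff of 45% of the maximal score. This stands in for a
   profile-HMM search; it is deliberately simple and is paired with the
   best-hit validation below, which carries the real discriminative load.
2. **Seed triage.** Each motif-positive protein is searched against a
   labelled validating database with pools of NBS-LRR, ABC-transporter and
   kinase proteins (E ≤ 1e-10). Only proteins whose single best hit
   (highest bit score; ties by percent identity, then a fixed category
   priority NBS-LRR > kinase > ABC) is NBS-LRR become seeds. A protein with
   no hit at the cutoff is dropped.
3. **Translated sweep.** Seeds are aligned against all six reading frames
   of the genome. Same-strand hits from any seed separated by at most
   `chain_gap` = 5 000 nt are chained into one candidate region. The value
   spans typical NBS-LRR intron sizes without bridging neighbouring gene
   copies at the gene densities the pipeline targets. A region overlapping
   an annotated gene's CDS adopts that gene (largest CDS overlap wins);
   `has_nbs` is set when the region covers ≥ 50% of some seed's NB-ARC
   span. This stage recovers partial genes with no NBS region at all.
4. **Re-validation.** Each candidate region is validated again by the
   best-hit rule against the validating database. The triage seed proteins
   are offered as additional NBS-LRR-labelled evidence here: a
   comprehensive protein database contains full-length relatives of
   partial genes, and the seeds play that role at desk scale. Survivors
   are renamed `<genome>-<4-digit ordinal>` in (chromosome, start) order;
   zero padding keeps lexicographic and coordinate order identical.

## Similarity engine

All similarity search goes through one engine: Smith–Waterman-optimal
local alignment with affine gaps (a gap of length L costs
`open + L·extend`), BLOSUM62 11/1 for proteins and +2/−3 with gap 5/2 for
nucleotides. Raw scores are calibrated as `bit = (λ·raw − ln K)/ln 2` and
`E = m·n·2^(−bit)` with fixed per-matrix constants (protein λ = 0.267,
K = 0.041; nucleotide λ = 0.625, K = 0.41) and a per-pair `m·n` search
space rather than a database-wide one. Every analysis in the package uses
a fixed cutoff (default 1e-10), so only relative calibration matters; this
is a deliberate simplification relative to full BLAST statistics and is
the reason the engine's E-values should not be compared with BLAST's.

Ambiguity characters (N, X) score 0 against everything; stop codons in
translated frames score −1000, so alignments never cross a stop. Search
uses an exact-word prefilter (11-mers for nucleotide, 5-mers for protein)
that skips pairs sharing no word; at the divergence levels where a pair
can still pass the cutoff, shared words are abundant, and equivalence with
the exhaustive all-pairs search is enforced by tests. The translated
search aligns only inside windows around word matches (two seeds minimum)
and re-searches the flanks of each accepted HSP so tandem copies are all
reported. Reciprocal-best-hit pairing additionally shortlists subjects by
shared-word count before scoring: best hits live at near-identity, where
the true partner dominates the word counts, so the shortlist changes no
outcome while avoiding alignment of the long tail of weak pairs.

## Subfamily classification

The reference genome's R genes are clustered by single linkage: connected
components of the graph with an edge for every nucleotide hit at
E ≤ 1e-10. Single linkage is order-independent and matches a plain
"hit graph" reading of similarity-based grouping. Components with no
full-length member are routed to an unclassified pool. "Full-length" is
judged within a group: NB-ARC region present, no premature stop, and
coding length ≥ 90% of the group's longest member — a group-relative rule
because no external reference length exists before a ref-gene is chosen.

Each anchored group elects a ref-gene: a curated known gene if the group
contains one, otherwise a seeded uniform choice among full-length members;
the subfamily is named after it. Genes of the other genomes join the
subfamily of their best-hitting ref-gene (best-hit, not any-hit). Genes
hitting no ref-gene pool up and the whole procedure iterates — new
components, new ref-genes, re-offering the remainder — until the pool is
empty or anchorless. Anchorless leftovers stay unclassified but are
retained in locus and chromosome counts.

TNL/nTNL class comes from a TIR position-weight scan of the protein: TIR
hit ⇒ TNL, otherwise nTNL. For truncated members the absence of TIR
evidence is weak (the region may simply be missing), so the call carries a
low-confidence flag. Externally supplied coiled-coil labels only annotate
the CNL subtype as metadata.

## Gene models and status

Intron phase is positional: the phase of intron *i* is the cumulative
coding length upstream of it modulo 3. The GFF3 `phase` column encodes a
different convention (frame offset within a CDS segment) and is ignored
and recomputed. Minus-strand segment order is flipped to transcription
order before computation, making phases strand-invariant.

Structure comparison matches introns greedily by nearest cumulative coding
offset within a 6 nt tolerance — enough to absorb small indels without
cross-matching neighbouring introns. Status against the subfamily
reference model: premature stop anywhere in the reading frame ⇒
pseudogene (pseudogene takes precedence); coding length < 70% of the
reference ⇒ partial; else intact. The 70% threshold separates genuinely
truncated copies (the generator removes ≥ 40%) from members that merely
accumulated substitutions.

## Loci, synteny anchoring and the integrated map

An R locus is a maximal run of R genes with ≤ `max_gap` = 8 non-R genes
between consecutive members; gaps count annotated protein-coding genes,
strand-ignorant, not physical distance. Single-copy loci are reported by
default (`include_singletons=True`) and multi-copy loci are those with
≥ 2 members.

A locus from a non-reference genome is anchored through its flanking non-R
genes (up to `flank_k` = 5 per side): after reciprocal-best-hit pairing of
non-R genes against the reference, the locus maps to the smallest
reference interval containing ≥ `min_support` = 2 flank orthologs on one
reference chromosome, with at least one ortholog from each side whenever
both sides contributed any. Small `flank_k`/`min_support` values tolerate
local rearrangement while still rejecting ambiguous placements; loci whose
flanks cannot support an interval are reported unmapped.

Anchored intervals on the same reference chromosome that overlap or lie
within `merge_tolerance` of each other collapse into one map entry
(default 50 kb for genome-scale gene spacing; the bundled fixture uses
8 kb — one gene slot — because its genes are far denser). Presence flags
are evaluated at species level (genomes carry a species tag): present in
every species ⇒ `shared_all`; exactly one species ⇒ `species_specific`;
anything else ⇒ `polymorphic`. In tallies, the polymorphic count includes
species-specific loci (they are P/A polymorphic too), so
total = shared_all + polymorphic.

## Phylogenetics

Distances use pairwise deletion; ambiguous characters are treated as gaps.
K2P: d = −½·ln((1−2P−Q)·√(1−2Q)); the distance is flagged undefined when
the logarithm's domain is violated (saturation), and bootstrap replicates
containing undefined distances are skipped and counted with a warning.
Neighbor joining follows Saitou–Nei with the standard Q-criterion;
ties break on the smallest taxon-index pair, and a negative branch length
is clamped to zero with the length moved to the sibling edge. Bootstrap
support for each bipartition of the full-data tree is the percentage of
successful replicate trees containing it; rendered Newick suppresses
supports below 65 while the tree object retains them.

A centre-star aligner (global pairwise alignments onto the longest
sequence, free end gaps) is bundled so fixture alignments are
self-contained; it handles substitutions and end-truncations, which is all
the generator produces, and is not a general MSA tool.

## The synthetic data

The generator emulates a small collection of related genomes:

* **Subfamily ancestors** derive from one random 420-residue protein
  scaffold: background positions substituted with probability 0.5 per
  ancestor and all codons redrawn uniformly, leaving ~29% background amino
  acid and ~37% nucleotide identity between ancestors. Every ancestor
  carries the canonical NB-ARC-like block (mutated at 12% per ancestor)
  and TNL ancestors the TIR-like block (10%); blocks stay detectable by
  the motif scanner while their nucleotide sequences diverge. A
  deterministic redraw loop additionally guarantees no cross-ancestor
  nucleotide alignment below an E-value floor of 1e-6 — four orders of
  magnitude above the linking cutoff — so planted partitions are clean by
  construction.
* **Members** substitute sites at `mutation_rate` (default 3%), with
  codons that would become premature stops redrawn. Partial members lose
  ≥ 40% of the CDS from one end (the NB-ARC block is lost with probability
  0.5); pseudogenes carry one planted in-frame stop at 30–60% of the CDS.
  The first planted copy of each subfamily per genome is always intact, so
  every subfamily present in a genome has a seedable full-length member.
* **Layout.** Chromosomes are grids of 8 kb gene slots (larger than the
  5 kb chain gap, so tandem copies cannot merge into one candidate).
  Non-R slots carry decoy genes: validating-database ABC and kinase
  proteins reverse-translated with a per-slot codon draw that is identical
  across genomes up to a 1% per-genome mutation rate — this is what makes
  flanking-gene synteny and RBH pairing well defined. A shared locus
  template plus per-genome presence flags plants the P/A design; absent
  loci leave decoys in place, so the syntenic region exists without R
  genes, exactly the situation the P/A rule describes.
* **Default study conditions**: three genomes (one per species), three
  chromosomes × 60 slots each, six subfamilies (two TNL) with fixed
  intron-phase plans (TNLs intron-rich, most non-TNLs intron-poor), ten
  planted loci including singletons and a gap-8 boundary case, 15%
  partial and 10% pseudogene copies, validating database of 40+40+40
  proteins as a scaled stand-in for a multi-thousand-protein database.

What the generator does **not** emulate: insertions/deletions other than
end-truncation, gene conversion and recombination between family members,
transposon interruption, assembly gaps or unanchored scaffolds, and
annotation errors. Passing tests therefore demonstrate the pipeline's
logic — triage rules, linkage clustering, gap counting, anchoring,
categorisation — under clean signal/noise separation; they do not
demonstrate robustness to the messier divergence structure of real
genomes, where thresholds (chain gap, 70% partial rule, linking cutoff)
would need tuning against curated annotations.

## Determinism and problem sizes

Every stochastic step is seed-pinned: the generator from its spec seed,
ref-gene election and bootstrap from explicit seeds. Identical seeds give
byte-identical FASTA/GFF3 and identical pipeline output. The bundled
fixture sizes (three ~1.4 Mb genomes, ~180 genes each, 48 planted R genes)
keep a full pipeline run under a minute on one CPU while still exercising
every rule — multi-exon models on both strands, partial and pseudogene
copies, a private subfamily that only the fixpoint iteration can recover,
and all three P/A categories; the phylogenetics checks use 6–8 taxa and
200 bootstrap replicates for the same reason.
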