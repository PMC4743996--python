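"""Physical R loci, reciprocal-best-hit orthologs, synteny anchoring and the
integrated presence/absence map.

An R locus is a run of R genes in which consecutive members are separated by
no more than ``max_gap`` (default 8) non-R protein-coding genes; gap counting
uses annotated genes between consecutive R genes, strand-ignorant, not
physical distance.  Loci from non-reference genomes are anchored onto the
reference genome through reciprocal-best-hit (RBH) orthologs of their
flanking non-R genes, and anchored loci whose reference intervals overlap
(or fall within a merge tolerance) collapse into one entry of the integrated
map.  A map entry present in every species is ``shared_all``; present in
exactly one species, ``species_specific``; anything else ``polymorphic``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .gene_model import GeneRecord
from .homology_engine import DEFAULT_SCORING, ScoringConfig, search


@dataclass
class RLocus:
    locus_id: str
    genome_id: str
    chrom: str
    members: List[str]                  # gene ids in coordinate order
    span: Tuple[int, int]
    flank_left: List[str] = field(default_factory=list)   # nearest first
    flank_right: List[str] = field(default_factory=list)  # nearest first

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def multi_copy(self) -> bool:
        return self.n_members >= 2


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    bit_ab: float
    bit_ba: float


@dataclass
class IntegratedLocus:
    map_position: Tuple[str, int, int]      # reference chrom, start, end
    presence: Dict[str, bool]               # per genome
    category: str                           # shared_all | polymorphic | species_specific
    contributing: List[str]                 # locus ids merged into this entry
    specific_species: Optional[str] = None  # set when category == species_specific


def call_loci(genes: Sequence[Tuple[str, int, bool]], max_gap: int = 8,
              include_singletons: bool = True) -> List[List[str]]:
    """Chain R genes of one chromosome into loci.

    ``genes`` is the chromosome's full gene list as (gene_id, start, is_r)
    sorted by start.  Greedy left-to-right chaining: an R gene joins the open
    locus iff at most ``max_gap`` non-R genes intervene since the previous
    member.  Singletons are emitted as single-copy loci when requested.
    """
    starts = [s for _, s, _ in genes]
    if starts != sorted(starts):
        raise ValueError("gene list must be sorted by start coordinate")
    loci: List[List[str]] = []
    current: List[str] = []
    gap = 0
    for gid, _start, is_r in genes:
        if is_r:
            if current and gap <= max_gap:
                current.append(gid)
            else:
                if current:
                    loci.append(current)
                current = [gid]
            gap = 0
        else:
            gap += 1
    if current:
        loci.append(current)
    if not include_singletons:
        loci = [l for l in loci if len(l) >= 2]
    return loci


def loci_for_genome(records: Sequence[GeneRecord], r_gene_ids: Set[str],
                    genome_id: str, max_gap: int = 8,
                    include_singletons: bool = True, flank_k: int = 5) -> List[RLocus]:
    """Call loci on every chromosome of a genome and attach flanking genes."""
    by_chrom: Dict[str, List[GeneRecord]] = {}
    for g in sorted(records, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    loci: List[RLocus] = []
    n = 0
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        triples = [(g.gene_id, g.start, g.gene_id in r_gene_ids) for g in genes]
        index = {g.gene_id: i for i, g in enumerate(genes)}
        for members in call_loci(triples, max_gap, include_singletons):
            n += 1
            first, last = index[members[0]], index[members[-1]]
            left = [genes[i].gene_id for i in range(first - 1, -1, -1)
                    if genes[i].gene_id not in r_gene_ids][:flank_k]
            right = [genes[i].gene_id for i in range(last + 1, len(genes))
                     if genes[i].gene_id not in r_gene_ids][:flank_k]
            loci.append(RLocus(
                locus_id=f"{genome_id}-locus-{n}", genome_id=genome_id,
                chrom=chrom, members=list(members),
                span=(genes[first].start, genes[last].end),
                flank_left=left, flank_right=right))
    return loci


def _directional_best(genes_q: Mapping[str, str], genes_s: Mapping[str, str],
                      cfg: ScoringConfig, e_cutoff: float,
                      shortlist: int = 3) -> Dict[str, Tuple[str, float]]:
    """Best subject per query: {query: (subject, bit score)}.

    Only a shortlist of subjects per query is aligned: the top ``shortlist``
    by shared 11-mer count plus every subject sharing at least 30 words.
    At the identity levels where best hits live (near-identical orthologs
    versus diverged paralogs) the true best hit always dominates the word
    counts, so the shortlist does not change the best-hit outcome; it only
    avoids aligning the long tail of weakly similar pairs.
    """
    from .homology_engine import _ALIGNERS, _kmer_set
    aligner = _ALIGNERS.get(cfg, "nucleotide")
    qk = {qid: _kmer_set(s, 11) for qid, s in genes_q.items()}
    sk = {sid: _kmer_set(s, 11) for sid, s in genes_s.items()}
    best: Dict[str, Tuple[str, float]] = {}
    for qid in sorted(genes_q):
        counts = [(len(qk[qid] & sk[sid]), sid) for sid in sorted(genes_s)]
        counts = [(n, sid) for n, sid in counts if n > 0]
        counts.sort(key=lambda t: (-t[0], t[1]))
        if not counts:
            continue
        if len(counts) == 1 or (counts[0][0] >= 100
                                and counts[0][0] >= 10 * counts[1][0]):
            chosen = [counts[0][1]]  # unambiguous near-identical partner
        else:
            chosen = [sid for _n, sid in counts[:shortlist]]
            chosen += [sid for n, sid in counts[shortlist:] if n >= 30]
        best_key = None
        for sid in chosen:
            raw = aligner.score(genes_q[qid], genes_s[sid])
            if raw <= 0:
                continue
            e = cfg.e_value(raw, len(genes_q[qid]), len(genes_s[sid]), "nucleotide")
            if e > e_cutoff:
                continue
            key = (-raw, sid)
            if best_key is None or key < best_key:
                best_key = key
                best[qid] = (sid, cfg.bit_score(raw, "nucleotide"))
    return best


def rbh_orthologs(genes_a: Mapping[str, str], genes_b: Mapping[str, str],
                  cfg: ScoringConfig = DEFAULT_SCORING,
                  e_cutoff: float = 1e-10) -> List[OrthologPair]:
    """Reciprocal best hits between two gene sets (bi-directional search)."""
    if not genes_a or not genes_b:
        return []
    ab = _directional_best(genes_a, genes_b, cfg, e_cutoff)
    ba = _directional_best(genes_b, genes_a, cfg, e_cutoff)
    pairs = []
    for a in sorted(ab):
        b, bit_ab = ab[a]
        if b in ba and ba[b][0] == a:
            pairs.append(OrthologPair(a, b, bit_ab, ba[b][1]))
    return pairs


def anchor_locus(locus: RLocus, ref_records: Mapping[str, GeneRecord],
                 flank_orthologs: Mapping[str, str], flank_k: int = 5,
                 min_support: int = 2) -> Optional[Tuple[str, int, int]]:
    """Anchor a locus onto the reference via its flanking-gene orthologs.

    Returns the smallest reference interval containing at least
    ``min_support`` flanking-gene orthologs on one reference chromosome,
    requiring at least one ortholog from each side whenever both sides
    contributed orthologs; None when no interval qualifies (unmapped).
    """
    placed: List[Tuple[str, int, int, str]] = []  # chrom, start, end, side
    for side, flank in (("L", locus.flank_left[:flank_k]),
                        ("R", locus.flank_right[:flank_k])):
        for gid in flank:
            ref_id = flank_orthologs.get(gid)
            if ref_id and ref_id in ref_records:
                r = ref_records[ref_id]
                placed.append((r.chrom, r.start, r.end, side))
    if len(placed) < min_support:
        return None
    sides_present = {s for *_xs, s in placed}
    best: Optional[Tuple[int, str, int, int]] = None
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for chrom, s, e, side in placed:
        by_chrom.setdefault(chrom, []).append((s, e, side))
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        for i in range(len(items)):
            for j in range(i, len(items)):
                window = items[i : j + 1]
                if len(window) < min_support:
                    continue
                win_sides = {s for *_x, s in window}
                if sides_present == {"L", "R"} and win_sides != {"L", "R"}:
                    continue
                start = min(s for s, _e, _x in window)
                end = max(e for _s, e, _x in window)
                key = (end - start, chrom, start, end)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    _, chrom, start, end = best
    return (chrom, start, end)


def integrate(anchored: Sequence[Tuple[RLocus, Optional[Tuple[str, int, int]]]],
              reference_loci: Sequence[RLocus], all_genomes: Sequence[str],
              species_of: Mapping[str, str], reference_id: str,
              merge_tolerance: int = 50_000,
              ) -> Tuple[List[IntegratedLocus], List[RLocus]]:
    """Merge anchored loci into the integrated reference map.

    Reference loci enter at their own coordinates.  Anchored intervals on
    the same reference chromosome that overlap or lie within
    ``merge_tolerance`` collapse into one map entry; unmapped loci are
    returned separately.
    """
    entries: List[Tuple[str, int, int, RLocus]] = []
    for locus in reference_loci:
        entries.append((locus.chrom, locus.span[0], locus.span[1], locus))
    unmapped: List[RLocus] = []
    for locus, interval in anchored:
        if interval is None:
            unmapped.append(locus)
        else:
            entries.append((interval[0], interval[1], interval[2], locus))
    entries.sort(key=lambda t: (t[0], t[1], t[2], t[3].locus_id))

    merged: List[IntegratedLocus] = []
    cluster: List[Tuple[str, int, int, RLocus]] = []

    def flush():
        if not cluster:
            return
        chrom = cluster[0][0]
        start = min(s for _c, s, _e, _l in cluster)
        end = max(e for _c, _s, e, _l in cluster)
        presence = {gid: False for gid in all_genomes}
        contributing = []
        for _c, _s, _e, locus in cluster:
            presence[locus.genome_id] = True
            contributing.append(locus.locus_id)
        species_present = {species_of.get(g, g) for g, p in presence.items() if p}
        all_species = {species_of.get(g, g) for g in all_genomes}
        if species_present == all_species:
            category, specific = "shared_all", None
        elif len(species_present) == 1:
            category, specific = "species_specific", next(iter(species_present))
        else:
            category, specific = "polymorphic", None
        merged.append(IntegratedLocus((chrom, start, end), presence, category,
                                      sorted(contributing), specific))

    for entry in entries:
        if cluster and entry[0] == cluster[-1][0] and \
                entry[1] <= max(e for _c, _s, e, _l in cluster) + merge_tolerance:
            cluster.append(entry)
        else:
            flush()
            cluster = [entry]
    flush()
    merged.sort(key=lambda m: m.map_position)
    return merged, unmapped


def build_integrated_map(records_by_genome: Mapping[str, Sequence[GeneRecord]],
                         r_ids_by_genome: Mapping[str, Set[str]],
                         gene_seqs_by_genome: Mapping[str, Mapping[str, str]],
                         reference_id: str,
                         species_of: Optional[Mapping[str, str]] = None,
                         cfg: ScoringConfig = DEFAULT_SCORING,
                         e_cutoff: float = 1e-10, max_gap: int = 8,
                         include_singletons: bool = True, flank_k: int = 5,
                         min_support: int = 2, merge_tolerance: int = 50_000,
                         ) -> Tuple[List[IntegratedLocus], Dict[str, List[RLocus]],
                                    List[RLocus]]:
    """End-to-end locus calling, RBH flank pairing, anchoring and integration.

    ``gene_seqs_by_genome`` maps genome -> {gene_id: nucleotide sequence}
    for all annotated genes (used for non-R flank RBH pairing).  Returns
    (integrated map, per-genome loci, unmapped loci).
    """
    species_of = dict(species_of or {g: g for g in records_by_genome})
    loci_by_genome: Dict[str, List[RLocus]] = {}
    for gid in sorted(records_by_genome):
        loci_by_genome[gid] = loci_for_genome(
            records_by_genome[gid], r_ids_by_genome[gid], gid,
            max_gap, include_singletons, flank_k)

    ref_records = {g.gene_id: g for g in records_by_genome[reference_id]}
    ref_non_r = {gid: seq for gid, seq in gene_seqs_by_genome[reference_id].items()
                 if gid not in r_ids_by_genome[reference_id]}
    anchored: List[Tuple[RLocus, Optional[Tuple[str, int, int]]]] = []
    for gid in sorted(records_by_genome):
        if gid == reference_id:
            continue
        non_r = {g: s for g, s in gene_seqs_by_genome[gid].items()
                 if g not in r_ids_by_genome[gid]}
        pairs = rbh_orthologs(non_r, ref_non_r, cfg, e_cutoff)
        fmap = {p.gene_a: p.gene_b for p in pairs}
        for locus in loci_by_genome[gid]:
            anchored.append((locus, anchor_locus(locus, ref_records, fmap,
                                                 flank_k, min_support)))
    integrated, unmapped = integrate(anchored, loci_by_genome[reference_id],
                                     sorted(records_by_genome), species_of,
                                     reference_id, merge_tolerance)
    return integrated, loci_by_genome, unmapped


def write_integrated_map_tsv(path: str, entries: Sequence[IntegratedLocus],
                             genomes: Sequence[str]) -> None:
    with open(path, "w") as fh:
        cols = ["chrom", "start", "end", "category", "specific_species",
                "contributing"] + [f"present_{g}" for g in genomes]
        fh.write("\t".join(cols) + "\n")
        for m in entries:
            row = [m.map_position[0], str(m.map_position[1]), str(m.map_position[2]),
                   m.category, m.specific_species or "",
                   ",".join(m.contributing)]
            row += [str(int(m.presence.get(g, False))) for g in genomes]
            fh.write("\t".join(row) + "\n")


def write_loci_tsv(path: str, loci: Sequence[RLocus]) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tgenome_id\tchrom\tstart\tend\tn_members\tmembers\n")
        for l in loci:
            fh.write(f"{l.locus_id}\t{l.genome_id}\t{l.chrom}\t{l.span[0]}\t"
                     f"{l.span[1]}\t{l.n_members}\t{','.join(l.members)}\n")


def write_bed(path: str, entries: Sequence[IntegratedLocus]) -> None:
    """Integrated map intervals as BED (0-based half-open, like the rest)."""
    with open(path, "w") as fh:
        for i, m in enumerate(entries, start=1):
            chrom, s, e = m.map_position
            fh.write(f"{chrom}\t{s}\t{e}\tlocus_{i:03d}:{m.category}\n")
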