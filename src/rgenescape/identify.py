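"""Four-stage R-gene identification triage.

Per genome: (1) scan the proteome for the NB-ARC motif; (2) keep only
proteins whose best hit in the labelled validating database is an NBS-LRR
protein (the triage seeds); (3) sweep the genome with the seeds through a
translated search, chaining same-strand hits into candidate regions, so
partial homologs lacking the NB-ARC region are recovered too; (4) re-validate
every candidate region against the validating database, keeping only regions
whose best hit is again NBS-LRR.  Survivors are named with a genome prefix
and a zero-padded ordinal in coordinate order (e.g. ``GA-0001``).

Stage 4 stands in for a best-hit validation against a comprehensive protein
database: because such a database contains full-length relatives of partial
genes, the triage seed proteins are offered as additional NBS-LRR-labelled
evidence by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from ._common import revcomp
from .gene_model import GeneRecord
from .homology_engine import (DEFAULT_SCORING, ScoringConfig, SimilarityHit,
                              search, search_translated)
from .synthetic_genome import NB_ARC_BLOCK, TIR_BLOCK, ValidatingDB

# ties across validating-DB categories: NBS-LRR is what the triage is for,
# and kinase domains co-occur with NBS more often than ABC cassettes do
CATEGORY_PRIORITY = {"NBS-LRR": 0, "kinase": 1, "ABC-transporter": 2}


# ---------------------------------------------------------------------------
# Motif scanning (profile-search stand-in)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifModel:
    """Position-weight model scored as +match per agreeing residue, -mismatch
    otherwise, over a sliding window the length of the canonical block."""

    label: str
    block: str
    match: float = 2.0
    mismatch: float = -1.0

    @property
    def max_score(self) -> float:
        return self.match * len(self.block)

    def default_cutoff(self) -> float:
        return 0.45 * self.max_score

    def score_window(self, window: str) -> float:
        return sum(self.match if a == b else self.mismatch
                   for a, b in zip(self.block, window))

    def best_hit(self, protein: str) -> Tuple[float, int]:
        """(best score, window start) over all windows; (-inf, -1) if too short."""
        L = len(self.block)
        if len(protein) < L:
            return float("-inf"), -1
        best, best_i = float("-inf"), -1
        for i in range(len(protein) - L + 1):
            s = self.score_window(protein[i : i + L])
            if s > best:
                best, best_i = s, i
        return best, best_i


NB_ARC_MOTIF = MotifModel("NB-ARC", NB_ARC_BLOCK)
TIR_MOTIF = MotifModel("TIR", TIR_BLOCK)


@dataclass
class DomainHit:
    protein_id: str
    domain_label: str  # NB-ARC or TIR
    score: float
    span: Tuple[int, int]  # protein coordinates, 0-based half-open


def scan_motif(proteome: Mapping[str, str], model: MotifModel,
               score_cutoff: Optional[float] = None) -> List[DomainHit]:
    """One best-scoring motif hit per protein above the cutoff."""
    if not proteome:
        raise ValueError("empty proteome")
    cutoff = model.default_cutoff() if score_cutoff is None else score_cutoff
    hits: List[DomainHit] = []
    for pid in sorted(proteome):
        score, start = model.best_hit(proteome[pid])
        if start >= 0 and score >= cutoff:
            hits.append(DomainHit(pid, model.label, score,
                                  (start, start + len(model.block))))
    return hits


def scan_nbarc(proteome: Mapping[str, str], motif_model: MotifModel = NB_ARC_MOTIF,
               score_cutoff: Optional[float] = None) -> List[DomainHit]:
    """Scan a proteome for the NB-ARC motif (profile-HMM search stand-in)."""
    return scan_motif(proteome, motif_model, score_cutoff)


# ---------------------------------------------------------------------------
# Candidate regions
# ---------------------------------------------------------------------------

@dataclass
class RGeneCandidate:
    candidate_id: str
    genome_id: str
    chrom: str
    span: Tuple[int, int]     # genomic, 0-based half-open
    strand: str
    source_gene: Optional[str] = None
    status: str = "intact"    # intact | partial | pseudogene
    r_class: str = "unknown"  # TNL | nTNL | unknown
    subfamily: Optional[str] = None
    has_nbs: bool = False
    low_confidence_class: bool = False
    cc_subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.span[1] <= self.span[0]:
            raise ValueError(f"{self.candidate_id}: empty span")


def _best_category(hits: Sequence[SimilarityHit], categories: Mapping[str, str],
                   side: str = "subject") -> Optional[str]:
    """Category of the single best hit; deterministic tie-breaks.

    ``side`` names the end of the hit that carries the validating-DB
    protein ('subject' when the DB was searched, 'query' when the DB
    proteins were used as translated-search queries).
    """
    if not hits:
        return None
    vdb_id = (lambda h: h.subject_id) if side == "subject" else (lambda h: h.query_id)
    best = min(hits, key=lambda h: (-h.bit_score, -h.percent_identity,
                                    CATEGORY_PRIORITY.get(categories[vdb_id(h)], 9),
                                    vdb_id(h)))
    return categories[vdb_id(best)]


def triage_seeds(domain_hits: Sequence[DomainHit], proteome: Mapping[str, str],
                 vdb: ValidatingDB, cfg: ScoringConfig = DEFAULT_SCORING,
                 e_cutoff: float = 1e-10) -> Dict[str, str]:
    """Keep domain-hit proteins whose best validating-DB hit is NBS-LRR.

    Proteins with no hit at the cutoff are dropped.  Returns {id: sequence}.
    """
    if len(set(vdb.categories.values())) < 2:
        warnings.warn("validating database has a single category; triage is degenerate")
    queries = {h.protein_id: proteome[h.protein_id] for h in domain_hits}
    if not queries:
        return {}
    all_hits = search(queries, vdb.proteins, cfg, e_cutoff)
    by_query: Dict[str, List[SimilarityHit]] = {}
    for h in all_hits:
        by_query.setdefault(h.query_id, []).append(h)
    seeds: Dict[str, str] = {}
    for pid in sorted(queries):
        if _best_category(by_query.get(pid, []), vdb.categories) == "NBS-LRR":
            seeds[pid] = queries[pid]
    return seeds


def _chain_hits(hits: Sequence[SimilarityHit], chain_gap: int) -> List[List[SimilarityHit]]:
    """Chain same-strand hits separated by <= chain_gap nt into regions."""
    by_key: Dict[Tuple[str, int], List[SimilarityHit]] = {}
    for h in hits:
        strand = 1 if h.frame >= 0 else -1
        by_key.setdefault((h.subject_id, strand), []).append(h)
    regions: List[List[SimilarityHit]] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda h: h.subject_span)
        current = [group[0]]
        end = group[0].subject_span[1]
        for h in group[1:]:
            if h.subject_span[0] - end <= chain_gap:
                current.append(h)
                end = max(end, h.subject_span[1])
            else:
                regions.append(current)
                current, end = [h], h.subject_span[1]
        regions.append(current)
    return regions


def _nbarc_spans(seeds: Mapping[str, str]) -> Dict[str, Tuple[int, int]]:
    spans = {}
    for pid, seq in seeds.items():
        score, start = NB_ARC_MOTIF.best_hit(seq)
        if start >= 0 and score >= NB_ARC_MOTIF.default_cutoff():
            spans[pid] = (start, start + len(NB_ARC_MOTIF.block))
    return spans


def sweep_genome(seeds: Mapping[str, str], genome: Mapping[str, str],
                 annotation: Sequence[GeneRecord], genome_id: str,
                 cfg: ScoringConfig = DEFAULT_SCORING, e_cutoff: float = 1e-10,
                 chain_gap: int = 5000) -> List[RGeneCandidate]:
    """Translated sweep of the genome with R-protein seeds.

    Same-strand translated hits separated by at most ``chain_gap``
    nucleotides are chained into one candidate region.  A region overlapping
    an annotated gene's CDS adopts that gene's identity (largest CDS overlap
    wins when two genes overlap); other regions become unannotated
    candidates.  ``has_nbs`` is set when the region covers at least half of
    some seed's NB-ARC span.
    """
    if not seeds:
        raise ValueError("no seeds supplied")
    hits = search_translated(seeds, genome, cfg, e_cutoff)
    nb_spans = _nbarc_spans(seeds)
    genes_by_chrom: Dict[str, List[GeneRecord]] = {}
    for g in annotation:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    candidates: List[RGeneCandidate] = []
    n_unannotated = 0
    for region in _chain_hits(hits, chain_gap):
        chrom = region[0].subject_id
        strand = "+" if region[0].frame >= 0 else "-"
        span = (min(h.subject_span[0] for h in region),
                max(h.subject_span[1] for h in region))
        has_nbs = False
        for h in region:
            nb = nb_spans.get(h.query_id)
            if nb is None:
                continue
            qs, qe = h.query_span
            overlap = max(0, min(qe, nb[1]) - max(qs, nb[0]))
            if overlap >= 0.5 * (nb[1] - nb[0]):
                has_nbs = True
                break
        best_gene, best_overlap = None, 0
        for g in genes_by_chrom.get(chrom, []):
            cds_overlap = sum(max(0, min(span[1], e) - max(span[0], s))
                              for s, e in g.cds_segments)
            if cds_overlap > best_overlap:
                best_gene, best_overlap = g, cds_overlap
        if best_gene is not None:
            cand = RGeneCandidate(
                candidate_id=f"{genome_id}:{best_gene.gene_id}", genome_id=genome_id,
                chrom=chrom, span=(best_gene.start, best_gene.end),
                strand=best_gene.strand, source_gene=best_gene.gene_id,
                has_nbs=has_nbs)
        else:
            n_unannotated += 1
            cand = RGeneCandidate(
                candidate_id=f"{genome_id}:region{n_unannotated:03d}",
                genome_id=genome_id, chrom=chrom, span=span, strand=strand,
                source_gene=None, has_nbs=has_nbs)
        cand.status = "intact" if has_nbs else "partial"
        candidates.append(cand)

    # chaining on both strands can nominate the same annotated gene twice
    seen: Dict[str, RGeneCandidate] = {}
    deduped: List[RGeneCandidate] = []
    for cand in candidates:
        key = cand.source_gene or cand.candidate_id
        if key in seen:
            seen[key].has_nbs = seen[key].has_nbs or cand.has_nbs
            if seen[key].has_nbs:
                seen[key].status = "intact"
            continue
        seen[key] = cand
        deduped.append(cand)
    deduped.sort(key=lambda c: (c.chrom, c.span))
    return deduped


def candidate_sequence(cand: RGeneCandidate, genome: Mapping[str, str]) -> str:
    """Forward-strand nucleotide sequence of a candidate region."""
    seq = genome[cand.chrom][cand.span[0] : cand.span[1]]
    return seq


def _best_translated_category(proteins: Mapping[str, str], categories: Mapping[str, str],
                              region: str, cfg: ScoringConfig,
                              e_cutoff: float) -> Optional[str]:
    """Category of the best-scoring protein against a small translated region.

    The region's six frames are scored whole (no HSP bookkeeping needed for a
    best-hit decision); a shared 5-mer prefilter skips unrelated proteins.
    Ties break by category priority then protein id.
    """
    from ._common import six_frame_translations
    from .homology_engine import _ALIGNERS, _kmer_set
    frames = [t for t in six_frame_translations(region).values() if t]
    frame_kmer_sets = [_kmer_set(t, 5) for t in frames]
    aligner = _ALIGNERS.get(cfg, "protein")
    best_key, best_cat = None, None
    for pid in sorted(proteins):
        seq = proteins[pid]
        pkmers = _kmer_set(seq, 5)
        # score only frames sharing at least two exact words with the protein
        scored = [t for t, fk in zip(frames, frame_kmer_sets)
                  if len(pkmers & fk) >= 2]
        raw = max((aligner.score(seq, t) for t in scored), default=0.0)
        if raw <= 0:
            continue
        e = cfg.e_value(raw, len(seq), max(len(t) for t in frames), "protein")
        if e > e_cutoff:
            continue
        key = (-raw, CATEGORY_PRIORITY.get(categories[pid], 9), pid)
        if best_key is None or key < best_key:
            best_key, best_cat = key, categories[pid]
    return best_cat


def validate_candidates(candidates: Sequence[RGeneCandidate], vdb: ValidatingDB,
                        genome: Mapping[str, str],
                        cfg: ScoringConfig = DEFAULT_SCORING, e_cutoff: float = 1e-10,
                        extra_nbs: Optional[Mapping[str, str]] = None,
                        id_prefix: Optional[str] = None) -> List[RGeneCandidate]:
    """Keep candidates whose best translated validating hit is NBS-LRR.

    ``extra_nbs`` supplies additional NBS-LRR-labelled proteins (normally the
    triage seeds), standing in for the full-length relatives a comprehensive
    database would contain.  Survivors receive candidate ids
    ``<prefix>-<4-digit ordinal>`` in (chromosome, start) order.
    """
    proteins = dict(vdb.proteins)
    categories = dict(vdb.categories)
    for pid, seq in (extra_nbs or {}).items():
        key = f"seed:{pid}"
        proteins[key] = seq
        categories[key] = "NBS-LRR"
    survivors: List[RGeneCandidate] = []
    for cand in candidates:
        region = candidate_sequence(cand, genome)
        best = _best_translated_category(proteins, categories, region, cfg, e_cutoff)
        if best == "NBS-LRR":
            survivors.append(cand)
    survivors.sort(key=lambda c: (c.chrom, c.span))
    prefix = id_prefix or (survivors[0].genome_id if survivors else "")
    for i, cand in enumerate(survivors, start=1):
        cand.candidate_id = f"{prefix}-{i:04d}"
    return survivors


def identify_genome(proteome: Mapping[str, str], genome: Mapping[str, str],
                    annotation: Sequence[GeneRecord], vdb: ValidatingDB,
                    genome_id: str, cfg: ScoringConfig = DEFAULT_SCORING,
                    e_cutoff: float = 1e-10, chain_gap: int = 5000,
                    domain_hits: Optional[Sequence[DomainHit]] = None,
                    ) -> Tuple[List[RGeneCandidate], Dict[str, str]]:
    """Run the full four-stage triage for one genome.

    Returns (validated candidates, triage seed proteins).  ``domain_hits``
    may be supplied from an external domain scan; otherwise the bundled
    NB-ARC motif model is used.
    """
    if domain_hits is None:
        domain_hits = scan_nbarc(proteome)
    seeds = triage_seeds(domain_hits, proteome, vdb, cfg, e_cutoff)
    if not seeds:
        return [], {}
    candidates = sweep_genome(seeds, genome, annotation, genome_id, cfg,
                              e_cutoff, chain_gap)
    validated = validate_candidates(candidates, vdb, genome, cfg, e_cutoff,
                                    extra_nbs=seeds, id_prefix=genome_id)
    return validated, seeds


def write_candidates_tsv(path: str, candidates: Sequence[RGeneCandidate]) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tgenome_id\tchrom\tstart\tend\tstrand\t"
                 "status\tr_class\tsubfamily\thas_nbs\tsource_gene\n")
        for c in candidates:
            fh.write(f"{c.candidate_id}\t{c.genome_id}\t{c.chrom}\t{c.span[0]}\t"
                     f"{c.span[1]}\t{c.strand}\t{c.status}\t{c.r_class}\t"
                     f"{c.subfamily or ''}\t{int(c.has_nbs)}\t{c.source_gene or ''}\n")
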