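"""Subfamily classification: iterative reference-genome-first workflow.

R genes of the reference genome are partitioned into subfamilies as the
connected components (single linkage) of the similarity graph with an edge
for every nucleotide-level hit at the E-value cutoff.  Each component with a
full-length member elects a reference gene (ref-gene), a curated gene if one
is present, otherwise a seeded random choice among full-length members, and
the subfamily is named after it.  R genes from every other genome then join
the subfamily of their best-hitting ref-gene.  Genes hitting no ref-gene are
pooled and the whole procedure repeats on the pool — new components, new
ref-genes — until the pool is empty or contains only groups without a
full-length member; those remain unclassified (in practice truncated
fragments that cannot anchor a subfamily).

"Full-length" is judged within a group: no premature stop codon, an NB-ARC
region present, and a coding length of at least 90% of the group's longest
member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from ._common import translate
from .homology_engine import DEFAULT_SCORING, ScoringConfig, search
from .identify import DomainHit, RGeneCandidate


@dataclass
class Subfamily:
    subfamily_id: str
    ref_gene: str                         # candidate_id of the elected ref-gene
    members: Dict[str, List[str]] = field(default_factory=dict)  # genome -> ids
    r_class: str = "unknown"              # class of the ref-gene: TNL | nTNL
    ref_model: Optional[object] = None    # GeneModelAnnotation of the ref-gene

    def all_members(self) -> List[str]:
        return [m for ms in self.members.values() for m in ms]

    def add(self, genome_id: str, candidate_id: str) -> None:
        self.members.setdefault(genome_id, []).append(candidate_id)


def _has_internal_stop(cds: str) -> bool:
    if len(cds) < 6:
        return False
    prot = translate(cds)
    stop = prot.find("*")
    return 0 <= stop < len(prot) - 1


def full_length_ids(group: Sequence[RGeneCandidate],
                    seqs: Mapping[str, str]) -> List[str]:
    """Members of a group that qualify as full-length (electable) genes."""
    max_len = max(len(seqs[c.candidate_id]) for c in group)
    out = []
    for c in group:
        seq = seqs[c.candidate_id]
        if (c.has_nbs and not _has_internal_stop(seq)
                and len(seq) >= 0.9 * max_len):
            out.append(c.candidate_id)
    return sorted(out)


def cluster_reference(genes: Sequence[RGeneCandidate], seqs: Mapping[str, str],
                      cfg: ScoringConfig = DEFAULT_SCORING, e_cutoff: float = 1e-10,
                      ) -> Tuple[List[List[RGeneCandidate]], List[RGeneCandidate]]:
    """Partition genes into similarity components; route anchorless ones out.

    Returns (groups, unclassified pool).  Groups are connected components of
    the hit graph (single linkage, hence order-independent); components
    without any full-length member go to the unclassified pool.
    """
    if not genes:
        return [], []
    by_id = {c.candidate_id: c for c in genes}
    gene_seqs = {c.candidate_id: seqs[c.candidate_id] for c in genes}
    graph = nx.Graph()
    graph.add_nodes_from(gene_seqs)
    for h in search(gene_seqs, gene_seqs, cfg, e_cutoff):
        graph.add_edge(h.query_id, h.subject_id)
    groups: List[List[RGeneCandidate]] = []
    unclassified: List[RGeneCandidate] = []
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        members = [by_id[i] for i in sorted(comp)]
        if full_length_ids(members, seqs):
            groups.append(members)
        else:
            unclassified.extend(members)
    return groups, unclassified


def elect_ref_gene(group: Sequence[RGeneCandidate], seqs: Mapping[str, str],
                   known_genes: Optional[Sequence[str]] = None,
                   seed: int = 0) -> str:
    """Choose the reference gene of a group.

    A curated gene present in the group wins (first in the curated list);
    otherwise a seeded uniform choice among full-length members.
    """
    eligible = full_length_ids(group, seqs)
    if not eligible:
        raise ValueError("group has no full-length member to elect")
    if known_genes:
        ids = {c.candidate_id for c in group}
        sources = {c.source_gene: c.candidate_id for c in group if c.source_gene}
        for k in known_genes:
            if k in ids:
                return k
            if k in sources:
                return sources[k]
    return Random(seed).choice(eligible)


def assign_members(genes: Sequence[RGeneCandidate], subfamilies: Sequence[Subfamily],
                   seqs: Mapping[str, str], cfg: ScoringConfig = DEFAULT_SCORING,
                   e_cutoff: float = 1e-10,
                   ) -> Tuple[List[Tuple[RGeneCandidate, Subfamily]], List[RGeneCandidate]]:
    """Assign each gene to the subfamily of its best-hitting ref-gene.

    Returns (assignments, unassigned pool).  Best hit = highest bit score,
    ties broken by percent identity then ref-gene id.
    """
    if not subfamilies:
        raise ValueError("no subfamilies to assign against")
    if not genes:
        return [], []
    ref_seqs = {sf.ref_gene: seqs[sf.ref_gene] for sf in subfamilies}
    by_ref = {sf.ref_gene: sf for sf in subfamilies}
    gene_seqs = {c.candidate_id: seqs[c.candidate_id] for c in genes}
    hits = search(gene_seqs, ref_seqs, cfg, e_cutoff)
    best: Dict[str, Tuple] = {}
    for h in hits:
        key = (-h.bit_score, -h.percent_identity, h.subject_id)
        if h.query_id not in best or key < best[h.query_id][0]:
            best[h.query_id] = (key, h.subject_id)
    assignments: List[Tuple[RGeneCandidate, Subfamily]] = []
    unassigned: List[RGeneCandidate] = []
    for c in genes:
        if c.candidate_id in best:
            assignments.append((c, by_ref[best[c.candidate_id][1]]))
        else:
            unassigned.append(c)
    return assignments, unassigned


def assign_class(candidate: RGeneCandidate, domain_hits: Sequence[DomainHit],
                 cc_labels: Optional[Mapping[str, str]] = None) -> str:
    """TNL if the candidate's protein has a TIR domain hit, else nTNL.

    For truncated genes the absence of a TIR hit is weak evidence (the TIR
    region may simply be missing), so the candidate is flagged low
    confidence.  ``cc_labels`` (externally predicted coiled-coil calls)
    only annotate the CNL subtype as metadata.
    """
    tir_ids = {h.protein_id for h in domain_hits if h.domain_label == "TIR"}
    keys = {candidate.candidate_id, candidate.source_gene}
    r_class = "TNL" if keys & tir_ids else "nTNL"
    candidate.r_class = r_class
    candidate.low_confidence_class = (r_class == "nTNL"
                                      and candidate.status != "intact")
    if cc_labels:
        key = candidate.source_gene or candidate.candidate_id
        candidate.cc_subtype = cc_labels.get(key)
    return r_class


def iterate_until_fixpoint(pools: Mapping[str, List[RGeneCandidate]],
                           seqs: Mapping[str, str],
                           subfamilies: List[Subfamily],
                           cfg: ScoringConfig = DEFAULT_SCORING,
                           e_cutoff: float = 1e-10, seed: int = 0,
                           known_genes: Optional[Sequence[str]] = None,
                           ) -> Tuple[List[Subfamily], List[RGeneCandidate]]:
    """Repeat clustering + ref-gene election on pooled unassigned genes.

    After each round the still-unassigned genes are re-offered to the newly
    created subfamilies, until no new subfamily can be formed.  Returns the
    updated subfamily list and the final unclassified pool.
    """
    pool: List[RGeneCandidate] = [c for gid in sorted(pools) for c in pools[gid]]
    unclassified: List[RGeneCandidate] = []
    round_no = 0
    while pool:
        round_no += 1
        groups, no_anchor = cluster_reference(pool, seqs, cfg, e_cutoff)
        if not groups:
            unclassified.extend(no_anchor)
            break
        new_subs: List[Subfamily] = []
        for gi, group in enumerate(groups):
            ref = elect_ref_gene(group, seqs, known_genes,
                                 seed=seed * 1009 + round_no * 101 + gi)
            sf = Subfamily(subfamily_id=ref, ref_gene=ref)
            for c in group:
                sf.add(c.genome_id, c.candidate_id)
                c.subfamily = sf.subfamily_id
            new_subs.append(sf)
        subfamilies.extend(new_subs)
        if not no_anchor:
            break
        # re-offer the remainder to the new subfamilies only; genes were
        # already compared against the older ref-genes
        assignments, pool = assign_members(no_anchor, new_subs, seqs, cfg, e_cutoff)
        for c, sf in assignments:
            sf.add(c.genome_id, c.candidate_id)
            c.subfamily = sf.subfamily_id
        if not assignments:
            unclassified.extend(pool)
            break
    return subfamilies, unclassified


def classify_collection(candidates_by_genome: Mapping[str, Sequence[RGeneCandidate]],
                        seqs: Mapping[str, str], reference_id: str,
                        cfg: ScoringConfig = DEFAULT_SCORING, e_cutoff: float = 1e-10,
                        seed: int = 0, known_genes: Optional[Sequence[str]] = None,
                        ) -> Tuple[List[Subfamily], List[RGeneCandidate]]:
    """Full classification across genomes; returns (subfamilies, unclassified).

    The reference genome is clustered first; other genomes are assigned
    against its ref-genes in the given (CLI) order; leftovers iterate to a
    fixpoint.
    """
    if reference_id not in candidates_by_genome:
        raise ValueError(f"reference genome {reference_id} not among candidates")
    ref_candidates = list(candidates_by_genome[reference_id])
    groups, ref_unclassified = cluster_reference(ref_candidates, seqs, cfg, e_cutoff)
    subfamilies: List[Subfamily] = []
    for gi, group in enumerate(groups):
        ref = elect_ref_gene(group, seqs, known_genes, seed=seed * 7919 + gi)
        sf = Subfamily(subfamily_id=ref, ref_gene=ref)
        for c in group:
            sf.add(c.genome_id, c.candidate_id)
            c.subfamily = sf.subfamily_id
        subfamilies.append(sf)
    pools: Dict[str, List[RGeneCandidate]] = {}
    for gid in candidates_by_genome:
        if gid == reference_id:
            continue
        if subfamilies:
            assignments, unassigned = assign_members(
                list(candidates_by_genome[gid]), subfamilies, seqs, cfg, e_cutoff)
            for c, sf in assignments:
                sf.add(c.genome_id, c.candidate_id)
                c.subfamily = sf.subfamily_id
            pools[gid] = unassigned
        else:
            pools[gid] = list(candidates_by_genome[gid])
    pools[reference_id] = ref_unclassified
    subfamilies, unclassified = iterate_until_fixpoint(
        pools, seqs, subfamilies, cfg, e_cutoff, seed, known_genes)
    for c in unclassified:
        c.subfamily = None
    return subfamilies, unclassified


def write_subfamilies_tsv(path: str, subfamilies: Sequence[Subfamily],
                          candidates: Mapping[str, RGeneCandidate]) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tgenome_id\tsubfamily_id\tis_ref_gene\tclass\tstatus\n")
        for sf in subfamilies:
            for gid in sorted(sf.members):
                for cid in sf.members[gid]:
                    c = candidates[cid]
                    fh.write(f"{cid}\t{gid}\t{sf.subfamily_id}\t"
                             f"{int(cid == sf.ref_gene)}\t{c.r_class}\t{c.status}\n")
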