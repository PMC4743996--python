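"""End-to-end orchestration: identify → classify → gene models → loci/map →
summaries, over an in-memory multi-genome collection.

This is the programmatic counterpart of running the CLI stages in order and
is what the test-suite and the reproduction script drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .classify import Subfamily, assign_class, classify_collection
from .gene_model import GeneModelAnnotation, GeneRecord, flag_status, intron_phases
from .homology_engine import DEFAULT_SCORING, ScoringConfig
from .identify import RGeneCandidate, TIR_MOTIF, identify_genome, scan_motif
from .locus_map import IntegratedLocus, RLocus, build_integrated_map
from .report import GenomeSummary, PATally, pa_category_tally, summarize_genome
from .synthetic_genome import ValidatingDB


@dataclass
class GenomeInput:
    """One genome's inputs: sequence, annotation, proteome, species tag."""

    genome_id: str
    chromosomes: Mapping[str, str]
    proteome: Mapping[str, str]
    genes: Sequence[GeneRecord]
    species: str = ""


@dataclass
class PipelineResult:
    candidates_by_genome: Dict[str, List[RGeneCandidate]]
    candidate_seqs: Dict[str, str]
    subfamilies: List[Subfamily]
    unclassified: List[RGeneCandidate]
    integrated_map: List[IntegratedLocus]
    loci_by_genome: Dict[str, List[RLocus]]
    unmapped_loci: List[RLocus]
    summaries: Dict[str, GenomeSummary]
    pa_tally: PATally

    def all_candidates(self) -> Dict[str, RGeneCandidate]:
        return {c.candidate_id: c
                for cands in self.candidates_by_genome.values() for c in cands}


def candidate_cds(cand: RGeneCandidate, genome: GenomeInput,
                  by_gene: Mapping[str, GeneRecord]) -> str:
    """Nucleotide sequence used downstream: spliced CDS for annotated
    candidates, raw region sequence for unannotated ones."""
    if cand.source_gene and cand.source_gene in by_gene:
        g = by_gene[cand.source_gene]
        return g.spliced_cds(genome.chromosomes[g.chrom])
    return genome.chromosomes[cand.chrom][cand.span[0] : cand.span[1]]


def run_pipeline(inputs: Sequence[GenomeInput], vdb: ValidatingDB,
                 reference_id: str, seed: int = 0,
                 cfg: ScoringConfig = DEFAULT_SCORING, e_cutoff: float = 1e-10,
                 chain_gap: int = 5000, max_gap: int = 8,
                 include_singletons: bool = True, flank_k: int = 5,
                 min_support: int = 2, merge_tolerance: int = 50_000,
                 known_genes: Optional[Sequence[str]] = None) -> PipelineResult:
    by_id = {g.genome_id: g for g in inputs}
    if reference_id not in by_id:
        raise ValueError(f"unknown reference genome {reference_id}")

    # stage 1: identification triage per genome
    candidates_by_genome: Dict[str, List[RGeneCandidate]] = {}
    seqs: Dict[str, str] = {}
    for g in inputs:
        cands, _seeds = identify_genome(g.proteome, g.chromosomes, g.genes,
                                        vdb, g.genome_id, cfg, e_cutoff, chain_gap)
        candidates_by_genome[g.genome_id] = cands
        by_gene = {x.gene_id: x for x in g.genes}
        for c in cands:
            seqs[c.candidate_id] = candidate_cds(c, g, by_gene)

    # stage 2: subfamily classification (reference genome first)
    subfamilies, unclassified = classify_collection(
        candidates_by_genome, seqs, reference_id, cfg, e_cutoff, seed, known_genes)

    # stage 3: TNL/nTNL class and gene-model-based status refinement
    tir_hits = []
    for g in inputs:
        r_prot = {}
        for c in candidates_by_genome[g.genome_id]:
            if c.source_gene and c.source_gene in g.proteome:
                r_prot[c.source_gene] = g.proteome[c.source_gene]
        if r_prot:
            tir_hits.extend(scan_motif(r_prot, TIR_MOTIF))
    all_cands = {c.candidate_id: c
                 for cands in candidates_by_genome.values() for c in cands}
    for c in all_cands.values():
        assign_class(c, tir_hits)

    gene_records = {g.genome_id: {x.gene_id: x for x in g.genes} for g in inputs}
    for sf in subfamilies:
        ref_cand = all_cands[sf.ref_gene]
        ref_rec = gene_records[ref_cand.genome_id].get(ref_cand.source_gene)
        if ref_rec is not None:
            sf.ref_model = intron_phases(ref_rec)
        sf.r_class = ref_cand.r_class
        if sf.ref_model is not None:
            for cid in sf.all_members():
                all_cands[cid].status = flag_status(seqs[cid], sf.ref_model)

    # stage 4: physical loci, RBH flank synteny, integrated P/A map
    records_by = {g.genome_id: g.genes for g in inputs}
    r_ids_by = {gid: {c.source_gene for c in cands if c.source_gene}
                for gid, cands in candidates_by_genome.items()}
    gene_seqs_by = {}
    for g in inputs:
        gene_seqs_by[g.genome_id] = {
            x.gene_id: x.spliced_cds(g.chromosomes[x.chrom]) for x in g.genes}
    species_of = {g.genome_id: (g.species or g.genome_id) for g in inputs}
    integrated, loci_by, unmapped = build_integrated_map(
        records_by, r_ids_by, gene_seqs_by, reference_id, species_of, cfg,
        e_cutoff, max_gap, include_singletons, flank_k, min_support,
        merge_tolerance)

    # stage 5: summaries
    summaries = {}
    for g in inputs:
        summaries[g.genome_id] = summarize_genome(
            candidates_by_genome[g.genome_id], subfamilies, g.genome_id)
    tally = pa_category_tally(integrated)

    return PipelineResult(candidates_by_genome, seqs, subfamilies, unclassified,
                          integrated, loci_by, unmapped, summaries, tally)
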