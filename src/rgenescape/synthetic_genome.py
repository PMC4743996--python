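"""Multi-genome fixture generator with planted NBS-LRR gene families.

The simulator emulates a small collection of related plant genomes in which
R-gene subfamilies, gene models with controlled intron phases, physical
clusters, partial/pseudogene copies and designed presence/absence (P/A)
polymorphism are all planted with full ground truth, so every pipeline stage
can be tested without any downloads.

Construction model
------------------
* Subfamily ancestors derive from one random protein scaffold whose
  non-motif positions are substituted with probability 0.5 per ancestor and
  whose codons are redrawn uniformly per ancestor.  Two ancestors therefore
  share ~29% of background amino acids and ~37% of background nucleotides:
  far below the similarity-graph linking threshold used for subfamily
  classification, which keeps planted partitions clean.
* Every ancestor carries the canonical NB-ARC-like motif block (lightly
  mutated, so the bundled motif scorer still detects it while the block's
  nucleotide sequence stays divergent between subfamilies); TNL ancestors
  additionally carry the canonical TIR-like block.
* Members mutate from their ancestor at ``mutation_rate`` per site
  (substitutions only; codons that would become premature stops are
  redrawn).  Partial members lose >=40% of the coding sequence from one
  end, dropping the NB-ARC block with probability 0.5; pseudogene members
  carry one planted premature stop.
* Chromosomes are a grid of gene "slots".  Non-R slots are filled with
  decoy genes: validating-database ABC-transporter and kinase proteins
  reverse-translated with a per-slot uniform codon draw, identical across
  genomes up to a small per-genome mutation rate, so flanking-gene synteny
  and reciprocal-best-hit pairing are well defined.
* A locus plan shared between genomes plus per-genome presence flags plants
  P/A polymorphism relative to a designated reference genome.

All randomness flows from explicit seeds; identical spec + seed yields
byte-identical FASTA/GFF3 output.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from random import Random

from Bio.Data.CodonTable import standard_dna_table

from ._common import revcomp, translate, write_fasta
from .gene_model import GeneRecord, write_gff3

# ---------------------------------------------------------------------------
# Canonical motif blocks (fixed protein-level constants of the artifact)
# ---------------------------------------------------------------------------

NB_ARC_BLOCK = "GLPLALKVLGSRLRGKSVEEWRSALSRLSQIPNGEIMDVL"   # 40 aa
TIR_BLOCK = "RYDVFLSFRGEDTRKTFVSHLYEALSRKGI"                 # 30 aa
ABC_CORE = "LSGGQKQRVALARALAMEPKVLLLDEPTSA"                  # 30 aa
KINASE_CORE = "HRDLKPENLLLDSKGVLKIADFGLARLLES"               # 30 aa

# Ancestor protein layout (amino-acid offsets)
ANCESTOR_LENGTH = 420
TIR_SLOT = (10, 10 + len(TIR_BLOCK))
NB_ARC_SLOT = (180, 180 + len(NB_ARC_BLOCK))

VDB_CATEGORIES = ("NBS-LRR", "ABC-transporter", "kinase")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = set(standard_dna_table.stop_codons)
_CODONS_BY_AA: Dict[str, List[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)


# ---------------------------------------------------------------------------
# Low-level sequence construction
# ---------------------------------------------------------------------------

def random_protein(rng: Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def reverse_translate(protein: str, rng: Random) -> str:
    """Back-translate a protein choosing uniformly among synonymous codons."""
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in protein)


def _mutate_protein(protein: str, rate: float, rng: Random,
                    frozen: Sequence[Tuple[int, int, float]] = ()) -> str:
    """Substitute residues at ``rate``; spans in ``frozen`` carry their own
    (usually much lower) rate, protecting motif blocks."""
    out = list(protein)
    for i in range(len(out)):
        r = rate
        for s, e, fr in frozen:
            if s <= i < e:
                r = fr
        if rng.random() < r:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = rng.choice(choices)
    return "".join(out)


def mutate_cds(cds: str, rate: float, rng: Random) -> str:
    """Substitute nucleotides at ``rate``, never creating an internal stop.

    Codons that would become stop codons are redrawn (the terminal codon is
    left alone), so mutation does not silently change a member's status.
    """
    out = list(cds)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = "ACGT".replace(out[i], "")
            out[i] = rng.choice(choices)
    n_codons = len(out) // 3
    for c in range(n_codons - 1):
        while "".join(out[3 * c : 3 * c + 3]) in _STOPS:
            j = 3 * c + rng.randrange(3)
            out[j] = rng.choice("ACGT".replace(out[j], ""))
    return "".join(out)


# ---------------------------------------------------------------------------
# Ancestors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ancestor:
    subfamily_id: str
    tnl: bool
    protein: str
    cds: str  # includes the terminal stop codon


def make_subfamily_ancestors(n_subfamilies: int, tnl_fraction: float = 0.25,
                             seed: int = 0) -> Dict[str, Ancestor]:
    """Generate founder coding sequences for ``n_subfamilies`` subfamilies.

    The first ``round(n * tnl_fraction)`` ancestors are TNL (carry the
    TIR-like block); the rest are nTNL.  All carry the NB-ARC-like block.
    """
    if n_subfamilies < 1:
        raise ValueError("n_subfamilies must be >= 1")
    if not 0.0 <= tnl_fraction <= 1.0:
        raise ValueError("tnl_fraction must lie in [0, 1]")
    rng = Random(seed)
    scaffold = list(random_protein(rng, ANCESTOR_LENGTH))
    scaffold[0] = "M"
    scaffold[TIR_SLOT[0]:TIR_SLOT[1]] = TIR_BLOCK
    scaffold[NB_ARC_SLOT[0]:NB_ARC_SLOT[1]] = NB_ARC_BLOCK
    scaffold = "".join(scaffold)
    n_tnl = int(round(n_subfamilies * tnl_fraction))
    out: Dict[str, Ancestor] = {}
    for i in range(n_subfamilies):
        sf_id = f"SF{i + 1:02d}"
        tnl = i < n_tnl
        # Blocks mutate mildly so the motif scorer keeps a wide margin even
        # after member-level mutation stacks on top; nucleotide-level
        # cross-subfamily similarity is controlled by the redraw loop below,
        # not by block divergence.
        frozen = [(0, 1, 0.0), (*NB_ARC_SLOT, 0.12)] + ([(*TIR_SLOT, 0.10)] if tnl else [])
        # Redraw until the new ancestor shows no residual nucleotide-level
        # similarity to any earlier one; guarantees the postcondition that
        # ancestors sit below the subfamily-linking threshold.
        while True:
            prot = _mutate_protein(scaffold, 0.5, rng, frozen=frozen)
            if not tnl:
                # replace the TIR slot entirely so no residual TIR signal remains
                prot = (prot[: TIR_SLOT[0]] + random_protein(rng, TIR_SLOT[1] - TIR_SLOT[0])
                        + prot[TIR_SLOT[1]:])
            cds = reverse_translate(prot, rng) + rng.choice(sorted(_STOPS))
            if _diverged_from_all(cds, [a.cds for a in out.values()]):
                break
        out[sf_id] = Ancestor(sf_id, tnl, prot, cds)
    return out


def _diverged_from_all(cds: str, others: Sequence[str], e_floor: float = 1e-6) -> bool:
    """True if no earlier ancestor aligns to ``cds`` with E below ``e_floor``.

    The floor sits four orders of magnitude above the pipeline's 1e-10
    linking cutoff, leaving headroom against chance codon collisions.
    """
    from .homology_engine import align_local  # deferred: avoid import cycle
    for other in others:
        hit = align_local(cds, other, alphabet="nucleotide")
        if hit is not None and hit.e_value < e_floor:
            return False
    return True


# ---------------------------------------------------------------------------
# Validating database
# ---------------------------------------------------------------------------

@dataclass
class ValidatingDB:
    """Labelled protein database: NBS-LRR, ABC-transporter and kinase pools."""

    proteins: Dict[str, str]
    categories: Dict[str, str]

    def by_category(self, category: str) -> Dict[str, str]:
        return {pid: seq for pid, seq in self.proteins.items()
                if self.categories[pid] == category}

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for pid, seq in self.proteins.items():
                fh.write(f">{pid} category={self.categories[pid]}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "ValidatingDB":
        proteins: Dict[str, str] = {}
        categories: Dict[str, str] = {}
        name = None
        chunks: List[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if name is not None:
                        proteins[name] = "".join(chunks)
                    parts = line[1:].split()
                    name = parts[0]
                    cat = next((p.split("=", 1)[1] for p in parts[1:]
                                if p.startswith("category=")), None)
                    if cat is None:
                        raise ValueError(f"{path}: record {name} lacks a category= tag")
                    categories[name] = cat
                    chunks = []
                elif line:
                    chunks.append(line)
        if name is not None:
            proteins[name] = "".join(chunks)
        return cls(proteins, categories)


def make_validating_db(n_nbs: int = 40, n_abc: int = 40, n_kinase: int = 40,
                       seed: int = 0) -> ValidatingDB:
    """Build the three-category validating database.

    Each category pool derives from its own random template carrying the
    category's core block, so pools are internally similar and mutually
    dissimilar.  The NBS-LRR pool carries the canonical NB-ARC block shared
    with the subfamily ancestors.  The default pool sizes are a scaled-down
    stand-in for a realistic multi-thousand-protein validating database.
    """
    for name, n in (("n_nbs", n_nbs), ("n_abc", n_abc), ("n_kinase", n_kinase)):
        if n < 1:
            raise ValueError(f"{name} must be >= 1")
    rng = Random(seed)
    spec = (("NBS", "NBS-LRR", NB_ARC_BLOCK, NB_ARC_SLOT[0], n_nbs),
            ("ABC", "ABC-transporter", ABC_CORE, 150, n_abc),
            ("KIN", "kinase", KINASE_CORE, 150, n_kinase))
    proteins: Dict[str, str] = {}
    categories: Dict[str, str] = {}
    for prefix, category, core, offset, n in spec:
        template = list(random_protein(rng, 340))
        template[0] = "M"
        template[offset : offset + len(core)] = core
        template = "".join(template)
        core_span = (offset, offset + len(core))
        for i in range(n):
            pid = f"{prefix}{i + 1:03d}"
            proteins[pid] = _mutate_protein(template, 0.10, rng,
                                            frozen=[(*core_span, 0.02)])
            categories[pid] = category
    return ValidatingDB(proteins, categories)


# ---------------------------------------------------------------------------
# Genome specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubfamilyPlan:
    subfamily_id: str
    n_members: int
    tnl: bool
    n_introns: int
    intron_phases: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.intron_phases) != self.n_introns:
            raise ValueError(f"{self.subfamily_id}: intron_phases length != n_introns")
        if any(p not in (0, 1, 2) for p in self.intron_phases):
            raise ValueError(f"{self.subfamily_id}: intron phases must be in {{0,1,2}}")


@dataclass(frozen=True)
class ClusterPlan:
    """A planted locus: R genes at consecutive slot positions of one chromosome.

    ``gaps[i]`` is the number of decoy (non-R) genes between members i and
    i+1, so member slots are ``start_slot + i + sum(gaps[:i])``.
    """

    label: str
    chrom: int
    start_slot: int
    subfamilies: Tuple[str, ...]
    gaps: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.gaps) != max(len(self.subfamilies) - 1, 0):
            raise ValueError(f"{self.label}: need {len(self.subfamilies) - 1} gaps")

    @property
    def slots(self) -> List[int]:
        out, pos = [], self.start_slot
        for i, _sf in enumerate(self.subfamilies):
            out.append(pos)
            if i < len(self.gaps):
                pos += self.gaps[i] + 1
        return out


@dataclass(frozen=True)
class GenomeSpec:
    genome_id: str
    n_chromosomes: int
    chromosome_length: int
    subfamily_plan: Tuple[SubfamilyPlan, ...]
    cluster_plan: Tuple[ClusterPlan, ...]
    pa_plan: Mapping[str, bool]           # locus label -> present in this genome
    fraction_partial: float = 0.0
    fraction_pseudogene: float = 0.0
    mutation_rate: float = 0.02
    seed: int = 0
    species: str = ""
    slot_size: int = 8000
    decoy_mutation_rate: float = 0.01

    @property
    def slots_per_chromosome(self) -> int:
        return self.chromosome_length // self.slot_size

    def present_clusters(self) -> List[ClusterPlan]:
        return [c for c in self.cluster_plan if self.pa_plan.get(c.label, True)]

    def validate(self, ancestors: Mapping[str, Ancestor]) -> None:
        n_slots = self.slots_per_chromosome
        occupied: Dict[Tuple[int, int], str] = {}
        for c in self.cluster_plan:
            if not 0 <= c.chrom < self.n_chromosomes:
                raise ValueError(f"{c.label}: chromosome {c.chrom} out of range")
            for s in c.slots:
                if s >= n_slots:
                    raise ValueError(f"{c.label}: slot {s} does not fit on a "
                                     f"{n_slots}-slot chromosome (overfull)")
                key = (c.chrom, s)
                if key in occupied:
                    raise ValueError(f"{c.label}: slot {key} already used by {occupied[key]}")
                occupied[key] = c.label
            for sf in c.subfamilies:
                if sf not in ancestors:
                    raise ValueError(f"{c.label}: unknown subfamily {sf}")
        counts: Dict[str, int] = {}
        for c in self.present_clusters():
            for sf in c.subfamilies:
                counts[sf] = counts.get(sf, 0) + 1
        for plan in self.subfamily_plan:
            if plan.tnl != ancestors[plan.subfamily_id].tnl:
                raise ValueError(f"{plan.subfamily_id}: tnl flag disagrees with ancestor")
            if counts.get(plan.subfamily_id, 0) != plan.n_members:
                raise ValueError(
                    f"{plan.subfamily_id}: cluster plan places "
                    f"{counts.get(plan.subfamily_id, 0)} members, plan says {plan.n_members}")


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Planted ground truth: one row per emitted gene; one per planned locus."""

    genes: pd.DataFrame   # gene_id, genome_id, chrom, start, end, strand, is_r,
                          # subfamily, r_class, status, locus_label, slot
    loci: pd.DataFrame    # locus_label, genome_id, chrom, present, n_members, gene_ids

    def write(self, genes_path: str, loci_path: str) -> None:
        self.genes.to_csv(genes_path, sep="\t", index=False)
        self.loci.to_csv(loci_path, sep="\t", index=False)

    def r_gene_ids(self) -> List[str]:
        return sorted(self.genes.loc[self.genes.is_r, "gene_id"])


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _intron_offsets(cds_len: int, phases: Sequence[int]) -> List[int]:
    """Cumulative coding offsets for introns realising the requested phases."""
    k = len(phases)
    offsets = []
    for i, phase in enumerate(phases):
        base = cds_len * (i + 1) // (k + 1)
        off = 3 * (base // 3) + phase
        offsets.append(off)
    for a, b in zip(offsets, offsets[1:]):
        if b <= a:
            raise ValueError("intron phase plan inconsistent with coding length")
    if offsets and (offsets[0] < 3 or offsets[-1] > cds_len - 3):
        raise ValueError("intron offsets fall outside the coding sequence")
    return offsets


def _truncate_partial(cds: str, tnl: bool, rng: Random) -> Tuple[str, bool]:
    """5'- or 3'-truncate a CDS, losing the NB-ARC block with probability 0.5.

    Cut points are codon-aligned so the retained segment stays in frame.
    Returns (truncated CDS, block_lost).
    """
    lose_block = rng.random() < 0.5
    block_start_nt = 3 * NB_ARC_SLOT[0]
    block_end_nt = 3 * NB_ARC_SLOT[1]
    if lose_block:
        # keep the 3' tail starting past the block (~43% of the CDS)
        cut = 3 * ((block_end_nt + 60) // 3)
        return cds[cut:], True
    # keep the 5' portion through the block (~60% of the CDS)
    cut = 3 * ((block_end_nt + 99) // 3)
    return cds[:cut], False


@dataclass
class PlantedGenome:
    genome_id: str
    species: str
    chromosomes: Dict[str, str]
    genes: List[GeneRecord]
    proteome: Dict[str, str]
    truth: TruthTable

    def write(self, outdir: str | os.PathLike) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / f"{self.genome_id}.genome.fa",
            "gff3": outdir / f"{self.genome_id}.gff3",
            "proteome": outdir / f"{self.genome_id}.proteome.fa",
            "truth_genes": outdir / f"{self.genome_id}.truth_genes.tsv",
            "truth_loci": outdir / f"{self.genome_id}.truth_loci.tsv",
        }
        write_fasta(paths["genome"], self.chromosomes)
        write_gff3(str(paths["gff3"]), self.genes)
        write_fasta(paths["proteome"], self.proteome)
        self.truth.write(str(paths["truth_genes"]), str(paths["truth_loci"]))
        return paths


def _decoy_record(vdb: ValidatingDB, chrom_idx: int, slot: int) -> Tuple[str, str, str]:
    """Deterministic decoy choice and base CDS for a (chromosome, slot) cell.

    The base CDS depends only on the validating-DB record and the cell, so
    the same decoy gene appears at the same syntenic position of every
    genome built against the same database.
    """
    pool = sorted(pid for pid, cat in vdb.categories.items() if cat != "NBS-LRR")
    pid = pool[(chrom_idx * 101 + slot) % len(pool)]
    cell_rng = Random(zlib.crc32(f"{pid}:{chrom_idx}:{slot}".encode()) & 0x7FFFFFFF)
    cds = reverse_translate(vdb.proteins[pid], cell_rng) + cell_rng.choice(sorted(_STOPS))
    return pid, vdb.categories[pid], cds


def plant_genome(spec: GenomeSpec, ancestors: Mapping[str, Ancestor],
                 vdb: Optional[ValidatingDB] = None) -> PlantedGenome:
    """Emit one genome (FASTA + GFF3 + proteome + truth) from its spec."""
    if vdb is None:
        vdb = make_validating_db(seed=0)
    spec.validate(ancestors)
    rng = Random(spec.seed)
    plans_by_sf = {p.subfamily_id: p for p in spec.subfamily_plan}

    # map (chrom, slot) -> (locus label, subfamily) for present loci
    r_slots: Dict[Tuple[int, int], Tuple[str, str]] = {}
    for c in spec.present_clusters():
        for s, sf in zip(c.slots, c.subfamilies):
            r_slots[(c.chrom, s)] = (c.label, sf)

    chromosomes: Dict[str, str] = {}
    genes: List[GeneRecord] = []
    proteome: Dict[str, str] = {}
    truth_rows: List[dict] = []
    locus_members: Dict[str, List[str]] = {}
    seen_subfamilies: set = set()
    counter = 0

    n_slots = spec.slots_per_chromosome
    for ci in range(spec.n_chromosomes):
        chrom_name = f"{spec.genome_id}_chr{ci + 1}"
        parts: List[str] = []
        pos = 0
        for s in range(n_slots):
            counter += 1
            gene_id = f"{spec.genome_id}g{counter:04d}"
            strand = rng.choice("+-")
            if (ci, s) in r_slots:
                locus_label, sf = r_slots[(ci, s)]
                anc = ancestors[sf]
                plan = plans_by_sf.get(sf)
                phases = plan.intron_phases if plan else ()
                cds = mutate_cds(anc.cds, spec.mutation_rate, rng)
                draw = rng.random()
                if sf not in seen_subfamilies:
                    # the first planted copy of each subfamily stays intact,
                    # so every subfamily present in a genome keeps at least
                    # one seedable full-length member
                    seen_subfamilies.add(sf)
                    draw = 1.0
                if draw < spec.fraction_partial:
                    status = "partial"
                    cds, _block_lost = _truncate_partial(cds, anc.tnl, rng)
                    offsets: List[int] = []
                elif draw < spec.fraction_partial + spec.fraction_pseudogene:
                    status = "pseudogene"
                    stop_codon = int(len(cds) // 3 * rng.uniform(0.30, 0.60))
                    cds = (cds[: 3 * stop_codon] + "TGA" + cds[3 * stop_codon + 3:])
                    offsets = _intron_offsets(len(cds), phases)
                else:
                    status = "intact"
                    offsets = _intron_offsets(len(cds), phases)
                is_r, subfamily = True, sf
                r_class = "TNL" if anc.tnl else "nTNL"
            else:
                _pid, _cat, base = _decoy_record(vdb, ci, s)
                cds = mutate_cds(base, spec.decoy_mutation_rate, rng)
                is_r, subfamily, r_class, status, locus_label = False, "", "", "decoy", ""
                offsets = []

            # realise the exon/intron body
            bounds = [0] + list(offsets) + [len(cds)]
            exons = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
            body_parts: List[str] = []
            seg_bounds: List[Tuple[int, int]] = []
            off = 0
            for i, exon in enumerate(exons):
                seg_bounds.append((off, off + len(exon)))
                body_parts.append(exon)
                off += len(exon)
                if i < len(exons) - 1:
                    intron = "GT" + "".join(rng.choices("ACGT", k=rng.randrange(86, 127))) + "AG"
                    body_parts.append(intron)
                    off += len(intron)
            body = "".join(body_parts)
            if strand == "-":
                body_seq = revcomp(body)
                segs = [(len(body) - e, len(body) - s) for s, e in seg_bounds]
            else:
                body_seq = body
                segs = seg_bounds

            spacer_len = rng.randrange(300, 500)
            if spacer_len + len(body) > spec.slot_size:
                raise ValueError(f"{gene_id}: gene body does not fit in slot")
            gene_start = pos + spacer_len
            parts.append("".join(rng.choices("ACGT", k=spacer_len)))
            parts.append(body_seq)
            tail = spec.slot_size - spacer_len - len(body)
            parts.append("".join(rng.choices("ACGT", k=tail)))
            pos += spec.slot_size

            record = GeneRecord(gene_id, chrom_name, gene_start, gene_start + len(body),
                                strand, [(gene_start + a, gene_start + b) for a, b in segs])
            genes.append(record)
            proteome[gene_id] = translate(cds, to_stop=True)
            if is_r and locus_label:
                locus_members.setdefault(locus_label, []).append(gene_id)
            truth_rows.append(dict(
                gene_id=gene_id, genome_id=spec.genome_id, chrom=chrom_name,
                start=gene_start, end=gene_start + len(body), strand=strand,
                is_r=is_r, subfamily=subfamily, r_class=r_class, status=status,
                locus_label=locus_label, slot=s,
            ))
        chromosomes[chrom_name] = "".join(parts)

    loci_rows = []
    for c in spec.cluster_plan:
        present = spec.pa_plan.get(c.label, True)
        members = locus_members.get(c.label, [])
        loci_rows.append(dict(
            locus_label=c.label, genome_id=spec.genome_id,
            chrom=f"{spec.genome_id}_chr{c.chrom + 1}", present=present,
            n_members=len(members), gene_ids=",".join(members),
        ))
    truth = TruthTable(pd.DataFrame(truth_rows), pd.DataFrame(loci_rows))
    return PlantedGenome(spec.genome_id, spec.species or spec.genome_id,
                         chromosomes, genes, proteome, truth)


# ---------------------------------------------------------------------------
# The bundled multi-genome study fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureCollection:
    ancestors: Dict[str, Ancestor]
    vdb: ValidatingDB
    genomes: List[PlantedGenome]
    reference_id: str

    @property
    def by_id(self) -> Dict[str, PlantedGenome]:
        return {g.genome_id: g for g in self.genomes}

    def combined_truth_genes(self) -> pd.DataFrame:
        return pd.concat([g.truth.genes for g in self.genomes], ignore_index=True)


# shared locus template: label, chrom, start slot, member subfamilies, gaps
_TEMPLATE_CLUSTERS: Tuple[Tuple[str, int, int, Tuple[str, ...], Tuple[int, ...]], ...] = (
    ("L01", 0, 2, ("SF01", "SF01", "SF01"), (2, 8)),
    ("L02", 0, 30, ("SF02", "SF02"), (0,)),
    ("L08", 0, 45, ("SF06", "SF06", "SF06"), (0, 1)),
    ("L03", 1, 3, ("SF03", "SF03"), (1,)),
    ("L04", 1, 20, ("SF04", "SF04", "SF04"), (0, 1)),
    ("L05", 1, 38, ("SF05",), ()),
    ("L09", 1, 52, ("SF01", "SF01"), (0,)),
    ("L06", 2, 4, ("SF02", "SF02"), (3,)),
    ("L07", 2, 24, ("SF05", "SF05"), (8,)),
    ("L10", 2, 48, ("SF03", "SF03"), (1,)),
)

# presence per genome (the planted P/A polymorphism, reference GA)
_TEMPLATE_PRESENCE: Mapping[str, Mapping[str, bool]] = {
    "GA": dict(L01=True, L02=True, L03=True, L04=True, L05=True, L06=True,
               L07=True, L08=False, L09=True, L10=False),
    "GB": dict(L01=True, L02=False, L03=True, L04=True, L05=True, L06=True,
               L07=True, L08=True, L09=False, L10=False),
    "GC": dict(L01=True, L02=True, L03=True, L04=True, L05=True, L06=True,
               L07=False, L08=False, L09=False, L10=True),
}

_SUBFAMILY_STRUCTURE = {
    # subfamily -> (n_introns, phases); TNL subfamilies get 4 exons, most
    # nTNL subfamilies none or one intron, mirroring the field's contrast
    # between intron-rich TNLs and intron-poor non-TNLs.
    "SF01": (3, (0, 1, 2)),   # TNL
    "SF02": (3, (0, 0, 1)),   # TNL
    "SF03": (0, ()),
    "SF04": (1, (1,)),
    "SF05": (0, ()),
    "SF06": (2, (0, 2)),
}


def default_fixture(seed: int = 0, mutation_rate: float = 0.03,
                    fraction_partial: float = 0.15,
                    fraction_pseudogene: float = 0.10,
                    genome_ids: Sequence[str] = ("GA", "GB", "GC")) -> FixtureCollection:
    """Build the standard three-genome study fixture with planted truth.

    Six subfamilies (two TNL), ten planned loci including singletons, planted
    P/A polymorphism relative to the reference genome GA, and partial and
    pseudogene copies at the given fractions.
    """
    ancestors = make_subfamily_ancestors(6, tnl_fraction=2 / 6, seed=seed * 977 + 11)
    vdb = make_validating_db(40, 40, 40, seed=seed * 613 + 29)
    genomes: List[PlantedGenome] = []
    for k, gid in enumerate(genome_ids):
        presence = _TEMPLATE_PRESENCE[gid]
        counts: Dict[str, int] = {}
        for label, chrom, start, sfs, gaps in _TEMPLATE_CLUSTERS:
            if presence[label]:
                for sf in sfs:
                    counts[sf] = counts.get(sf, 0) + 1
        sub_plans = tuple(
            SubfamilyPlan(sf, counts.get(sf, 0), ancestors[sf].tnl,
                          *_SUBFAMILY_STRUCTURE[sf])
            for sf in sorted(_SUBFAMILY_STRUCTURE) if counts.get(sf, 0) > 0)
        clusters = tuple(ClusterPlan(label, chrom, start, sfs, gaps)
                         for label, chrom, start, sfs, gaps in _TEMPLATE_CLUSTERS)
        spec = GenomeSpec(
            genome_id=gid, n_chromosomes=3, chromosome_length=480_000,
            subfamily_plan=sub_plans, cluster_plan=clusters, pa_plan=presence,
            fraction_partial=fraction_partial, fraction_pseudogene=fraction_pseudogene,
            mutation_rate=mutation_rate, seed=seed * 389 + 7 * (k + 1),
            species=gid[-1], slot_size=8000)
        genomes.append(plant_genome(spec, ancestors, vdb))
    return FixtureCollection(ancestors, vdb, genomes, reference_id=genome_ids[0])
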