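"""Gene models: exon/intron structure, intron phase, and status flagging.

Intron phase follows the positional definition used throughout comparative
R-gene work: a phase-0 intron sits before the first nucleotide of a codon,
phase-1 before the second, phase-2 before the third.  Equivalently the phase
of intron *i* is the cumulative coding length upstream of it modulo 3.  The
GFF3 ``phase`` column (frame of the next codon within a CDS segment) is a
different convention and is deliberately ignored and recomputed.

Coordinates are 0-based half-open internally; GFF3 is 1-based inclusive and
converted at the read/write boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._common import revcomp, translate


@dataclass
class GeneRecord:
    """One annotated gene: coordinates, strand and CDS exon segments."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_segments: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds_segments = sorted(self.cds_segments)

    @property
    def transcription_order_segments(self) -> List[Tuple[int, int]]:
        """CDS segments ordered 5'→3' on the coding strand."""
        return self.cds_segments if self.strand == "+" else self.cds_segments[::-1]

    def spliced_cds(self, chrom_seq: str) -> str:
        """Spliced coding sequence on the coding strand."""
        parts = [chrom_seq[s:e] for s, e in self.cds_segments]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class GeneModelAnnotation:
    """Exon lengths (transcription order), intron phases and positions."""

    gene_id: str
    exon_lengths: List[int]
    intron_phases: List[int]
    intron_positions: List[int]  # cumulative coding offset of each intron

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    @property
    def coding_length(self) -> int:
        return sum(self.exon_lengths)


def intron_phases(gene: GeneRecord) -> GeneModelAnnotation:
    """Annotate exon lengths and intron phases from a gene's CDS segments.

    The phase of each intron is the cumulative coding length before it
    modulo 3.  Minus-strand segment order is flipped to transcription order
    before computing.
    """
    segs = gene.transcription_order_segments
    if not segs:
        raise ValueError(f"{gene.gene_id}: gene has no CDS segments")
    for (s1, e1), (s2, e2) in zip(gene.cds_segments, gene.cds_segments[1:]):
        if s2 < e1:
            raise ValueError(f"{gene.gene_id}: overlapping CDS segments")
    lengths = [e - s for s, e in segs]
    if any(l <= 0 for l in lengths):
        raise ValueError(f"{gene.gene_id}: empty CDS segment")
    positions: List[int] = []
    acc = 0
    for l in lengths[:-1]:
        acc += l
        positions.append(acc)
    phases = [p % 3 for p in positions]
    return GeneModelAnnotation(gene.gene_id, lengths, phases, positions)


@dataclass
class StructureReport:
    """Pairwise intron-structure comparison of a member against a reference."""

    matched: List[Tuple[int, int, bool]]  # (ref intron idx, member intron idx, phase equal)
    missing: List[int]                    # ref intron indices with no member counterpart
    extra: List[int]                      # member intron indices with no ref counterpart

    @property
    def all_phases_match(self) -> bool:
        return all(eq for _, _, eq in self.matched) and not self.missing and not self.extra


def compare_model(member: GeneModelAnnotation, ref: GeneModelAnnotation,
                  tolerance: int = 6) -> StructureReport:
    """Match introns of a member against a reference model.

    Introns are paired greedily by nearest cumulative coding offset; pairs
    further apart than ``tolerance`` nucleotides stay unmatched.  The default
    tolerance absorbs small indels without cross-matching neighbouring
    introns.
    """
    candidates = []
    for i, rp in enumerate(ref.intron_positions):
        for j, mp in enumerate(member.intron_positions):
            d = abs(rp - mp)
            if d <= tolerance:
                candidates.append((d, i, j))
    candidates.sort()
    used_ref: set = set()
    used_mem: set = set()
    matched: List[Tuple[int, int, bool]] = []
    for d, i, j in candidates:
        if i in used_ref or j in used_mem:
            continue
        used_ref.add(i)
        used_mem.add(j)
        matched.append((i, j, ref.intron_phases[i] == member.intron_phases[j]))
    matched.sort()
    missing = [i for i in range(len(ref.intron_positions)) if i not in used_ref]
    extra = [j for j in range(len(member.intron_positions)) if j not in used_mem]
    return StructureReport(matched, missing, extra)


def flag_status(member_cds: str, ref: GeneModelAnnotation,
                partial_fraction: float = 0.70) -> str:
    """Classify a member against its subfamily reference model.

    A premature stop codon in the member's reading frame makes it a
    pseudogene (pseudogene takes precedence over partial).  A coding length
    below ``partial_fraction`` of the reference coding length makes it
    partial.  Anything else is intact.  The 70% default separates genuinely
    truncated copies from members that merely accumulated substitutions.
    """
    if len(member_cds) >= 3:
        prot = translate(member_cds)
        stop = prot.find("*")
        if 0 <= stop < len(prot) - 1:
            return "pseudogene"
    if len(member_cds) < partial_fraction * ref.coding_length:
        return "partial"
    return "intact"


# ---------------------------------------------------------------------------
# GFF3 reading / writing (gene -> mRNA -> CDS)
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> Dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str) -> List[GeneRecord]:
    """Read gene records (gene/mRNA/CDS hierarchy) from a GFF3 file.

    Returns genes sorted by (chromosome, start).  CDS features are attached
    to their gene through the mRNA Parent chain.
    """
    genes: Dict[str, GeneRecord] = {}
    mrna_to_gene: Dict[str, str] = {}
    pending_cds: List[Tuple[str, str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: malformed GFF3 row: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f
            a = _parse_attributes(attrs)
            s, e = int(start) - 1, int(end)
            if ftype == "gene":
                gid = a["ID"]
                genes[gid] = GeneRecord(gid, chrom, s, e, strand, [])
            elif ftype == "mRNA":
                mrna_to_gene[a["ID"]] = a["Parent"]
            elif ftype == "CDS":
                pending_cds.append((a["Parent"], chrom, s, e))
    for parent, chrom, s, e in pending_cds:
        gid = mrna_to_gene.get(parent, parent)
        if gid not in genes:
            genes[gid] = GeneRecord(gid, chrom, s, e, "+", [])
        genes[gid].cds_segments.append((s, e))
    for g in genes.values():
        g.cds_segments.sort()
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def write_gff3(path: str, genes: Sequence[GeneRecord], source: str = "rgenescape") -> None:
    """Write gene/mRNA/CDS features, with the GFF3 phase column populated.

    The phase column carries the GFF3 frame convention (bases to skip to the
    next codon start), which differs from the positional intron phase this
    package analyses.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write("\t".join([g.chrom, source, "gene", str(g.start + 1), str(g.end),
                                ".", g.strand, ".", f"ID={g.gene_id}"]) + "\n")
            mrna = f"{g.gene_id}.1"
            fh.write("\t".join([g.chrom, source, "mRNA", str(g.start + 1), str(g.end),
                                ".", g.strand, ".", f"ID={mrna};Parent={g.gene_id}"]) + "\n")
            acc = 0
            rows = []
            for s, e in g.transcription_order_segments:
                frame = (3 - acc % 3) % 3
                acc += e - s
                rows.append((s, e, frame))
            rows.sort()  # emit in coordinate order
            for s, e, frame in rows:
                fh.write("\t".join([g.chrom, source, "CDS", str(s + 1), str(e),
                                    ".", g.strand, str(frame), f"ID=cds-{mrna};Parent={mrna}"]) + "\n")


def write_model_tsv(path: str, annotations: Sequence[GeneModelAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_exons\texon_lengths\tintron_phases\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.n_exons}\t"
                     f"{','.join(map(str, a.exon_lengths))}\t"
                     f"{','.join(map(str, a.intron_phases))}\n")
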