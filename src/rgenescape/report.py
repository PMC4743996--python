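"""Summary tables: per-chromosome R-gene counts, per-subfamily statistics,
top-k subfamily shares and presence/absence map tallies.

All reported means and percentages round half-up (not banker's) to one
decimal, independent of locale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence

from .classify import Subfamily
from .identify import RGeneCandidate
from .locus_map import IntegratedLocus, RLocus

_UNANCHORED = re.compile(r"(?i)(chr0*0|scaffold|^un)")


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GenomeSummary:
    genome_id: str
    per_chromosome: Dict[str, int]
    unanchored: int
    total: int
    n_subfamilies_detected: int
    n_homologous_to_refs: int
    n_not_homologous: int
    n_tnl: int
    n_ntnl: int
    n_singleton_subfamilies: int
    n_subfamilies_ge_10: int
    mean_subfamily_size: float
    degenerate: bool = False   # set when no subfamily was detected


def summarize_genome(candidates: Sequence[RGeneCandidate],
                     subfamilies: Sequence[Subfamily],
                     genome_id: str) -> GenomeSummary:
    """Populate the per-genome summary row.

    ``candidates`` are all validated R genes of the genome (classified or
    not); subfamily statistics cover only genes homologous to a ref-gene,
    mirroring summary tables that separate the two.  Chromosomes whose name
    marks them as unanchored scaffolds count into a separate bucket.
    """
    mine = [c for c in candidates if c.genome_id == genome_id]
    per_chrom: Dict[str, int] = {}
    unanchored = 0
    for c in mine:
        if _UNANCHORED.search(c.chrom):
            unanchored += 1
        else:
            per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
    sizes = [len(sf.members.get(genome_id, [])) for sf in subfamilies]
    sizes = [s for s in sizes if s > 0]
    classified_ids = {m for sf in subfamilies for m in sf.members.get(genome_id, [])}
    classified = [c for c in mine if c.candidate_id in classified_ids]
    n_hom = len(classified)
    n_tnl = sum(1 for c in classified if c.r_class == "TNL")
    n_sub = len(sizes)
    mean = round_half_up(n_hom / n_sub, 1) if n_sub else 0.0
    return GenomeSummary(
        genome_id=genome_id,
        per_chromosome=dict(sorted(per_chrom.items())),
        unanchored=unanchored,
        total=len(mine),
        n_subfamilies_detected=n_sub,
        n_homologous_to_refs=n_hom,
        n_not_homologous=len(mine) - n_hom,
        n_tnl=n_tnl,
        n_ntnl=n_hom - n_tnl,
        n_singleton_subfamilies=sum(1 for s in sizes if s == 1),
        n_subfamilies_ge_10=sum(1 for s in sizes if s >= 10),
        mean_subfamily_size=mean,
        degenerate=(n_sub == 0),
    )


def top_k_share(subfamily_sizes: Sequence[int], total: int, k: int) -> float:
    """Percentage of all R genes contributed by the k largest subfamilies.

    Half-up, one decimal.  Ties at rank k do not affect the share (sizes are
    sorted descending and the k largest summed).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if k > len(subfamily_sizes):
        raise ValueError("k exceeds the number of subfamilies")
    top = sum(sorted(subfamily_sizes, reverse=True)[:k])
    return round_half_up(100.0 * top / total, 1)


@dataclass
class PATally:
    n_total: int
    n_shared_all: int
    n_polymorphic: int          # includes species-specific loci
    n_species_specific: int
    per_species: Dict[str, int] = field(default_factory=dict)


def pa_category_tally(entries: Sequence[IntegratedLocus]) -> PATally:
    """Count integrated-map entries per presence/absence category.

    ``n_polymorphic`` counts every locus not shared by all species, so
    species-specific loci are a subset of it and
    total = shared_all + polymorphic.
    """
    shared = sum(1 for m in entries if m.category == "shared_all")
    specific = [m for m in entries if m.category == "species_specific"]
    other_poly = sum(1 for m in entries if m.category == "polymorphic")
    per_species: Dict[str, int] = {}
    for m in specific:
        per_species[m.specific_species] = per_species.get(m.specific_species, 0) + 1
    return PATally(
        n_total=len(entries),
        n_shared_all=shared,
        n_polymorphic=other_poly + len(specific),
        n_species_specific=len(specific),
        per_species=dict(sorted(per_species.items())),
    )


def write_summary_tsv(path: str, summaries: Sequence[GenomeSummary]) -> None:
    chroms = sorted({c for s in summaries for c in s.per_chromosome})
    with open(path, "w") as fh:
        cols = (["genome_id"] + chroms
                + ["unanchored", "total", "n_subfamilies", "n_homologous",
                   "n_not_homologous", "n_tnl", "n_ntnl", "n_singletons",
                   "n_ge_10", "mean_subfamily_size"])
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            row = [s.genome_id] + [str(s.per_chromosome.get(c, 0)) for c in chroms]
            row += [str(s.unanchored), str(s.total), str(s.n_subfamilies_detected),
                    str(s.n_homologous_to_refs), str(s.n_not_homologous),
                    str(s.n_tnl), str(s.n_ntnl), str(s.n_singleton_subfamilies),
                    str(s.n_subfamilies_ge_10), f"{s.mean_subfamily_size:.1f}"]
            fh.write("\t".join(row) + "\n")
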