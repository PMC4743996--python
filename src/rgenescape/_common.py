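"""Shared sequence helpers: FASTA IO, alphabets, translation.

Coordinates everywhere in this package are 0-based half-open on the forward
strand; files in standard formats (GFF3, BLAST outfmt-6) are converted at the
read/write boundary.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping, Tuple

from Bio.Seq import Seq

NT_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def guess_alphabet(seq: str) -> str:
    """Classify a sequence as 'nucleotide' or 'protein'.

    A sequence consisting only of A/C/G/T/N is taken as nucleotide; anything
    else as protein.  Empty sequences are rejected.
    """
    if not seq:
        raise ValueError("empty sequence")
    letters = set(seq.upper())
    if letters <= NT_ALPHABET:
        return "nucleotide"
    if letters <= PROTEIN_ALPHABET:
        return "protein"
    raise ValueError(f"unrecognised characters in sequence: {letters - PROTEIN_ALPHABET}")


def translate(cds: str, to_stop: bool = False) -> str:
    """Translate a CDS with the standard genetic code.

    Trailing incomplete codons are dropped.  With ``to_stop`` the translation
    ends before the first stop codon; otherwise stops appear as '*'.
    """
    if len(cds) < 3:
        raise ValueError("sequence shorter than one codon")
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=to_stop))


def six_frame_translations(chrom_seq: str) -> Dict[int, str]:
    """Return {frame: translation} for frames +1..+3 and -1..-3.

    Frame +k translates the forward strand starting at offset k-1; frame -k
    translates the reverse complement starting at offset k-1.  Stop codons
    appear as '*'.
    """
    out: Dict[int, str] = {}
    rc = revcomp(chrom_seq)
    for off in range(3):
        for strand, seq in ((+1, chrom_seq), (-1, rc)):
            sub = seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                out[strand * (off + 1)] = str(Seq(sub).translate())
            else:
                out[strand * (off + 1)] = ""
    return out


def frame_to_genomic(frame: int, aa_start: int, aa_end: int, chrom_len: int) -> Tuple[int, int]:
    """Map an amino-acid span in a reading frame to forward-strand coordinates."""
    off = abs(frame) - 1
    nt_start = off + 3 * aa_start
    nt_end = off + 3 * aa_end
    if frame > 0:
        return nt_start, nt_end
    return chrom_len - nt_end, chrom_len - nt_start


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    records: Dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        records[name] = "".join(chunks)
    return records


def read_fasta_descriptions(path: str | os.PathLike) -> Dict[str, str]:
    """Read FASTA headers into {id: full description line}."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                parts = line[1:].rstrip("\n").split(None, 1)
                out[parts[0]] = parts[1] if len(parts) > 1 else ""
    return out


def write_fasta(path: str | os.PathLike, records: Mapping[str, str] | Iterable[Tuple[str, str]],
                width: int = 70) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
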