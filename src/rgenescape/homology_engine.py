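"""Desk-scale pairwise similarity search standing in for BLASTP/BLASTN/TBLASTN.

The engine computes Smith-Waterman-optimal local alignments with affine gap
penalties (via Biopython's C-accelerated :class:`Bio.Align.PairwiseAligner`)
and calibrates them to bit scores and E-values with fixed per-matrix
Karlin-Altschul constants:

    bit = (lambda * raw - ln K) / ln 2
    E   = m * n * 2**(-bit)

with m, n the lengths of the two sequences being compared.  The search space
is per-pair rather than database-wide: analyses in this package only ever use
a fixed E-value cutoff, so relative calibration suffices.  This is a
deliberate simplification relative to BLAST statistics.

A gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from ._common import frame_to_genomic, guess_alphabet, six_frame_translations

OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

# Fixed Karlin-Altschul constants per scoring system (gapped values in the
# style of BLAST's lookup tables for BLOSUM62 11/1 and blastn +2/-3).
_PROTEIN_LAMBDA, _PROTEIN_K = 0.267, 0.041
_NT_LAMBDA, _NT_K = 0.625, 0.41


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring parameters for local alignment and E-value calibration."""

    protein_matrix: str = "BLOSUM62"
    nt_match: float = 2.0
    nt_mismatch: float = -3.0
    protein_gap_open: float = 11.0
    protein_gap_extend: float = 1.0
    nt_gap_open: float = 5.0
    nt_gap_extend: float = 2.0
    protein_lambda: float = _PROTEIN_LAMBDA
    protein_k: float = _PROTEIN_K
    nt_lambda: float = _NT_LAMBDA
    nt_k: float = _NT_K

    def __post_init__(self) -> None:
        for name in ("protein_gap_open", "protein_gap_extend", "nt_gap_open", "nt_gap_extend"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("protein_lambda", "protein_k", "nt_lambda", "nt_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def constants(self, alphabet: str) -> Tuple[float, float]:
        if alphabet == "protein":
            return self.protein_lambda, self.protein_k
        return self.nt_lambda, self.nt_k

    def bit_score(self, raw: float, alphabet: str) -> float:
        lam, k = self.constants(alphabet)
        return (lam * raw - math.log(k)) / math.log(2.0)

    def e_value(self, raw: float, m: int, n: int, alphabet: str) -> float:
        return m * n * 2.0 ** (-self.bit_score(raw, alphabet))


DEFAULT_SCORING = ScoringConfig()


@dataclass
class SimilarityHit:
    """Best local alignment between a query and a subject.

    Spans are 0-based half-open.  ``frame`` is 0 for untranslated
    comparisons and +1..+3 / -1..-3 for translated searches (sign gives the
    subject strand).
    """

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    e_value: float
    percent_identity: float
    query_span: Tuple[int, int]
    subject_span: Tuple[int, int]
    frame: int = 0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must lie in [0, 100]")


def _nt_matrix(cfg: ScoringConfig) -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = cfg.nt_match if a == b else cfg.nt_mismatch
    # N is neutral against everything (score 0 is the Array default).
    return m


def _protein_matrix(cfg: ScoringConfig) -> substitution_matrices.Array:
    m = substitution_matrices.load(cfg.protein_matrix).copy()
    alphabet = m.alphabet
    for a in alphabet:
        # X neutral; '*' forbidding so alignments never cross a stop codon.
        if "X" in alphabet:
            m[a, "X"] = m["X", a] = 0.0
        if "*" in alphabet:
            m[a, "*"] = m["*", a] = -1000.0
    return m


def _make_aligner(cfg: ScoringConfig, alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if alphabet == "protein":
        aligner.substitution_matrix = _protein_matrix(cfg)
        open_, ext = cfg.protein_gap_open, cfg.protein_gap_extend
    else:
        aligner.substitution_matrix = _nt_matrix(cfg)
        open_, ext = cfg.nt_gap_open, cfg.nt_gap_extend
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one; cost(L) = open + L * extend.
    aligner.open_gap_score = -(open_ + ext)
    aligner.extend_gap_score = -ext
    return aligner


class _AlignerCache:
    """Reuse aligner objects; building substitution matrices is not free."""

    def __init__(self) -> None:
        self._cache: Dict[Tuple[ScoringConfig, str], Align.PairwiseAligner] = {}

    def get(self, cfg: ScoringConfig, alphabet: str) -> Align.PairwiseAligner:
        key = (cfg, alphabet)
        if key not in self._cache:
            self._cache[key] = _make_aligner(cfg, alphabet)
        return self._cache[key]


_ALIGNERS = _AlignerCache()


def _identity_and_spans(alignment) -> Tuple[float, Tuple[int, int], Tuple[int, int]]:
    counts = alignment.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    pid = 100.0 * counts.identities / ncols if ncols else 0.0
    (qstart, qend) = (alignment.coordinates[0][0], alignment.coordinates[0][-1])
    (sstart, send) = (alignment.coordinates[1][0], alignment.coordinates[1][-1])
    # PairwiseAligner puts the target first; we align (query, subject) with
    # query as target throughout, so row 0 is the query.
    return pid, (int(qstart), int(qend)), (int(sstart), int(send))


def align_local(a: str, b: str, cfg: ScoringConfig = DEFAULT_SCORING,
                alphabet: Optional[str] = None) -> Optional[SimilarityHit]:
    """Best local alignment of two sequences, or None if no positive score.

    Both sequences must be of the same alphabet (nucleotide or protein);
    mixing raises ``ValueError``.  The returned hit carries query ids "a"
    and "b" for free-standing use; :func:`search` replaces them.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if alphabet is None:
        alpha_a, alpha_b = guess_alphabet(a), guess_alphabet(b)
        if alpha_a != alpha_b:
            raise ValueError(f"mixed alphabets: {alpha_a} vs {alpha_b}")
        alphabet = alpha_a
    aligner = _ALIGNERS.get(cfg, alphabet)
    raw = aligner.score(a, b)
    if raw <= 0:
        return None
    alignment = next(iter(aligner.align(a, b)))
    pid, qspan, sspan = _identity_and_spans(alignment)
    return SimilarityHit(
        query_id="a", subject_id="b", raw_score=float(raw),
        bit_score=cfg.bit_score(raw, alphabet),
        e_value=cfg.e_value(raw, len(a), len(b), alphabet),
        percent_identity=pid, query_span=qspan, subject_span=sspan, frame=0,
    )


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _shares_kmer(kmers: set, seq: str, k: int) -> bool:
    return any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1))


def search(queries: Mapping[str, str], subjects: Mapping[str, str],
           cfg: ScoringConfig = DEFAULT_SCORING, e_cutoff: float = 1e-10,
           prefilter: bool = True) -> List[SimilarityHit]:
    """All query-subject pairs whose best local alignment has E <= cutoff.

    One hit (the best local alignment) per passing pair.  A shared-k-mer
    prefilter (11-mers for nucleotide, 4-mers for protein) skips hopeless
    pairs; at the scales this engine targets any alignment passing a
    stringent cutoff contains an exact word of that size, and equivalence
    with the exhaustive all-pairs search is covered by tests.
    """
    if not queries or not subjects:
        raise ValueError("query and subject sets must be non-empty")
    some_q = next(iter(queries.values()))
    alphabet = guess_alphabet(some_q)
    k = 11 if alphabet == "nucleotide" else 5
    aligner = _ALIGNERS.get(cfg, alphabet)
    hits: List[SimilarityHit] = []
    for s in subjects.values():
        if guess_alphabet(s) != alphabet:
            raise ValueError("mixed alphabets between queries and subjects")
    q_kmers = {qid: _kmer_set(q, k) for qid, q in queries.items()} if prefilter else None
    s_kmers = {sid: _kmer_set(s, k) for sid, s in subjects.items()} if prefilter else None
    for qid, q in queries.items():
        for sid, s in subjects.items():
            if prefilter and q_kmers[qid].isdisjoint(s_kmers[sid]):
                continue
            # score first; the costlier traceback runs only for passing pairs
            raw = aligner.score(q, s)
            if raw <= 0 or cfg.e_value(raw, len(q), len(s), alphabet) > e_cutoff:
                continue
            hit = align_local(q, s, cfg, alphabet=alphabet)
            hit.query_id, hit.subject_id = qid, sid
            hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, -h.bit_score, h.subject_id))
    return hits


def best_hits(hits: Sequence[SimilarityHit]) -> Dict[str, SimilarityHit]:
    """Map each query id to its single best hit (highest bit score).

    Ties are broken by higher percent identity, then subject id, so the
    result does not depend on input order.
    """
    best: Dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (h.bit_score, h.percent_identity)
        key_cur = (cur.bit_score, cur.percent_identity)
        if key_new > key_cur or (key_new == key_cur and h.subject_id < cur.subject_id):
            best[h.query_id] = h
    return best


def _windows_from_seeds(positions: List[int], qlen: int, slen: int,
                        merge_gap: int) -> List[Tuple[int, int, int]]:
    """Merge seed positions into (window start, window end, n seeds) triples.

    The margin beyond the outermost seeds is generous relative to seed
    density at the identity levels the engine targets (word matches every
    few residues within a real HSP) while keeping alignment windows small.
    """
    if not positions:
        return []
    positions.sort()
    margin = min(qlen, 80)
    windows: List[Tuple[int, int, int]] = []
    start = prev = positions[0]
    count = 1
    for p in positions[1:]:
        if p - prev > merge_gap:
            windows.append((max(0, start - margin), min(slen, prev + 2 * margin), count))
            start, count = p, 0
        prev = p
        count += 1
    windows.append((max(0, start - margin), min(slen, prev + 2 * margin), count))
    return windows


def _extract_hsps(query: str, subject: str, cfg: ScoringConfig, e_cutoff: float,
                  m: int, n: int, lo: int, hi: int,
                  out: List[Tuple[float, Tuple[int, int], Tuple[int, int], float]]) -> None:
    """Recursively pull non-overlapping passing HSPs out of subject[lo:hi]."""
    if hi - lo < 10:
        return
    window = subject[lo:hi]
    aligner = _ALIGNERS.get(cfg, "protein")
    raw = aligner.score(query, window)
    if raw <= 0 or cfg.e_value(raw, m, n, "protein") > e_cutoff:
        return
    alignment = next(iter(aligner.align(query, window)))
    pid, qspan, sspan = _identity_and_spans(alignment)
    abs_span = (lo + sspan[0], lo + sspan[1])
    out.append((float(raw), qspan, abs_span, pid))
    _extract_hsps(query, subject, cfg, e_cutoff, m, n, lo, abs_span[0], out)
    _extract_hsps(query, subject, cfg, e_cutoff, m, n, abs_span[1], hi, out)


def search_translated(protein_queries: Mapping[str, str], genome: Mapping[str, str],
                      cfg: ScoringConfig = DEFAULT_SCORING, e_cutoff: float = 1e-10,
                      seed_k: int = 5, min_seeds: int = 2) -> List[SimilarityHit]:
    """TBLASTN stand-in: protein queries vs all six reading frames of a genome.

    Hits carry genomic coordinates on the forward strand in ``subject_span``
    and the reading frame in ``frame``.  Stop codons break alignments (they
    score -1000 in the translated frames).  Alignment is restricted to
    windows around exact ``seed_k``-mer word matches (at least ``min_seeds``
    per window), with each frame scanned once against a shared index over
    all queries; within a window, after the best HSP is taken the flanking
    stretches are re-searched recursively so every gene copy is reported.
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    index: Dict[str, List[str]] = {}
    for qid, q in protein_queries.items():
        for i in range(len(q) - seed_k + 1):
            index.setdefault(q[i : i + seed_k], []).append(qid)
    hits: List[SimilarityHit] = []
    for chrom_id, chrom_seq in genome.items():
        chrom_len = len(chrom_seq)
        frames = six_frame_translations(chrom_seq)
        for frame, trans in frames.items():
            if len(trans) < seed_k:
                continue
            positions: Dict[str, List[int]] = {}
            for i in range(len(trans) - seed_k + 1):
                qids = index.get(trans[i : i + seed_k])
                if qids:
                    for qid in qids:
                        positions.setdefault(qid, []).append(i)
            for qid, pos in positions.items():
                query = protein_queries[qid]
                qlen = len(query)
                hsps: List[Tuple[float, Tuple[int, int], Tuple[int, int], float]] = []
                for lo, hi, support in _windows_from_seeds(pos, qlen, len(trans), qlen):
                    if support < min_seeds:
                        continue
                    _extract_hsps(query, trans, cfg, e_cutoff, qlen, len(trans),
                                  lo, hi, hsps)
                for raw, qspan, sspan, pid in hsps:
                    g_span = frame_to_genomic(frame, sspan[0], sspan[1], chrom_len)
                    hits.append(SimilarityHit(
                        query_id=qid, subject_id=chrom_id, raw_score=raw,
                        bit_score=cfg.bit_score(raw, "protein"),
                        e_value=cfg.e_value(raw, qlen, len(trans), "protein"),
                        percent_identity=pid, query_span=qspan,
                        subject_span=g_span, frame=frame,
                    ))
    hits.sort(key=lambda h: (h.subject_id, h.subject_span, h.query_id))
    return hits


def read_tabular_hits(path: str, dialect: str = "outfmt6") -> List[SimilarityHit]:
    """Read externally produced hits in BLAST tabular (outfmt 6) format.

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    a subject interval given in minus orientation (sstart > send) is
    normalised to forward order with frame = -1 recording the orientation.
    Raw scores are not present in the format; ``raw_score`` mirrors the
    file's bit score.
    """
    if dialect != "outfmt6":
        raise ValueError(f"unsupported dialect: {dialect}")
    hits: List[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}: row {lineno}: expected 12 columns, got {len(fields)}")
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue, bit = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: non-numeric field") from exc
            frame = 0
            if sstart > send:
                sstart, send = send, sstart
                frame = -1
            hits.append(SimilarityHit(
                query_id=qid, subject_id=sid, raw_score=bit, bit_score=bit,
                e_value=evalue, percent_identity=pident,
                query_span=(qstart - 1, qend), subject_span=(sstart - 1, send),
                frame=frame,
            ))
    return hits
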