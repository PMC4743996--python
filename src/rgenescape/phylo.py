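"""Distance-based phylogenetics: p-distance, Kimura two-parameter distance,
neighbor joining and column-resampling bootstrap.

Distances use pairwise deletion: columns with a gap in either sequence are
excluded, and ambiguity characters (N for nucleotide, X for protein) are
treated as gaps.  The Kimura two-parameter (K2P) correction is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over compared
columns; the distance is flagged undefined when the logarithm's domain is
violated (saturation).  Trees are built with Saitou-Nei neighbor joining
under the standard Q-criterion, ties broken by the smallest taxon-index
pair and negative branch lengths clamped to zero with the length moved to
the sibling edge.  Bootstrap support for each bipartition of the full-data
tree is the percentage of replicate trees (columns resampled with
replacement) containing it; rendered output suppresses supports below a
display floor (default 65) while the data retain them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np

from ._common import translate as _translate

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass
class PairwiseDistance:
    P: float            # transition proportion (0 for protein distances)
    Q: float            # transversion proportion (0 for protein distances)
    p: float            # raw mismatch proportion
    d: float            # corrected distance (== p for p-distance)
    n_compared: int
    defined: bool = True


def _compared_columns(a: str, b: str, skip: Set[str]) -> List[Tuple[str, str]]:
    return [(x, y) for x, y in zip(a.upper(), b.upper())
            if x not in skip and y not in skip]


def p_distance(a: str, b: str, alphabet: str = "protein") -> PairwiseDistance:
    """Raw mismatch proportion with pairwise deletion of gap columns."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    skip = {"-", "N"} if alphabet == "nucleotide" else {"-", "X"}
    cols = _compared_columns(a, b, skip)
    if not cols:
        raise ValueError("no comparable columns after gap removal")
    mism = sum(1 for x, y in cols if x != y)
    p = mism / len(cols)
    return PairwiseDistance(P=0.0, Q=0.0, p=p, d=p, n_compared=len(cols))


def k2p_distance(a: str, b: str) -> PairwiseDistance:
    """Kimura two-parameter distance for aligned nucleotide sequences."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    cols = _compared_columns(a, b, {"-", "N"})
    if not cols:
        raise ValueError("no comparable columns after gap removal")
    ts = tv = 0
    for x, y in cols:
        if x == y:
            continue
        if (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    n = len(cols)
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return PairwiseDistance(P=P, Q=Q, p=P + Q, d=math.inf,
                                n_compared=n, defined=False)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return PairwiseDistance(P=P, Q=Q, p=P + Q, d=d, n_compared=n)


def distance_matrix(alignment: Mapping[str, str],
                    method: str = "k2p") -> Tuple[List[str], np.ndarray, bool]:
    """(ids, matrix, all_defined) for an aligned sequence set."""
    ids = list(alignment)
    n = len(ids)
    D = np.zeros((n, n))
    ok = True
    fn = k2p_distance if method == "k2p" else p_distance
    for i in range(n):
        for j in range(i + 1, n):
            pd = fn(alignment[ids[i]], alignment[ids[j]])
            D[i, j] = D[j, i] = pd.d
            ok = ok and pd.defined
    return ids, D, ok


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: Optional[str] = None
    children: List[Tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    def leaves(self) -> List[str]:
        if not self.children:
            return [self.name]
        out: List[str] = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> List[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> Set[frozenset]:
        """Non-trivial splits, canonicalised to the side lacking the first
        (alphabetically) leaf so each internal edge yields one split."""
        all_leaves = frozenset(self.root.leaves())
        anchor = min(all_leaves)
        splits: Set[frozenset] = set()

        def walk(node: TreeNode) -> None:
            for child, _bl in node.children:
                under = frozenset(child.leaves())
                side = under if anchor not in under else all_leaves - under
                if 2 <= len(side) <= len(all_leaves) - 2:
                    splits.add(side)
                walk(child)

        walk(self.root)
        return splits

    def set_supports(self, supports: Mapping[frozenset, float]) -> None:
        all_leaves = frozenset(self.root.leaves())
        anchor = min(all_leaves)

        def walk(node: TreeNode) -> None:
            for child, _bl in node.children:
                if child.children:
                    under = frozenset(child.leaves())
                    side = under if anchor not in under else all_leaves - under
                    if side in supports:
                        child.support = supports[side]
                walk(child)

        walk(self.root)

    def newick(self, support_floor: Optional[float] = 65.0) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
            label = ""
            if node.support is not None and (support_floor is None
                                             or node.support >= support_floor):
                label = f"{node.support:.0f}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def nj_tree(D: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Requires a symmetric matrix with zero diagonal and n >= 3.  Ties in the
    Q-criterion break on the smallest (i, j) index pair; negative branch
    lengths are clamped to zero with the length moved to the sibling edge.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n != D.shape[1] or n != len(ids):
        raise ValueError("matrix shape and id count disagree")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")

    nodes: List[TreeNode] = [TreeNode(name=i) for i in ids]
    D = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best, best_q = None, math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj, li = D[i, j], 0.0
        if lj < 0:
            li, lj = D[i, j], 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    # final unrooted trifurcation with closed-form branch lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, (d01 + d02 - d12) / 2.0)
    l1 = max(0.0, (d01 + d12 - d02) / 2.0)
    l2 = max(0.0, (d02 + d12 - d01) / 2.0)
    root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return PhyloTree(root)


class TranslationResult(NamedTuple):
    protein: str
    internal_stop: bool


def translate_cds(cds: str) -> TranslationResult:
    """Standard-code translation, stopping at the first stop codon.

    ``internal_stop`` is set when a stop occurs before the final codon,
    which is the pseudogene signal used elsewhere in the package.
    """
    if len(cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    full = _translate(cds)
    stop = full.find("*")
    internal = 0 <= stop < len(full) - 1
    protein = full[:stop] if stop >= 0 else full
    return TranslationResult(protein, internal)


def bootstrap_support(alignment: Mapping[str, str], n_replicates: int = 1000,
                      seed: int = 0, distance: str = "k2p",
                      support_floor: float = 65.0) -> Tuple[PhyloTree, int]:
    """NJ tree with bootstrap supports from column resampling.

    Support for each bipartition of the full-data tree is the percentage of
    replicate trees containing it, over replicates whose distance matrices
    were fully defined; undefined replicates are skipped, counted and
    reported with a warning.  Returns (tree, n_skipped).
    """
    if not alignment:
        raise ValueError("empty alignment")
    ids = list(alignment)
    ncols = len(next(iter(alignment.values())))
    if ncols < 1:
        raise ValueError("alignment has no columns")
    if any(len(s) != ncols for s in alignment.values()):
        raise ValueError("unequal aligned lengths")
    full_ids, D, ok = distance_matrix(alignment, distance)
    if not ok:
        raise ValueError("undefined distances in the full alignment")
    tree = nj_tree(D, full_ids)
    target_splits = tree.bipartitions()
    counts = {s: 0 for s in target_splits}
    rng = np.random.RandomState(seed)
    n_ok, n_skipped = 0, 0
    rows = {i: alignment[i] for i in ids}
    for _ in range(n_replicates):
        cols = rng.randint(0, ncols, size=ncols)
        rep = {i: "".join(rows[i][c] for c in cols) for i in ids}
        rep_ids, repD, rep_ok = distance_matrix(rep, distance)
        if not rep_ok:
            n_skipped += 1
            continue
        n_ok += 1
        rep_splits = nj_tree(repD, rep_ids).bipartitions()
        for s in target_splits & rep_splits:
            counts[s] += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} bootstrap replicates skipped "
                      f"(undefined distances)")
    denom = max(n_ok, 1)
    supports = {s: 100.0 * c / denom for s, c in counts.items()}
    tree.set_supports(supports)
    return tree, n_skipped


# ---------------------------------------------------------------------------
# Naive fixed-cost progressive (center-star) aligner for fixture inputs
# ---------------------------------------------------------------------------

def align_star(seqs: Mapping[str, str]) -> Dict[str, str]:
    """Center-star multiple alignment around the longest sequence.

    A deliberately simple aligner for self-contained fixtures (substitutions
    and end-truncations); it is not a general-purpose MSA tool.  End gaps
    are free so truncated fragments anchor correctly.
    """
    from Bio import Align

    if not seqs:
        return {}
    if len(seqs) == 1:
        return dict(seqs)
    center = max(seqs, key=lambda k: (len(seqs[k]), k))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0

    center_seq = seqs[center]
    # master gap pattern for the center; each insertion point stores the
    # maximum insert length required by any sequence
    inserts: Dict[int, int] = {}
    aligned_pairs: Dict[str, List[Tuple[int, int]]] = {}
    for name, seq in seqs.items():
        if name == center:
            continue
        aln = next(iter(aligner.align(center_seq, seq)))
        coords = aln.coordinates
        aligned_pairs[name] = [(int(coords[0][k]), int(coords[1][k]))
                               for k in range(coords.shape[1])]
        # record insertions relative to the center
        for k in range(coords.shape[1] - 1):
            c0, q0 = coords[0][k], coords[1][k]
            c1, q1 = coords[0][k + 1], coords[1][k + 1]
            if c1 == c0 and q1 > q0:  # insertion in the other sequence
                pos, ln = int(c0), int(q1 - q0)
                inserts[pos] = max(inserts.get(pos, 0), ln)

    def expand_center() -> str:
        out = []
        for i, ch in enumerate(center_seq):
            if i in inserts:
                out.append("-" * inserts[i])
            out.append(ch)
        if len(center_seq) in inserts:
            out.append("-" * inserts[len(center_seq)])
        return "".join(out)

    def expand_other(name: str) -> str:
        seq = seqs[name]
        pairs = aligned_pairs[name]
        out = []
        ci = 0
        # walk center positions, tracking the pair segments
        pos_map: Dict[int, str] = {}
        ins_map: Dict[int, str] = {}
        for k in range(len(pairs) - 1):
            c0, q0 = pairs[k]
            c1, q1 = pairs[k + 1]
            if c1 > c0 and q1 > q0:      # aligned block
                for off in range(c1 - c0):
                    pos_map[c0 + off] = seq[q0 + off]
            elif c1 > c0 and q1 == q0:   # deletion in other
                for off in range(c1 - c0):
                    pos_map[c0 + off] = "-"
            elif c1 == c0 and q1 > q0:   # insertion in other
                ins_map[c0] = seq[q0:q1]
        out = []
        for i in range(len(center_seq)):
            if i in inserts:
                ins = ins_map.get(i, "")
                out.append(ins.ljust(inserts[i], "-"))
            out.append(pos_map.get(i, "-"))
        if len(center_seq) in inserts:
            out.append(ins_map.get(len(center_seq), "").ljust(inserts[len(center_seq)], "-"))
        return "".join(out)

    result = {center: expand_center()}
    for name in seqs:
        if name != center:
            result[name] = expand_other(name)
    width = len(result[center])
    assert all(len(v) == width for v in result.values())
    return result
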