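"""Alignment engine: oracle equivalence, statistics and format handling."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from rgenescape.homology_engine import (DEFAULT_SCORING, align_local,
                                        read_tabular_hits, search,
                                        search_translated)
from rgenescape._common import revcomp, translate

from oracles import smith_waterman_affine

PROT = "ACDEFGHIKLMNPQRSTVWY"


def _rand_protein(rng, n):
    return "".join(rng.choice(PROT) for _ in range(n))


def _rand_nt(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestAlignLocal:
    def test_self_alignment_is_full_length_identity(self):
        rng = random.Random(0)
        p = _rand_protein(rng, 200)
        hit = align_local(p, p)
        assert hit.percent_identity == 100.0
        assert hit.query_span == (0, 200) and hit.subject_span == (0, 200)

    def test_unrelated_random_pair_rejected_at_stringent_cutoff(self):
        rng = random.Random(1)
        a, b = _rand_nt(rng, 400), _rand_nt(rng, 400)
        hit = align_local(a, b)
        assert hit is None or hit.e_value > 1e-10

    @pytest.mark.parametrize("alphabet,lengths", [
        ("protein", (10, 7)), ("protein", (40, 55)), ("protein", (80, 80)),
        ("nucleotide", (30, 30)), ("nucleotide", (60, 90)),
    ])
    def test_score_matches_bruteforce_dp_oracle(self, alphabet, lengths):
        rng = random.Random(sum(lengths))
        make = _rand_protein if alphabet == "protein" else _rand_nt
        cfg = DEFAULT_SCORING
        if alphabet == "protein":
            go, ge = cfg.protein_gap_open, cfg.protein_gap_extend
        else:
            go, ge = cfg.nt_gap_open, cfg.nt_gap_extend
        for _ in range(5):
            a, b = make(rng, lengths[0]), make(rng, lengths[1])
            expected = smith_waterman_affine(a, b, alphabet, go, ge)
            hit = align_local(a, b, alphabet=alphabet)
            got = hit.raw_score if hit else 0.0
            assert got == pytest.approx(expected)

    def test_classic_toy_pair_against_oracle(self):
        # small hand-checkable pair under BLOSUM62 with gap 10/1
        from rgenescape.homology_engine import ScoringConfig
        cfg = ScoringConfig(protein_gap_open=10, protein_gap_extend=1)
        a, b = "HEAGAWGHEE", "PAWHEAE"
        expected = smith_waterman_affine(a, b, "protein", 10, 1)
        hit = align_local(a, b, cfg, alphabet="protein")
        assert hit.raw_score == pytest.approx(expected)

    def test_symmetry_of_raw_score(self):
        rng = random.Random(2)
        for _ in range(10):
            a, b = _rand_protein(rng, 60), _rand_protein(rng, 45)
            ha, hb = align_local(a, b), align_local(b, a)
            sa = ha.raw_score if ha else 0.0
            sb = hb.raw_score if hb else 0.0
            assert sa == sb

    def test_flanking_unrelated_sequence_never_decreases_score(self):
        rng = random.Random(3)
        a = _rand_nt(rng, 80)
        b = a  # strong core similarity
        base = align_local(a, b).raw_score
        padded = _rand_nt(rng, 50) + b + _rand_nt(rng, 50)
        assert align_local(a, padded).raw_score >= base

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError):
            align_local("ACGTACGTACGT", "MKLVWEERTYHH")


class TestSearch:
    def test_single_sequence_self_hit(self):
        seqs = {"x": "ATGGCTGCTAGGCTTAGGCTAGCTAGGTGATCGATCGTAGCTAGC" * 3}
        hits = search(seqs, seqs, e_cutoff=1e-5)
        assert [(h.query_id, h.subject_id) for h in hits] == [("x", "x")]

    def test_infinite_cutoff_bounded_by_all_pairs_with_positive_score(self):
        rng = random.Random(4)
        qs = {f"q{i}": _rand_nt(rng, 100) for i in range(3)}
        hits = search(qs, qs, e_cutoff=float("inf"), prefilter=False)
        assert len(hits) <= 9
        assert all(h.raw_score > 0 for h in hits)

    def test_prefiltered_search_equals_all_pairs_oracle(self, collection):
        """Words prefilter must not drop any pair passing the cutoff."""
        truth = collection.genomes[0].truth.genes
        g = collection.genomes[0]
        r_genes = truth[truth.is_r].gene_id.tolist()[:12]
        by_id = {x.gene_id: x for x in g.genes}
        seqs = {gid: by_id[gid].spliced_cds(g.chromosomes[by_id[gid].chrom])
                for gid in r_genes}
        fast = {(h.query_id, h.subject_id)
                for h in search(seqs, seqs, e_cutoff=1e-10, prefilter=True)}
        slow = {(h.query_id, h.subject_id)
                for h in search(seqs, seqs, e_cutoff=1e-10, prefilter=False)}
        assert fast == slow

    def test_hits_only_within_subfamilies_across_diverged_ancestors(self, collection, truth_genes):
        g = collection.genomes[0]
        by_id = {x.gene_id: x for x in g.genes}
        tg = collection.genomes[0].truth.genes
        picks = tg[tg.is_r & (tg.status == "intact")].groupby("subfamily").head(3)
        seqs = {row.gene_id: by_id[row.gene_id].spliced_cds(g.chromosomes[row.chrom])
                for row in picks.itertuples()}
        sf = {row.gene_id: row.subfamily for row in picks.itertuples()}
        for h in search(seqs, seqs, e_cutoff=1e-10):
            assert sf[h.query_id] == sf[h.subject_id]


class TestSearchTranslated:
    def _mini_genome(self):
        from rgenescape.synthetic_genome import reverse_translate
        rng = random.Random(5)
        prot = "M" + _rand_protein(rng, 119)
        cds = reverse_translate(prot, rng) + "TAA"
        left, right = _rand_nt(rng, 400), _rand_nt(rng, 400)
        return cds, left + cds + right, len(left)

    def test_exact_translation_hits_cds_interval(self):
        cds, chrom, offset = self._mini_genome()
        prot = translate(cds, to_stop=True)
        hits = search_translated({"q": prot}, {"c": chrom})
        assert len(hits) == 1
        h = hits[0]
        assert h.frame == offset % 3 + 1
        s, e = h.subject_span
        assert abs(s - offset) <= 3 and abs(e - (offset + len(cds) - 3)) <= 3

    def test_minus_strand_gene_found_with_negative_frame(self):
        cds, chrom, offset = self._mini_genome()
        prot = translate(cds, to_stop=True)
        hits = search_translated({"q": prot}, {"c": revcomp(chrom)})
        assert len(hits) == 1
        assert hits[0].frame < 0

    def test_no_hit_when_gene_deleted(self):
        cds, chrom, offset = self._mini_genome()
        prot = translate(cds, to_stop=True)
        without = chrom.replace(cds, "")
        assert search_translated({"q": prot}, {"c": without}) == []

    def test_truncated_copy_hits_only_retained_fraction(self):
        cds, chrom, offset = self._mini_genome()
        keep = cds[: 3 * (int(len(cds) * 0.6) // 3)]
        rng = random.Random(6)
        chrom2 = _rand_nt(rng, 300) + keep + _rand_nt(rng, 300)
        prot = translate(cds, to_stop=True)
        hits = search_translated({"q": prot}, {"c": chrom2})
        assert len(hits) == 1
        qs, qe = hits[0].query_span
        kept_codons = len(keep) // 3
        # covers the retained fraction but never the missing 40% (short
        # chance extensions into flanking sequence are allowed by SW)
        assert qe - qs >= kept_codons - 1
        assert qe - qs < kept_codons + 20


class TestReadTabularHits:
    def _write(self, tmp_path, rows):
        p = tmp_path / "hits.tsv"
        p.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return str(p)

    def test_coordinates_converted_to_half_open(self, tmp_path):
        path = self._write(tmp_path, [
            ["q", "s", 98.5, 10, 0, 0, 1, 10, 21, 30, 1e-20, 55.2]])
        (h,) = read_tabular_hits(path)
        assert h.query_span == (0, 10)
        assert h.subject_span == (20, 30)
        assert h.frame == 0

    def test_minus_orientation_normalised_with_negative_frame(self, tmp_path):
        path = self._write(tmp_path, [
            ["q", "s", 90.0, 100, 5, 1, 1, 100, 100, 1, 1e-30, 120.0]])
        (h,) = read_tabular_hits(path)
        assert h.subject_span == (0, 100)
        assert h.frame == -1

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert read_tabular_hits(str(p)) == []

    @pytest.mark.parametrize("row", [
        ["q", "s", "x", 10, 0, 0, 1, 10, 1, 10, 1e-5, 20.0],   # non-numeric
        ["q", "s", 90.0, 10, 0, 0, 1, 10, 1, 10, 1e-5],        # 11 columns
    ])
    def test_malformed_row_rejected_with_row_number(self, tmp_path, row):
        path = self._write(tmp_path, [row])
        with pytest.raises(ValueError, match="row 1"):
            read_tabular_hits(path)
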