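"""Subfamily classification: clustering, election, assignment, fixpoint."""

import random

import pytest

from rgenescape._common import translate
from rgenescape.classify import (Subfamily, assign_class, assign_members,
                                 classify_collection, cluster_reference,
                                 elect_ref_gene, iterate_until_fixpoint)
from rgenescape.identify import DomainHit, RGeneCandidate
from rgenescape.synthetic_genome import make_subfamily_ancestors, mutate_cds


def _member_set(n_subfamilies=2, members=5, seed=51, mutation=0.03,
                genome="GX"):
    """Candidates + sequences for planted subfamilies (no genomes needed)."""
    anc = make_subfamily_ancestors(n_subfamilies, 0.0, seed=seed)
    rng = random.Random(seed)
    cands, seqs, truth = [], {}, {}
    i = 0
    for sf_id, a in anc.items():
        for _ in range(members):
            i += 1
            cid = f"{genome}-{i:04d}"
            cands.append(RGeneCandidate(cid, genome, "c1", (i * 10, i * 10 + 5),
                                        "+", has_nbs=True))
            seqs[cid] = mutate_cds(a.cds, mutation, rng)
            truth[cid] = sf_id
    return cands, seqs, truth


class TestClusterReference:
    def test_two_planted_subfamilies_give_two_groups(self):
        cands, seqs, truth = _member_set()
        groups, pool = cluster_reference(cands, seqs)
        assert len(groups) == 2 and not pool
        for group in groups:
            assert len({truth[c.candidate_id] for c in group}) == 1

    def test_gene_hitting_nothing_is_unclassified(self):
        cands, seqs, truth = _member_set(n_subfamilies=1, members=3)
        rng = random.Random(1)
        loner = RGeneCandidate("GX-9999", "GX", "c1", (0, 5), "+", has_nbs=True)
        cands.append(loner)
        seqs["GX-9999"] = "".join(rng.choice("ACGT") for _ in range(900))
        groups, pool = cluster_reference(cands, seqs)
        assert [c.candidate_id for c in pool] == ["GX-9999"]

    def test_component_of_partials_only_routed_to_pool(self):
        cands, seqs, truth = _member_set(n_subfamilies=1, members=3)
        for c in cands:
            c.has_nbs = False  # nothing anchors the group
            seqs[c.candidate_id] = seqs[c.candidate_id][600:]
        groups, pool = cluster_reference(cands, seqs)
        assert not groups and len(pool) == 3

    def test_order_invariance_of_membership(self):
        cands, seqs, _ = _member_set(seed=53)
        groups1, _ = cluster_reference(cands, seqs)
        groups2, _ = cluster_reference(list(reversed(cands)), seqs)
        as_sets = lambda gs: sorted(
            tuple(sorted(c.candidate_id for c in g)) for g in gs)
        assert as_sets(groups1) == as_sets(groups2)


class TestElectRefGene:
    def test_curated_gene_wins(self):
        cands, seqs, _ = _member_set(n_subfamilies=1, members=4)
        curated = cands[2].candidate_id
        assert elect_ref_gene(cands, seqs, known_genes=[curated], seed=0) == curated

    def test_election_is_seed_stable(self):
        cands, seqs, _ = _member_set(n_subfamilies=1, members=4)
        winners = {elect_ref_gene(cands, seqs, seed=17) for _ in range(5)}
        assert len(winners) == 1

    def test_single_intact_member_forced(self):
        cands, seqs, _ = _member_set(n_subfamilies=1, members=5)
        for c in cands[1:]:
            seqs[c.candidate_id] = seqs[c.candidate_id][600:]  # truncate
        winner = elect_ref_gene(cands, seqs, seed=3)
        assert winner == cands[0].candidate_id

    def test_no_intact_member_is_an_error(self):
        cands, seqs, _ = _member_set(n_subfamilies=1, members=2)
        for c in cands:
            c.has_nbs = False
        with pytest.raises(ValueError, match="full-length"):
            elect_ref_gene(cands, seqs, seed=0)


class TestAssignMembers:
    def _subfamilies(self, cands, seqs):
        groups, _ = cluster_reference(cands, seqs)
        subs = []
        for g in groups:
            ref = elect_ref_gene(g, seqs, seed=5)
            sf = Subfamily(ref, ref)
            for c in g:
                sf.add(c.genome_id, c.candidate_id)
            subs.append(sf)
        return subs

    def test_other_genome_member_joins_its_subfamily(self):
        cands, seqs, truth = _member_set(seed=57)
        subs = self._subfamilies(cands, seqs)
        anc = make_subfamily_ancestors(2, 0.0, seed=57)
        rng = random.Random(99)
        newbie = RGeneCandidate("GY-0001", "GY", "c1", (0, 5), "+", has_nbs=True)
        seqs["GY-0001"] = mutate_cds(anc["SF02"].cds, 0.03, rng)
        assignments, unassigned = assign_members([newbie], subs, seqs)
        assert not unassigned
        ((c, sf),) = assignments
        assert truth[sf.ref_gene] == "SF02"

    def test_private_subfamily_member_unassigned(self):
        cands, seqs, truth = _member_set(seed=57)
        subs = self._subfamilies(cands, seqs)
        private = make_subfamily_ancestors(3, 0.0, seed=1001)["SF03"]
        rng = random.Random(5)
        newbie = RGeneCandidate("GY-0002", "GY", "c1", (0, 5), "+", has_nbs=True)
        seqs["GY-0002"] = mutate_cds(private.cds, 0.03, rng)
        assignments, unassigned = assign_members([newbie], subs, seqs)
        assert not assignments and unassigned == [newbie]


class TestFixpointAndCollection:
    def test_fixture_recovers_shared_plus_private_subfamilies(self, pipeline_result):
        # six planted subfamilies; one private to a non-reference genome
        assert len(pipeline_result.subfamilies) == 6
        assert not pipeline_result.unclassified

    def test_partition_property(self, pipeline_result):
        seen = {}
        for sf in pipeline_result.subfamilies:
            for cid in sf.all_members():
                assert cid not in seen, "member in two subfamilies"
                seen[cid] = sf.subfamily_id
        n_cands = sum(len(v) for v in pipeline_result.candidates_by_genome.values())
        assert len(seen) + len(pipeline_result.unclassified) == n_cands

    def test_ref_gene_is_member_of_own_subfamily(self, pipeline_result):
        for sf in pipeline_result.subfamilies:
            assert sf.ref_gene in sf.all_members()

    def test_class_consistency_within_subfamily(self, pipeline_result):
        cands = pipeline_result.all_candidates()
        for sf in pipeline_result.subfamilies:
            classes = {cands[cid].r_class for cid in sf.all_members()
                       if cands[cid].status == "intact"}
            assert len(classes) == 1
            assert sf.r_class in classes

    def test_empty_pool_adds_no_subfamilies(self):
        subs, unclassified = iterate_until_fixpoint({}, {}, [])
        assert subs == [] and unclassified == []

    def test_pool_of_only_partials_reported_unclassified(self):
        cands, seqs, _ = _member_set(n_subfamilies=1, members=3, seed=61)
        for c in cands:
            c.has_nbs = False
            seqs[c.candidate_id] = seqs[c.candidate_id][600:]
        subs, unclassified = iterate_until_fixpoint({"GX": cands}, seqs, [])
        assert subs == []
        assert len(unclassified) == 3


class TestAssignClass:
    def test_tir_hit_makes_tnl(self):
        c = RGeneCandidate("X-0001", "X", "c", (0, 10), "+",
                           source_gene="g1", status="intact")
        hits = [DomainHit("g1", "TIR", 50.0, (10, 40))]
        assert assign_class(c, hits) == "TNL"
        assert not c.low_confidence_class

    def test_no_tir_hit_makes_ntnl(self):
        c = RGeneCandidate("X-0002", "X", "c", (0, 10), "+",
                           source_gene="g2", status="intact")
        assert assign_class(c, []) == "nTNL"
        assert not c.low_confidence_class

    def test_truncated_gene_without_tir_is_low_confidence(self):
        c = RGeneCandidate("X-0003", "X", "c", (0, 10), "+",
                           source_gene="g3", status="partial")
        assert assign_class(c, []) == "nTNL"
        assert c.low_confidence_class
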