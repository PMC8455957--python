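"""Similarity search, rank/tandem/segmental classification, collinearity, cscore."""

import math

import numpy as np
import pytest

from hsp20pipe.duplication import (
    CollinearBlock,
    GeneRank,
    SimilarityHit,
    all_vs_all,
    classify_duplicates,
    cross_species_synteny,
    cscore,
    detect_collinear_blocks,
    find_duplicates,
    gene_ranks,
)
from hsp20pipe.config import SimulationParams
from hsp20pipe.seqio import GeneModel
from hsp20pipe.simulate import generate_family_genome


def _hit(a, b, score=100.0):
    return SimilarityHit(a, b, score, 1e-30, 1.0, 1.0)


def _rank_table(spec):
    """spec: {gene: (chrom, rank)}"""
    return {g: GeneRank(g, c, r) for g, (c, r) in spec.items()}


class TestAllVsAll:
    def test_identical_proteins_have_identity_one(self):
        seq = "MKV" * 50
        hits = all_vs_all({"a": seq, "b": seq})
        assert len(hits) == 1
        assert hits[0].identity_fraction == pytest.approx(1.0)
        assert hits[0].coverage == pytest.approx(1.0)

    def test_scores_are_symmetric(self):
        rng = np.random.default_rng(0)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        a = "".join(aa[rng.integers(0, 20, 150)])
        b = "".join(aa[rng.integers(0, 20, 150)])
        h_ab = all_vs_all({"x": a, "y": b}, e_value_max=math.inf)
        h_ba = all_vs_all({"x": b, "y": a}, e_value_max=math.inf)
        assert h_ab[0].alignment_score == pytest.approx(h_ba[0].alignment_score)

    def test_unrelated_random_pairs_rarely_pass_the_threshold(self):
        rng = np.random.default_rng(1)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        prots = {
            f"p{i}": "".join(aa[rng.integers(0, 20, 150)]) for i in range(46)
        }
        hits = all_vs_all(prots, e_value_max=1e-10)  # 1035 random pairs
        assert len(hits) <= 10  # << 1% of trials

    def test_needs_at_least_two_proteins(self):
        with pytest.raises(ValueError):
            all_vs_all({"only": "MKVLM"})


class TestRanksAndClassification:
    def test_ranks_are_a_permutation_per_chromosome(self, sim):
        ranks = gene_ranks(sim.genes)
        by_chrom = {}
        for r in ranks.values():
            by_chrom.setdefault(r.chromosome, []).append(r.rank)
        for chrom, rs in by_chrom.items():
            assert sorted(rs) == list(range(1, len(rs) + 1))

    def test_rank_adjacent_pair_without_block_is_tandem(self):
        ranks = _rank_table({"a": ("Chr1", 4), "b": ("Chr1", 5)})
        out = classify_duplicates([_hit("a", "b")], ranks, [])
        assert out[0].duplicate_class == "tandem"

    def test_block_membership_outranks_tandem_adjacency(self):
        ranks = _rank_table({"a": ("Chr1", 4), "b": ("Chr1", 5)})
        block = CollinearBlock(1, (("a", "b"),), 5.0)
        out = classify_duplicates([_hit("a", "b")], ranks, [block])
        assert out[0].duplicate_class == "wgd_segmental"
        assert out[0].block_id == 1

    def test_distant_pair_is_dispersed(self):
        ranks = _rank_table({"a": ("Chr1", 1), "b": ("Chr2", 9)})
        out = classify_duplicates([_hit("a", "b")], ranks, [])
        assert out[0].duplicate_class == "dispersed"

    def test_missing_rank_is_a_consistency_error(self):
        with pytest.raises(KeyError):
            classify_duplicates([_hit("a", "b")], _rank_table({"a": ("Chr1", 1)}), [])

    def test_classification_invariant_to_hit_order(self):
        ranks = _rank_table(
            {"a": ("Chr1", 1), "b": ("Chr1", 2), "c": ("Chr2", 1), "d": ("Chr2", 5)}
        )
        hits = [_hit("a", "b"), _hit("c", "d"), _hit("a", "d")]
        fwd = classify_duplicates(hits, ranks, [])
        rev = classify_duplicates(hits[::-1], ranks, [])
        assert {(p.gene_a, p.gene_b, p.duplicate_class) for p in fwd} == {
            (p.gene_a, p.gene_b, p.duplicate_class) for p in rev
        }


class TestChaining:
    def test_five_consecutive_anchors_form_one_block(self):
        ranks = _rank_table(
            {f"a{i}": ("Chr1", i + 1) for i in range(5)}
            | {f"b{i}": ("Chr2", i + 1) for i in range(5)}
        )
        anchors = [_hit(f"a{i}", f"b{i}") for i in range(5)]
        blocks = detect_collinear_blocks(anchors, ranks, min_anchors=5)
        assert len(blocks) == 1
        assert len(blocks[0].anchor_pairs) == 5

    def test_four_anchors_fall_below_the_default_minimum(self):
        ranks = _rank_table(
            {f"a{i}": ("Chr1", i + 1) for i in range(4)}
            | {f"b{i}": ("Chr2", i + 1) for i in range(4)}
        )
        anchors = [_hit(f"a{i}", f"b{i}") for i in range(4)]
        assert detect_collinear_blocks(anchors, ranks, min_anchors=5) == []

    def test_antiparallel_blocks_are_chained_too(self):
        ranks = _rank_table(
            {f"a{i}": ("Chr1", i + 1) for i in range(5)}
            | {f"b{i}": ("Chr2", 5 - i) for i in range(5)}
        )
        anchors = [_hit(f"a{i}", f"b{i}") for i in range(5)]
        blocks = detect_collinear_blocks(anchors, ranks, min_anchors=5)
        assert len(blocks) == 1

    def test_block_survives_interleaved_spurious_anchors(self):
        ranks = {}
        for i in range(30):
            ranks[f"a{i}"] = GeneRank(f"a{i}", "Chr1", i + 1)
            ranks[f"b{i}"] = GeneRank(f"b{i}", "Chr2", i + 1)
        true_anchors = [_hit(f"a{i}", f"b{i}") for i in range(0, 20, 2)]  # 10 anchors
        rng = np.random.default_rng(0)
        spurious = [
            _hit(f"a{rng.integers(20, 30)}", f"b{rng.integers(0, 10)}")
            for _ in range(2)
        ]
        blocks = detect_collinear_blocks(true_anchors + spurious, ranks)
        assert any(
            {(p[0], p[1]) for p in b.anchor_pairs}
            >= {(f"a{i}", f"b{i}") for i in range(0, 20, 2)}
            for b in blocks
        )


class TestCscore:
    def test_unique_best_reciprocal_hit_scores_one(self):
        hits = [_hit("a", "b", 200.0), _hit("a", "c", 90.0)]
        sc = cscore(hits)
        assert sc[frozenset(("a", "b"))] == pytest.approx(1.0)

    def test_secondary_hit_at_half_best_is_below_the_cutoff(self):
        hits = [_hit("a", "b", 200.0), _hit("a", "c", 100.0)]
        sc = cscore(hits)
        assert sc[frozenset(("a", "c"))] == pytest.approx(0.5)
        assert sc[frozenset(("a", "c"))] < 0.70


class TestRecovery:
    @pytest.mark.parametrize("mutation_rate", [0.0, 0.1])
    def test_planted_duplicates_recovered_exactly(self, mutation_rate):
        genome = generate_family_genome(
            SimulationParams(seed=11, domain_mutation_rate=mutation_rate)
        )
        pairs, blocks, _ = find_duplicates(genome.genes, genome.proteins)
        fam = set(genome.manifest.family_gene_ids)
        truth_t = {frozenset(p) for p in genome.manifest.tandem_pairs}
        truth_s = {frozenset(p) for p in genome.manifest.segmental_pairs}
        got_t = {
            frozenset((p.gene_a, p.gene_b))
            for p in pairs
            if p.duplicate_class == "tandem" and {p.gene_a, p.gene_b} <= fam
        }
        got_s = {
            frozenset((p.gene_a, p.gene_b))
            for p in pairs
            if p.duplicate_class == "wgd_segmental" and {p.gene_a, p.gene_b} <= fam
        }
        assert got_t == truth_t  # precision and recall 1.0
        assert got_s == truth_s

    def test_no_pair_is_reported_twice(self, sim):
        pairs, _, _ = find_duplicates(sim.genes, sim.proteins)
        keys = [frozenset((p.gene_a, p.gene_b)) for p in pairs]
        assert len(keys) == len(set(keys))


class TestCrossSpecies:
    def test_self_comparison_anchors_every_copied_gene_at_cscore_one(self, sim):
        genes_b = [
            GeneModel(gene_id=f"B_{g.gene_id}", chrom=g.chrom, start=g.start,
                      end=g.end, strand=g.strand)
            for g in sim.genes
        ]
        prot_b = {f"B_{k}": v for k, v in sim.proteins.items()}
        hits = all_vs_all(sim.proteins, e_value_max=1e-10, cross=prot_b)
        sc = cscore(hits)
        # each gene's exact copy is its best cross-genome hit
        for g in list(sim.proteins)[:20]:
            assert sc[frozenset((g, f"B_{g}"))] == pytest.approx(1.0)
        blocks = cross_species_synteny(sim.genes, genes_b, hits)
        anchored = {x for b in blocks for p in b.anchor_pairs for x in p}
        assert {g.gene_id for g in sim.genes} <= anchored

    def test_overlapping_gene_ids_rejected(self, sim):
        with pytest.raises(ValueError):
            cross_species_synteny(sim.genes, sim.genes, [])
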