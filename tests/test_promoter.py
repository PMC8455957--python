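"""Promoter windows, IUPAC/HSE scanning, category summaries, Fisher enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from hsp20pipe.promoter import (
    CisElementHit,
    Promoter,
    extract_promoters,
    fisher_exact_two_tailed,
    hse_enrichment,
    iupac_regex,
    load_motif_catalog,
    scan_hse,
    scan_motifs,
    summarize_categories,
)
from hsp20pipe.seqio import GeneModel, reverse_complement


class TestExtractPromoters:
    def test_plus_strand_window_ends_one_bp_before_start(self):
        contig = "A" * 5000
        gene = GeneModel("g", "c", 2000, 2500, "+")
        prom = extract_promoters({"c": contig}, [gene])["g"]
        assert len(prom.sequence) == 1500
        assert not prom.truncated

    def test_minus_strand_window_is_reverse_complement_downstream(self):
        rng = np.random.default_rng(0)
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 6000))
        gene = GeneModel("g", "c", 2000, 2500, "-")
        prom = extract_promoters({"c": contig}, [gene])["g"]
        assert prom.sequence == reverse_complement(contig[2500:4000])

    def test_contig_start_truncates_and_flags(self):
        contig = "A" * 3000
        gene = GeneModel("g", "c", 800, 1200, "+")
        prom = extract_promoters({"c": contig}, [gene])["g"]
        assert len(prom.sequence) == 799
        assert prom.truncated

    def test_unknown_chromosome_is_a_lookup_error(self):
        with pytest.raises(KeyError):
            extract_promoters({"c": "A" * 100}, [GeneModel("g", "x", 50, 60, "+")])


@pytest.fixture(scope="module")
def catalog():
    return load_motif_catalog()


class TestScanMotifs:
    def test_meja_motif_found_as_hormone_related(self, catalog):
        seq = "T" * 50 + "CGTCA" + "T" * 50
        hits = scan_motifs(seq, catalog, gene_id="g")
        named = [h for h in hits if h.motif_name == "CGTCA-motif" and h.strand == "+"]
        assert len(named) == 1
        assert named[0].category == "hormone_related"
        assert named[0].offset == 51

    def test_all_a_promoter_misses_catalog_without_a_runs(self):
        cat = pd.DataFrame(
            [{"motif_name": "x", "pattern": "CGCG", "category": "stress_responsive",
              "subtype": "light"}]
        )
        assert scan_motifs("A" * 200, cat, gene_id="g") == []

    def test_poly_n_pattern_matches_everywhere(self):
        cat = pd.DataFrame(
            [{"motif_name": "nn", "pattern": "NN", "category": "stress_responsive",
              "subtype": "light"}]
        )
        hits = scan_motifs("ACGTA", cat, gene_id="g")
        assert len([h for h in hits if h.strand == "+"]) == 4  # overlapping

    def test_minus_strand_motif_reported_with_minus_strand(self, catalog):
        planted = reverse_complement("CGTCA")
        seq = "T" * 40 + planted + "T" * 40
        hits = scan_motifs(seq, catalog, gene_id="g")
        minus = [h for h in hits if h.motif_name == "CGTCA-motif" and h.strand == "-"]
        assert len(minus) == 1
        assert minus[0].offset == 41

    def test_invalid_iupac_letter_is_a_config_error(self):
        with pytest.raises(ValueError, match="invalid IUPAC"):
            iupac_regex("ACGZ")

    def test_strand_symmetry_under_reverse_complement(self, catalog):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        fwd = scan_motifs(seq, catalog, gene_id="g")
        rev = scan_motifs(reverse_complement(seq), catalog, gene_id="g")
        L = len(seq)

        def key(h, flip):
            if not flip:
                return (h.motif_name, h.offset, h.strand)
            mlen = len(
                catalog.set_index("motif_name").loc[h.motif_name, "pattern"]
            )
            strand = "-" if h.strand == "+" else "+"
            return (h.motif_name, L - h.offset - mlen + 2, strand)

        assert sorted(key(h, False) for h in fwd) == sorted(
            key(h, True) for h in rev
        )


class TestScanHSE:
    def test_constructed_gaa_first_module_at_offset_one(self):
        hits = scan_hse("AGAATTTTCGGGAAT", gene_id="g")
        assert len(hits) == 1
        assert hits[0].module == "GAA_first"
        assert hits[0].strand == "+"
        assert hits[0].offset == 1
        assert hits[0].matched_sequence == "AGAATTTTCGGGAAT"

    def test_reverse_complement_reports_the_minus_strand_reading(self):
        hits = scan_hse(reverse_complement("AGAATTTTCGGGAAT"), gene_id="g")
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].offset == 1

    def test_random_sequence_hit_count_matches_analytic_expectation(self):
        """Each module fixes 9 bases, so a window matches a given module with
        probability 4^-9; summed over both modules and all windows."""
        rng = np.random.default_rng(123)
        length = 10_000
        n_rep = 100
        per_window = 2 * 0.25**9
        expected = (length - 14) * per_window * n_rep
        total = 0
        for _ in range(n_rep):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
            total += len(scan_hse(seq, gene_id="g"))
        assert abs(total - expected) <= 3 * np.sqrt(expected)

    def test_planted_hse_recall_is_total_with_exact_coordinates(self, sim):
        promoters = extract_promoters(sim.genome, sim.genes, window=1500)
        recalled, planted = 0, 0
        for gid, entries in sim.manifest.hse_positions.items():
            found = {
                (h.offset, h.strand, h.module) for h in scan_hse(promoters[gid])
            }
            for e in entries:
                planted += 1
                recalled += (e["offset"], e["strand"], e["module"]) in found
        assert planted > 0
        assert recalled == planted


class TestSummarize:
    def _hit(self, cat):
        return CisElementHit("g", "m", cat, "s", 1, "+")

    def test_percentages_sum_to_one_hundred(self):
        hits = [self._hit("stress_responsive")] * 29 + [
            self._hit("hormone_related")
        ] * 22 + [self._hit("development_related")] * 8
        df = summarize_categories(hits)
        assert df["percent"].sum() == pytest.approx(100.0, abs=0.01)
        assert df.iloc[0]["category"] == "stress_responsive"  # largest first

    def test_empty_hit_set_gives_empty_summary(self):
        df = summarize_categories([])
        assert len(df) == 0

    def test_single_hit_is_one_hundred_percent(self):
        df = summarize_categories([self._hit("hormone_related")])
        assert df.iloc[0]["percent"] == pytest.approx(100.0)


def fisher_oracle(a, b, c, d):
    """Exact-rational brute force: enumerate all tables with the observed
    margins, sum probabilities of tables no more probable than observed."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        probs[k] = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisher:
    def test_balanced_table_has_no_association(self):
        orr, p = fisher_exact_two_tailed(((5, 5), (5, 5)))
        assert p == pytest.approx(1.0)
        assert orr == pytest.approx(1.0)

    def test_example_table_matches_enumeration(self):
        _, p = fisher_exact_two_tailed(((8, 2), (1, 9)))
        assert p == pytest.approx(fisher_oracle(8, 2, 1, 9), abs=1e-12)

    def test_haldane_anscombe_correction_on_zero_cells(self):
        orr, _ = fisher_exact_two_tailed(((5, 0), (2, 7)))
        assert orr == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))

    def test_degenerate_margins_return_p_one(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            _, p = fisher_exact_two_tailed(((0, 0), (3, 4)))
        assert p == 1.0
        assert "degenerate" in caplog.text

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            _, p = fisher_exact_two_tailed(((a, b), (c, d)))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)


class TestEnrichment:
    def test_labels_must_cover_the_same_genes(self):
        with pytest.raises(ValueError):
            hse_enrichment({"a": True}, {"b": True})

    def test_contingency_is_tabulated_correctly(self):
        hse = {"a": True, "b": True, "c": False, "d": False}
        up = {"a": True, "b": False, "c": True, "d": False}
        res = hse_enrichment(hse, up)
        assert res.contingency == ((1, 1), (1, 1))

    def test_strong_association_on_the_default_synthetic_cohort(self, sim):
        """HSE presence and the planted up-regulation label associate
        significantly on the default 40-gene cohort."""
        fam = sim.manifest.family_gene_ids
        hse = {g: bool(sim.manifest.hse_positions.get(g)) for g in fam}
        up = {g: g in set(sim.manifest.upregulated_ids) for g in fam}
        res = hse_enrichment(hse, up)
        assert res.p_value < 0.05
        assert res.odds_ratio > 1.0
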