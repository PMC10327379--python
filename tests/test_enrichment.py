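"""Interaction ranking and preranked gene-set enrichment."""

import numpy as np
import pytest

import olivenet as ov
from olivenet.enrichment import (
    EnrichmentResult,
    RankedGeneList,
    enrich_collection,
    gsea_prerank,
    interaction_ranking,
    pathway_frequency,
    read_gmt,
    significant_pathways,
    write_gmt,
)
from olivenet.propagation import PerturbationProfile, PropagationSettings


def brute_force_es(genes, scores, gene_set, weight):
    """Independent direct enumeration of the weighted running sum."""
    hits = [g in gene_set for g in genes]
    n, n_hit = len(genes), sum(hits)
    hit_total = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    running, hi, lo = 0.0, 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            running += (abs(s) ** weight / hit_total) if hit_total > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        hi = max(hi, running)
        lo = min(lo, running)
    # positive extremum wins an (exact or roundoff-level) tie
    return hi if hi + 1e-12 >= -lo else lo


def _ranking(scores, label="m"):
    genes = tuple(f"g{i:02d}" for i in range(len(scores)))
    return RankedGeneList(genes=genes, scores=np.asarray(scores, float),
                         molecule_label=label)


def _profile(values, threshold=400):
    v = np.asarray(values, float)
    return PerturbationProfile(
        values=v / v.sum(),
        settings=PropagationSettings(threshold=threshold, c_disease=0.5, c_molecule=0.5),
    )


class TestInteractionRanking:
    def test_zero_disease_value_annihilates(self):
        d = _profile([0.0, 1.0, 1.0])
        m = _profile([5.0, 1.0, 2.0])
        out = interaction_ranking(d, m, ["gA", "gB", "gC"])
        assert out.scores[out.genes.index("gA")] == 0.0
        assert out.genes[-1] == "gA"

    def test_identical_profiles_rank_by_squared_value(self):
        d = _profile([1.0, 4.0, 2.0])
        out = interaction_ranking(d, d, ["gA", "gB", "gC"])
        assert out.genes == ("gB", "gC", "gA")

    def test_four_gene_hand_computation(self):
        d = _profile([0.4, 0.3, 0.2, 0.1])
        m = _profile([0.1, 0.2, 0.3, 0.4])
        out = interaction_ranking(d, m, ["gA", "gB", "gC", "gD"])
        # products: 0.04, 0.06, 0.06, 0.04 -> ties broken by gene id
        assert out.genes == ("gB", "gC", "gA", "gD")

    def test_threshold_mismatch_is_an_error(self):
        d = _profile([1.0, 1.0], threshold=400)
        m = _profile([1.0, 1.0], threshold=800)
        with pytest.raises(ValueError, match="threshold"):
            interaction_ranking(d, m, ["gA", "gB"])


class TestReadGmt:
    def test_two_sets(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SetA\tdesc\tg1\tg2\nSetB\tdesc\tg3\tg4\tg5\n")
        sets = read_gmt(p)
        assert set(sets) == {"SetA", "SetB"}
        assert sets["SetA"] == frozenset({"g1", "g2"})

    def test_repeated_gene_within_line_deduplicated(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SetA\tdesc\tg1\tg1\tg2\n")
        assert read_gmt(p)["SetA"] == frozenset({"g1", "g2"})

    def test_duplicate_set_name_rejected(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SetA\tdesc\tg1\nSetA\tdesc\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_short_line_reports_line_number(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SetA\tdesc\tg1\nSetB\tdesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(p)

    def test_write_read_round_trip(self, tmp_path):
        sets = {"A": frozenset({"g1", "g2"}), "B": frozenset({"g9"})}
        p = tmp_path / "out.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets


class TestGseaPrerank:
    def test_top_gene_singleton_set_matches_oracle(self):
        rk = _ranking([5.0, 3.0, 2.0, 1.0, 0.5])
        res = gsea_prerank(rk, {"g00"}, n_perm=50, rng_seed=0, min_size=1)
        assert res.es == pytest.approx(
            brute_force_es(rk.genes, rk.scores, {"g00"}, 1.0), abs=1e-12
        )
        assert res.es == pytest.approx(1.0)

    def test_equal_scores_weight_zero_matches_ks_statistic(self):
        rk = _ranking([1.0] * 10)
        gene_set = {"g01", "g02", "g05"}
        res = gsea_prerank(rk, gene_set, weight=0.0, n_perm=50, rng_seed=0)
        assert res.es == pytest.approx(
            brute_force_es(rk.genes, rk.scores, gene_set, 0.0), abs=1e-12
        )

    def test_es_matches_oracle_on_random_small_rankings(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            scores = np.sort(rng.normal(size=n))[::-1]
            size = int(rng.integers(1, n))
            gene_set = {f"g{i:02d}" for i in rng.choice(n, size=size, replace=False)}
            weight = float(rng.choice([0.0, 1.0, 2.0]))
            rk = _ranking(scores)
            res = gsea_prerank(rk, gene_set, weight=weight, n_perm=10,
                               rng_seed=1, min_size=1)
            assert res.es == pytest.approx(
                brute_force_es(rk.genes, rk.scores, gene_set, weight), abs=1e-12
            )
            assert -1.0 <= res.es <= 1.0

    def test_permutation_p_reproducible_under_seed(self):
        rk = _ranking(np.linspace(3, -3, 30))
        s = {"g00", "g03", "g07", "g11"}
        a = gsea_prerank(rk, s, n_perm=200, rng_seed=5)
        b = gsea_prerank(rk, s, n_perm=200, rng_seed=5)
        assert a == b
        assert a.nominal_p >= 1.0 / 201.0

    def test_small_overlap_flagged_untested(self):
        rk = _ranking([3.0, 2.0, 1.0])
        res = gsea_prerank(rk, {"g00"}, n_perm=10, rng_seed=0, min_size=3)
        assert not res.tested
        assert np.isnan(res.es)

    def test_enrich_collection_covers_all_sets(self):
        rk = _ranking(np.linspace(2, -2, 12))
        coll = {"a": {"g00", "g01", "g02"}, "b": {"g09", "g10", "g11"}}
        out = enrich_collection(rk, coll, n_perm=50, rng_seed=1)
        assert [r.set_name for r in out] == ["a", "b"]
        assert out[0].es > 0 > out[1].es


class TestSignificantPathways:
    def _res(self, name, p, es=0.5):
        return EnrichmentResult(set_name=name, es=es, nominal_p=p,
                                n_perm=999, overlap_size=5)

    def test_strict_threshold(self):
        out = significant_pathways([self._res("a", 0.0005), self._res("b", 0.01)],
                                   alpha=0.001)
        assert out == ["a"]

    def test_boundary_p_equal_alpha_excluded(self):
        out = significant_pathways([self._res("a", 0.001)], alpha=0.001)
        assert out == []

    def test_empty_results(self):
        assert significant_pathways([]) == []

    def test_ordering_by_p_then_es_then_name(self):
        out = significant_pathways(
            [self._res("b", 0.0002, es=0.3), self._res("a", 0.0002, es=0.9),
             self._res("c", 0.0001, es=0.1)],
            alpha=0.001,
        )
        assert out == ["c", "a", "b"]


class TestPathwayFrequency:
    def test_single_molecule_single_pathway(self):
        assert pathway_frequency({"m": ["p1"]}) == {"p1": 1}

    def test_empty_map(self):
        assert pathway_frequency({}) == {}

    def test_published_top10_fixture_counts(self):
        _, pathways = ov.table1_fixture()
        freq = pathway_frequency(pathways)
        assert freq["Olfactory Transduction"] == 10
        assert freq["Alzheimer's disease"] == 9
        assert freq["Insulin Signaling Pathway"] == 7
        assert freq["Phosphatidylinositol Signaling System"] == 5
        assert freq["Vascular Smooth Muscle Contraction"] == 3
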