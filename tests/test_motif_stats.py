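import itertools

import numpy as np
import pytest

from lncmech.io_core import MotifModel, PromoterRecord
from lncmech.motif_stats import (SCORE_GRANULARITY, motif_similarity,
                                 presence_fisher, relative_enrichment,
                                 scan_best_scores, scan_motif,
                                 tfbs_enrichment)
from lncmech.synthetic import gen_promoters, random_motif
from oracles import (fisher_greater_oracle, revcomp, scan_pvalue_oracle,
                     sf_lookup, welch_oracle)


def _random_promoter(rng, n=200, name="g1"):
    return PromoterRecord(name, "".join(
        "ACGT"[i] for i in rng.integers(0, 4, n)))


class TestScan:
    def test_consensus_word_attains_max_logodds(self, fixture_motifs):
        for m in fixture_motifs:
            prom = PromoterRecord("c", m.consensus())
            hits = scan_motif(prom, m, alpha=1.0)
            fwd = hits[(hits.strand == "+") & (hits.pos == 0)]
            theory = np.log2(
                ((m.probs + 0.01 * m.background[:, None]) / 1.01)
                / m.background[:, None]).max(axis=0).sum()
            assert fwd.logodds.max() == pytest.approx(theory)

    def test_uniform_motif_scores_zero_everywhere(self):
        m = MotifModel("u", np.full((4, 4), 0.25))
        prom = PromoterRecord("g", "ACGTACGTACGT")
        hits = scan_motif(prom, m, alpha=1.0)
        assert np.allclose(hits.logodds, 0.0)

    def test_motif_wider_than_promoter_is_empty(self, fixture_motifs):
        prom = PromoterRecord("g", "ACG")
        assert scan_motif(prom, fixture_motifs[-1]).empty

    def test_hit_count_monotone_in_alpha(self, fixture_motifs):
        rng = np.random.default_rng(8)
        prom = _random_promoter(rng, 500)
        m = fixture_motifs[2]
        counts = [len(scan_motif(prom, m, alpha=a))
                  for a in (1e-4, 1e-2, 0.5, 1.0)]
        assert counts == sorted(counts)

    def test_n_bases_keep_scan_length(self, fixture_motifs):
        m = fixture_motifs[1]
        prom_n = PromoterRecord("g", "ACGTN" * 20)
        hits = scan_motif(prom_n, m, alpha=1.0)
        expected_windows = 2 * (prom_n.length - m.width + 1)
        assert len(hits) == expected_windows

    @pytest.mark.parametrize("use_skewed_bg", [False, True])
    def test_pvalues_match_word_enumeration(self, fixture_motifs,
                                            skewed_background,
                                            use_skewed_bg):
        """Exact scan p-values equal exhaustive enumeration over all 4^w
        words, both strands, for every fixture motif of width <= 6."""
        rng = np.random.default_rng(99)
        prom = _random_promoter(rng, 150)
        bg = skewed_background if use_skewed_bg else np.full(4, 0.25)
        letter = {c: i for i, c in enumerate("ACGT")}
        for m in fixture_motifs:
            w = m.width
            sf = scan_pvalue_oracle(m.probs, bg)
            sf_rc = scan_pvalue_oracle(m.probs[::-1, ::-1], bg)
            hits = scan_motif(prom, m, background=bg, alpha=1.0)
            assert len(hits) == 2 * (prom.length - w + 1)
            S = np.log2((((m.probs + 0.01 * bg[:, None]) / 1.01))
                        / bg[:, None])
            K = np.rint(S / SCORE_GRANULARITY).astype(int)
            K_rc = K[::-1, ::-1]
            for _, h in hits.iterrows():
                word = [letter[c]
                        for c in prom.sequence[h.pos: h.pos + w]]
                if h.strand == "+":
                    k = int(sum(K[b, c] for c, b in enumerate(word)))
                    expected = sf_lookup(sf, k)
                else:
                    k = int(sum(K_rc[b, c] for c, b in enumerate(word)))
                    expected = sf_lookup(sf_rc, k)
                assert h.pvalue == pytest.approx(expected, abs=1e-9)


class TestRelativeEnrichment:
    def test_identical_sets_are_null(self, fixture_motifs):
        rng = np.random.default_rng(1)
        proms = [_random_promoter(rng, 300, f"g{i}") for i in range(8)]
        res = relative_enrichment(proms, proms, [fixture_motifs[-1]],
                                  scan_alpha=1e-3)
        row = res.iloc[0]
        assert row.pvalue == pytest.approx(1.0) or row.pvalue > 0.5
        assert row.enrichment_ratio == pytest.approx(1.0, rel=0.2)

    def test_all_vs_none_matches_hypergeometric_closed_form(self):
        ratio, p = presence_fisher(10, 10, 0, 10)
        assert p == pytest.approx(fisher_greater_oracle(10, 10, 0, 10),
                                  rel=1e-9)
        assert ratio > 10

    def test_fisher_matches_hypergeometric_oracle_on_random_tables(self):
        rng = np.random.default_rng(15)
        for _ in range(300):
            T = int(rng.integers(1, 61))
            B = int(rng.integers(1, 61))
            t = int(rng.integers(0, T + 1))
            b = int(rng.integers(0, B + 1))
            _, p = presence_fisher(t, T, b, B)
            assert p == pytest.approx(fisher_greater_oracle(t, T, b, B),
                                      rel=1e-9, abs=1e-12)

    def test_planted_motif_flagged_significant(self):
        rng_seed = 42
        motif = random_motif(np.random.default_rng(7), "planted")
        targets, background, _ = gen_promoters(
            n_target=15, n_background=41, length=600, motifs=[motif],
            target_rate=0.9, background_rate=0.1, seed=rng_seed)
        res = relative_enrichment(targets, background, [motif],
                                  scan_alpha=1e-5)
        assert bool(res.iloc[0].significant)
        assert res.iloc[0].enrichment_ratio > 1


class TestSimilarity:
    def test_self_similarity_is_one_forward(self, fixture_motifs):
        m = fixture_motifs[2]
        res = motif_similarity(m, m, n_perm=50, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["best_offset"] == 0
        assert res["orientation"] == "forward"

    def test_reverse_complement_detected(self, fixture_motifs):
        m = fixture_motifs[3]
        res = motif_similarity(m, m.reverse_complement(), n_perm=50, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["orientation"] == "reverse_complement"

    def test_permutation_p_within_mc_error_of_exhaustive(self):
        rng = np.random.default_rng(23)
        m1 = MotifModel("a", rng.dirichlet(np.ones(4), size=4).T)
        m2 = MotifModel("b", rng.dirichlet(np.ones(4), size=4).T)
        # exhaustive null over all 4! = 24 column permutations
        base = motif_similarity(m1, m2, n_perm=2000, seed=1)
        exceed = 0
        total = 0
        from lncmech.motif_stats import _best_alignment
        for perm in itertools.permutations(range(4)):
            p2 = m2.probs[:, list(perm)]
            r = max(_best_alignment(m1.probs, p2, 4)[0],
                    _best_alignment(m1.probs, p2[::-1, ::-1], 4)[0])
            total += 1
            if r >= base["r"] - 1e-12:
                exceed += 1
        exact = exceed / total
        mc_sd = (exact * (1 - exact) / 2000) ** 0.5
        assert abs(base["pvalue"] - exact) < max(4 * mc_sd, 0.02)


class TestTfbsEnrichment:
    def test_identical_sets_not_significant(self, fixture_motifs):
        rng = np.random.default_rng(31)
        proms = [_random_promoter(rng, 300, f"g{i}") for i in range(6)]
        res = tfbs_enrichment(proms, proms, fixture_motifs[:2])
        assert not res["significant"].any()

    def test_planted_sites_detected_with_positive_direction(self):
        motif = random_motif(np.random.default_rng(3), "m")
        targets, background, _ = gen_promoters(
            n_target=10, n_background=20, length=400, motifs=[motif],
            target_rate=1.0, background_rate=0.0, seed=5)
        res = tfbs_enrichment(targets, background, [motif],
                              {"m": ["TFX"]})
        row = res.iloc[0]
        assert bool(row.significant)
        assert row.z > 0
        assert row.tf_names == ["TFX"]

    def test_welch_statistic_matches_closed_form(self):
        x = [12.0, 14.5, 13.1]
        y = [9.0, 8.2, 10.4]
        t_oracle, p_oracle = welch_oracle(x, y)
        from scipy import stats
        res = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        # the implementation delegates to the same Welch formulation
        assert res.statistic == pytest.approx(t_oracle)
        assert res.pvalue == pytest.approx(p_oracle)

    def test_verdicts_invariant_to_promoter_order(self, fixture_motifs):
        rng = np.random.default_rng(41)
        t = [_random_promoter(rng, 250, f"t{i}") for i in range(5)]
        b = [_random_promoter(rng, 250, f"b{i}") for i in range(7)]
        r1 = tfbs_enrichment(t, b, fixture_motifs[:3])
        r2 = tfbs_enrichment(t[::-1], b[::-1], fixture_motifs[:3][::-1])
        m1 = dict(zip(r1.motif_id, r1.pvalue))
        m2 = dict(zip(r2.motif_id, r2.pvalue))
        for k in m1:
            assert m1[k] == pytest.approx(m2[k])
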