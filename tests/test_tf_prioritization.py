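import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lncmech.synthetic import gen_evidence_matrix
from lncmech.tf_prioritization import (EvidenceRecord, ScoreMatrix,
                                       build_score_matrix, cluster_tfs,
                                       evidence_score, intersect_candidates,
                                       select_high_coverage_cluster)


class TestEvidenceScore:
    def test_exhaustive_truth_table(self):
        """All 8 flag combinations map to the five ordinal constants, with
        the strongest applicable category winning on co-occurrence."""
        expected = {
            (False, False, False): 0,
            (True, False, False): 2,
            (False, True, False): 6,
            (True, True, False): 6,
            (False, False, True): 8,
            (True, False, True): 8,
            (False, True, True): 10,
            (True, True, True): 10,
        }
        for (pred, lit, enc), score in expected.items():
            assert evidence_score(lit_predicted_tfbs=pred, lit_chip=lit,
                                  encode_chip=enc) == score

    def test_record_form_agrees_with_flags(self):
        for pred, lit, enc in itertools.product([False, True], repeat=3):
            rec = EvidenceRecord("tf", "g", pred, lit, enc)
            assert evidence_score(rec) == evidence_score(
                lit_predicted_tfbs=pred, lit_chip=lit, encode_chip=enc)


class TestScoreMatrix:
    def test_no_records_gives_zero_matrix(self):
        m = build_score_matrix([], tfs=["a", "b"], genes=["g1"])
        assert (m.scores == 0).all()

    def test_single_encode_record(self):
        m = build_score_matrix(
            [EvidenceRecord("A", "g1", encode_chip=True)],
            tfs=["A", "B"], genes=["g1", "g2"])
        assert m.scores[0, 0] == 8
        assert m.scores.sum() == 8

    def test_conflicting_duplicates_rejected(self):
        recs = [EvidenceRecord("A", "g1", lit_chip=True),
                EvidenceRecord("A", "g1", encode_chip=True)]
        with pytest.raises(ValueError, match="conflicting"):
            build_score_matrix(recs)

    def test_entries_always_in_valid_set(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            recs = [
                EvidenceRecord(f"t{rng.integers(5)}", f"g{rng.integers(4)}",
                               bool(rng.integers(2)), bool(rng.integers(2)),
                               bool(rng.integers(2)))
                for _ in range(10)
            ]
            # deduplicate to avoid conflicting-flag rejections
            uniq = {}
            for r in recs:
                uniq.setdefault((r.tf, r.gene), r)
            m = build_score_matrix(list(uniq.values()))
            assert set(np.unique(m.scores)) <= {0, 2, 6, 8, 10}


class TestClustering:
    def test_identical_rows_one_cluster(self):
        m = ScoreMatrix(tfs=["a", "b", "c"], genes=["g1", "g2"],
                        scores=np.full((3, 2), 8))
        assert len(set(cluster_tfs(m, k=1))) == 1

    def test_k_exceeding_tfs_rejected(self):
        m = ScoreMatrix(tfs=["a"], genes=["g"], scores=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            cluster_tfs(m, k=3)

    def test_planted_two_block_recovery(self):
        recs, manifest = gen_evidence_matrix(n_tf=60, block_size=20,
                                             noise_rate=0.0, seed=2)
        # zero noise means zero-evidence TFs have no records, so the TF
        # universe is passed explicitly
        m = build_score_matrix(recs,
                               tfs=manifest.planted_tf_block["all_tfs"],
                               genes=manifest.planted_tf_block["all_genes"])
        labels = cluster_tfs(m, k=2)
        truth = np.array([t in set(manifest.planted_tf_block["tfs"])
                          for t in m.tfs], dtype=int)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_assignment_invariant_under_row_permutation(self):
        recs, _ = gen_evidence_matrix(n_tf=40, block_size=12, seed=4)
        m = build_score_matrix(recs)
        labels = cluster_tfs(m, k=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(m.tfs))
        m2 = ScoreMatrix(tfs=[m.tfs[i] for i in perm], genes=m.genes,
                         scores=m.scores[perm])
        labels2 = cluster_tfs(m2, k=3)
        # same partition up to relabeling
        by_tf1 = dict(zip(m.tfs, labels))
        by_tf2 = dict(zip(m2.tfs, labels2))
        pairs1 = {frozenset((a, b)) for a in m.tfs for b in m.tfs
                  if a < b and by_tf1[a] == by_tf1[b]}
        pairs2 = {frozenset((a, b)) for a in m.tfs for b in m.tfs
                  if a < b and by_tf2[a] == by_tf2[b]}
        assert pairs1 == pairs2


class TestClusterSelection:
    def test_dominant_cluster_wins_with_full_coverage(self):
        scores = np.zeros((6, 4), dtype=int)
        scores[:3] = 10
        m = ScoreMatrix(tfs=[f"t{i}" for i in range(6)],
                        genes=[f"g{j}" for j in range(4)], scores=scores)
        assignment = np.array([1, 1, 1, 2, 2, 2])
        res = select_high_coverage_cluster(m, assignment)
        assert res["cluster_id"] == 1
        assert res["coverage"] == 1.0
        assert res["tfs"] == ["t0", "t1", "t2"]

    def test_higher_coverage_cluster_beats_lower(self):
        scores = np.zeros((4, 10), dtype=int)
        scores[0:2, 0:8] = 8   # cluster 1 covers 80%
        scores[2:4, 0:3] = 10  # cluster 2 covers 30%
        m = ScoreMatrix(tfs=list("abcd"),
                        genes=[f"g{j}" for j in range(10)], scores=scores)
        res = select_high_coverage_cluster(m, np.array([1, 1, 2, 2]))
        assert res["cluster_id"] == 1
        assert res["coverage"] == pytest.approx(0.8)

    def test_winner_invariant_to_relabeling(self):
        scores = np.zeros((4, 10), dtype=int)
        scores[0:2, 0:8] = 8
        scores[2:4, 0:3] = 10
        m = ScoreMatrix(tfs=list("abcd"),
                        genes=[f"g{j}" for j in range(10)], scores=scores)
        r1 = select_high_coverage_cluster(m, np.array([1, 1, 2, 2]))
        r2 = select_high_coverage_cluster(m, np.array([5, 5, 3, 3]))
        assert r1["tfs"] == r2["tfs"]

    def test_low_coverage_triggers_warning(self):
        scores = np.zeros((2, 10), dtype=int)
        scores[:, 0] = 8
        m = ScoreMatrix(tfs=["a", "b"],
                        genes=[f"g{j}" for j in range(10)], scores=scores)
        with pytest.warns(UserWarning, match="covers only"):
            select_high_coverage_cluster(m, np.array([1, 1]))


class TestIntersection:
    @staticmethod
    def _rows(sig_names, nonsig_names=()):
        return pd.DataFrame({
            "motif_id": [f"m{i}" for i in range(len(sig_names)
                                                + len(nonsig_names))],
            "tf_names": [[n] for n in list(sig_names) + list(nonsig_names)],
            "significant": [True] * len(sig_names)
                           + [False] * len(nonsig_names),
        })

    def test_disjoint_lists_empty(self):
        res = intersect_candidates(["A", "B"], self._rows(["C", "D"]))
        assert res.final_tfs == []

    def test_identical_lists_pass_through_sorted(self):
        res = intersect_candidates(["b", "A"], self._rows(["a", "B"]))
        assert res.final_tfs == ["A", "B"]

    def test_nonsignificant_rows_excluded(self):
        res = intersect_candidates(["A", "B"],
                                   self._rows(["A"], nonsig_names=["B"]))
        assert res.final_tfs == ["A"]

    def test_name_normalization(self):
        res = intersect_candidates([" stat1 "], self._rows(["STAT1"]))
        assert res.final_tfs == ["STAT1"]


class TestOrderInvariance:
    def test_full_prioritization_invariant_to_record_order(self):
        recs, _ = gen_evidence_matrix(n_tf=50, block_size=15, seed=8)
        rng = np.random.default_rng(1)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        m1 = build_score_matrix(recs)
        m2 = build_score_matrix(shuffled)
        w1 = select_high_coverage_cluster(m1, cluster_tfs(m1, k=3))
        w2 = select_high_coverage_cluster(m2, cluster_tfs(m2, k=3))
        assert sorted(w1["tfs"]) == sorted(w2["tfs"])
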