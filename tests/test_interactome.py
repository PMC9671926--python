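import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncmech.interactome import (call_binding_elements, classify_candidates,
                                 combine_catrapid, merge_predictions,
                                 select_consensus)
from oracles import consensus_oracle, elements_oracle


def _merged(ids, interaction, discriminative, lncpro) -> pd.DataFrame:
    df = pd.DataFrame({
        "protein_id": ids,
        "catrapid_interaction": interaction,
        "catrapid_discriminative": discriminative,
        "lncpro_score": lncpro,
    })
    df["catrapid_combined"] = 0.5 * (df["catrapid_interaction"]
                                     + df["catrapid_discriminative"])
    return df


class TestCombine:
    @pytest.mark.parametrize("i, d, expected",
                             [(1.0, 0.0, 0.5), (0.8, 0.6, 0.7)])
    def test_mean(self, i, d, expected):
        assert combine_catrapid(i, d) == pytest.approx(expected)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, a, b):
        assert combine_catrapid(a, b) == combine_catrapid(b, a)


class TestMerge:
    def test_inner_join_keeps_common_only(self):
        cat = pd.DataFrame({"protein_id": ["a", "b", "c"],
                            "interaction_score": [1.0, 2.0, 3.0],
                            "discriminative_power": [0.0, 1.0, 2.0]})
        lnc = pd.DataFrame({"protein_id": ["b", "c", "d"],
                            "score": [10.0, 20.0, 30.0]})
        merged = merge_predictions(cat, lnc)
        assert merged["protein_id"].tolist() == ["b", "c"]
        assert merged["catrapid_combined"].tolist() == [1.5, 2.5]


class TestSelectConsensus:
    def test_identical_scores_select_nothing(self):
        df = _merged(["a", "b", "c"], [1.0] * 3, [1.0] * 3, [5.0] * 3)
        sel, _ = select_consensus(df)
        assert not sel["selected"].any()

    def test_single_winner(self):
        df = _merged(["a", "b", "c"], [0.9, 0.1, 0.2], [0.9, 0.1, 0.2],
                     [50.0, 10.0, 20.0])
        sel, thr = select_consensus(df)
        assert sel.loc[sel["selected"], "protein_id"].tolist() == ["a"]
        assert thr["catrapid_combined"] == pytest.approx(0.4)
        assert thr["lncpro_score"] == pytest.approx(80 / 3)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            select_consensus(_merged([], [], [], []))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 80))
            df = _merged([f"p{i}" for i in range(n)],
                         rng.normal(size=n), rng.normal(size=n),
                         rng.normal(30, 10, size=n))
            sel, _ = select_consensus(df)
            got = set(sel.loc[sel["selected"], "protein_id"])
            assert got == consensus_oracle(df.to_dict("records"))

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 40
        df = _merged([f"p{i}" for i in range(n)], rng.normal(size=n),
                     rng.normal(size=n), rng.normal(30, 10, size=n))
        sel1, _ = select_consensus(df)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        sel2, _ = select_consensus(shuffled)
        assert (set(sel1.loc[sel1["selected"], "protein_id"])
                == set(sel2.loc[sel2["selected"], "protein_id"]))

    def test_raising_thresholds_shrinks_selection(self):
        # strictness monotonicity: >= selects a superset of >
        rng = np.random.default_rng(4)
        n = 60
        df = _merged([f"p{i}" for i in range(n)],
                     rng.integers(0, 3, n).astype(float),
                     rng.integers(0, 3, n).astype(float),
                     rng.integers(0, 50, n).astype(float))
        strict, _ = select_consensus(df, strict=True)
        loose, _ = select_consensus(df, strict=False)
        s = set(strict.loc[strict["selected"], "protein_id"])
        l = set(loose.loc[loose["selected"], "protein_id"])
        assert s <= l


class TestClassify:
    def test_split_and_tf_share(self):
        ann = pd.DataFrame({
            "protein_id": ["a", "b", "c", "d"],
            "family": ["f"] * 4,
            "functional_class": ["transcriptional", "transcriptional",
                                 "post_transcriptional",
                                 "post_transcriptional"],
            "is_tf": [True, False, False, False],
        })
        s = classify_candidates(["a", "b", "c", "d"], ann)
        assert s["pct_transcriptional"] == 50.0
        assert s["pct_post_transcriptional"] == 50.0
        assert s["pct_tf_among_transcriptional"] == 50.0

    def test_no_annotations_warns_with_zero_denominator(self):
        ann = pd.DataFrame({"protein_id": [], "family": [],
                            "functional_class": [], "is_tf": []})
        s = classify_candidates(["x"], ann)
        assert s["n_annotated"] == 0
        assert s["pct_transcriptional"] == 0.0
        assert "warning" in s


class TestBindingElements:
    def test_flat_profile_empty(self):
        assert call_binding_elements(np.zeros(100), 0.5) == []

    def test_single_block_recovered_exactly(self):
        profile = np.zeros(600)
        profile[300:480] = 1.0
        (el,) = call_binding_elements(profile, 0.5, min_length=10)
        assert (el.start, el.end, el.label) == (300, 480, "PBE-1")

    def test_sub_gap_valley_merged(self):
        profile = np.zeros(200)
        profile[50:80] = 1.0
        profile[84:120] = 1.0
        (el,) = call_binding_elements(profile, 0.5, min_length=10,
                                      merge_gap=5)
        assert (el.start, el.end) == (50, 120)

    def test_matches_segmentation_oracle_on_random_profiles(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(5, 300))
            profile = rng.normal(size=n)
            thr = float(rng.normal(0, 0.5))
            min_len = int(rng.integers(1, 8))
            gap = int(rng.integers(0, 5))
            got = [(e.start, e.end) for e in call_binding_elements(
                profile, thr, min_length=min_len, merge_gap=gap)]
            assert got == elements_oracle(profile, thr, min_len, gap)

    def test_labels_rank_by_mean_score(self):
        profile = np.zeros(300)
        profile[10:40] = 1.0
        profile[100:130] = 3.0
        els = call_binding_elements(profile, 0.5, min_length=10)
        labels = {e.label: (e.start, e.end) for e in els}
        assert labels["PBE-1"] == (100, 130)
        assert labels["PBE-2"] == (10, 40)
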