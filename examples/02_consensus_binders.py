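"""Consensus selection of putative lncRNA-binding proteins.

Two predictor score tables (catRAPID-shaped and lncPRO-shaped) with 50
planted binders among 1,000 proteins; proteins above both predictor means
are selected and summarized by functional class.
"""

from lncmech.interactome import (classify_candidates, merge_predictions,
                                 select_consensus)
from lncmech.synthetic import gen_annotations, gen_interaction_scores

catrapid, lncpro, truth = gen_interaction_scores(n=1000, n_true=50, seed=1)
merged = merge_predictions(catrapid, lncpro)
selected, thresholds = select_consensus(merged)
picked = set(selected.loc[selected["selected"], "protein_id"])
planted = set(truth.planted_binders)

print(f"common proteins: {len(merged)}")
print(f"thresholds: combined catRAPID > {thresholds['catrapid_combined']:.3f},"
      f" lncPRO > {thresholds['lncpro_score']:.2f}")
print(f"selected: {len(picked)}  |  planted binders recovered: "
      f"{len(picked & planted)}/{len(planted)}")

annotations = gen_annotations(sorted(picked), seed=2)
summary = classify_candidates(picked, annotations)
print(f"functional classes: {summary['pct_transcriptional']:.0f}% "
      f"transcriptional (n={summary['n_transcriptional']}), "
      f"{summary['pct_post_transcriptional']:.0f}% post-transcriptional; "
      f"{summary['pct_tf_among_transcriptional']:.0f}% of transcriptional "
      "candidates are transcription factors")
print("-> a transcription-factor-heavy consensus set is what points the"
      " mechanism search toward TF partners.")
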