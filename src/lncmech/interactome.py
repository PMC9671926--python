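"""Consensus selection of putative lncRNA-binding proteins from two
predictor score tables, functional-class summarization, and binding-element
calling on per-position RNA-protein interaction profiles.

Two sequence-based interaction predictors are combined: one reports an
interaction score plus a discriminative power per protein (catRAPID-shaped
table), the other a single score (lncPRO-shaped table). Only proteins scored
by both predictors are candidates; a protein is selected when it exceeds the
mean combined score *and* the mean single score over the common set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InteractionPrediction",
    "AnnotationRecord",
    "BindingElement",
    "combine_catrapid",
    "merge_predictions",
    "select_consensus",
    "classify_candidates",
    "call_binding_elements",
]


@dataclass
class InteractionPrediction:
    protein_id: str
    catrapid_interaction: float
    catrapid_discriminative: float
    lncpro_score: float
    selected: bool = False

    @property
    def catrapid_combined(self) -> float:
        return combine_catrapid(self.catrapid_interaction,
                                self.catrapid_discriminative)


@dataclass
class AnnotationRecord:
    protein_id: str
    family: str
    functional_class: str  # transcriptional | post_transcriptional | other
    is_tf: bool


@dataclass
class BindingElement:
    """A contiguous high-score region of an interaction profile (0-based,
    half-open nt coordinates on the RNA)."""
    start: int
    end: int
    mean_score: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("element start must be < end")


def combine_catrapid(interaction: float, discriminative: float) -> float:
    """Arithmetic mean of the interaction score and discriminative power."""
    return 0.5 * (float(interaction) + float(discriminative))


def merge_predictions(catrapid: pd.DataFrame,
                      lncpro: pd.DataFrame) -> pd.DataFrame:
    """Inner-join the two predictor tables on protein_id and add the
    combined catRAPID score. Input shapes: catrapid(protein_id,
    interaction_score, discriminative_power), lncpro(protein_id, score)."""
    for col in ("protein_id", "interaction_score", "discriminative_power"):
        if col not in catrapid.columns:
            raise ValueError(f"catrapid table missing column {col!r}")
    for col in ("protein_id", "score"):
        if col not in lncpro.columns:
            raise ValueError(f"lncpro table missing column {col!r}")
    merged = catrapid.merge(
        lncpro.rename(columns={"score": "lncpro_score"}), on="protein_id",
        how="inner",
    ).rename(columns={"interaction_score": "catrapid_interaction",
                      "discriminative_power": "catrapid_discriminative"})
    merged["catrapid_combined"] = [
        combine_catrapid(i, d)
        for i, d in zip(merged["catrapid_interaction"],
                        merged["catrapid_discriminative"])
    ]
    return merged


def select_consensus(predictions: pd.DataFrame,
                     strict: bool = True) -> tuple[pd.DataFrame, dict]:
    """Select proteins scoring above both predictor means.

    ``predictions`` is the merged common-protein table (see
    :func:`merge_predictions`). Thresholds are the means of
    ``catrapid_combined`` and ``lncpro_score`` over that common set; selection
    is strictly-greater by default (``strict=False`` uses >=). Returns the
    table with a ``selected`` flag plus the thresholds used.
    """
    if predictions.empty:
        raise ValueError("empty predictor intersection: no common proteins")
    df = predictions.copy()
    thr_cat = float(df["catrapid_combined"].mean())
    thr_lnc = float(df["lncpro_score"].mean())
    if strict:
        sel = (df["catrapid_combined"] > thr_cat) & (df["lncpro_score"] > thr_lnc)
    else:
        sel = (df["catrapid_combined"] >= thr_cat) & (df["lncpro_score"] >= thr_lnc)
    df["selected"] = sel.to_numpy()
    thresholds = {"catrapid_combined": thr_cat, "lncpro_score": thr_lnc,
                  "strict": strict}
    return df, thresholds


def classify_candidates(selected_ids, annotations: pd.DataFrame) -> dict:
    """Functional-class summary of the selected binders.

    Percentages are over annotated candidates with a non-"other" class; the
    TF percentage is over the transcriptional subset. Returns counts with
    their denominators so the percentages are auditable.
    """
    ids = set(selected_ids)
    ann = annotations[annotations["protein_id"].isin(ids)]
    classed = ann[ann["functional_class"].isin(
        ["transcriptional", "post_transcriptional"])]
    n_classed = len(classed)
    n_trans = int((classed["functional_class"] == "transcriptional").sum())
    n_post = n_classed - n_trans
    trans = classed[classed["functional_class"] == "transcriptional"]
    n_tf = int(trans["is_tf"].astype(bool).sum())
    summary = {
        "n_candidates": len(ids),
        "n_annotated": n_classed,
        "n_transcriptional": n_trans,
        "n_post_transcriptional": n_post,
        "pct_transcriptional": 100.0 * n_trans / n_classed if n_classed else 0.0,
        "pct_post_transcriptional": 100.0 * n_post / n_classed if n_classed else 0.0,
        "n_tf": n_tf,
        "pct_tf_among_transcriptional": 100.0 * n_tf / n_trans if n_trans else 0.0,
    }
    if n_classed == 0:
        summary["warning"] = "no annotated candidates (denominator 0)"
    return summary


def call_binding_elements(profile, threshold: float, min_length: int = 10,
                          merge_gap: int = 0) -> list[BindingElement]:
    """Call contiguous binding elements on a per-position score profile.

    Maximal runs of positions with score >= threshold are found; runs
    separated by a below-threshold gap shorter than ``merge_gap`` are merged
    (the gap positions are absorbed into the element); merged runs shorter
    than ``min_length`` are dropped. Elements are returned sorted by start
    and labelled PBE-1, PBE-2, ... in order of descending mean score.
    """
    x = np.asarray(profile, dtype=float)
    above = x >= threshold
    runs: list[list[int]] = []
    i = 0
    n = len(x)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    elements = [
        BindingElement(start=s, end=e, mean_score=float(x[s:e].mean()))
        for s, e in merged if e - s >= min_length
    ]
    order = sorted(range(len(elements)),
                   key=lambda k: (-elements[k].mean_score, elements[k].start))
    for rank, k in enumerate(order, start=1):
        elements[k].label = f"PBE-{rank}"
    return elements
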