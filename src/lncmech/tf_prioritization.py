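"""Evidence-based prioritization of candidate lncRNA-partner transcription
factors.

Each (TF, target-gene promoter) pair is scored on an ordinal evidence scale:

* 0 — no information for that promoter;
* 2 — a predicted TF binding site reported in the literature;
* 6 — experimental literature evidence (ChIP) of recruitment;
* 8 — ENCODE ChIP evidence of recruitment;
* 10 — recruitment reported both in the literature and in ENCODE.

When several evidence types co-occur the strongest applicable category wins
(ENCODE outranks literature ChIP, which outranks a predicted site). The
TF x gene score matrix is hierarchically clustered (Euclidean distance,
complete linkage by default), the cluster covering the largest fraction of
genes is selected, and its TFs are intersected with the TFs whose binding
sites are enriched in the target promoters to yield the final candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "EvidenceRecord",
    "ScoreMatrix",
    "CandidateSet",
    "evidence_score",
    "build_score_matrix",
    "cluster_tfs",
    "select_high_coverage_cluster",
    "intersect_candidates",
]

VALID_SCORES = frozenset({0, 2, 6, 8, 10})


@dataclass
class EvidenceRecord:
    tf: str
    gene: str
    lit_predicted_tfbs: bool = False
    lit_chip: bool = False
    encode_chip: bool = False


@dataclass
class ScoreMatrix:
    tfs: list[str]
    genes: list[str]
    scores: np.ndarray  # len(tfs) x len(genes), entries in VALID_SCORES

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.shape != (len(self.tfs), len(self.genes)):
            raise ValueError("score matrix shape mismatch")
        bad = set(np.unique(self.scores)) - VALID_SCORES
        if bad:
            raise ValueError(f"invalid score values {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.tfs, columns=self.genes)


@dataclass
class CandidateSet:
    cluster_id: int
    cluster_tfs: list[str]
    enriched_tfbs_tfs: list[str]
    final_tfs: list[str] = field(default_factory=list)


def evidence_score(record: EvidenceRecord | None = None, *,
                   lit_predicted_tfbs: bool = False, lit_chip: bool = False,
                   encode_chip: bool = False) -> int:
    """Ordinal evidence score for one TF-promoter pair (see module docs)."""
    if record is not None:
        lit_predicted_tfbs = record.lit_predicted_tfbs
        lit_chip = record.lit_chip
        encode_chip = record.encode_chip
    if lit_chip and encode_chip:
        return 10
    if encode_chip:
        return 8
    if lit_chip:
        return 6
    if lit_predicted_tfbs:
        return 2
    return 0


def build_score_matrix(
    records: list[EvidenceRecord],
    tfs: list[str] | None = None,
    genes: list[str] | None = None,
) -> ScoreMatrix:
    """Dense TF x gene score matrix from evidence records.

    Pairs without a record score 0. Row/column order follows first
    appearance in the record list, then lexicographic for axis labels that
    were requested but never seen. Duplicate (tf, gene) records with
    conflicting flags raise.
    """
    seen: dict[tuple[str, str], tuple[bool, bool, bool]] = {}
    rec_tfs: list[str] = []
    rec_genes: list[str] = []
    for r in records:
        key = (r.tf, r.gene)
        flags = (r.lit_predicted_tfbs, r.lit_chip, r.encode_chip)
        if key in seen:
            if seen[key] != flags:
                raise ValueError(
                    f"conflicting duplicate evidence for TF {r.tf!r} / "
                    f"gene {r.gene!r}")
            continue
        seen[key] = flags
        if r.tf not in rec_tfs:
            rec_tfs.append(r.tf)
        if r.gene not in rec_genes:
            rec_genes.append(r.gene)
    if tfs is None:
        tfs = rec_tfs
    else:
        tfs = list(tfs) + sorted(set(rec_tfs) - set(tfs))
    if genes is None:
        genes = rec_genes
    else:
        genes = list(genes) + sorted(set(rec_genes) - set(genes))
    mat = np.zeros((len(tfs), len(genes)), dtype=int)
    tf_idx = {t: i for i, t in enumerate(tfs)}
    gene_idx = {g: j for j, g in enumerate(genes)}
    for (tf, gene), (pred, lit, enc) in seen.items():
        mat[tf_idx[tf], gene_idx[gene]] = evidence_score(
            lit_predicted_tfbs=pred, lit_chip=lit, encode_chip=enc)
    return ScoreMatrix(tfs=list(tfs), genes=list(genes), scores=mat)


def cluster_tfs(matrix: ScoreMatrix, k: int = 4, method: str = "complete",
                metric: str = "euclidean") -> np.ndarray:
    """Agglomerative clustering of TF score vectors, cut into k clusters.

    Returns a cluster label (1..k) per TF in matrix row order. Ties in the
    linkage are broken deterministically by input order (scipy's behaviour
    with observation indices).
    """
    n = len(matrix.tfs)
    if k > n:
        raise ValueError(f"k={k} exceeds number of TFs ({n})")
    if k == n:
        return np.arange(1, n + 1)
    d = pdist(matrix.scores.astype(float), metric=metric)
    Z = linkage(d, method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def select_high_coverage_cluster(
    matrix: ScoreMatrix,
    assignment: np.ndarray,
    coverage_threshold: float = 0.5,
) -> dict:
    """Pick the cluster whose TFs cover the largest fraction of genes.

    Coverage of a cluster = fraction of genes whose within-cluster mean
    score is > 0. Ties are broken by the higher overall mean score. A winner
    below ``coverage_threshold`` triggers a warning (the "majority of
    genes" expectation is not met).
    """
    assignment = np.asarray(assignment)
    stats_ = []
    for cid in sorted(set(assignment.tolist())):
        rows = matrix.scores[assignment == cid]
        coverage = float((rows.mean(axis=0) > 0).mean())
        stats_.append({"cluster_id": int(cid), "coverage": coverage,
                       "mean_score": float(rows.mean()),
                       "n_tfs": int(rows.shape[0])})
    winner = max(stats_, key=lambda s: (s["coverage"], s["mean_score"]))
    if winner["coverage"] <= coverage_threshold:
        warnings.warn(
            f"winning cluster covers only {winner['coverage']:.0%} of genes "
            f"(threshold {coverage_threshold:.0%})", stacklevel=2)
    tf_list = [t for t, c in zip(matrix.tfs, assignment)
               if c == winner["cluster_id"]]
    return {"cluster_id": winner["cluster_id"], "tfs": tf_list,
            "coverage": winner["coverage"], "all_clusters": stats_}


def _norm(name: str) -> str:
    return name.strip().upper()


def intersect_candidates(cluster_tfs: list[str],
                         enriched_rows: pd.DataFrame) -> CandidateSet:
    """Intersect the high-coverage cluster TFs with enriched-TFBS TFs.

    ``enriched_rows`` is a TFBS enrichment table with ``tf_names`` and
    ``significant`` columns; the enriched TF set is the union of tf_names
    over significant rows. Name matching is case-insensitive and
    whitespace-stripped; the final list is sorted.
    """
    enriched: set[str] = set()
    if not enriched_rows.empty:
        for names in enriched_rows.loc[enriched_rows["significant"],
                                       "tf_names"]:
            enriched.update(_norm(n) for n in names)
    cluster_norm = {_norm(t) for t in cluster_tfs}
    final = sorted(cluster_norm & enriched)
    return CandidateSet(
        cluster_id=-1,
        cluster_tfs=sorted({_norm(t) for t in cluster_tfs}),
        enriched_tfbs_tfs=sorted(enriched),
        final_tfs=final,
    )
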