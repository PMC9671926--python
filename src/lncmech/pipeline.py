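"""Run configuration and the full-pipeline orchestrator.

The orchestrator chains the stages in dependency order on a run directory of
inputs (real or produced by :func:`lncmech.synthetic.simulate_run`):

    expression | consensus | triplex   (independent)
        -> NBS relative enrichment
        -> TFBS enrichment
        -> TF prioritization (cluster -> high-coverage cluster -> intersect)

Every output table carries a provenance header (package version, config
hash, seed) and the machine-readable ``summary.json`` enumerates every
threshold actually applied plus the final candidate TF set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import analyze_fractionation, analyze_rip, analyze_silencing
from .interactome import classify_candidates, merge_predictions, select_consensus
from .io_core import read_fasta, read_meme_motifs, read_table, write_table
from .motif_stats import relative_enrichment, tfbs_enrichment
from .tf_prioritization import (EvidenceRecord, build_score_matrix,
                                cluster_tfs, intersect_candidates,
                                select_high_coverage_cluster)
from .triplex import find_triplex_pairs, hits_to_frame, rank_tfos

logger = logging.getLogger("lncmech")

_INPUT_KEYS = {
    "rna_fasta": "rna.fasta",
    "target_promoters": "promoters_target.fasta",
    "background_promoters": "promoters_background.fasta",
    "nbs_motifs": "nbs_motifs.meme",
    "pwm_library": "pwm_library.meme",
    "motif_to_tf": "motif_to_tf.tsv",
    "catrapid": "catrapid.tsv",
    "lncpro": "lncpro.tsv",
    "annotations": "annotations.tsv",
    "evidence": "evidence.tsv",
    "qpcr_silencing": "qpcr_silencing.tsv",
    "qpcr_fractionation": "qpcr_fractionation.tsv",
    "qpcr_rip": "qpcr_rip.tsv",
}


@dataclass
class RunConfig:
    """Validated configuration for :func:`run_all`.

    ``inputs`` maps the canonical input names to file paths; thresholds are
    explicit so the summary can enumerate them. Unknown keys are rejected.
    """

    inputs: dict = field(default_factory=dict)
    outdir: str = "run_out"
    seed: int = 0
    scan_alpha: float = 1e-4
    enrichment_alpha: float = 0.05
    consensus_strict: bool = True
    triplex_min_len: int = 20
    triplex_max_mismatch_rate: float = 0.1
    triplex_min_purity: float = 0.8
    k_clusters: int = 4
    coverage_threshold: float = 0.5
    rip_input_fraction: float = 0.1
    qpcr_efficiency: float = 2.0

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - set(_INPUT_KEYS)
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        for alpha in (self.scan_alpha, self.enrichment_alpha):
            if not 0 < alpha <= 1:
                raise ValueError(f"alpha must be in (0, 1], got {alpha}")
        if self.triplex_min_len < 10:
            raise ValueError("triplex_min_len must be >= 10")
        if not 0 <= self.triplex_max_mismatch_rate < 1:
            raise ValueError("triplex_max_mismatch_rate must be in [0, 1)")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def for_run_dir(cls, run_dir, outdir=None, **overrides) -> "RunConfig":
        """Config pointing at a simulate-style run directory layout."""
        run_dir = Path(run_dir)
        inputs = {k: str(run_dir / v) for k, v in _INPUT_KEYS.items()
                  if (run_dir / v).exists()}
        return cls(inputs=inputs,
                   outdir=str(outdir or run_dir / "results"), **overrides)

    def config_hash(self) -> str:
        # outdir is where results land, not what they are — keep the hash
        # stable across output locations
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [f"lncmech {__version__}", f"config {config.config_hash()}",
            f"seed {config.seed}"]


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write per-stage tables plus summary.json.

    Raises before execution starts if a required input is missing. Returns
    the summary dict (also written to ``<outdir>/summary.json``).
    """
    missing = [k for k in _INPUT_KEYS if k not in config.inputs]
    if missing:
        raise FileNotFoundError(
            f"missing inputs for requested stages: {missing}")
    for key, path in config.inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key!r} not found at {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    prov = _provenance(config)
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            "scan_alpha": config.scan_alpha,
            "enrichment_alpha": config.enrichment_alpha,
            "consensus_strict": config.consensus_strict,
            "triplex_min_len": config.triplex_min_len,
            "triplex_max_mismatch_rate": config.triplex_max_mismatch_rate,
            "triplex_min_purity": config.triplex_min_purity,
            "k_clusters": config.k_clusters,
            "coverage_threshold": config.coverage_threshold,
            "rip_input_fraction": config.rip_input_fraction,
            "qpcr_efficiency": config.qpcr_efficiency,
        },
    }
    try:
        # --- expression ---------------------------------------------------
        logger.info("stage: expression")
        sil = analyze_silencing(
            read_table(config.inputs["qpcr_silencing"],
                       {"gene": str, "ct": float}),
            efficiency=config.qpcr_efficiency)
        write_table(sil, outdir / "silencing.tsv", header_comments=prov)
        frac = analyze_fractionation(
            read_table(config.inputs["qpcr_fractionation"],
                       {"gene": str, "ct": float}),
            efficiency=config.qpcr_efficiency)
        write_table(frac, outdir / "fractionation.tsv", header_comments=prov)
        rip = analyze_rip(
            read_table(config.inputs["qpcr_rip"], {"gene": str, "ct": float}),
            input_fraction=config.rip_input_fraction)
        write_table(rip, outdir / "rip.tsv", header_comments=prov)
        summary["expression"] = {
            "mean_percent_change": float(sil["percent_change_mean"].mean()),
            "n_genes": int(len(sil)),
        }

        # --- consensus binders --------------------------------------------
        logger.info("stage: consensus")
        merged = merge_predictions(
            read_table(config.inputs["catrapid"],
                       {"protein_id": str, "interaction_score": float,
                        "discriminative_power": float}),
            read_table(config.inputs["lncpro"],
                       {"protein_id": str, "score": float}))
        sel, thresholds = select_consensus(merged,
                                           strict=config.consensus_strict)
        write_table(sel, outdir / "consensus.tsv", header_comments=prov)
        ann = read_table(config.inputs["annotations"],
                         {"protein_id": str, "functional_class": str,
                          "is_tf": bool})
        classes = classify_candidates(
            sel.loc[sel["selected"], "protein_id"], ann)
        summary["consensus"] = {
            "n_common": int(len(sel)),
            "n_selected": int(sel["selected"].sum()),
            "thresholds": thresholds,
            "classification": classes,
        }

        # --- triplex --------------------------------------------------------
        logger.info("stage: triplex")
        rna = read_fasta(config.inputs["rna_fasta"])[0].sequence
        targets = read_fasta(config.inputs["target_promoters"])
        hits = find_triplex_pairs(
            rna, targets, min_len=config.triplex_min_len,
            max_mismatch_rate=config.triplex_max_mismatch_rate,
            min_purity=config.triplex_min_purity)
        write_table(hits_to_frame(hits), outdir / "triplex_hits.tsv",
                    header_comments=prov)
        ranking = rank_tfos(hits)
        if not ranking.empty:
            rank_out = ranking.copy()
            rank_out["hit_indices"] = rank_out["hit_indices"].map(
                lambda ix: ",".join(map(str, ix)))
            write_table(rank_out, outdir / "tfo_ranking.tsv",
                        header_comments=prov)
        summary["triplex"] = {
            "n_hits": len(hits),
            "tfo1": (ranking.iloc[0][["tfo_start", "tfo_end",
                                      "n_tts"]].to_dict()
                     if not ranking.empty else None),
        }

        # --- motif enrichment ----------------------------------------------
        logger.info("stage: nbs enrichment")
        background_set = read_fasta(config.inputs["background_promoters"])
        nbs = read_meme_motifs(config.inputs["nbs_motifs"])
        enr = relative_enrichment(
            targets, background_set, nbs, scan_alpha=config.scan_alpha,
            significance=config.enrichment_alpha)
        write_table(enr, outdir / "nbs_enrichment.tsv", header_comments=prov)
        summary["nbs_enrichment"] = {
            "n_motifs": int(len(enr)),
            "n_significant": int(enr["significant"].sum()),
            "significant": sorted(
                enr.loc[enr["significant"], "motif_id"].tolist()),
        }

        # --- TFBS enrichment ------------------------------------------------
        logger.info("stage: tfbs enrichment")
        library = read_meme_motifs(config.inputs["pwm_library"])
        mapping_df = read_table(config.inputs["motif_to_tf"],
                                {"motif_id": str, "tf_name": str})
        motif_to_tf: dict[str, list[str]] = {}
        for _, row in mapping_df.iterrows():
            motif_to_tf.setdefault(row["motif_id"], []).append(row["tf_name"])
        tfbs = tfbs_enrichment(
            targets, background_set, library, motif_to_tf,
            significance=config.enrichment_alpha)
        tfbs_out = tfbs.copy()
        tfbs_out["tf_names"] = tfbs_out["tf_names"].map(",".join)
        write_table(tfbs_out, outdir / "tfbs_enrichment.tsv",
                    header_comments=prov)
        summary["tfbs_enrichment"] = {
            "n_motifs": int(len(tfbs)),
            "n_significant": int(tfbs["significant"].sum()),
        }

        # --- TF prioritization ----------------------------------------------
        logger.info("stage: prioritize")
        ev = read_table(config.inputs["evidence"],
                        {"tf": str, "gene": str, "lit_predicted_tfbs": bool,
                         "lit_chip": bool, "encode_chip": bool})
        records = [
            EvidenceRecord(tf=r.tf, gene=r.gene,
                           lit_predicted_tfbs=bool(r.lit_predicted_tfbs),
                           lit_chip=bool(r.lit_chip),
                           encode_chip=bool(r.encode_chip))
            for r in ev.itertuples()
        ]
        matrix = build_score_matrix(records)
        write_table(matrix.to_frame().reset_index(names="tf"),
                    outdir / "score_matrix.tsv", header_comments=prov)
        assignment = cluster_tfs(matrix, k=config.k_clusters)
        write_table(pd.DataFrame({"tf": matrix.tfs, "cluster": assignment}),
                    outdir / "clusters.tsv", header_comments=prov)
        winner = select_high_coverage_cluster(
            matrix, assignment, coverage_threshold=config.coverage_threshold)
        candidates = intersect_candidates(winner["tfs"], tfbs)
        candidates.cluster_id = winner["cluster_id"]
        write_table(pd.DataFrame({"tf": candidates.final_tfs}),
                    outdir / "candidates.tsv", header_comments=prov)
        summary["prioritization"] = {
            "n_tfs": len(matrix.tfs),
            "winning_cluster": winner["cluster_id"],
            "cluster_size": len(winner["tfs"]),
            "cluster_coverage": winner["coverage"],
            "enriched_tfbs_tfs": candidates.enriched_tfbs_tfs,
            "final_tfs": candidates.final_tfs,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("run complete: %d candidate TFs",
                len(summary["prioritization"]["final_tfs"]))
    return summary
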