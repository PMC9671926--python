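"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and seed, and returns
(or writes) both the emitted inputs and a :class:`TruthManifest` recording
what was planted where, so recovery can be asserted without external data.

Default scales mirror a realistic single-lncRNA study: 15 target and 41
background promoters, a 1,000-protein interaction table with 50 true
binders, 158 TFs with a 34-TF high-evidence block containing 8 planted
partner TFs, and 4-5 donor qPCR designs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (MotifModel, PromoterRecord, write_fasta,
                      write_meme_motifs, write_table)
from .tf_prioritization import EvidenceRecord

__all__ = [
    "TruthManifest",
    "random_motif",
    "sample_motif_instance",
    "gen_promoters",
    "gen_interaction_scores",
    "gen_annotations",
    "gen_evidence_matrix",
    "gen_qpcr",
    "gen_fractionation",
    "gen_rip",
    "gen_triplex_case",
    "simulate_run",
    "verify_manifest",
]

DNA = "ACGT"

#: default 15-gene target panel (interferon-stimulated genes)
TARGET_GENES = [
    "CXCL10", "CXCL11", "DDX58", "EPSTI1", "IFI44", "IFIT2", "MX1", "CCL8",
    "APOBEC3A", "USP18", "IFIH1", "OAS2", "OAS3", "IFITM3", "ISG15",
]
#: default planted partner TF panel
PARTNER_TFS = ["SP1", "MYC", "MAX", "STAT1", "TBP", "STAT2", "YY1", "IRF1"]
#: TFs for the decoy PWMs (background-biased sites; outside the block)
DECOY_TFS = ["NFKB1", "JUN", "FOS", "ELK1"]


@dataclass
class TruthManifest:
    """Ground truth planted by the generators (JSON-serializable)."""

    seed: int
    planted_motifs: list = field(default_factory=list)
    planted_binders: list = field(default_factory=list)
    planted_tf_block: dict = field(default_factory=dict)
    planted_partners: list = field(default_factory=list)
    planted_effects: dict = field(default_factory=dict)
    planted_triplex: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(DNA))[rng.choice(4, size=length, p=p)])


def random_motif(rng: np.random.Generator, motif_id: str, width: int = 12,
                 consensus_prob: float = 0.98) -> MotifModel:
    """An informative PWM with a random consensus word."""
    cons = rng.integers(0, 4, size=width)
    probs = np.full((4, width), (1 - consensus_prob) / 3)
    probs[cons, np.arange(width)] = consensus_prob
    return MotifModel(motif_id=motif_id, probs=probs)


def sample_motif_instance(rng: np.random.Generator, motif: MotifModel) -> str:
    return "".join(
        DNA[rng.choice(4, p=motif.probs[:, c])] for c in range(motif.width)
    )


def _plant(rng: np.random.Generator, seq: list[str], occupied: list,
           instance: str) -> int | None:
    """Place ``instance`` at a uniform random non-overlapping position;
    returns the position or None if no room was found."""
    w = len(instance)
    for _ in range(200):
        pos = int(rng.integers(0, len(seq) - w + 1))
        if all(pos + w <= s or pos >= e for s, e in occupied):
            seq[pos: pos + w] = list(instance)
            occupied.append((pos, pos + w))
            return pos
    return None


def gen_promoters(
    n_target: int = 15,
    n_background: int = 41,
    length: int = 5000,
    gc: float = 0.45,
    motifs: list[MotifModel] | None = None,
    target_rate: float = 0.9,
    background_rate: float = 0.1,
    seed: int = 0,
    target_names: list[str] | None = None,
    background_names: list[str] | None = None,
) -> tuple[list[PromoterRecord], list[PromoterRecord], TruthManifest]:
    """Target and background promoter sets with planted motif instances.

    Sequences are i.i.d. with the requested GC content. For every motif,
    each promoter independently receives one sampled instance with its
    set's rate at a uniform random position; instances never overlap.
    """
    rng = np.random.default_rng(seed)
    motifs = motifs or []
    manifest = TruthManifest(seed=seed)
    t_names = target_names or [f"TGT{i + 1:02d}" for i in range(n_target)]
    b_names = background_names or [f"BG{i + 1:02d}" for i in range(n_background)]

    def build(names: list[str], rate: float, set_name: str):
        out = []
        for name in names:
            seq = list(_random_seq(rng, length, gc))
            occupied: list = []
            for motif in motifs:
                if rng.random() < rate:
                    inst = sample_motif_instance(rng, motif)
                    pos = _plant(rng, seq, occupied, inst)
                    if pos is not None:
                        manifest.planted_motifs.append(
                            {"motif_id": motif.motif_id, "set": set_name,
                             "gene_id": name, "pos": pos, "instance": inst,
                             "target_rate": target_rate,
                             "background_rate": background_rate})
            out.append(PromoterRecord(gene_id=name, sequence="".join(seq)))
        return out

    targets = build(t_names, target_rate, "target")
    backgrounds = build(b_names, background_rate, "background")
    return targets, backgrounds, manifest


def gen_interaction_scores(
    n: int = 1000,
    n_true: int = 50,
    true_shift: tuple[float, float, float] = (2.5, 2.5, 25.0),
    noise_sd: tuple[float, float, float] = (1.0, 1.0, 10.0),
    channel_corr: float = 0.3,
    lncpro_mean: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthManifest]:
    """Two predictor score tables with planted true binders.

    Null scores are Gaussian (catRAPID interaction and discriminative power
    centred at 0, the single-score predictor at ``lncpro_mean``); planted
    binders are shifted upward in every channel by ``true_shift`` with
    cross-channel correlation ``channel_corr``.
    """
    rng = np.random.default_rng(seed)
    ids = [f"P{i + 1:04d}" for i in range(n)]
    true_idx = rng.choice(n, size=n_true, replace=False)
    is_true = np.zeros(n, dtype=bool)
    is_true[true_idx] = True
    z = rng.normal(size=n)  # shared latent propensity

    def channel(mu0: float, shift: float, sd: float) -> np.ndarray:
        eps = rng.normal(size=n)
        noise = channel_corr * z + np.sqrt(1 - channel_corr ** 2) * eps
        return mu0 + shift * is_true + sd * noise

    catrapid = pd.DataFrame({
        "protein_id": ids,
        "interaction_score": channel(0.0, true_shift[0], noise_sd[0]),
        "discriminative_power": channel(0.0, true_shift[1], noise_sd[1]),
    })
    lncpro = pd.DataFrame({
        "protein_id": ids,
        "score": channel(lncpro_mean, true_shift[2], noise_sd[2]),
    })
    manifest = TruthManifest(
        seed=seed, planted_binders=[ids[i] for i in sorted(true_idx)])
    return catrapid, lncpro, manifest


def gen_annotations(
    protein_ids: list[str],
    transcriptional_frac: float = 0.6,
    tf_frac_within_transcriptional: float = 0.87,
    seed: int = 0,
) -> pd.DataFrame:
    """PANTHER-shaped functional annotation table for a protein list."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in protein_ids:
        if rng.random() < transcriptional_frac:
            cls = "transcriptional"
            is_tf = bool(rng.random() < tf_frac_within_transcriptional)
            fam = "TF family" if is_tf else "chromatin regulator"
        else:
            cls = "post_transcriptional"
            is_tf = False
            fam = "RNA-binding protein"
        rows.append({"protein_id": pid, "family": fam,
                     "functional_class": cls, "is_tf": is_tf})
    return pd.DataFrame(rows)


def gen_evidence_matrix(
    n_tf: int = 158,
    genes: list[str] | None = None,
    block_tfs: list[str] | None = None,
    block_size: int = 34,
    block_gene_frac: float = 0.8,
    block_score_probs: dict[int, float] | None = None,
    block_pred_rate: float = 0.7,
    noise_rate: float = 0.02,
    seed: int = 0,
) -> tuple[list[EvidenceRecord], TruthManifest]:
    """TF x gene evidence records with a planted high-evidence TF block.

    On a majority subset of the genes, block TFs draw their evidence
    category from ``block_score_probs`` (default 10: 0.5, 8: 0.45, 6: 0.05
    — ChIP evidence essentially always present, so block rows are tight).
    Block TFs additionally carry a literature-predicted binding site on any
    gene at ``block_pred_rate`` (predicted sites are cheap and ubiquitous
    for genuinely binding TFs). Every other (TF, gene) pair receives each
    flag independently at ``noise_rate``.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else list(TARGET_GENES)
    if block_score_probs is None:
        block_score_probs = {10: 0.5, 8: 0.45, 6: 0.05}
    cats = sorted(block_score_probs)
    cat_p = np.array([block_score_probs[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()
    if block_tfs is None:
        block_tfs = [f"TF{i + 1:03d}" for i in range(block_size)]
    if len(block_tfs) != block_size:
        block_size = len(block_tfs)
    other = [f"TF{i + 1:03d}" for i in range(block_size, n_tf)]
    # keep names unique if caller-provided block names collide with TFnnn
    other = [t for t in other if t not in set(block_tfs)]
    tfs = list(block_tfs) + other
    n_block_genes = max(1, int(round(block_gene_frac * len(genes))))
    block_genes = genes[:n_block_genes]
    records: list[EvidenceRecord] = []
    for tf in tfs:
        in_block = tf in set(block_tfs)
        for gene in genes:
            if in_block:
                pred = bool(rng.random() < block_pred_rate)
                lit = enc = False
                if gene in block_genes:
                    score = cats[int(rng.choice(len(cats), p=cat_p))]
                    enc = score in (8, 10)
                    lit = score in (6, 10)
            else:
                enc = bool(rng.random() < noise_rate)
                lit = bool(rng.random() < noise_rate)
                pred = bool(rng.random() < noise_rate)
            if enc or lit or pred:
                records.append(EvidenceRecord(
                    tf=tf, gene=gene, lit_predicted_tfbs=pred,
                    lit_chip=lit, encode_chip=enc))
    manifest = TruthManifest(
        seed=seed,
        planted_tf_block={"tfs": list(block_tfs), "genes": block_genes,
                          "all_tfs": tfs, "all_genes": genes})
    return records, manifest


def gen_qpcr(
    genes: list[str] | None = None,
    knockdown_fraction: float | dict = 0.5,
    replicate_sd: float = 0.15,
    n_donors: int = 5,
    efficiency: float = 2.0,
    lps_fold: float = 20.0,
    base_ct: float = 30.0,
    ref_ct: float = 15.0,
    reference: str = "ACTB",
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Silencing-experiment Ct table (donor x treatment x silencing x gene).

    Expression model: 1x in medium, ``lps_fold``x under LPS; the knockdown
    multiplies the LPS-induced expression by (1 - fraction). Ct = base -
    log2(expression) + Gaussian noise; the reference gene is constant.
    With ``replicate_sd=0`` the recovered percent change is exact.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else list(TARGET_GENES[:12])
    if not isinstance(knockdown_fraction, dict):
        knockdown_fraction = {g: float(knockdown_fraction) for g in genes}
    rows = []
    for donor in range(1, n_donors + 1):
        for treatment in ("med", "LPS"):
            for silencing in ("si_ctr", "si_lnc"):
                for gene in genes:
                    expr = 1.0
                    if treatment == "LPS":
                        expr = lps_fold
                        if silencing == "si_lnc":
                            expr = lps_fold * (1 - knockdown_fraction[gene])
                    ct = base_ct - np.log2(expr) + rng.normal(0, replicate_sd)
                    rows.append({"donor": donor, "treatment": treatment,
                                 "silencing": silencing, "gene": gene,
                                 "ct": float(ct)})
                rows.append({"donor": donor, "treatment": treatment,
                             "silencing": silencing, "gene": reference,
                             "ct": float(ref_ct
                                         + rng.normal(0, replicate_sd))})
    manifest = TruthManifest(
        seed=seed,
        planted_effects={g: -100.0 * knockdown_fraction[g] for g in genes})
    return pd.DataFrame(rows), manifest


def gen_fractionation(
    gene_percents: dict[str, tuple[float, float, float]] | None = None,
    replicate_sd: float = 0.0,
    base_ct: float = 28.0,
    ref_ct: float = 15.0,
    reference: str = "ACTB",
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Fractionation Ct table encoding planted per-fraction shares (%).

    Default plants a chromatin-enriched nuclear lncRNA profile
    (cytoplasm/nucleoplasm/chromatin = 12.36/54.92/32.72).
    """
    rng = np.random.default_rng(seed)
    if gene_percents is None:
        gene_percents = {"LNC1": (12.36, 54.92, 32.72)}
    fractions = ("cytoplasm", "nucleoplasm", "chromatin")
    rows = []
    for gene, shares in gene_percents.items():
        for frac, share in zip(fractions, shares):
            ct = base_ct - np.log2(share) + rng.normal(0, replicate_sd)
            rows.append({"fraction": frac, "gene": gene, "ct": float(ct)})
    for frac in fractions:
        rows.append({"fraction": frac, "gene": reference,
                     "ct": float(ref_ct + rng.normal(0, replicate_sd))})
    manifest = TruthManifest(
        seed=seed,
        planted_effects={g: list(v) for g, v in gene_percents.items()})
    return pd.DataFrame(rows), manifest


def gen_rip(
    folds: dict[str, float] | None = None,
    gene: str = "LNC1",
    igg_percent: float = 0.5,
    input_fraction: float = 0.1,
    input_ct: float = 20.0,
    replicate_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthManifest]:
    """RIP Ct table with planted fold-over-IgG enrichments per antibody."""
    rng = np.random.default_rng(seed)
    folds = folds if folds is not None else {"aSTAT1": 8.0, "aSTAT2": 8.0,
                                             "ap50": 1.0}
    adjusted = input_ct - np.log2(1.0 / input_fraction)
    rows = [{"antibody": "input", "gene": gene, "ct": float(input_ct)}]
    percents = {"IgG": igg_percent} | {
        ab: fold * igg_percent for ab, fold in folds.items()}
    for ab, pct in percents.items():
        ct_ip = adjusted - np.log2(pct / 100.0) + rng.normal(0, replicate_sd)
        rows.append({"antibody": ab, "gene": gene, "ct": float(ct_ip)})
    manifest = TruthManifest(seed=seed,
                             planted_effects={"folds": folds,
                                              "igg_percent": igg_percent,
                                              "input_fraction": input_fraction})
    return pd.DataFrame(rows), manifest


def gen_triplex_case(
    rna_len: int = 1000,
    tract_len: int = 25,
    n_promoters: int = 5,
    promoter_len: int = 1000,
    gc: float = 0.45,
    seed: int = 0,
) -> tuple[str, list[PromoterRecord], TruthManifest]:
    """An RNA / promoter-set pair with one planted parallel-motif triplex.

    A mixed polypurine tract (A/G, both present) is planted in one promoter
    and the rule-complementary pyrimidine window (A->T, G->C) in the RNA.
    The DNA positions flanking the tract are set to T so no canonical
    triplet can extend the planted window; recovery is therefore exact.
    """
    rng = np.random.default_rng(seed)
    rna = list(_random_seq(rng, rna_len, gc))
    promoters = [
        list(_random_seq(rng, promoter_len, gc)) for _ in range(n_promoters)
    ]
    tract = ""
    while not ("A" in tract and "G" in tract):
        tract = "".join(
            "AG"[i] for i in rng.integers(0, 2, size=tract_len))
    which = int(rng.integers(0, n_promoters))
    tts_pos = int(rng.integers(1, promoter_len - tract_len - 1))
    prom = promoters[which]
    prom[tts_pos: tts_pos + tract_len] = list(tract)
    prom[tts_pos - 1] = "T"
    prom[tts_pos + tract_len] = "T"
    rna_window = tract.replace("A", "t").replace("G", "c").upper()
    tfo_pos = int(rng.integers(1, rna_len - tract_len - 1))
    rna[tfo_pos: tfo_pos + tract_len] = list(rna_window)
    # block RNA-side extension too: G never pairs in the parallel code
    rna[tfo_pos - 1] = "G"
    rna[tfo_pos + tract_len] = "G"
    records = [
        PromoterRecord(gene_id=f"PROM{i + 1:02d}", sequence="".join(p))
        for i, p in enumerate(promoters)
    ]
    manifest = TruthManifest(
        seed=seed,
        planted_triplex={
            "gene_id": records[which].gene_id,
            "tts_start": tts_pos, "tts_end": tts_pos + tract_len,
            "tfo_start": tfo_pos, "tfo_end": tfo_pos + tract_len,
            "orientation": "parallel", "strand": "+",
            "tract": tract, "rna_window": rna_window,
        })
    return "".join(rna), records, manifest


# ---------------------------------------------------------------------------
# full simulated run directory


def simulate_run(
    outdir,
    seed: int = 0,
    promoter_len: int = 1000,
    rna_len: int = 1000,
    n_background: int = 41,
    n_proteins: int = 1000,
    n_true_binders: int = 50,
    n_tf: int = 158,
    block_size: int = 34,
    partner_rate: float = 0.95,
    decoy_target_rate: float = 0.3,
    decoy_background_rate: float = 0.8,
    nbs_target_rate: float = 0.9,
    nbs_background_rate: float = 0.1,
) -> TruthManifest:
    """Write a self-contained simulated run directory and its truth manifest.

    Planted structure: partner-TF PWMs occur almost exclusively in target
    promoters; decoy PWMs are background-biased (so a one-sided target
    enrichment test stays null for them); the evidence block contains the
    partner TFs, so the final cluster x enrichment intersection equals the
    planted partner set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2 ** 31 - 1))  # noqa: E731

    manifest = TruthManifest(seed=seed)
    manifest.planted_partners = list(PARTNER_TFS)

    # PWM library: 8 partner motifs + 4 decoys, plus 3 NBS-style motifs
    motif_rng = np.random.default_rng(sub())
    partner_motifs = [
        random_motif(motif_rng, f"M_{tf}") for tf in PARTNER_TFS]
    decoy_motifs = [random_motif(motif_rng, f"M_{tf}") for tf in DECOY_TFS]
    nbs_motifs = [random_motif(motif_rng, f"NBS-{i + 1}") for i in range(3)]
    write_meme_motifs(partner_motifs + decoy_motifs,
                      outdir / "pwm_library.meme")
    write_meme_motifs(nbs_motifs, outdir / "nbs_motifs.meme")
    motif_to_tf = pd.DataFrame(
        {"motif_id": [m.motif_id for m in partner_motifs + decoy_motifs],
         "tf_name": PARTNER_TFS + DECOY_TFS})
    write_table(motif_to_tf, outdir / "motif_to_tf.tsv")

    # promoters: partner motifs target-only; decoys background-biased;
    # NBS motifs target-enriched. Plant in three passes with disjoint rates.
    t1, b1, m1 = gen_promoters(
        n_target=len(TARGET_GENES), n_background=n_background,
        length=promoter_len, motifs=partner_motifs,
        target_rate=partner_rate, background_rate=0.0, seed=sub(),
        target_names=TARGET_GENES)
    # plant decoys and NBS into the same sequences; occupied intervals are
    # shared across passes so no planted instance overwrites another
    plant_rng = np.random.default_rng(sub())
    occupied_by_gene: dict[str, list] = {}
    for item in m1.planted_motifs:
        occupied_by_gene.setdefault(item["gene_id"], []).append(
            (item["pos"], item["pos"] + len(item["instance"])))

    def plant_more(records, motifs, rate, set_name):
        for rec in records:
            seq = list(rec.sequence)
            occupied = occupied_by_gene.setdefault(rec.gene_id, [])
            for motif in motifs:
                if plant_rng.random() < rate:
                    inst = sample_motif_instance(plant_rng, motif)
                    pos = _plant(plant_rng, seq, occupied, inst)
                    if pos is not None:
                        manifest.planted_motifs.append(
                            {"motif_id": motif.motif_id, "set": set_name,
                             "gene_id": rec.gene_id, "pos": pos,
                             "instance": inst})
            rec.sequence = "".join(seq)

    plant_more(t1, decoy_motifs, decoy_target_rate, "target")
    plant_more(b1, decoy_motifs, decoy_background_rate, "background")
    plant_more(t1, nbs_motifs, nbs_target_rate, "target")
    plant_more(b1, nbs_motifs, nbs_background_rate, "background")
    manifest.planted_motifs.extend(m1.planted_motifs)
    write_fasta(b1, outdir / "promoters_background.fasta")

    # RNA with a planted triplex into the first target promoter
    rna, _, tri = gen_triplex_case(
        rna_len=rna_len, n_promoters=1, promoter_len=promoter_len,
        seed=sub())
    tri.planted_triplex["gene_id"] = t1[0].gene_id
    t1_seq = list(t1[0].sequence)
    s, e = tri.planted_triplex["tts_start"], tri.planted_triplex["tts_end"]
    t1_seq[s - 1: e + 1] = list(
        "T" + tri.planted_triplex["tract"] + "T")
    t1[0].sequence = "".join(t1_seq)
    # planted motif instances clobbered by the triplex tract are retracted
    manifest.planted_motifs = [
        it for it in manifest.planted_motifs
        if not (it["gene_id"] == t1[0].gene_id
                and it["pos"] < e + 1
                and it["pos"] + len(it["instance"]) > s - 1)
    ]
    write_fasta(t1, outdir / "promoters_target.fasta")
    with open(outdir / "rna.fasta", "w") as fh:
        fh.write(">LNC1\n")
        for i in range(0, len(rna), 70):
            fh.write(rna[i: i + 70] + "\n")
    manifest.planted_triplex = tri.planted_triplex

    # interaction score tables + annotations
    cat, lnc, mi = gen_interaction_scores(
        n=n_proteins, n_true=n_true_binders, seed=sub())
    write_table(cat, outdir / "catrapid.tsv")
    write_table(lnc, outdir / "lncpro.tsv")
    manifest.planted_binders = mi.planted_binders
    ann = gen_annotations(list(cat["protein_id"]), seed=sub())
    write_table(ann, outdir / "annotations.tsv")

    # evidence records with the partner TFs inside the block
    extra_block = [f"TF{i + 1:03d}" for i in range(block_size
                                                   - len(PARTNER_TFS))]
    block = PARTNER_TFS + extra_block
    records, me = gen_evidence_matrix(
        n_tf=n_tf, genes=TARGET_GENES, block_tfs=block, seed=sub())
    ev = pd.DataFrame([
        {"tf": r.tf, "gene": r.gene,
         "lit_predicted_tfbs": r.lit_predicted_tfbs,
         "lit_chip": r.lit_chip, "encode_chip": r.encode_chip}
        for r in records
    ])
    write_table(ev, outdir / "evidence.tsv")
    manifest.planted_tf_block = me.planted_tf_block

    # qPCR designs
    qpcr, mq = gen_qpcr(seed=sub())
    write_table(qpcr, outdir / "qpcr_silencing.tsv")
    manifest.planted_effects["knockdown"] = mq.planted_effects
    frac, mf = gen_fractionation(seed=sub())
    write_table(frac, outdir / "qpcr_fractionation.tsv")
    manifest.planted_effects["fractionation"] = mf.planted_effects
    rip, mr = gen_rip(seed=sub())
    write_table(rip, outdir / "qpcr_rip.tsv")
    manifest.planted_effects["rip"] = mr.planted_effects

    manifest.to_json(outdir / "truth.json")
    return manifest


def verify_manifest(run_dir) -> list[str]:
    """Independent check that every planted item exists in the emitted files.

    Returns a list of discrepancy messages (empty = everything verified).
    """
    from .io_core import read_fasta, read_table

    run_dir = Path(run_dir)
    manifest = TruthManifest.from_json(run_dir / "truth.json")
    problems: list[str] = []
    seqs: dict[str, str] = {}
    for fname in ("promoters_target.fasta", "promoters_background.fasta"):
        for rec in read_fasta(run_dir / fname):
            seqs[rec.gene_id] = rec.sequence
    for item in manifest.planted_motifs:
        seq = seqs.get(item["gene_id"], "")
        found = seq[item["pos"]: item["pos"] + len(item["instance"])]
        if found != item["instance"]:
            problems.append(
                f"motif {item['motif_id']} not at {item['gene_id']}:"
                f"{item['pos']} (found {found!r})")
    tri = manifest.planted_triplex
    if tri:
        seq = seqs.get(tri["gene_id"], "")
        if seq[tri["tts_start"]: tri["tts_end"]] != tri["tract"]:
            problems.append("planted TTS tract missing from promoter")
        rna = read_fasta(run_dir / "rna.fasta")[0].sequence
        if rna[tri["tfo_start"]: tri["tfo_end"]] != tri["rna_window"]:
            problems.append("planted TFO window missing from RNA")
    if manifest.planted_binders:
        cat = read_table(run_dir / "catrapid.tsv")
        missing = set(manifest.planted_binders) - set(cat["protein_id"])
        if missing:
            problems.append(f"planted binders missing: {sorted(missing)[:3]}")
    if manifest.planted_tf_block:
        ev = read_table(run_dir / "evidence.tsv")
        missing = set(manifest.planted_tf_block["tfs"]) - set(ev["tf"])
        if missing:
            problems.append(f"block TFs without evidence: {sorted(missing)[:3]}")
    return problems
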