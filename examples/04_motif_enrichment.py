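"""Promoter motif statistics: exact-null scanning, relative enrichment and
motif similarity.

One informative PWM is planted in 90% of 15 target promoters and 10% of 41
background promoters; the scan finds its sites with exact p-values and the
presence-based Fisher test flags the motif as target-enriched.
"""

import numpy as np

from lncmech.motif_stats import (motif_similarity, relative_enrichment,
                                 scan_motif)
from lncmech.synthetic import gen_promoters, random_motif

motif = random_motif(np.random.default_rng(4), "NBS-demo")
targets, background, truth = gen_promoters(
    n_target=15, n_background=41, length=800, motifs=[motif],
    target_rate=0.9, background_rate=0.1, seed=4)

hits = scan_motif(targets[0], motif, alpha=1e-5)
print(f"scan of {targets[0].gene_id}: {len(hits)} hit(s)")
if not hits.empty:
    h = hits.iloc[0]
    print(f"  best site at {h.pos} ({h.strand}): {h.logodds:.2f} bits, "
          f"exact p = {h.pvalue:.2e}")

enr = relative_enrichment(targets, background, [motif], scan_alpha=1e-5)
row = enr.iloc[0]
print(f"\nenrichment: {row.n_target_with}/{row.n_target} targets vs "
      f"{row.n_background_with}/{row.n_background} background, "
      f"ratio {row.enrichment_ratio:.1f}, Fisher p = {row.pvalue:.2e}, "
      f"significant = {row.significant}")
print("-> presence in targets but not background is what separates"
      " lncRNA-dependent from independent promoters.")

sim = motif_similarity(motif, motif.reverse_complement(), n_perm=500, seed=0)
print(f"\nself vs reverse complement: r = {sim['r']:.3f} "
      f"({sim['orientation']}), permutation p = {sim['pvalue']:.3f}")
print("-> orientation-aware similarity groups near-duplicate motifs.")
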