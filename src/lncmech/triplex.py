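"""Simplified RNA:DNA triplex search.

A triplex forms when a single-stranded RNA stretch (the triplex-forming
oligonucleotide, TFO) lies in the major groove of duplex DNA and makes
Hoogsteen or reverse-Hoogsteen hydrogen bonds with the purine strand of the
duplex (the triplex target site, TTS). The canonical triplet code used here:

* parallel (pyrimidine) motif: U·A:T and C·G:C — the RNA runs parallel to
  the purine strand, so RNA U pairs opposite duplex A and RNA C opposite G;
* antiparallel (purine) motif: A·A:T, G·G:C and U·A:T — the RNA runs
  antiparallel to the purine strand.

The search enumerates, for every promoter, both duplex strands and both
orientations, and reports every *maximal* gapless window pair of length >=
``min_len`` whose mismatch rate and TTS purine purity satisfy the configured
thresholds. "Maximal" means no qualifying window on the same alignment
diagonal strictly contains it; window endpoints must be matching triplets.
This is a documented simplification of dedicated triplex engines — it keeps
the canonical pairing chemistry but none of their heuristics or statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import PromoterRecord, reverse_complement

__all__ = [
    "TriplexRuleSet",
    "TriplexHit",
    "CANONICAL_RULES",
    "find_triplex_pairs",
    "rank_tfos",
    "hits_to_frame",
]

_BASES = "ACGT"
_PURINES = frozenset("AG")


@dataclass(frozen=True)
class TriplexRuleSet:
    """Allowed (third-strand RNA base, duplex purine-strand base) triplets
    per orientation. RNA bases are T-normalized (U == T)."""

    name: str
    parallel: frozenset[tuple[str, str]]
    antiparallel: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.parallel and not self.antiparallel:
            raise ValueError("rule set must allow at least one triplet")

    def table(self, orientation: str) -> np.ndarray:
        """5x5 boolean lookup over codes A,C,G,T,N (N never matches)."""
        allowed = getattr(self, orientation)
        t = np.zeros((5, 5), dtype=bool)
        for r, d in allowed:
            t[_BASES.index(r), _BASES.index(d)] = True
        return t


#: canonical triplex code (pyrimidine motif parallel, purine motif antiparallel)
CANONICAL_RULES = TriplexRuleSet(
    name="canonical",
    parallel=frozenset({("T", "A"), ("C", "G")}),
    antiparallel=frozenset({("A", "A"), ("G", "G"), ("T", "A")}),
)


@dataclass
class TriplexHit:
    """One maximal TFO/TTS window pair (0-based, half-open coordinates; TTS
    coordinates are always on the promoter's forward strand)."""

    tfo_start: int
    tfo_end: int
    gene_id: str
    tts_start: int
    tts_end: int
    orientation: str  # parallel | antiparallel
    strand: str       # duplex strand that served as the purine target
    matches: int
    mismatches: int
    score: float

    @property
    def length(self) -> int:
        return self.tfo_end - self.tfo_start


def normalize_rna(rna: str) -> str:
    """Uppercase and convert U to T; validate the alphabet."""
    seq = rna.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return seq


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int64)
    for i, c in enumerate(_BASES):
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(c)] = i
    return out


def _seed_length(min_len: int, rate: float, max_l: int = 5000) -> int:
    """Shortest all-match run every qualifying window must contain.

    A window of length L may carry at most floor(rate*L) mismatches, which
    split the matches into at most floor(rate*L)+1 runs; the pigeonhole bound
    is minimized over admissible window lengths.
    """
    best = min_len
    for L in range(min_len, max_l + 1):
        k = math.floor(rate * L + 1e-12)
        best = min(best, math.ceil((L - k) / (k + 1)))
    return max(best, 1)


def _max_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def _diagonal_windows(m: np.ndarray, pur: np.ndarray, min_len: int,
                      rate: float, min_purity: float) -> list[tuple[int, int]]:
    """Maximal qualifying windows [a, b) on one alignment diagonal.

    ``m`` marks matching triplets, ``pur`` purine positions of the DNA side.
    """
    ell = len(m)
    if ell < min_len:
        return []
    mismatch_prefix = np.concatenate([[0], np.cumsum(~m)])
    purine_prefix = np.concatenate([[0], np.cumsum(pur)])
    match_pos = np.flatnonzero(m)
    results: list[tuple[int, int]] = []
    run_max = -1
    for a in match_pos:
        if a + min_len > ell:
            break
        b = np.arange(a + min_len, ell + 1)
        length = b - a
        ok = (
            m[b - 1]
            & ((mismatch_prefix[b] - mismatch_prefix[a]) <= rate * length)
            & ((purine_prefix[b] - purine_prefix[a]) >= min_purity * length)
        )
        if not ok.any():
            continue
        bmax = int(b[np.flatnonzero(ok)[-1]])
        if bmax > run_max:
            results.append((int(a), bmax))
            run_max = bmax
    return results


def find_triplex_pairs(
    rna: str,
    promoters: list[PromoterRecord],
    rules: TriplexRuleSet = CANONICAL_RULES,
    min_len: int = 20,
    max_mismatch_rate: float = 0.1,
    min_purity: float = 0.8,
    mismatch_penalty: float = 1.0,
) -> list[TriplexHit]:
    """Enumerate maximal TFO/TTS window pairs between an RNA and promoters.

    Both duplex strands and both orientations are examined. Hits are returned
    in deterministic (gene, tts_start, tfo_start, orientation, strand) order.
    """
    if min_len < 10:
        raise ValueError("min_len below 10 nt is sub-biological for a triplex")
    if not 0 <= max_mismatch_rate < 1:
        raise ValueError("max_mismatch_rate must be in [0, 1)")
    rna_t = normalize_rna(rna)
    n = len(rna_t)
    r_fwd = _encode(rna_t)
    seed = _seed_length(min_len, max_mismatch_rate)
    hits: list[TriplexHit] = []
    for prom in promoters:
        mlen = prom.length
        for strand in ("+", "-"):
            dna = prom.sequence if strand == "+" else reverse_complement(
                prom.sequence)
            d_codes = _encode(dna)
            purine = (d_codes == 0) | (d_codes == 2)  # A or G
            for orientation in ("parallel", "antiparallel"):
                r_codes = r_fwd if orientation == "parallel" else r_fwd[::-1]
                table = rules.table(orientation)
                match = table[r_codes[:, None], d_codes[None, :]]
                for d in range(-(n - 1), mlen):
                    i0 = max(0, -d)
                    j0 = max(0, d)
                    ell = min(n - i0, mlen - j0)
                    if ell < min_len:
                        continue
                    m = match[i0 + np.arange(ell), j0 + np.arange(ell)]
                    if _max_run(m) < seed:
                        continue
                    p = purine[j0: j0 + ell]
                    for a, b in _diagonal_windows(
                        m, p, min_len, max_mismatch_rate, min_purity
                    ):
                        ia, ib = i0 + a, i0 + b
                        ja, jb = j0 + a, j0 + b
                        length = b - a
                        mism = int((~m[a:b]).sum())
                        if orientation == "parallel":
                            tfo = (ia, ib)
                        else:
                            tfo = (n - ib, n - ia)
                        if strand == "+":
                            tts = (ja, jb)
                        else:
                            tts = (mlen - jb, mlen - ja)
                        hits.append(
                            TriplexHit(
                                tfo_start=tfo[0], tfo_end=tfo[1],
                                gene_id=prom.gene_id,
                                tts_start=tts[0], tts_end=tts[1],
                                orientation=orientation, strand=strand,
                                matches=length - mism, mismatches=mism,
                                score=float(
                                    (length - mism)
                                    - mismatch_penalty * mism
                                ),
                            )
                        )
    hits.sort(key=lambda h: (h.gene_id, h.tts_start, h.tfo_start,
                             h.orientation, h.strand))
    return hits


def rank_tfos(hits: list[TriplexHit],
              merge_overlap: bool = True) -> pd.DataFrame:
    """Merge TFO windows into regions and rank them to nominate TFO1.

    Overlapping TFO windows (on the RNA) are merged into regions; regions are
    ranked by supporting-TTS count, then total score, then position. The top
    region is labelled TFO1. Returns one row per region with its supporting
    hit indices (into the input list, original order preserved).
    """
    if not hits:
        return pd.DataFrame(columns=[
            "label", "tfo_start", "tfo_end", "n_tts", "total_score",
            "hit_indices"])
    order = sorted(range(len(hits)), key=lambda k: hits[k].tfo_start)
    regions: list[dict] = []
    for k in order:
        h = hits[k]
        if (merge_overlap and regions
                and h.tfo_start < regions[-1]["tfo_end"]):
            regions[-1]["tfo_end"] = max(regions[-1]["tfo_end"], h.tfo_end)
            regions[-1]["hit_indices"].append(k)
        elif (not merge_overlap and regions
                and (h.tfo_start, h.tfo_end) == (regions[-1]["tfo_start"],
                                                 regions[-1]["tfo_end"])):
            regions[-1]["hit_indices"].append(k)
        else:
            regions.append({"tfo_start": h.tfo_start, "tfo_end": h.tfo_end,
                            "hit_indices": [k]})
    for reg in regions:
        reg["n_tts"] = len(reg["hit_indices"])
        reg["total_score"] = float(
            sum(hits[k].score for k in reg["hit_indices"]))
        reg["hit_indices"] = sorted(reg["hit_indices"])
    regions.sort(key=lambda r: (-r["n_tts"], -r["total_score"],
                                r["tfo_start"]))
    for rank, reg in enumerate(regions, start=1):
        reg["label"] = f"TFO{rank}"
    return pd.DataFrame(regions)[
        ["label", "tfo_start", "tfo_end", "n_tts", "total_score",
         "hit_indices"]]


def hits_to_frame(hits: list[TriplexHit]) -> pd.DataFrame:
    """BED-like table of hits (TTS coordinates on the forward strand)."""
    return pd.DataFrame([
        {"gene_id": h.gene_id, "tts_start": h.tts_start,
         "tts_end": h.tts_end, "tfo_start": h.tfo_start,
         "tfo_end": h.tfo_end, "orientation": h.orientation,
         "strand": h.strand, "matches": h.matches,
         "mismatches": h.mismatches, "score": h.score}
        for h in hits
    ])
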