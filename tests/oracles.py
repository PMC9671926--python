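"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result from first principles along a
different algorithmic path than the implementation it checks (exhaustive
enumeration, closed forms, naive loops). Keep them dumb and obvious.
"""

from __future__ import annotations

import itertools
import math
from statistics import fmean

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PARALLEL = {("T", "A"), ("C", "G")}
ANTIPARALLEL = {("A", "A"), ("G", "G"), ("T", "A")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def triplex_windows_oracle(rna: str, promoter_seq: str, gene_id: str,
                           min_len: int, rate: float,
                           purity: float) -> set[tuple]:
    """All maximal qualifying TFO/TTS windows by exhaustive enumeration.

    A window qualifies when its endpoints are matching triplets, its
    mismatch count is <= rate * length and the purine fraction of the DNA
    side is >= purity * length; maximal = not strictly contained in another
    qualifying window on the same (strand, orientation, diagonal).
    Returns tuples (gene, tts_start, tts_end, tfo_start, tfo_end,
    orientation, strand, matches, mismatches).
    """
    rna_t = rna.upper().replace("U", "T")
    n = len(rna_t)
    m = len(promoter_seq)
    out: set[tuple] = set()
    for strand in "+-":
        dna = promoter_seq if strand == "+" else revcomp(promoter_seq)
        for orientation, allowed in (("parallel", PARALLEL),
                                     ("antiparallel", ANTIPARALLEL)):
            r = rna_t if orientation == "parallel" else rna_t[::-1]
            by_diag: dict[int, set[tuple[int, int]]] = {}
            for d in range(-(n - 1), m):
                i0, j0 = max(0, -d), max(0, d)
                ell = min(n - i0, m - j0)
                if ell < min_len:
                    continue
                flags = np.array([
                    (r[i0 + k], dna[j0 + k]) in allowed for k in range(ell)])
                purs = np.array([dna[j0 + k] in "AG" for k in range(ell)])
                mpre = np.concatenate([[0], np.cumsum(~flags)])
                ppre = np.concatenate([[0], np.cumsum(purs)])
                a_idx = np.arange(ell - min_len + 1)
                b_idx = np.arange(min_len, ell + 1)
                aa, bb = np.meshgrid(a_idx, b_idx, indexing="ij")
                length = bb - aa
                valid = (
                    (length >= min_len)
                    & flags[aa]
                    & flags[np.minimum(bb, ell) - 1]
                    & ((mpre[bb] - mpre[aa]) <= rate * length)
                    & ((ppre[bb] - ppre[aa]) >= purity * length)
                )
                for a, b in zip(aa[valid], bb[valid]):
                    by_diag.setdefault(d, set()).add(
                        (int(i0 + a), int(i0 + b)))
            for d, wins in by_diag.items():
                for (a, b) in wins:
                    if any(a2 <= a and b <= b2 and (a2, b2) != (a, b)
                           for (a2, b2) in wins):
                        continue
                    L = b - a
                    pairs = list(zip(r[a:b], dna[d + a: d + b]))
                    mism = L - sum(p in allowed for p in pairs)
                    tfo = (a, b) if orientation == "parallel" else (n - b, n - a)
                    tts = ((d + a, d + b) if strand == "+"
                           else (m - (d + b), m - (d + a)))
                    out.add((gene_id, tts[0], tts[1], tfo[0], tfo[1],
                             orientation, strand, L - mism, mism))
    return out


def consensus_oracle(rows: list[dict], strict: bool = True) -> set[str]:
    """Naive two-threshold filter over merged predictor rows."""
    combined = {r["protein_id"]: 0.5 * (r["catrapid_interaction"]
                                        + r["catrapid_discriminative"])
                for r in rows}
    lncpro = {r["protein_id"]: r["lncpro_score"] for r in rows}
    thr_c = fmean(combined.values())
    thr_l = fmean(lncpro.values())
    if strict:
        return {p for p in combined
                if combined[p] > thr_c and lncpro[p] > thr_l}
    return {p for p in combined
            if combined[p] >= thr_c and lncpro[p] >= thr_l}


def fisher_greater_oracle(t: int, T: int, b: int, B: int) -> float:
    """One-sided Fisher p for [[t, T-t], [b, B-b]] by hypergeometric sums."""
    k = t + b
    denom = math.comb(T + B, k)
    total = 0
    for x in range(t, min(T, k) + 1):
        if k - x <= B:
            total += math.comb(T, x) * math.comb(B, k - x)
    return total / denom


def scan_pvalue_oracle(probs: np.ndarray, background: np.ndarray,
                       pseudocount: float = 0.01,
                       granularity: float = 1e-3) -> dict[int, float]:
    """Exact p-value per integer window score by enumerating all 4^w words."""
    p = (probs + pseudocount * background[:, None]) / (1 + pseudocount)
    scores = np.log2(p / background[:, None])
    K = np.rint(scores / granularity).astype(int)
    w = K.shape[1]
    mass: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=w):
        k = int(sum(K[b, c] for c, b in enumerate(word)))
        pr = float(np.prod([background[b] for b in word]))
        mass[k] = mass.get(k, 0.0) + pr
    keys = sorted(mass, reverse=True)
    sf: dict[int, float] = {}
    acc = 0.0
    for k in keys:
        acc += mass[k]
        sf[k] = min(acc, 1.0)
    return sf


def sf_lookup(sf: dict[int, float], score: int) -> float:
    """P(word score >= score) from an integer-score survival table."""
    keys = sorted(sf)
    if score > keys[-1]:
        return 0.0
    for k in keys:
        if k >= score:
            return sf[k]
    raise AssertionError


def elements_oracle(profile, threshold: float, min_length: int,
                    merge_gap: int) -> list[tuple[int, int]]:
    """Naive segmentation: above-threshold runs, short-gap merge, length
    filter. Returns (start, end) pairs sorted by start."""
    runs = []
    cur = None
    for i, v in enumerate(list(profile) + [threshold - 1]):
        if v >= threshold:
            if cur is None:
                cur = [i, i + 1]
            else:
                cur[1] = i + 1
        elif cur is not None:
            runs.append(tuple(cur))
            cur = None
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_length]


def welch_oracle(x, y) -> tuple[float, float]:
    """One-sided (x greater) Welch t-test from the textbook formulas."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, float(tdist.sf(t, df))


def anova_ss_oracle(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict:
    """Hand-computed sums of squares for a balanced two-way layout."""
    y = np.asarray(y, float)
    grand = y.mean()
    la = sorted(set(a))
    lb = sorted(set(b))
    ss_a = sum((a == x).sum() * (y[a == x].mean() - grand) ** 2 for x in la)
    ss_b = sum((b == x).sum() * (y[b == x].mean() - grand) ** 2 for x in lb)
    ss_cells = sum(
        ((a == x) & (b == z)).sum()
        * (y[(a == x) & (b == z)].mean() - grand) ** 2
        for x in la for z in lb
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_within = sum(
        ((y[(a == x) & (b == z)]
          - y[(a == x) & (b == z)].mean()) ** 2).sum()
        for x in la for z in lb
    )
    df_res = len(y) - len(la) * len(lb)
    return {"ss_a": ss_a, "ss_b": ss_b, "ss_ab": ss_ab,
            "ss_within": ss_within, "df_res": df_res,
            "f_a": (ss_a / (len(la) - 1)) / (ss_within / df_res),
            "f_b": (ss_b / (len(lb) - 1)) / (ss_within / df_res)}
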