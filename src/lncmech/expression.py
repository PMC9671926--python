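"""RT-qPCR analytics: MNE, knockdown percent change, two-way ANOVA with
Bonferroni contrasts, subcellular fractionation percentages, and RIP
percent-of-input / fold-over-IgG.

Mean normalized expression (MNE) for a target gene against a reference gene
(here typically beta-actin) is

    MNE = E_ref ** mean(Ct_ref) / E_target ** mean(Ct_target)

with E the per-primer amplification efficiency (2.0 = perfect doubling).
Knockdown strength is reported as the percent change of treated vs control
MNE. Subcellular localization is the percent of the summed signal across the
cytoplasmic, nucleoplasmic and chromatin fractions. RNA immunoprecipitation
yield is the percent of the diluted input channel, optionally expressed as
fold enrichment over the IgG isotype control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FRACTIONS = ("cytoplasm", "nucleoplasm", "chromatin")

__all__ = [
    "QpcrMeasurement",
    "FractionationResult",
    "RipResult",
    "mne",
    "percent_change",
    "anova2_bonferroni",
    "fraction_percentages",
    "percent_of_input",
    "fold_over_igg",
    "analyze_silencing",
    "analyze_fractionation",
    "analyze_rip",
]


@dataclass
class QpcrMeasurement:
    sample_id: str
    condition: str
    target: str
    ct: list[float]
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not self.ct:
            raise ValueError("at least one Ct replicate required")
        if not all(math.isfinite(c) and c > 0 for c in self.ct):
            raise ValueError(f"{self.sample_id}/{self.target}: Ct values must be finite and > 0")
        if not 1.5 <= self.efficiency <= 2.2:
            raise ValueError(f"efficiency {self.efficiency} outside [1.5, 2.2]")


@dataclass
class FractionationResult:
    fraction: str
    gene: str
    percent_of_total: float


@dataclass
class RipResult:
    antibody: str
    gene: str
    percent_input: float
    fold_over_igg: float


def _check_cts(cts: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray(list(cts), dtype=float)
    if arr.size == 0:
        raise ValueError(f"{label}: empty Ct replicate set")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{label}: non-finite Ct value")
    return arr


def mne(ct_target: Sequence[float], ct_ref: Sequence[float],
        e_target: float = 2.0, e_ref: float = 2.0) -> float:
    """Mean normalized expression of a target gene over a reference gene."""
    t = _check_cts(ct_target, "ct_target")
    r = _check_cts(ct_ref, "ct_ref")
    return float(e_ref ** np.mean(r) / e_target ** np.mean(t))


def percent_change(mne_treated: float, mne_control: float) -> float:
    """Percent change of treated vs control expression (negative = knockdown)."""
    if mne_control <= 0:
        raise ValueError(f"control MNE must be > 0, got {mne_control}")
    return 100.0 * (mne_treated - mne_control) / mne_control


def anova2_bonferroni(
    table: pd.DataFrame,
    value: str = "mne",
    factor_a: str = "treatment",
    factor_b: str = "silencing",
) -> dict:
    """Two-way ANOVA with interaction, then Bonferroni-adjusted contrasts.

    ``table`` holds one row per replicate with a numeric ``value`` column and
    two categorical factor columns. The contrast family is the pairwise
    comparison of ``factor_b`` levels within each level of ``factor_a``
    (e.g. si-control vs si-lncRNA separately in medium and in LPS), each raw
    two-sided p multiplied by the family size and capped at 1. Contrast t
    statistics use the pooled residual mean square from the full model.

    Returns a dict with ``anova`` (effect -> {F, p, df}), ``contrasts``
    (list of dicts) and ``residual_df``.
    """
    df = table[[value, factor_a, factor_b]].copy()
    cells = df.groupby([factor_a, factor_b])[value]
    if (cells.count() < 2).any():
        raise ValueError("every factor cell needs >= 2 replicates")

    y = df[value].to_numpy(dtype=float)
    a = df[factor_a].to_numpy()
    b = df[factor_b].to_numpy()
    a_levels = list(pd.unique(a))
    b_levels = list(pd.unique(b))
    n = len(y)
    grand = y.mean()

    # classical sums of squares (valid for the balanced designs used here;
    # for unbalanced tables this is the type-I decomposition in A, B, A:B order)
    cell_mean = {
        (la, lb): y[(a == la) & (b == lb)].mean()
        for la in a_levels for lb in b_levels
    }
    ss_a = sum(
        ((a == la).sum()) * (y[a == la].mean() - grand) ** 2 for la in a_levels
    )
    ss_b = sum(
        ((b == lb).sum()) * (y[b == lb].mean() - grand) ** 2 for lb in b_levels
    )
    ss_within = sum(
        ((y[(a == la) & (b == lb)] - cell_mean[(la, lb)]) ** 2).sum()
        for la in a_levels for lb in b_levels
    )
    ss_total = ((y - grand) ** 2).sum()
    ss_ab = ss_total - ss_a - ss_b - ss_within
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_res = n - len(a_levels) * len(b_levels)
    mse = ss_within / df_res if df_res > 0 else float("nan")

    def f_test(ss: float, dfx: int) -> dict:
        if mse == 0:
            # degenerate zero-variance design: no evidence either way
            fstat = 0.0 if ss <= 1e-12 else float("inf")
            p = 1.0 if ss <= 1e-12 else 0.0
        else:
            fstat = (ss / dfx) / mse
            p = float(stats.f.sf(fstat, dfx, df_res))
        return {"F": float(fstat), "p": p, "df": dfx}

    anova = {
        factor_a: f_test(ss_a, df_a),
        factor_b: f_test(ss_b, df_b),
        f"{factor_a}:{factor_b}": f_test(max(ss_ab, 0.0), df_ab),
    }

    contrasts = []
    pairs = [
        (la, b1, b2)
        for la in a_levels
        for i, b1 in enumerate(b_levels)
        for b2 in b_levels[i + 1:]
    ]
    family = len(pairs)
    for la, b1, b2 in pairs:
        y1 = y[(a == la) & (b == b1)]
        y2 = y[(a == la) & (b == b2)]
        diff = y1.mean() - y2.mean()
        if mse == 0:
            p_raw = 1.0 if diff == 0 else 0.0
            t = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
        else:
            se = math.sqrt(mse * (1 / len(y1) + 1 / len(y2)))
            t = diff / se
            p_raw = 2 * float(stats.t.sf(abs(t), df_res))
        contrasts.append(
            {
                factor_a: la,
                "pair": (b1, b2),
                "diff": float(diff),
                "t": float(t),
                "p_raw": p_raw,
                "p_adj": min(1.0, p_raw * family),
            }
        )
    return {"anova": anova, "contrasts": contrasts, "residual_df": df_res,
            "family_size": family}


def fraction_percentages(
    mne_by_fraction: Mapping[str, float],
    gene: str = "",
    total: float | None = None,
) -> dict:
    """Express per-fraction signal as percent of the total cell lysate.

    The denominator defaults to the sum over the three fractions; a separately
    measured total-lysate value can be supplied via ``total``. Also reports
    the nuclear share (nucleoplasm + chromatin).
    """
    missing = [f for f in FRACTIONS if f not in mne_by_fraction]
    if missing:
        raise ValueError(f"missing fractions: {missing}")
    vals = {f: float(mne_by_fraction[f]) for f in FRACTIONS}
    if any(v < 0 for v in vals.values()):
        raise ValueError("fraction values must be non-negative")
    denom = float(total) if total is not None else sum(vals.values())
    if denom <= 0:
        raise ValueError("total signal must be > 0")
    pct = {f: 100.0 * v / denom for f, v in vals.items()}
    results = [
        FractionationResult(fraction=f, gene=gene, percent_of_total=pct[f])
        for f in FRACTIONS
    ]
    return {
        "results": results,
        "percent": pct,
        "nuclear_percent": pct["nucleoplasm"] + pct["chromatin"],
    }


def percent_of_input(ct_ip: float, ct_input: float,
                     input_fraction: float = 0.1) -> float:
    """RIP yield as percent of the (diluted) input channel.

    The input Ct is first adjusted for the dilution: a 10% input lags the
    full input by log2(1/0.1) cycles. Returns 100 * 2**(adjusted - ct_ip).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    for name, v in (("ct_ip", ct_ip), ("ct_input", ct_input)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def fold_over_igg(percent_input_ab: float, percent_input_igg: float) -> float:
    """Antibody RIP yield as fold over the IgG isotype control."""
    if percent_input_igg <= 0:
        raise ValueError("IgG percent-of-input must be > 0 (degenerate control)")
    if percent_input_ab < 0:
        raise ValueError("antibody percent-of-input must be >= 0")
    return percent_input_ab / percent_input_igg


# ---------------------------------------------------------------------------
# table-level analyses


def _cell_mne(df: pd.DataFrame, reference: str, efficiency: float,
              keys: list[str]) -> pd.DataFrame:
    """MNE per grouping cell from a long Ct table (gene column holds target
    and reference rows)."""
    ref = df[df["gene"] == reference]
    tgt = df[df["gene"] != reference]
    if ref.empty:
        raise ValueError(f"reference gene {reference!r} absent from table")
    ref_ct = ref.groupby(keys)["ct"].apply(list)
    rows = []
    for (gene, *cell), sub in tgt.groupby(["gene"] + keys):
        cell_key = tuple(cell) if len(cell) > 1 else cell[0]
        if cell_key not in ref_ct.index:
            raise ValueError(f"no reference Ct for cell {cell}")
        rows.append(
            dict(zip(["gene"] + keys, [gene] + list(cell)))
            | {"mne": mne(list(sub["ct"]), ref_ct.loc[cell_key],
                          efficiency, efficiency)}
        )
    return pd.DataFrame(rows)


def analyze_silencing(
    ct_table: pd.DataFrame,
    reference: str = "ACTB",
    efficiency: float = 2.0,
    treated_level: str = "si_lnc",
    control_level: str = "si_ctr",
    stimulus_level: str = "LPS",
) -> pd.DataFrame:
    """Per-gene knockdown summary from a silencing-experiment Ct table.

    Expects columns donor, treatment, silencing, gene, ct (reference-gene rows
    included). Computes MNE per (donor, treatment, silencing, gene), the
    per-donor percent change of treated vs control silencing under the
    stimulus, and the two-way ANOVA (treatment x silencing on donor MNEs)
    with Bonferroni-adjusted contrasts; returns one row per gene.
    """
    mne_df = _cell_mne(ct_table, reference, efficiency,
                       ["donor", "treatment", "silencing"])
    out = []
    for gene, sub in mne_df.groupby("gene"):
        lps = sub[sub["treatment"] == stimulus_level]
        per_donor = []
        for donor, dsub in lps.groupby("donor"):
            ctr = dsub[dsub["silencing"] == control_level]["mne"]
            trt = dsub[dsub["silencing"] == treated_level]["mne"]
            if len(ctr) == 1 and len(trt) == 1:
                per_donor.append(
                    percent_change(float(trt.iloc[0]), float(ctr.iloc[0]))
                )
        res = anova2_bonferroni(sub, value="mne", factor_a="treatment",
                                factor_b="silencing")
        stim_contrast = next(
            c for c in res["contrasts"]
            if c["treatment"] == stimulus_level
        )
        out.append(
            {
                "gene": gene,
                "percent_change_mean": float(np.mean(per_donor)),
                "percent_change_sem": (
                    float(np.std(per_donor, ddof=1) / math.sqrt(len(per_donor)))
                    if len(per_donor) > 1 else 0.0
                ),
                "n_donors": len(per_donor),
                "p_adj": stim_contrast["p_adj"],
            }
        )
    return pd.DataFrame(out).sort_values("gene").reset_index(drop=True)


def analyze_fractionation(
    ct_table: pd.DataFrame, reference: str = "ACTB", efficiency: float = 2.0
) -> pd.DataFrame:
    """Percent-of-total across the three fractions per gene.

    Expects columns fraction, gene, ct (with reference rows per fraction).
    """
    mne_df = _cell_mne(ct_table, reference, efficiency, ["fraction"])
    rows = []
    for gene, sub in mne_df.groupby("gene"):
        vals = dict(zip(sub["fraction"], sub["mne"]))
        summary = fraction_percentages(vals, gene=gene)
        for frac in FRACTIONS:
            rows.append({"gene": gene, "fraction": frac,
                         "percent_of_total": summary["percent"][frac],
                         "nuclear_percent": summary["nuclear_percent"]})
    return pd.DataFrame(rows)


def analyze_rip(
    ct_table: pd.DataFrame,
    input_fraction: float = 0.1,
    igg_label: str = "IgG",
    input_label: str = "input",
) -> pd.DataFrame:
    """Percent-of-input and fold-over-IgG per antibody and gene.

    Expects columns antibody, gene, ct; one ``input`` row per gene.
    """
    cts = ct_table.groupby(["antibody", "gene"])["ct"].mean()
    genes = sorted(ct_table["gene"].unique())
    antibodies = [a for a in ct_table["antibody"].unique()
                  if a != input_label]
    rows = []
    for gene in genes:
        ct_in = float(cts.loc[(input_label, gene)])
        pi = {
            ab: percent_of_input(float(cts.loc[(ab, gene)]), ct_in,
                                 input_fraction)
            for ab in antibodies
        }
        for ab in antibodies:
            fold = (fold_over_igg(pi[ab], pi[igg_label])
                    if ab != igg_label and pi[igg_label] > 0 else 1.0)
            rows.append({"antibody": ab, "gene": gene,
                         "percent_input": pi[ab], "fold_over_igg": fold})
    return pd.DataFrame(rows)
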