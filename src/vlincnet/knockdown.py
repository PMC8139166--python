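"""Transcriptome response to CRISPR/Cas13 vlincRNA knockdown.

Uses bounded fold changes: FC-Td = Td/(Td + T0) compares day d of induction
to day 0 within one arm (targeting T or mismatch control NT), and the
relative fold change RFC-Td = FC-Td/(FC-Td + FC-NTd) compares the targeting
arm to its control. Both statistics live in (0, 1) and equal 0.5 exactly
under no change, so an RFC above 0.5 means the gene rose more (or fell
less) upon knockdown than in the control line. Effect sizes contrast the
negatively and positively co-expressed gene groups, whose RFCs should move
apart when the vlincRNA regulates its network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import cohens_d
from .expression import P_MAX, RHO_MIN

ARM_DAY_COLUMNS = ["T0", "T3", "T6", "NT0", "NT3", "NT6"]
MIN_FPKM = 1.0
FC_PSEUDOCOUNT = 0.01  # FPKM added to every value before the bounded ratios

RFC_COLUMNS = ["FC_T3", "FC_T6", "FC_NT3", "FC_NT6", "RFC_T3", "RFC_T6", "RFC_T36"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in ARM_DAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"knockdown table missing columns: {missing}")
    if (table[ARM_DAY_COLUMNS].to_numpy() < 0).any():
        raise ValueError("negative FPKM values")


def filter_expressed(table: pd.DataFrame, min_fpkm: float = MIN_FPKM) -> pd.Index:
    """Genes with FPKM above ``min_fpkm`` in at least one of the six
    arm x day columns."""
    _check_table(table)
    return table.index[(table[ARM_DAY_COLUMNS] > min_fpkm).any(axis=1)]


def relative_fold_change(
    table: pd.DataFrame, pseudocount: float = FC_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-gene bounded fold changes and relative fold changes.

    FC_Td  = Td / (Td + T0)         (same for the NT arm)
    RFC_Td = FC_Td / (FC_Td + FC_NTd)
    RFC_T36 = (RFC_T3 + RFC_T6) / 2

    A pseudocount is added to every FPKM value so that the ratios are
    defined at zero abundance while preserving FC = RFC = 0.5 under exact
    equality.
    """
    _check_table(table)
    v = table[ARM_DAY_COLUMNS].astype(float) + pseudocount
    out = pd.DataFrame(index=table.index)
    out["FC_T3"] = v.T3 / (v.T3 + v.T0)
    out["FC_T6"] = v.T6 / (v.T6 + v.T0)
    out["FC_NT3"] = v.NT3 / (v.NT3 + v.NT0)
    out["FC_NT6"] = v.NT6 / (v.NT6 + v.NT0)
    out["RFC_T3"] = out.FC_T3 / (out.FC_T3 + out.FC_NT3)
    out["RFC_T6"] = out.FC_T6 / (out.FC_T6 + out.FC_NT6)
    out["RFC_T36"] = (out.RFC_T3 + out.RFC_T6) / 2
    bad = ~np.isfinite(out[RFC_COLUMNS].to_numpy()).all(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} genes with undefined ratios excluded")
        out = out[~bad]
    return out


@dataclass
class GeneGroups:
    """The four correlation-based gene groups for one targeted vlincRNA."""

    positive: pd.Index
    negative: pd.Index
    background_positive: pd.Index
    background_negative: pd.Index

    def top(self, sign: str, n: int) -> pd.Index:
        group = self.positive if sign == "positive" else self.negative
        return group[:n]


def group_genes(
    rho: pd.Series,
    p: pd.Series,
    rho_min: float = RHO_MIN,
    p_max: float = P_MAX,
    strict_background: bool = False,
) -> GeneGroups:
    """Split genes by their co-expression with the targeted vlincRNA.

    positive/negative networks: rho beyond +/-rho_min with p < p_max,
    ordered by correlation strength (most positive / most negative first)
    so that ``top(sign, n)`` yields the strongest co-expressed genes.
    Background groups: remaining genes by correlation sign; with
    ``strict_background`` they additionally require p > p_max.
    """
    rho, p = rho.align(p, join="inner")
    ok = rho.notna() & p.notna()
    rho, p = rho[ok], p[ok]
    pos_net = (rho > rho_min) & (p < p_max)
    neg_net = (rho < -rho_min) & (p < p_max)
    bg_pos = (rho > 0) & ~pos_net
    bg_neg = (rho < 0) & ~neg_net
    if strict_background:
        bg_pos &= p > p_max
        bg_neg &= p > p_max
    return GeneGroups(
        positive=rho[pos_net].sort_values(ascending=False, kind="stable").index,
        negative=rho[neg_net].sort_values(ascending=True, kind="stable").index,
        background_positive=rho[bg_pos].index,
        background_negative=rho[bg_neg].index,
    )


def _one_comparison(neg_vals: np.ndarray, pos_vals: np.ndarray) -> Dict[str, float]:
    if neg_vals.size < 3 or pos_vals.size < 3:
        return {"median_diff": float("nan"), "cohens_d": float("nan"),
                "p": float("nan"), "n_neg": neg_vals.size, "n_pos": pos_vals.size}
    res = stats.mannwhitneyu(neg_vals, pos_vals, alternative="greater")
    return {
        "median_diff": float(np.median(neg_vals) - np.median(pos_vals)),
        "cohens_d": cohens_d(neg_vals, pos_vals),
        "p": float(res.pvalue),
        "n_neg": neg_vals.size,
        "n_pos": pos_vals.size,
    }


def effect_summary(
    rfc: pd.DataFrame,
    groups: GeneGroups,
    mode: str = "combined",
    top_ns: Sequence[int] = (100, 50),
) -> pd.DataFrame:
    """Difference of medians, Cohen's d, and one-sided rank-sum p that the
    negatively co-expressed genes' RFC exceeds the positively co-expressed
    genes', at each granularity (all network, top-100, top-50, background).

    ``mode="combined"`` pools the day-3 and day-6 RFC values; ``"by_day"``
    reports each day separately. Groups with < 3 genes yield missing
    statistics.
    """
    if mode == "combined":
        day_cols = {"combined": ["RFC_T3", "RFC_T6"]}
    elif mode == "by_day":
        day_cols = {"day3": ["RFC_T3"], "day6": ["RFC_T6"]}
    else:
        raise ValueError("mode must be 'combined' or 'by_day'")

    comparisons: Dict[str, Tuple[pd.Index, pd.Index]] = {
        "network_all": (groups.negative, groups.positive),
        "background": (groups.background_negative, groups.background_positive),
    }
    for n in top_ns:
        if len(groups.negative) < n or len(groups.positive) < n:
            warnings.warn(f"network smaller than top-{n}; using all network genes")
        comparisons[f"network_top{n}"] = (
            groups.top("negative", n),
            groups.top("positive", n),
        )

    rows = []
    for when, cols in day_cols.items():
        for name, (neg_idx, pos_idx) in comparisons.items():
            neg = rfc.loc[rfc.index.intersection(neg_idx), cols].to_numpy().ravel()
            pos = rfc.loc[rfc.index.intersection(pos_idx), cols].to_numpy().ravel()
            rows.append({"timepoints": when, "comparison": name,
                         **_one_comparison(neg, pos)})
    return pd.DataFrame(
        rows,
        columns=["timepoints", "comparison", "median_diff", "cohens_d",
                 "p", "n_neg", "n_pos"],
    )
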