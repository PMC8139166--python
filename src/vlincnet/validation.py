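"""Cross-validation of co-expression networks against RAT gene sets.

The co-expressed genes of each sign are split by expression half (the
negative network is evaluated in the top half of expression, the positive
network in the bottom half), overlapped with the RAT-derived gene sets at
each percentile threshold with a one-sided hypergeometric test, and the
percentile with the lowest p at the gene level is chosen per sign. The
final (validated) network per (vlincRNA, treatment, sign) is the
co-expressed set intersected with the RAT genes at that threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import _stats
from .annotation import GeneAnnotation
from .expression import CoexpressionNetwork
from .rat import PERCENTILES

logger = logging.getLogger(__name__)

# (sign, expression half) groups whose gene-level overlap picks the final
# threshold: negative network in the top half, positive in the bottom half
DESIGNATED_GROUPS = {"negative": "top", "positive": "bottom"}

OVERLAP_COLUMNS = [
    "vlinc",
    "treatment",
    "sign",
    "half",
    "percentile",
    "level",
    "n_group",
    "a",
    "b",
    "c",
    "d",
    "odds_ratio",
    "p",
    "flagged",
]

RatGeneSets = Mapping[Tuple[str, str, int, str], Set[str]]
"""(vlinc, treatment, percentile, level) -> gene set."""


@dataclass
class FinalNetwork:
    """Chosen percentile and validated gene set per (vlinc, treatment, sign)."""

    choices: pd.DataFrame = field(repr=False)  # vlinc, treatment, sign, percentile, p, flagged
    validated: Dict[Tuple[str, str, str], Set[str]] = field(repr=False, default_factory=dict)

    def genes(self, vlinc: str, treatment: str, sign: str) -> Set[str]:
        return self.validated.get((vlinc, treatment, sign), set())


def stratified_overlap(
    net: CoexpressionNetwork,
    vlinc: str,
    treatment: str,
    rat_genes: RatGeneSets,
    halves: pd.Series,
    universe: Set[str],
    levels: Sequence[str] = ("gene", "region"),
    percentiles: Sequence[int] = PERCENTILES,
) -> pd.DataFrame:
    """2x2 overlap of each (sign x expression-half) co-expression group with
    the RAT gene sets, per percentile and level, over the expressed universe."""
    rows = []
    for sign in ("negative", "positive"):
        partners = net.partners(vlinc, sign) & universe
        for half in ("top", "bottom"):
            group = {g for g in partners if halves.get(g) == half}
            for level in levels:
                for pct in percentiles:
                    rat = rat_genes.get((vlinc, treatment, pct, level), set()) & universe
                    if group:
                        s = _stats.overlap_stats(group, rat, universe)
                        flagged = False
                    else:
                        s = {"a": 0, "b": 0, "c": len(rat),
                             "d": len(universe) - len(rat),
                             "odds_ratio": float("nan"), "p": 1.0}
                        flagged = True
                    rows.append({
                        "vlinc": vlinc, "treatment": treatment, "sign": sign,
                        "half": half, "percentile": pct, "level": level,
                        "n_group": len(group), **s, "flagged": flagged,
                    })
    return pd.DataFrame(rows, columns=OVERLAP_COLUMNS)


def select_final_threshold(
    overlaps: pd.DataFrame,
    net: CoexpressionNetwork,
    rat_genes: RatGeneSets,
) -> FinalNetwork:
    """Pick, per (vlinc, treatment, sign), the percentile with the lowest
    gene-level overlap p in the designated sign x half group (ties and the
    all-p=1 fallback resolve to the strictest percentile), and intersect the
    full co-expressed sign group with the RAT genes at that threshold."""
    gene_level = overlaps[overlaps.level == "gene"]
    rows = []
    validated: Dict[Tuple[str, str, str], Set[str]] = {}
    for (vlinc, treatment), sub in gene_level.groupby(["vlinc", "treatment"]):
        for sign, half in DESIGNATED_GROUPS.items():
            cand = sub[(sub.sign == sign) & (sub.half == half)].sort_values("percentile")
            if cand.empty:
                continue
            if set(cand.percentile) != set(PERCENTILES):
                raise ValueError(
                    f"overlaps must cover all percentiles for {vlinc}/{treatment}"
                )
            flagged = bool((cand.p == 1.0).all())
            # stable sort: lowest p, then strictest (smallest) percentile
            best = cand.sort_values(["p", "percentile"], kind="stable").iloc[0]
            pct = int(best.percentile)
            rat = rat_genes.get((vlinc, treatment, pct, "gene"), set())
            validated[(vlinc, treatment, sign)] = net.partners(vlinc, sign) & rat
            rows.append({
                "vlinc": vlinc, "treatment": treatment, "sign": sign,
                "percentile": pct, "p": float(best.p), "flagged": flagged,
            })
            if flagged:
                logger.warning(
                    "all overlap p-values are 1 for %s/%s/%s; strictest "
                    "percentile used", vlinc, treatment, sign,
                )
    choices = pd.DataFrame(
        rows, columns=["vlinc", "treatment", "sign", "percentile", "p", "flagged"]
    )
    return FinalNetwork(choices=choices, validated=validated)


def network_stability(final: FinalNetwork, universe: Set[str]) -> pd.DataFrame:
    """Pairwise agreement of a vlincRNA's validated networks across
    treatments: shared fraction (|intersection| / |smaller set|), odds ratio
    and one-sided hypergeometric p over the expressed universe."""
    rows = []
    by_vlinc_sign: Dict[Tuple[str, str], Dict[str, Set[str]]] = {}
    for (vlinc, treatment, sign), genes in final.validated.items():
        by_vlinc_sign.setdefault((vlinc, sign), {})[treatment] = genes
    for (vlinc, sign), per_treat in sorted(by_vlinc_sign.items()):
        treatments = sorted(per_treat)
        if len(treatments) < 2:
            logger.info("single treatment for %s/%s; stability skipped", vlinc, sign)
            continue
        for i, ta in enumerate(treatments):
            for tb in treatments[i + 1 :]:
                a, b = per_treat[ta] & universe, per_treat[tb] & universe
                smaller = min(len(a), len(b))
                frac = len(a & b) / smaller if smaller else float("nan")
                if a or b:
                    s = _stats.overlap_stats(a, b, universe)
                    orr, p = s["odds_ratio"], s["p"]
                else:
                    orr, p = float("nan"), 1.0
                rows.append({
                    "vlinc": vlinc, "sign": sign,
                    "treatment_a": ta, "treatment_b": tb,
                    "shared_fraction": frac, "odds_ratio": orr, "p": p,
                })
    return pd.DataFrame(
        rows,
        columns=["vlinc", "sign", "treatment_a", "treatment_b",
                 "shared_fraction", "odds_ratio", "p"],
    )


def cis_trans_comparison(
    final: FinalNetwork,
    ann: GeneAnnotation,
    net: CoexpressionNetwork,
    rat_genes: RatGeneSets,
    universe: Set[str],
) -> Dict[str, object]:
    """Per-sample overlap odds ratios recomputed on same-chromosome (cis)
    genes versus all genes, with a pooled two-sided rank-sum comparison.

    Returns {"table": per-sample DataFrame, "p": rank-sum p,
    "median_cis", "median_all"}. Samples with no cis genes are excluded.
    """
    chrom_of = ann.chromosome_of()
    rows = []
    for _, row in final.choices.iterrows():
        vlinc, treatment, sign, pct = row.vlinc, row.treatment, row.sign, int(row.percentile)
        group = net.partners(vlinc, sign) & universe
        rat = rat_genes.get((vlinc, treatment, pct, "gene"), set()) & universe
        if not group:
            continue
        s_all = _stats.overlap_stats(group, rat, universe)
        vchrom = chrom_of[vlinc]
        cis_universe = {g for g in universe if chrom_of.get(g) == vchrom}
        cis_group = group & cis_universe
        if not cis_group or not cis_universe:
            logger.info("no cis genes for %s/%s/%s; excluded", vlinc, treatment, sign)
            continue
        s_cis = _stats.overlap_stats(cis_group, rat & cis_universe, cis_universe)
        rows.append({
            "vlinc": vlinc, "treatment": treatment, "sign": sign,
            "percentile": pct,
            "odds_ratio_all": s_all["odds_ratio"],
            "odds_ratio_cis": s_cis["odds_ratio"],
        })
    table = pd.DataFrame(
        rows,
        columns=["vlinc", "treatment", "sign", "percentile",
                 "odds_ratio_all", "odds_ratio_cis"],
    )
    if len(table) >= 2:
        res = stats.mannwhitneyu(
            table.odds_ratio_cis, table.odds_ratio_all, alternative="two-sided"
        )
        p = float(res.pvalue)
    else:
        p = float("nan")
    return {
        "table": table,
        "p": p,
        "median_cis": float(table.odds_ratio_cis.median()) if len(table) else float("nan"),
        "median_all": float(table.odds_ratio_all.median()) if len(table) else float("nan"),
    }
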