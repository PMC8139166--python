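"""Relative cell survival from pooled gRNA abundance counts.

Each targeting gRNA has a cognate mismatch control; survival of cells
carrying the targeting guide relative to control cells is estimated as the
ratio of the two guides' library fractions per condition (replicate ratios
averaged), and condition contrasts use a one-sided paired Student's t-test
across gRNA pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

COUNT_COLUMNS = ["grna", "condition", "replicate", "count"]


@dataclass
class SurvivalCounts:
    """Raw gRNA counts per (condition, replicate) plus the targeting ->
    mismatch-control pairing."""

    counts: pd.DataFrame = field(repr=False)  # grna, condition, replicate, count
    pairing: Dict[str, str] = field(default_factory=dict)  # targeting -> control

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"counts table missing columns: {missing}")
        if (self.counts["count"] < 0).any():
            raise ValueError("negative counts")
        grnas = set(self.counts.grna)
        for t, c in self.pairing.items():
            if t not in grnas or c not in grnas:
                raise ValueError(f"pairing references unknown gRNA: {t} -> {c}")


def normalize_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Add a ``fraction`` column: each gRNA's share of its (condition,
    replicate) sample total. Fractions sum to 1 per sample."""
    out = counts.copy()
    totals = out.groupby(["condition", "replicate"])["count"].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, ["condition", "replicate"]].drop_duplicates()
        raise ValueError(f"zero-total samples: {bad.to_records(index=False).tolist()}")
    out["fraction"] = out["count"] / totals
    return out


def targeting_ratios(
    norm: pd.DataFrame, pairing: Mapping[str, str]
) -> pd.DataFrame:
    """Targeting/control abundance ratio per gRNA pair and condition.

    The ratio is computed per replicate and averaged across replicates; a
    replicate whose control fraction is 0 is dropped with a flag, and a
    pair-condition with no usable replicate reports a missing ratio.
    """
    frac = norm.set_index(["grna", "condition", "replicate"]).sort_index().fraction
    rows = []
    conditions = sorted(norm.condition.unique())
    for targ, ctrl in sorted(pairing.items()):
        for cond in conditions:
            t = frac.loc[targ, cond]
            c = frac.loc[ctrl, cond]
            t, c = t.align(c, join="inner")
            usable = c > 0
            flagged = bool((~usable).any())
            ratios = (t[usable] / c[usable]).to_numpy()
            rows.append({
                "pair": targ,
                "control": ctrl,
                "condition": cond,
                "ratio": float(ratios.mean()) if ratios.size else float("nan"),
                "n_replicates": int(usable.sum()),
                "flagged": flagged,
            })
    return pd.DataFrame(
        rows, columns=["pair", "control", "condition", "ratio",
                       "n_replicates", "flagged"]
    )


def summarize_ratios(ratios: pd.DataFrame) -> pd.DataFrame:
    """Mean and median targeting/control ratio per condition."""
    g = ratios.groupby("condition").ratio
    return pd.DataFrame({"mean": g.mean(), "median": g.median()}).reset_index()


def condition_comparison(
    ratios: pd.DataFrame, condition_a: str, condition_b: str
) -> float:
    """One-sided paired t-test p that the per-pair survival ratio is higher
    in condition A than in condition B (a drop under B means depletion)."""
    wide = ratios.pivot(index="pair", columns="condition", values="ratio")
    for cond in (condition_a, condition_b):
        if cond not in wide.columns:
            raise ValueError(f"unknown condition: {cond}")
    sub = wide[[condition_a, condition_b]].dropna()
    if len(sub) < 2:
        raise ValueError("need >= 2 gRNA pairs for the paired t-test")
    res = stats.ttest_rel(
        sub[condition_a], sub[condition_b], alternative="greater"
    )
    return float(res.pvalue)
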