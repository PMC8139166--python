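"""Shared fixtures and independent reference implementations (oracles).

The oracles deliberately re-derive results with the most literal possible
algorithms (per-base loops, exhaustive enumeration) so the optimized library
code can be checked against them.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import pytest

from vlincnet.annotation import GeneAnnotation, MRNA, VLINC
from vlincnet.expression import ExpressionMatrix


# ---------------------------------------------------------------------------
# oracles


def region_oracle(
    scores: Dict[str, np.ndarray],
    other: Dict[str, np.ndarray],
    percentile: int,
) -> List[Tuple[str, int, int, float]]:
    """Literal per-base re-implementation of proximity region calling.

    Keep bases > 0 in both tracks, rank all surviving scores, keep the top
    percentile% (k = ceil(pct/100 * n), ties at the k-th largest kept),
    merge adjacent bases; returns sorted (chrom, start, end, mean_score).
    """
    surviving = []  # (chrom, pos, score)
    for chrom in sorted(scores):
        if chrom not in other:
            continue
        s, o = scores[chrom], other[chrom]
        for i in range(len(s)):
            if s[i] > 0 and o[i] > 0:
                surviving.append((chrom, i, float(s[i])))
    if not surviving:
        return []
    vals = sorted((v for _, _, v in surviving), reverse=True)
    k = math.ceil(percentile / 100 * len(vals))
    threshold = vals[k - 1]
    kept = [(c, i) for c, i, v in surviving if v >= threshold]
    kept.sort()
    regions = []
    run_chrom, run_start, run_prev = None, None, None
    for c, i in kept:
        if c == run_chrom and i == run_prev + 1:
            run_prev = i
        else:
            if run_chrom is not None:
                regions.append((run_chrom, run_start, run_prev + 1))
            run_chrom, run_start, run_prev = c, i, i
    regions.append((run_chrom, run_start, run_prev + 1))
    out = []
    for c, lo, hi in regions:
        mean = float(np.mean(scores[c][lo:hi]))
        out.append((c, lo, hi, mean))
    return out


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-transform then plain Pearson, computed longhand."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


# ---------------------------------------------------------------------------
# builders


def make_expression(
    values: Dict[str, List[float]],
    classes: Dict[str, str],
    meta_rows: List[Tuple[str, int, bool, str]],
) -> ExpressionMatrix:
    """Expression matrix from plain dicts; meta rows are
    (drug, timepoint_h, solvent_flag, solvent) per sample."""
    samples = [f"s{i + 1}" for i in range(len(meta_rows))]
    vals = pd.DataFrame(values, index=samples).T
    meta = pd.DataFrame(
        meta_rows,
        columns=["drug", "timepoint_h", "solvent_flag", "solvent"],
        index=pd.Index(samples, name="sample"),
    )
    klass = pd.Series(classes)
    return ExpressionMatrix(values=vals, sample_meta=meta, transcript_class=klass)


def make_ann(rows) -> GeneAnnotation:
    """Annotation from (chrom, start, end, name, strand) tuples; the class
    is inferred from the name prefix as in the BED reader."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    df["score"] = 0
    df["klass"] = [VLINC if n.startswith("vlinc") else MRNA for n in df.name]
    return GeneAnnotation(
        df[["chrom", "start", "end", "name", "score", "strand", "klass"]]
    )


@pytest.fixture
def toy_annotation() -> GeneAnnotation:
    return make_ann(
        [
            ("chr1", 100, 200, "g1", "+"),
            ("chr1", 300, 400, "g2", "-"),
            ("chr1", 500, 700, "g3", "+"),
            ("chr2", 100, 250, "g4", "+"),
            ("chr1", 800, 1200, "vlinc1", "+"),
        ]
    )
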