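"""Differential expression and Spearman co-expression networks.

The co-expression network links each vlincRNA to the protein-coding
mRNAs whose expression across a drug-treatment sample series correlates
with it: pairs are retained when |rho| > 0.35 and the correlation p-value
is < 0.01, computed over all samples. The module also provides the
fold-change-based differential-expression caller (FC > 1.5 versus the
matched solvent control at both time points), median-of-max expression
stratification, distance-stratified correlation summaries, and the
one-sided signed-rank test for the excess of negative over positive
network partners.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneAnnotation, MRNA, VLINC

logger = logging.getLogger(__name__)

RHO_MIN = 0.35
P_MAX = 0.01
FC_THRESHOLD = 1.5
DE_PSEUDOCOUNT = 0.1  # RPKM added to both sides of the fold-change ratio

DISTANCE_BINS: Tuple[Tuple[float, float], ...] = (
    (0, 5_000),
    (5_000, 10_000),
    (10_000, 100_000),
    (100_000, math.inf),
)


@dataclass
class ExpressionMatrix:
    """Abundance table (transcripts x samples) with sample metadata.

    ``sample_meta`` is indexed by sample id with columns: drug,
    timepoint_h, solvent_flag (bool), solvent (name of the matched
    solvent control series). ``transcript_class`` maps transcript id to
    "mRNA" or "vlincRNA".
    """

    values: pd.DataFrame = field(repr=False)
    sample_meta: pd.DataFrame = field(repr=False)
    transcript_class: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundances")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        unclassed = set(self.values.index) - set(self.transcript_class.index)
        if unclassed:
            raise ValueError(f"transcripts without class: {sorted(unclassed)[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def of_class(self, klass: str) -> pd.DataFrame:
        mask = self.values.index.map(self.transcript_class) == klass
        return self.values.loc[mask]


@dataclass
class DESet:
    """Per-drug up/down transcript sets with the underlying fold changes."""

    up: Dict[str, Set[str]]
    down: Dict[str, Set[str]]
    fold_changes: Dict[str, pd.DataFrame]  # drug -> transcripts x timepoints

    def __post_init__(self) -> None:
        for drug in self.up:
            if self.up[drug] & self.down.get(drug, set()):
                raise ValueError(f"transcript both up and down for {drug}")


@dataclass
class CoexpressionNetwork:
    """Thresholded vlincRNA-mRNA Spearman edges.

    ``edges`` columns: vlinc_id, gene_id, rho, p, sign; every row
    satisfies |rho| > rho_min and p < p_max. ``half_labels`` (optional)
    maps gene id to "top"/"bottom" expression half.
    """

    edges: pd.DataFrame = field(repr=False)
    rho_min: float = RHO_MIN
    p_max: float = P_MAX
    half_labels: Optional[pd.Series] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if not ((e.rho.abs() > self.rho_min) & (e.p < self.p_max)).all():
                raise ValueError("edges violating the rho/p thresholds")
            expect = np.where(e.rho > 0, "positive", "negative")
            if not (e.sign.to_numpy() == expect).all():
                raise ValueError("edge sign inconsistent with rho")

    def partners(self, vlinc: str, sign: Optional[str] = None) -> Set[str]:
        sel = self.edges[self.edges.vlinc_id == vlinc]
        if sign is not None:
            sel = sel[sel.sign == sign]
        return set(sel.gene_id)

    @property
    def vlinc_ids(self) -> Sequence[str]:
        return sorted(self.edges.vlinc_id.unique())


# ---------------------------------------------------------------------------
# differential expression


def call_de(
    expr: ExpressionMatrix,
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = DE_PSEUDOCOUNT,
) -> DESet:
    """Call up/down transcripts per drug: FC vs the matched solvent control
    beyond the threshold at both time points.

    The fold change at each time point is (x + eps) / (ctrl + eps) against
    the mean of the solvent-control samples of the drug's solvent at the
    same time point. Drugs with fewer than two time points are skipped with
    a warning; a missing solvent control is a hard error naming the drug.
    """
    meta = expr.sample_meta
    controls = meta[meta.solvent_flag]
    up: Dict[str, Set[str]] = {}
    down: Dict[str, Set[str]] = {}
    fcs: Dict[str, pd.DataFrame] = {}
    for drug, dmeta in meta[~meta.solvent_flag].groupby("drug"):
        tps = sorted(dmeta.timepoint_h.unique())
        if len(tps) < 2:
            warnings.warn(f"drug {drug!r} has a single time point; skipped")
            continue
        solvent = dmeta.solvent.iloc[0]
        per_tp = {}
        for tp in tps:
            csel = controls[(controls.drug == solvent) & (controls.timepoint_h == tp)]
            if csel.empty:
                raise ValueError(
                    f"no solvent control ({solvent!r}, {tp} h) for drug {drug!r}"
                )
            ctrl = expr.values[csel.index].mean(axis=1)
            treat = expr.values[dmeta[dmeta.timepoint_h == tp].index].mean(axis=1)
            per_tp[tp] = (treat + pseudocount) / (ctrl + pseudocount)
        fc = pd.DataFrame(per_tp)
        fcs[drug] = fc
        up[drug] = set(fc.index[(fc > fc_threshold).all(axis=1)])
        down[drug] = set(fc.index[(fc < 1 / fc_threshold).all(axis=1)])
    return DESet(up=up, down=down, fold_changes=fcs)


# ---------------------------------------------------------------------------
# Spearman correlation


def _rank_standardize(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Average-rank rows and standardize; flags constant rows."""
    ranks = stats.rankdata(values, axis=1, method="average")
    sd = ranks.std(axis=1)
    constant = sd == 0
    mean = ranks.mean(axis=1, keepdims=True)
    z = np.zeros_like(ranks)
    ok = ~constant
    z[ok] = (ranks[ok] - mean[ok]) / sd[ok][:, None]
    return z, constant


def _spearman_p_t(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-approximation (n - 2 df)."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    return 2 * stats.t.sf(np.abs(t), n - 2)


_PERM_CACHE: Dict[int, np.ndarray] = {}


def _permutations(n: int) -> np.ndarray:
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(list(itertools.permutations(range(n))))
    return _PERM_CACHE[n]


def _spearman_p_exact(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact permutation p for the rank correlation of one pair."""
    n = rx.size
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    obs = float(zx @ zy / n)
    perms = _permutations(n)
    rho_null = (zy[perms] @ zx) / n
    return float(np.mean(np.abs(rho_null) >= abs(obs) - 1e-12))


def spearman_full(expr: ExpressionMatrix) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p for every (vlincRNA, mRNA) pair.

    Rows are vlincRNAs, columns mRNAs. Constant series yield NaN and a
    logged warning. p-values use the t-approximation for n >= 10 samples
    and exact permutation enumeration below that.
    """
    vl = expr.of_class(VLINC)
    mr = expr.of_class(MRNA)
    if expr.n_samples < 5:
        raise ValueError("need >= 5 samples for the co-expression analysis")
    if vl.empty or mr.empty:
        raise ValueError("both vlincRNAs and mRNAs must be present")
    n = expr.n_samples
    zv, const_v = _rank_standardize(vl.to_numpy(dtype=float))
    zm, const_m = _rank_standardize(mr.to_numpy(dtype=float))
    n_const = int(const_v.sum() + const_m.sum())
    if n_const:
        logger.warning("%d constant series skipped (rho undefined)", n_const)
    rho = zv @ zm.T / n
    rho[const_v, :] = np.nan
    rho[:, const_m] = np.nan
    if n >= 10:
        p = _spearman_p_t(rho, n)
    else:
        rv = stats.rankdata(vl.to_numpy(dtype=float), axis=1)
        rm = stats.rankdata(mr.to_numpy(dtype=float), axis=1)
        p = np.full_like(rho, np.nan)
        for i in range(rho.shape[0]):
            if const_v[i]:
                continue
            for j in range(rho.shape[1]):
                if not const_m[j]:
                    p[i, j] = _spearman_p_exact(rv[i], rm[j])
    p = np.where(np.isnan(rho), np.nan, p)
    rho_df = pd.DataFrame(rho, index=vl.index, columns=mr.index)
    p_df = pd.DataFrame(p, index=vl.index, columns=mr.index)
    return rho_df, p_df


def spearman_network(
    expr: ExpressionMatrix,
    rho_min: float = RHO_MIN,
    p_max: float = P_MAX,
    half_labels: Optional[pd.Series] = None,
) -> CoexpressionNetwork:
    """Build the thresholded co-expression network (|rho| > rho_min, p < p_max)."""
    rho_df, p_df = spearman_full(expr)
    keep = (rho_df.abs() > rho_min) & (p_df < p_max)
    rows = []
    for vlinc in rho_df.index:
        mask = keep.loc[vlinc].fillna(False)
        genes = rho_df.columns[mask.to_numpy()]
        for g in genes:
            r = rho_df.at[vlinc, g]
            rows.append(
                {
                    "vlinc_id": vlinc,
                    "gene_id": g,
                    "rho": r,
                    "p": p_df.at[vlinc, g],
                    "sign": "positive" if r > 0 else "negative",
                }
            )
    edges = pd.DataFrame(rows, columns=["vlinc_id", "gene_id", "rho", "p", "sign"])
    return CoexpressionNetwork(
        edges=edges, rho_min=rho_min, p_max=p_max, half_labels=half_labels
    )


# ---------------------------------------------------------------------------
# stratification & summaries


def stratify_by_expression(expr: ExpressionMatrix) -> pd.Series:
    """Label each expressed mRNA "top" or "bottom" by its maximum abundance.

    Genes with max abundance 0 are dropped before ranking; genes are ranked
    descending by max; with an odd count the top half gets the extra gene.
    """
    mr = expr.of_class(MRNA)
    maxes = mr.max(axis=1)
    maxes = maxes[maxes > 0]
    order = maxes.sort_values(ascending=False, kind="stable").index
    n_top = math.ceil(len(order) / 2)
    labels = pd.Series("bottom", index=order, name="half")
    labels.iloc[:n_top] = "top"
    return labels


def distance_stratified_medians(
    net: CoexpressionNetwork,
    ann: GeneAnnotation,
    bins: Sequence[Tuple[float, float]] = DISTANCE_BINS,
) -> pd.Series:
    """Median edge rho per vlincRNA-gene genomic-distance bin (cis only).

    Distance is the gap between the two intervals (0 when they overlap);
    pairs on different chromosomes are excluded. Empty bins are NaN.
    """
    by_name = ann.df.set_index("name")
    rows = []
    for _, e in net.edges.iterrows():
        v = by_name.loc[e.vlinc_id]
        g = by_name.loc[e.gene_id]
        if v.chrom != g.chrom:
            continue
        gap = max(v.start - g.end, g.start - v.end, 0)
        rows.append((gap, e.rho))
    labels = [f"{int(lo)}-{hi if math.isinf(hi) else int(hi)}" for lo, hi in bins]
    out = pd.Series(np.nan, index=labels, name="median_rho")
    for (lo, hi), lab in zip(bins, labels):
        vals = [r for gap, r in rows if lo <= gap < hi]
        if vals:
            out[lab] = float(np.median(vals))
    return out


def negative_bias_test(net: CoexpressionNetwork) -> float:
    """One-sided Wilcoxon signed-rank p that vlincRNAs have more negative
    than positive network partners (paired counts per vlincRNA)."""
    vlincs = net.vlinc_ids
    if len(vlincs) < 2:
        raise ValueError("need >= 2 vlincRNAs for the signed-rank test")
    n_neg = np.array(
        [len(net.partners(v, "negative")) for v in vlincs], dtype=float
    )
    n_pos = np.array(
        [len(net.partners(v, "positive")) for v in vlincs], dtype=float
    )
    if np.all(n_neg == n_pos):
        warnings.warn("all vlincRNAs tied; signed-rank p reported as 1")
        return 1.0
    res = stats.wilcoxon(n_neg, n_pos, alternative="greater")
    return float(res.pvalue)
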