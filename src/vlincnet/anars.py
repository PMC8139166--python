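"""Average normalized aggregated RAT score (ANARS) over metagene profiles.

Each gene body is rescaled to 5,000 relative positions (slice means, which
preserve total signal mass up to rounding); the 5-kb windows immediately
up- and downstream are taken unscaled. Body and flank vectors are oriented
5'->3' by gene strand. The group profile is the per-position mean over the
group's genes. Enrichment between groups is tested on the top 30% of each
profile's ranked values with a one-sided Wilcoxon rank-sum test; the
cis-versus-all comparison drops zero values first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import GeneAnnotation
from .rat import RatTrack

PROFILE_LEN = 5000
FLANK = 5000
TOP_FRACTION = 0.30


@dataclass
class AnarsProfile:
    """Aggregated profile of one gene group: body (scaled) plus unscaled
    5-kb flanks, all of length 5,000."""

    body: np.ndarray = field(repr=False)
    upstream_flank: np.ndarray = field(repr=False)
    downstream_flank: np.ndarray = field(repr=False)
    group: str = ""
    n_genes: int = 0

    def __post_init__(self) -> None:
        for v in (self.body, self.upstream_flank, self.downstream_flank):
            if v.shape != (PROFILE_LEN,):
                raise ValueError(f"profile vectors must have length {PROFILE_LEN}")
        if self.n_genes < 1:
            raise ValueError("profile needs at least one gene")

    def region(self, which: str) -> np.ndarray:
        return {
            "body": self.body,
            "upstream": self.upstream_flank,
            "downstream": self.downstream_flank,
        }[which]


def scale_gene(scores: np.ndarray, out_len: int = PROFILE_LEN) -> np.ndarray:
    """Rescale a gene-body score vector to ``out_len`` positions.

    Position j (1..out_len) is the mean of the half-open base slice
    [floor((j-1)L/out_len), floor(jL/out_len)); when the slice is empty
    (L < out_len) the containing base's score is used. Input must already
    be oriented 5'->3'.
    """
    scores = np.asarray(scores, dtype=float)
    L = scores.size
    if L < 1:
        raise ValueError("gene must span at least one base")
    edges = (np.arange(out_len + 1, dtype=np.int64) * L) // out_len
    lo, hi = edges[:-1], edges[1:]
    width = hi - lo
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    with np.errstate(invalid="ignore"):
        means = (csum[hi] - csum[lo]) / np.maximum(width, 1)
    return np.where(width > 0, means, scores[np.minimum(lo, L - 1)])


def _gene_vectors(
    track: RatTrack, chrom: str, start: int, end: int, strand: str, flank: int
):
    """(scaled body, upstream flank, downstream flank) for one gene,
    oriented 5'->3'; bases outside the chromosome read as 0."""
    arr = track.scores.get(chrom)
    if arr is None:
        body = np.zeros(end - start)
        left = right = np.zeros(flank)
    else:
        n = arr.size

        def window(a: int, b: int) -> np.ndarray:
            out = np.zeros(b - a)
            lo, hi = max(a, 0), min(b, n)
            if lo < hi:
                out[lo - a : hi - a] = arr[lo:hi]
            return out

        body = window(start, end)
        left = window(start - flank, start)
        right = window(end, end + flank)
    if strand == "-":
        body = body[::-1]
        upstream, downstream = right[::-1], left[::-1]
    else:
        upstream, downstream = left, right
    return scale_gene(body), upstream, downstream


def compute_anars(
    track: RatTrack,
    genes: Iterable[str],
    ann: GeneAnnotation,
    group: str = "",
    flank: int = FLANK,
) -> AnarsProfile:
    """Per-position mean profile of the averaged RAT score over a gene group."""
    genes = list(genes)
    if not genes:
        raise ValueError("gene group is empty")
    by_name = ann.df.set_index("name")
    body = np.zeros(PROFILE_LEN)
    up = np.zeros(flank)
    down = np.zeros(flank)
    for g in genes:
        row = by_name.loc[g]
        b, u, d = _gene_vectors(
            track, row.chrom, int(row.start), int(row.end), row.strand, flank
        )
        body += b
        up += u
        down += d
    k = len(genes)
    return AnarsProfile(
        body=body / k,
        upstream_flank=up / k,
        downstream_flank=down / k,
        group=group,
        n_genes=k,
    )


def _top_fraction(values: np.ndarray, fraction: float) -> np.ndarray:
    k = max(1, int(round(fraction * values.size)))
    return np.sort(values)[-k:]


def _ranksum_greater(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p of a > b; exact for small untied
    samples, normal approximation with tie correction otherwise."""
    method = "exact" if (a.size < 50 and b.size < 50) else "asymptotic"
    if method == "exact" and np.intersect1d(a, b).size:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.pvalue)


def top30_test(
    values_a: np.ndarray, values_b: np.ndarray, fraction: float = TOP_FRACTION
) -> float:
    """One-sided rank-sum p that group A's top-30% profile values exceed
    group B's (each profile ranked independently)."""
    a = _top_fraction(np.asarray(values_a, dtype=float), fraction)
    b = _top_fraction(np.asarray(values_b, dtype=float), fraction)
    return _ranksum_greater(a, b)


def cis_vs_all_test(values_cis: np.ndarray, values_all: np.ndarray) -> Optional[float]:
    """One-sided rank-sum p that cis genes' non-zero profile values exceed
    those of all co-expressed genes; zero values dropped from both sides."""
    a = np.asarray(values_cis, dtype=float)
    b = np.asarray(values_all, dtype=float)
    a, b = a[a != 0], b[b != 0]
    if a.size == 0 or b.size == 0:
        warnings.warn("all-zero profile; cis-vs-all test skipped")
        return None
    return _ranksum_greater(a, b)
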