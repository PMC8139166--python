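"""RNA-chromatin proximity (RAT) signal processing and region calling.

A RAT experiment yields, per (vlincRNA, treatment), raw per-base read
coverage for two targeting oligonucleotide sets and a no-oligo background
control, in two biological replicas. Processing steps:

1. normalize   — per-base coverage divided by the sample's total reads;
2. subtract    — normalized no-oligo background subtracted per base
                 (negative values retained, removed later by the > 0 filter);
3. average     — per-base mean across tracks (the replica-averaged score
                 consumed by the metagene statistic);
4. call_regions — per replica: keep bases > 0 in both oligo-set tracks,
                 rank the surviving scores, keep the top-N% bases (ties at
                 the threshold kept), merge adjacent bases into intervals;
5. genes_with_regions — genes holding regions in both replicas, either
                 anywhere within the gene (gene level) or with base-wise
                 coordinate agreement between replicas (region level).

Tracks are dense per-chromosome float arrays; all coordinates 0-based
half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import _stats
from .annotation import GeneAnnotation, genes_overlapping

logger = logging.getLogger(__name__)

PERCENTILES = (1, 5, 10, 20, 30)

OLIGO_1 = "oligo_set_1"
OLIGO_2 = "oligo_set_2"
NO_OLIGO = "no_oligo"


@dataclass
class RatTrack:
    """Per-base signal keyed by chromosome, with provenance.

    ``stage`` records how far the track has been processed:
    raw -> normalized -> subtracted -> averaged.
    """

    scores: Dict[str, np.ndarray] = field(repr=False)
    vlinc: str = ""
    treatment: str = ""
    replica: int = 0
    source: str = OLIGO_1
    total_reads: Optional[int] = None
    stage: str = "raw"

    def total_signal(self) -> float:
        return float(sum(a.sum() for a in self.scores.values()))

    def chrom(self, name: str, length: Optional[int] = None) -> np.ndarray:
        if name in self.scores:
            return self.scores[name]
        if length is None:
            raise KeyError(name)
        return np.zeros(length)


@dataclass
class RatRegionSet:
    """Called intervals (chrom, start, end, mean_score), non-overlapping and
    sorted within each chromosome."""

    intervals: pd.DataFrame = field(repr=False)
    percentile: int = 0
    level: str = "per_replica"
    vlinc: str = ""
    treatment: str = ""
    replica: int = 0

    def __post_init__(self) -> None:
        df = self.intervals
        for chrom, grp in df.groupby("chrom"):
            g = grp.sort_values("start")
            if (g.start.to_numpy()[1:] < g.end.to_numpy()[:-1]).any():
                raise ValueError(f"overlapping regions on {chrom}")
        self.intervals = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    @property
    def n_bases(self) -> int:
        if self.intervals.empty:
            return 0
        return int((self.intervals.end - self.intervals.start).sum())


def normalize(track: RatTrack) -> RatTrack:
    """Divide each base's coverage by the track's total read count."""
    if track.total_reads is None or track.total_reads <= 0:
        raise ValueError("total_reads must be positive to normalize")
    scores = {c: a / track.total_reads for c, a in track.scores.items()}
    return replace(track, scores=scores, stage="normalized")


def subtract_control(track: RatTrack, control: RatTrack) -> RatTrack:
    """Per-base difference track - no-oligo control (negatives retained)."""
    if control.source != NO_OLIGO:
        raise ValueError("control must be a no-oligo track")
    if (track.vlinc, track.treatment, track.replica) != (
        control.vlinc,
        control.treatment,
        control.replica,
    ):
        raise ValueError("track/control provenance mismatch")
    chroms = set(track.scores) | set(control.scores)
    scores = {}
    for c in sorted(chroms):
        a = track.scores.get(c)
        b = control.scores.get(c)
        if a is None:
            scores[c] = -b
        elif b is None:
            scores[c] = a.copy()
        else:
            if a.shape != b.shape:
                raise ValueError(f"chromosome length mismatch on {c}")
            scores[c] = a - b
    return replace(track, scores=scores, stage="subtracted")


def average_replicas(r1: RatTrack, r2: RatTrack) -> RatTrack:
    """Per-base arithmetic mean of two control-subtracted tracks of the same
    (vlincRNA, treatment)."""
    if (r1.vlinc, r1.treatment) != (r2.vlinc, r2.treatment):
        raise ValueError("replica mismatch: different vlincRNA or treatment")
    return _mean_tracks([r1, r2])


def average_tracks(tracks: Sequence[RatTrack]) -> RatTrack:
    """Per-base mean over any number of control-subtracted tracks (used to
    collapse the two oligo sets x two replicas into the single averaged score)."""
    if not tracks:
        raise ValueError("no tracks to average")
    vt = {(t.vlinc, t.treatment) for t in tracks}
    if len(vt) > 1:
        raise ValueError("tracks from different (vlincRNA, treatment)")
    return _mean_tracks(list(tracks))


def _mean_tracks(tracks: Sequence[RatTrack]) -> RatTrack:
    chroms = sorted(set().union(*(t.scores for t in tracks)))
    scores = {}
    for c in chroms:
        lengths = {t.scores[c].size for t in tracks if c in t.scores}
        if len(lengths) > 1:
            raise ValueError(f"chromosome length mismatch on {c}")
        (n,) = lengths
        acc = np.zeros(n)
        for t in tracks:
            acc += t.scores.get(c, 0.0)
        scores[c] = acc / len(tracks)
    t0 = tracks[0]
    return RatTrack(
        scores=scores,
        vlinc=t0.vlinc,
        treatment=t0.treatment,
        replica=0,
        source="averaged",
        total_reads=None,
        stage="averaged",
    )


def _merge_adjacent(positions: np.ndarray) -> Iterable[Tuple[int, int]]:
    """Merge sorted base positions into half-open runs."""
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [positions.size - 1]])
    return [(int(positions[s]), int(positions[e]) + 1) for s, e in zip(starts, ends)]


def call_regions(
    track: RatTrack, other_oligo_track: RatTrack, percentile: int
) -> RatRegionSet:
    """Call proximity regions for one replica's oligo-set track.

    Bases with score > 0 in *both* oligo-set tracks survive; the surviving
    scores of ``track`` are ranked genome-wide and the top ``percentile``%
    are kept (k = ceil(pct/100 * n) bases; ties at the k-th largest score
    all kept); adjacent kept bases merge into intervals.
    """
    if percentile not in PERCENTILES:
        raise ValueError(f"percentile must be one of {PERCENTILES}")
    masks: Dict[str, np.ndarray] = {}
    surviving = []
    for chrom in sorted(track.scores):
        s = track.scores[chrom]
        o = other_oligo_track.scores.get(chrom)
        if o is None:
            continue
        m = (s > 0) & (o > 0)
        if m.any():
            masks[chrom] = m
            surviving.append(s[m])
    if not surviving:
        logger.info(
            "no base survived the >0 intersection filter (%s/%s rep %d)",
            track.vlinc,
            track.treatment,
            track.replica,
        )
        return _empty_region_set(track, percentile)
    vals = np.concatenate(surviving)
    k = math.ceil(percentile / 100 * vals.size)
    thr = np.partition(vals, vals.size - k)[vals.size - k]
    frames = []
    for chrom, m in masks.items():
        s = track.scores[chrom]
        keep = np.flatnonzero(m & (s >= thr))
        if keep.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(keep) > 1)
        starts = keep[np.concatenate([[0], breaks + 1])]
        ends = keep[np.concatenate([breaks, [keep.size - 1]])] + 1
        csum = np.concatenate([[0.0], np.cumsum(s)])
        means = (csum[ends] - csum[starts]) / (ends - starts)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "mean_score": means}
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end", "mean_score"])
    )
    return RatRegionSet(
        intervals=df,
        percentile=percentile,
        level="per_replica",
        vlinc=track.vlinc,
        treatment=track.treatment,
        replica=track.replica,
    )


def _empty_region_set(track: RatTrack, percentile: int) -> RatRegionSet:
    return RatRegionSet(
        intervals=pd.DataFrame(columns=["chrom", "start", "end", "mean_score"]),
        percentile=percentile,
        level="per_replica",
        vlinc=track.vlinc,
        treatment=track.treatment,
        replica=track.replica,
    )


def intersect_regions(a: RatRegionSet, b: RatRegionSet) -> pd.DataFrame:
    """Base-wise intersection of two region sets (chrom/start/end rows)."""
    rows = []
    for chrom in sorted(set(a.intervals.chrom) & set(b.intervals.chrom)):
        ia = a.intervals[a.intervals.chrom == chrom][["start", "end"]].to_numpy()
        ib = b.intervals[b.intervals.chrom == chrom][["start", "end"]].to_numpy()
        i = j = 0
        while i < len(ia) and j < len(ib):
            lo = max(ia[i, 0], ib[j, 0])
            hi = min(ia[i, 1], ib[j, 1])
            if lo < hi:
                rows.append({"chrom": chrom, "start": int(lo), "end": int(hi)})
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def genes_with_regions(
    regions_r1: RatRegionSet,
    regions_r2: RatRegionSet,
    ann: GeneAnnotation,
    level: str = "gene",
) -> Set[str]:
    """Genes supported by both replicas' regions.

    gene level — the gene overlaps >= 1 region in each replica, anywhere
    within its boundaries; region level — the base-wise intersection of the
    two replicas' regions is non-empty within the gene.
    """
    if level == "gene":
        g1 = genes_overlapping(regions_r1.intervals, ann)
        g2 = genes_overlapping(regions_r2.intervals, ann)
        return g1 & g2
    if level == "region":
        inter = intersect_regions(regions_r1, regions_r2)
        return genes_overlapping(inter, ann)
    raise ValueError("level must be 'gene' or 'region'")


def replica_concordance(
    genes_r1: Set[str], genes_r2: Set[str], universe: Set[str]
) -> Tuple[float, float]:
    """Odds ratio and one-sided hypergeometric p of the replica gene-set
    overlap over the gene universe."""
    s = _stats.overlap_stats(genes_r1, genes_r2, universe)
    return s["odds_ratio"], s["p"]
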