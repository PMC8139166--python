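"""Genomic annotation of mRNA genes and vlincRNA loci.

Intervals are 0-based half-open throughout. The transcript class
(mRNA vs vlincRNA) is carried in a dedicated column; on disk the
annotation is a 6-column BED and the class is recovered from the
name prefix (``vlinc``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "klass"]

MRNA = "mRNA"
VLINC = "vlincRNA"


@dataclass
class GeneAnnotation:
    """Table of gene/vlincRNA intervals.

    ``df`` columns: chrom, start, end, name, score, strand,
    klass in {"mRNA", "vlincRNA"}.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if (self.df.end <= self.df.start).any():
            bad = self.df[self.df.end <= self.df.start].name.tolist()
            raise ValueError(f"empty/inverted intervals: {bad[:5]}")
        if self.df.name.duplicated().any():
            raise ValueError("duplicate feature names in annotation")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genes(self) -> pd.DataFrame:
        return self.df[self.df.klass == MRNA]

    @property
    def vlincs(self) -> pd.DataFrame:
        return self.df[self.df.klass == VLINC]

    def interval(self, name: str):
        """(chrom, start, end, strand) of a named feature."""
        row = self.df[self.df.name == name]
        if row.empty:
            raise KeyError(name)
        r = row.iloc[0]
        return r.chrom, int(r.start), int(r.end), r.strand

    def chromosome_of(self) -> pd.Series:
        """Series name -> chrom for all features."""
        return self.df.set_index("name").chrom

    def chrom_sizes(self) -> dict:
        """Minimal chromosome sizes covering all intervals (max end per chrom)."""
        return self.df.groupby("chrom").end.max().astype(int).to_dict()

    def overlaps_ok(self) -> bool:
        """True iff intervals are pairwise disjoint within each chromosome."""
        for _, grp in self.df.groupby("chrom"):
            g = grp.sort_values("start")
            if (g.start.values[1:] < g.end.values[:-1]).any():
                return False
        return True


def genes_overlapping(
    regions: pd.DataFrame, ann: GeneAnnotation, klass: str = MRNA
) -> set:
    """Names of annotation features overlapped by >= 1 region.

    ``regions``: DataFrame with chrom/start/end, non-overlapping and sorted
    within each chromosome (as produced by region calling).
    """
    feats = ann.df if klass is None else ann.df[ann.df.klass == klass]
    hits: set = set()
    for chrom, grp in regions.groupby("chrom"):
        sub = feats[feats.chrom == chrom]
        if sub.empty:
            continue
        grp = grp.sort_values("start")
        starts = grp.start.to_numpy()
        ends = grp.end.to_numpy()
        # regions are disjoint & sorted, so ends are sorted too
        i = np.searchsorted(starts, sub.end.to_numpy(), side="left")
        ok = (i > 0) & (ends[np.maximum(i - 1, 0)] > sub.start.to_numpy())
        hits |= set(sub.name.to_numpy()[ok])
    return hits
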