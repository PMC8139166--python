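"""Readers and writers for the pipeline's on-disk formats.

All genomic coordinates are 0-based half-open in memory and on disk (BED
and bedGraph conventions). The annotation is a 6-column BED; the
mRNA/vlincRNA class is recovered from the feature-name prefix ``vlinc``.
Expression, networks, gene sets and count tables are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import numpy as np
import pandas as pd

from .annotation import COLUMNS as ANN_COLUMNS
from .annotation import GeneAnnotation, MRNA, VLINC
from .expression import CoexpressionNetwork, ExpressionMatrix
from .rat import RatTrack
from .survival import SurvivalCounts

PathLike = Union[str, Path]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def _klass_from_name(name: str) -> str:
    return VLINC if name.startswith("vlinc") else MRNA


# ---------------------------------------------------------------------------
# BED / annotation


def read_bed(path: PathLike) -> GeneAnnotation:
    """Parse a 6-column BED annotation; malformed lines error with their
    line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if strand not in {"+", "-", "."}:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: empty/inverted interval")
            rows.append(
                {
                    "chrom": chrom,
                    "start": start_i,
                    "end": end_i,
                    "name": name,
                    "score": score,
                    "strand": strand,
                    "klass": _klass_from_name(name),
                }
            )
    return GeneAnnotation(pd.DataFrame(rows, columns=ANN_COLUMNS))


def write_bed(ann: GeneAnnotation, path: PathLike) -> None:
    ann.df[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path: PathLike, chrom_sizes: Optional[Dict[str, int]] = None
) -> Dict[str, np.ndarray]:
    """Parse a bedGraph into dense per-chromosome arrays.

    Overlapping intervals are rejected with the offending line number.
    Without ``chrom_sizes`` each array is sized to the last covered base.
    """
    spans: Dict[str, list] = {}
    last_end: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts
            try:
                start_i, end_i, val = int(start), int(end), float(value)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed fields") from None
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: empty/inverted interval")
            if start_i < last_end.get(chrom, 0):
                raise ValueError(f"{path}:{lineno}: overlapping/unsorted interval")
            last_end[chrom] = end_i
            spans.setdefault(chrom, []).append((start_i, end_i, val))
    out: Dict[str, np.ndarray] = {}
    for chrom, items in spans.items():
        size = (chrom_sizes or {}).get(chrom, items[-1][1])
        arr = np.zeros(size)
        for start_i, end_i, val in items:
            arr[start_i:end_i] = val
        out[chrom] = arr
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            out.setdefault(chrom, np.zeros(size))
    return out


def write_bedgraph(scores: Dict[str, np.ndarray], path: PathLike) -> None:
    """Write dense arrays as run-length-encoded bedGraph (zero runs omitted)."""
    frames = []
    for chrom in sorted(scores):
        arr = np.asarray(scores[chrom], dtype=float)
        if arr.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [arr.size]])
        vals = arr[starts]
        nz = vals != 0
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts[nz], "end": ends[nz], "value": vals[nz]}
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end", "value"])
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# RAT manifest


def write_rat_tracks(
    tracks: Iterable[RatTrack], outdir: PathLike, manifest_name: str = "rat_manifest.tsv"
) -> Path:
    """Write one bedGraph per track plus a manifest TSV with provenance and
    total read counts; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tracks:
        fname = f"{t.vlinc}_{t.treatment}_rep{t.replica}_{t.source}.bedgraph"
        write_bedgraph(t.scores, outdir / fname)
        rows.append(
            {
                "path": fname,
                "vlinc": t.vlinc,
                "treatment": t.treatment,
                "replica": t.replica,
                "source": t.source,
                "total_reads": t.total_reads,
            }
        )
    manifest = outdir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_rat_tracks(
    manifest_path: PathLike, chrom_sizes: Optional[Dict[str, int]] = None
) -> List[RatTrack]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    tracks = []
    for _, r in df.iterrows():
        scores = read_bedgraph(manifest_path.parent / r.path, chrom_sizes)
        tracks.append(
            RatTrack(
                scores=scores,
                vlinc=r.vlinc,
                treatment=r.treatment,
                replica=int(r.replica),
                source=r.source,
                total_reads=int(r.total_reads),
                stage="raw",
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# expression & networks


def write_expression(expr: ExpressionMatrix, values_path: PathLike, meta_path: PathLike) -> None:
    expr.values.rename_axis("transcript").to_csv(values_path, sep="\t")
    expr.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


def read_expression(values_path: PathLike, meta_path: PathLike) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta["solvent_flag"] = meta["solvent_flag"].astype(bool)
    klass = pd.Series([_klass_from_name(t) for t in values.index], index=values.index)
    return ExpressionMatrix(values=values, sample_meta=meta, transcript_class=klass)


def write_network(net: CoexpressionNetwork, path: PathLike) -> None:
    edges = net.edges.copy()
    if net.half_labels is not None:
        edges["half_label"] = edges.gene_id.map(net.half_labels)
    edges.to_csv(path, sep="\t", index=False)


def read_network(
    path: PathLike, rho_min: float = 0.35, p_max: float = 0.01
) -> CoexpressionNetwork:
    edges = pd.read_csv(path, sep="\t")
    half = None
    if "half_label" in edges.columns:
        half = edges.dropna(subset=["half_label"]).set_index("gene_id").half_label
        half = half[~half.index.duplicated()]
        edges = edges.drop(columns=["half_label"])
    return CoexpressionNetwork(edges=edges, rho_min=rho_min, p_max=p_max, half_labels=half)


# ---------------------------------------------------------------------------
# knockdown & survival tables


def write_tsv(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_knockdown_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_survival(counts: SurvivalCounts, counts_path: PathLike, pairs_path: PathLike) -> None:
    counts.counts.to_csv(counts_path, sep="\t", index=False)
    pairs = pd.DataFrame(
        sorted(counts.pairing.items()), columns=["targeting", "control"]
    )
    pairs.to_csv(pairs_path, sep="\t", index=False)


def read_survival(counts_path: PathLike, pairs_path: PathLike) -> SurvivalCounts:
    counts = pd.read_csv(counts_path, sep="\t")
    pairs = pd.read_csv(pairs_path, sep="\t")
    pairing = dict(zip(pairs.targeting, pairs.control))
    return SurvivalCounts(counts=counts, pairing=pairing)


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
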