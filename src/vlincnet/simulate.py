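"""Synthetic inputs with planted ground truth for the whole pipeline.

Emulates the five input kinds of a vlincRNA regulatory-network study:

* a gene/vlincRNA annotation with non-overlapping intervals;
* a drug-treatment expression series in which each vlincRNA shares a
  Gaussian latent treatment-response factor with its planted target genes
  (a Gaussian copula, so the planted Spearman correlation is exact in
  population and survives the monotone map to positive abundances);
* RAT coverage tracks (two oligo sets + no-oligo control, two replicas)
  with Poisson counts over a piecewise-constant rate, enriched by a known
  fold over the planted network gene bodies;
* knockdown FPKM tables in which targeting-arm days 3/6 shift negative
  targets up and positive targets down by a known fraction;
* pooled gRNA survival counts with known multiplicative depletion of the
  targeting guides per condition.

All randomness flows from one seed through per-generator child streams, so
the five outputs are mutually independent given the ground truth and every
generator is reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, MRNA, VLINC
from .expression import ExpressionMatrix
from .rat import NO_OLIGO, OLIGO_1, OLIGO_2, RatTrack
from .survival import SurvivalCounts

# child-stream ids, one per generator, so outputs are order-independent
_STREAM_ANNOT, _STREAM_TRUTH, _STREAM_EXPR, _STREAM_RAT, _STREAM_KD, _STREAM_SURV = range(6)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults mirror the emulated study design: a 64-sample drug-treatment
    series (drugs at 3 h and 6 h plus DMSO/water solvent controls), two
    treatments carried through the chromatin assay, a 1:2 positive:negative
    planted network imbalance, and survival depletion factors anchored at
    the reported condition means (0.9 at pooling, ~0.91 before/without
    induction, 0.78 with drug plus induction).
    """

    seed: int = 0
    n_chromosomes: int = 4
    genes_per_chromosome: int = 50
    n_vlinc: int = 2
    n_samples: int = 64
    network_size_pos: int = 15
    network_size_neg: int = 30
    rho_target: float = 0.9
    chromatin_enrichment: float = 3.0
    knockdown_effect: float = 0.4
    noise_sd: float = 0.5
    # geometry; the spacer exceeds the enriched flank so planted signal
    # never bleeds into a neighboring gene body
    gene_length: int = 2000
    spacer: int = 6000
    vlinc_length: int = 20000
    chromosome_length: Optional[int] = None
    # expression design
    n_de_genes: int = 10
    de_fold: float = 2.0
    # chromatin assay
    treatments: Tuple[str, ...] = ("DMSO", "etoposide")
    rat_background_rate: float = 20.0
    chromatin_flank: int = 5000
    # knockdown assay
    grnas_per_vlinc: int = 2
    kd_noise_sd: float = 0.2
    vlinc_depletion: float = 0.2
    # survival assay
    survival_depletion: Mapping[str, float] = field(
        default_factory=lambda: {
            "baseline": 0.9,
            "pre_drug": 0.91,
            "drug_no_dox": 0.91,
            "drug_dox": 0.78,
        }
    )
    survival_depth: int = 100_000
    survival_replicates: int = 3
    survival_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "genes_per_chromosome": self.genes_per_chromosome,
            "n_vlinc": self.n_vlinc,
            "n_samples": self.n_samples,
            "gene_length": self.gene_length,
            "grnas_per_vlinc": self.grnas_per_vlinc,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.rho_target < 1:
            raise ValueError("rho_target must lie in (0, 1)")
        if self.chromatin_enrichment < 1:
            raise ValueError("chromatin_enrichment must be >= 1")
        if not 0 <= self.knockdown_effect < 1:
            raise ValueError("knockdown_effect must lie in [0, 1)")
        per_vlinc = self.network_size_pos + self.network_size_neg
        if self.n_vlinc * per_vlinc >= self.n_genes:
            raise ValueError("planted networks exceed the number of genes")
        if self.n_samples < 6:
            raise ValueError("need >= 6 samples (4 solvent controls + 1 drug)")
        for cond, dep in self.survival_depletion.items():
            if dep <= 0:
                raise ValueError(f"depletion for {cond!r} must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome


@dataclass
class GroundTruth:
    """Planted structure the pipeline should recover."""

    genes: List[str]
    vlincs: List[str]
    pos_targets: Dict[str, Set[str]]
    neg_targets: Dict[str, Set[str]]
    cis_targets: Dict[str, Set[str]]  # targets on the vlincRNA's chromosome
    kd_direction: Dict[str, Dict[str, int]]  # vlinc -> gene -> +1 (up) / -1

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for v in self.pos_targets:
            if self.pos_targets[v] & self.neg_targets[v]:
                raise ValueError(f"overlapping positive/negative targets for {v}")
            stray = (self.pos_targets[v] | self.neg_targets[v]) - gene_set
            if stray:
                raise ValueError(f"targets not in the gene universe: {sorted(stray)[:5]}")

    def targets(self, vlinc: str) -> Set[str]:
        return self.pos_targets[vlinc] | self.neg_targets[vlinc]

    def edge_set(self) -> Set[Tuple[str, str, str]]:
        edges = set()
        for v in self.vlincs:
            edges |= {(v, g, "positive") for g in self.pos_targets[v]}
            edges |= {(v, g, "negative") for g in self.neg_targets[v]}
        return edges

    def to_json(self) -> str:
        payload = {
            "genes": self.genes,
            "vlincs": self.vlincs,
            "pos_targets": {v: sorted(s) for v, s in self.pos_targets.items()},
            "neg_targets": {v: sorted(s) for v, s in self.neg_targets.items()},
            "cis_targets": {v: sorted(s) for v, s in self.cis_targets.items()},
            "kd_direction": self.kd_direction,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            genes=d["genes"],
            vlincs=d["vlincs"],
            pos_targets={v: set(s) for v, s in d["pos_targets"].items()},
            neg_targets={v: set(s) for v, s in d["neg_targets"].items()},
            cis_targets={v: set(s) for v, s in d["cis_targets"].items()},
            kd_direction=d["kd_direction"],
        )


# ---------------------------------------------------------------------------
# annotation & truth


def make_annotation(spec: SimulationSpec) -> GeneAnnotation:
    """Place non-overlapping gene and vlincRNA intervals on each chromosome.

    Genes occupy fixed slots of (gene_length + spacer); vlincRNAs are
    appended after the gene block of their host chromosome (round-robin).
    An explicit ``chromosome_length`` too small to hold the layout is
    rejected.
    """
    rng = _rng(spec.seed, _STREAM_ANNOT)
    slot = spec.gene_length + spec.spacer
    vl_slot = spec.vlinc_length + spec.spacer
    vlinc_hosts = [f"chr{(j % spec.n_chromosomes) + 1}" for j in range(spec.n_vlinc)]
    rows = []
    gid = 0
    for c in range(1, spec.n_chromosomes + 1):
        chrom = f"chr{c}"
        n_vl_here = vlinc_hosts.count(chrom)
        needed = spec.genes_per_chromosome * slot + n_vl_here * vl_slot + spec.spacer
        if spec.chromosome_length is not None and spec.chromosome_length < needed:
            raise ValueError(
                f"chromosome_length {spec.chromosome_length} cannot hold "
                f"{spec.genes_per_chromosome} genes on {chrom} (need {needed})"
            )
        for i in range(spec.genes_per_chromosome):
            start = spec.spacer // 2 + i * slot
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + spec.gene_length,
                    "name": f"g{gid:05d}",
                    "score": 0,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "klass": MRNA,
                }
            )
            gid += 1
    gene_block_end = spec.spacer // 2 + spec.genes_per_chromosome * slot
    per_chrom_count: Dict[str, int] = {}
    for j, chrom in enumerate(vlinc_hosts):
        k = per_chrom_count.get(chrom, 0)
        start = gene_block_end + spec.spacer + k * vl_slot
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + spec.vlinc_length,
                "name": f"vlinc-{j + 1}",
                "score": 0,
                "strand": "+" if rng.random() < 0.5 else "-",
                "klass": VLINC,
            }
        )
        per_chrom_count[chrom] = k + 1
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    ann = GeneAnnotation(df)
    assert ann.overlaps_ok()
    return ann


def make_ground_truth(spec: SimulationSpec, ann: GeneAnnotation) -> GroundTruth:
    """Draw mutually disjoint positive/negative target sets per vlincRNA."""
    rng = _rng(spec.seed, _STREAM_TRUTH)
    genes = list(ann.genes.name)
    vlincs = list(ann.vlincs.name)
    chrom_of = ann.chromosome_of()
    pool = np.array(genes)
    rng.shuffle(pool)
    pos: Dict[str, Set[str]] = {}
    neg: Dict[str, Set[str]] = {}
    cis: Dict[str, Set[str]] = {}
    direction: Dict[str, Dict[str, int]] = {}
    cursor = 0
    for v in vlincs:
        take_pos = spec.network_size_pos
        take_neg = spec.network_size_neg
        chunk = pool[cursor : cursor + take_pos + take_neg]
        cursor += take_pos + take_neg
        pos[v] = set(chunk[:take_pos])
        neg[v] = set(chunk[take_pos:])
        cis[v] = {g for g in chunk if chrom_of[g] == chrom_of[v]}
        direction[v] = {g: -1 for g in pos[v]}
        direction[v].update({g: +1 for g in neg[v]})
    return GroundTruth(
        genes=genes,
        vlincs=vlincs,
        pos_targets=pos,
        neg_targets=neg,
        cis_targets=cis,
        kd_direction=direction,
    )


def empty_ground_truth(ann: GeneAnnotation) -> GroundTruth:
    """A truth object with no planted structure (null simulations)."""
    genes = list(ann.genes.name)
    vlincs = list(ann.vlincs.name)
    empty = {v: set() for v in vlincs}
    return GroundTruth(
        genes=genes,
        vlincs=vlincs,
        pos_targets={v: set() for v in vlincs},
        neg_targets={v: set() for v in vlincs},
        cis_targets=empty,
        kd_direction={v: {} for v in vlincs},
    )


# ---------------------------------------------------------------------------
# expression


def _sample_design(spec: SimulationSpec) -> pd.DataFrame:
    """64-sample-style design: DMSO/water solvent controls at 3 h and 6 h,
    then drugs with two time points each (solvent alternating)."""
    rows = []
    for solvent in ("DMSO", "water"):
        for tp in (3, 6):
            rows.append((solvent, tp, True, solvent))
    n_drugs = (spec.n_samples - 4) // 2
    for d in range(n_drugs):
        solvent = "DMSO" if d % 2 == 0 else "water"
        for tp in (3, 6):
            rows.append((f"drug{d + 1:02d}", tp, False, solvent))
    while len(rows) < spec.n_samples:  # odd remainder -> extra solvent controls
        rows.append(("DMSO", 3, True, "DMSO"))
    meta = pd.DataFrame(
        rows, columns=["drug", "timepoint_h", "solvent_flag", "solvent"]
    )
    meta.index = pd.Index([f"s{i + 1:03d}" for i in range(len(meta))], name="sample")
    return meta


def simulate_expression(
    spec: SimulationSpec, ann: GeneAnnotation, truth: GroundTruth
) -> ExpressionMatrix:
    """Positive abundance matrix with the planted rank-correlation structure.

    Each vlincRNA and its targets load on a shared standard-normal latent
    factor with loading sqrt(rho_p), rho_p = 2 sin(pi * rho_s / 6), which
    makes the population Spearman correlation of a planted pair exactly
    +/- rho_target; non-network genes are independent noise. Latents map to
    abundances via base * exp(noise_sd * z), a strictly increasing
    transform, and per-drug fold effects are added for a small
    drug-responsive gene set so the differential-expression caller has
    structure to find.
    """
    rng = _rng(spec.seed, _STREAM_EXPR)
    meta = _sample_design(spec)
    n = spec.n_samples
    genes, vlincs = truth.genes, truth.vlincs
    rho_p = 2 * math.sin(math.pi * spec.rho_target / 6)
    a = math.sqrt(rho_p)
    b = math.sqrt(1 - rho_p)

    z = pd.DataFrame(
        rng.normal(size=(len(genes) + len(vlincs), n)),
        index=genes + vlincs,
        columns=meta.index,
    )
    for v in vlincs:
        f = rng.normal(size=n)
        z.loc[v] = a * f + b * rng.normal(size=n)
        for g in sorted(truth.pos_targets[v]):
            z.loc[g] = a * f + b * rng.normal(size=n)
        for g in sorted(truth.neg_targets[v]):
            z.loc[g] = -(a * f + b * rng.normal(size=n))

    base = pd.Series(
        rng.lognormal(mean=2.3, sigma=1.0, size=len(z)), index=z.index
    )
    values = base.to_numpy()[:, None] * np.exp(spec.noise_sd * z.to_numpy())
    values = pd.DataFrame(values, index=z.index, columns=meta.index)

    if spec.n_de_genes > 0:
        networked = set().union(*truth.pos_targets.values(), *truth.neg_targets.values())
        free = [g for g in genes if g not in networked]
        n_de = min(spec.n_de_genes, len(free))
        de_genes = rng.choice(free, size=n_de, replace=False)
        drugs = sorted(meta[~meta.solvent_flag].drug.unique())
        for g in de_genes:
            drug = drugs[int(rng.integers(len(drugs)))]
            fold = spec.de_fold if rng.random() < 0.5 else 1 / spec.de_fold
            cols = meta.index[meta.drug == drug]
            values.loc[g, cols] *= fold

    klass = pd.Series(
        [MRNA] * len(genes) + [VLINC] * len(vlincs), index=genes + vlincs
    )
    return ExpressionMatrix(values=values, sample_meta=meta, transcript_class=klass)


# ---------------------------------------------------------------------------
# RAT tracks


def simulate_rat_tracks(
    spec: SimulationSpec, ann: GeneAnnotation, truth: GroundTruth
) -> List[RatTrack]:
    """Raw Poisson coverage tracks: per (vlincRNA, treatment), two replicas
    of two oligo sets plus a background-level no-oligo control.

    The oligo-set rate is enriched by ``chromatin_enrichment`` over the
    planted network gene bodies and their ``chromatin_flank`` surroundings
    (chromatin proximity is not confined to the transcribed unit, and the
    metagene statistic profiles the flanks too)."""
    rng = _rng(spec.seed, _STREAM_RAT)
    sizes = ann.chrom_sizes()
    lam = spec.rat_background_rate
    gene_rows = ann.genes.set_index("name")
    tracks: List[RatTrack] = []
    for v in truth.vlincs:
        # merged enriched spans per chromosome (flanks of adjacent targets
        # may overlap, so build a mask and take its runs)
        enriched_mask: Dict[str, np.ndarray] = {
            c: np.zeros(sizes[c], dtype=bool) for c in sorted(sizes)
        }
        for g in sorted(truth.targets(v)):
            r = gene_rows.loc[g]
            lo = max(int(r.start) - spec.chromatin_flank, 0)
            hi = min(int(r.end) + spec.chromatin_flank, sizes[r.chrom])
            enriched_mask[r.chrom][lo:hi] = True
        spans: Dict[str, List[Tuple[int, int]]] = {}
        for c, m in enriched_mask.items():
            edges = np.flatnonzero(np.diff(np.concatenate([[0], m, [0]])))
            spans[c] = list(zip(edges[0::2].tolist(), edges[1::2].tolist()))
        for treatment in spec.treatments:
            for replica in (1, 2):
                for source in (OLIGO_1, OLIGO_2, NO_OLIGO):
                    scores = {
                        c: rng.poisson(lam, sizes[c]).astype(float)
                        for c in sorted(sizes)
                    }
                    if source != NO_OLIGO:
                        for c in sorted(sizes):
                            for lo, hi in spans[c]:
                                scores[c][lo:hi] = rng.poisson(
                                    lam * spec.chromatin_enrichment, hi - lo
                                )
                    total = int(sum(s.sum() for s in scores.values()))
                    tracks.append(
                        RatTrack(
                            scores=scores,
                            vlinc=v,
                            treatment=treatment,
                            replica=replica,
                            source=source,
                            total_reads=max(total, 1),
                            stage="raw",
                        )
                    )
    return tracks


# ---------------------------------------------------------------------------
# knockdown


def simulate_knockdown(
    spec: SimulationSpec, truth: GroundTruth
) -> Dict[Tuple[str, str], pd.DataFrame]:
    """FPKM tables per (vlincRNA, gRNA): days 3/6 of the targeting arm
    shift negative targets up and positive targets down by the knockdown
    effect; day 0 and the whole mismatch arm are effect-free; the vlincRNA
    itself is depleted by ``vlinc_depletion`` in the targeting arm."""
    rng = _rng(spec.seed, _STREAM_KD)
    cols = ["T0", "T3", "T6", "NT0", "NT3", "NT6"]
    out: Dict[Tuple[str, str], pd.DataFrame] = {}
    for v in truth.vlincs:
        shift = pd.Series(1.0, index=truth.genes + [v])
        for g, d in truth.kd_direction[v].items():
            shift[g] = 1 + d * spec.knockdown_effect
        shift[v] = 1 - spec.vlinc_depletion
        for k in range(1, spec.grnas_per_vlinc + 1):
            base = pd.Series(
                rng.lognormal(mean=2.3, sigma=1.0, size=len(shift)), index=shift.index
            )
            table = pd.DataFrame(index=shift.index, columns=cols, dtype=float)
            for col in cols:
                factor = shift if col in ("T3", "T6") else 1.0
                noise = rng.lognormal(
                    mean=-spec.kd_noise_sd**2 / 2,
                    sigma=spec.kd_noise_sd,
                    size=len(shift),
                )
                table[col] = base * factor * noise
            out[(v, f"{v}_g{k}")] = table
    return out


# ---------------------------------------------------------------------------
# survival


def simulate_survival_counts(
    spec: SimulationSpec,
    truth: GroundTruth,
    n_pairs: Optional[int] = None,
    depletion: Optional[Mapping[str, float]] = None,
) -> SurvivalCounts:
    """Pooled gRNA counts with planted multiplicative depletion of the
    targeting guides. Replicate fractions carry mean-one lognormal noise;
    counts are Poisson at the configured depth."""
    rng = _rng(spec.seed, _STREAM_SURV)
    depletion = dict(depletion or spec.survival_depletion)
    if n_pairs is None:
        pairs = [
            (f"{v}_g{k}", f"{v}_g{k}_mm")
            for v in truth.vlincs
            for k in range(1, spec.grnas_per_vlinc + 1)
        ]
    else:
        pairs = [(f"pair{i + 1:03d}", f"pair{i + 1:03d}_mm") for i in range(n_pairs)]
    rows = []
    for cond in sorted(depletion):
        dep = depletion[cond]
        for rep in range(1, spec.survival_replicates + 1):
            weights = {}
            for targ, ctrl in pairs:
                noise = rng.lognormal(
                    mean=-spec.survival_noise_sd**2 / 2, sigma=spec.survival_noise_sd
                )
                weights[targ] = dep * noise
                weights[ctrl] = 1.0
            total_w = sum(weights.values())
            for grna, w in weights.items():
                count = int(rng.poisson(spec.survival_depth * w / total_w))
                rows.append(
                    {"grna": grna, "condition": cond, "replicate": rep, "count": count}
                )
    counts = pd.DataFrame(rows, columns=["grna", "condition", "replicate", "count"])
    return SurvivalCounts(counts=counts, pairing=dict(pairs))
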