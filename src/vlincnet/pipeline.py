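"""End-to-end orchestration: simulate -> co-expression -> RAT -> ANARS ->
validation -> knockdown -> survival, with every stage's outputs written as
plain-text tables under one output directory.

Identical config + seed produces a byte-identical output tree: all
randomness flows from the seed, tables are written in sorted order, and
the run manifest carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import anars as anars_mod
from . import io as vio
from . import rat as rat_mod
from . import validation as val_mod
from .annotation import GeneAnnotation, genes_overlapping
from .expression import (
    ExpressionMatrix,
    call_de,
    distance_stratified_medians,
    negative_bias_test,
    spearman_full,
    spearman_network,
    stratify_by_expression,
)
from .knockdown import effect_summary, filter_expressed, group_genes, relative_fold_change
from .rat import NO_OLIGO, OLIGO_1, OLIGO_2, PERCENTILES, RatTrack
from .simulate import GroundTruth, SimulationSpec, make_annotation, make_ground_truth
from .simulate import simulate_expression, simulate_knockdown, simulate_rat_tracks
from .simulate import simulate_survival_counts
from .survival import condition_comparison, normalize_abundance, summarize_ratios, targeting_ratios

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed driving one pipeline run."""

    outdir: Path
    seed: int = 0
    simulate: Dict = field(default_factory=dict)  # SimulationSpec overrides
    rho_min: float = 0.35
    p_max: float = 0.01
    fc_threshold: float = 1.5
    min_fpkm: float = 1.0
    percentiles: Tuple[int, ...] = PERCENTILES

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not 0 < self.rho_min < 1:
            raise ValueError("rho_min must lie in (0, 1)")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        bad = set(self.percentiles) - set(PERCENTILES)
        if bad:
            raise ValueError(f"unsupported percentiles: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "percentiles" in raw:
            raw["percentiles"] = tuple(raw["percentiles"])
        return cls(**raw)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["percentiles"] = list(self.percentiles)
        return d

    def spec(self) -> SimulationSpec:
        params = dict(self.simulate)
        params["seed"] = self.seed
        return SimulationSpec(**params)


# ---------------------------------------------------------------------------
# RAT processing helpers shared by pipeline, CLI and tests


def preprocess_rat(
    tracks: Sequence[RatTrack],
) -> Dict[Tuple[str, str], Dict[str, RatTrack]]:
    """Normalize, control-subtract and average raw tracks.

    Returns, per (vlinc, treatment): the four control-subtracted oligo
    tracks keyed "rep{r}_{source}" plus the replica/oligo-averaged track
    under "averaged".
    """
    by_key: Dict[Tuple[str, str, int], Dict[str, RatTrack]] = {}
    for t in tracks:
        by_key.setdefault((t.vlinc, t.treatment, t.replica), {})[t.source] = t
    out: Dict[Tuple[str, str], Dict[str, RatTrack]] = {}
    for (vlinc, treatment, replica), sources in sorted(by_key.items()):
        missing = {OLIGO_1, OLIGO_2, NO_OLIGO} - set(sources)
        if missing:
            raise ValueError(
                f"incomplete RAT set for {vlinc}/{treatment} rep {replica}: "
                f"missing {sorted(missing)}"
            )
        control = rat_mod.normalize(sources[NO_OLIGO])
        slot = out.setdefault((vlinc, treatment), {})
        for source in (OLIGO_1, OLIGO_2):
            norm = rat_mod.normalize(sources[source])
            slot[f"rep{replica}_{source}"] = rat_mod.subtract_control(norm, control)
    for key, slot in out.items():
        subtracted = [slot[k] for k in sorted(slot)]
        slot["averaged"] = rat_mod.average_tracks(subtracted)
    return out


def call_rat_gene_sets(
    processed: Mapping[Tuple[str, str], Mapping[str, RatTrack]],
    ann: GeneAnnotation,
    percentiles: Sequence[int] = PERCENTILES,
) -> Tuple[val_mod.RatGeneSets, pd.DataFrame, pd.DataFrame]:
    """Region calling and per-replica gene sets at every percentile.

    The oligo-set-1 track scores are ranked, masked by positivity of the
    oligo-set-2 track (and vice versa is not repeated: one scoring track
    per replica, fixed for determinism). Returns (gene sets keyed by
    (vlinc, treatment, percentile, level), regions table, concordance table).
    """
    gene_sets: Dict[Tuple[str, str, int, str], Set[str]] = {}
    region_rows: List[pd.DataFrame] = []
    concordance_rows = []
    universe = set(ann.genes.name)
    for (vlinc, treatment), slot in sorted(processed.items()):
        for pct in percentiles:
            per_replica = {}
            for rep in (1, 2):
                track = slot[f"rep{rep}_{OLIGO_1}"]
                other = slot[f"rep{rep}_{OLIGO_2}"]
                regions = rat_mod.call_regions(track, other, pct)
                per_replica[rep] = regions
                df = regions.intervals.copy()
                df.insert(0, "percentile", pct)
                df.insert(0, "replica", rep)
                df.insert(0, "treatment", treatment)
                df.insert(0, "vlinc", vlinc)
                region_rows.append(df)
            for level in ("gene", "region"):
                genes = rat_mod.genes_with_regions(
                    per_replica[1], per_replica[2], ann, level=level
                )
                gene_sets[(vlinc, treatment, pct, level)] = genes
            g1 = genes_overlapping(per_replica[1].intervals, ann)
            g2 = genes_overlapping(per_replica[2].intervals, ann)
            orr, p = rat_mod.replica_concordance(g1, g2, universe)
            concordance_rows.append(
                {
                    "vlinc": vlinc,
                    "treatment": treatment,
                    "percentile": pct,
                    "n_rep1": len(g1),
                    "n_rep2": len(g2),
                    "odds_ratio": orr,
                    "p": p,
                }
            )
    regions = (
        pd.concat(region_rows, ignore_index=True)
        if region_rows
        else pd.DataFrame(
            columns=["vlinc", "treatment", "replica", "percentile",
                     "chrom", "start", "end", "mean_score"]
        )
    )
    concordance = pd.DataFrame(concordance_rows)
    return gene_sets, regions, concordance


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage on a synthetic dataset; returns the output dir."""
    out = config.outdir
    spec = config.spec()
    dirs = {
        name: out / name
        for name in ("inputs", "coexpr", "rat", "anars", "validation", "knockdown", "survival")
    }
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)

    # --- stage 1: synthetic inputs -----------------------------------------
    logger.info("simulating inputs (seed=%d)", spec.seed)
    ann = make_annotation(spec)
    truth = make_ground_truth(spec, ann)
    expr = simulate_expression(spec, ann, truth)
    tracks = simulate_rat_tracks(spec, ann, truth)
    kd_tables = simulate_knockdown(spec, truth)
    surv = simulate_survival_counts(spec, truth)

    vio.write_bed(ann, dirs["inputs"] / "annotation.bed")
    vio.write_expression(
        expr, dirs["inputs"] / "expression.tsv", dirs["inputs"] / "samples.tsv"
    )
    vio.write_rat_tracks(tracks, dirs["inputs"] / "rat")
    for (vlinc, grna), table in sorted(kd_tables.items()):
        table.rename_axis("gene").to_csv(
            dirs["inputs"] / f"kd_{grna}.tsv", sep="\t"
        )
    vio.write_survival(
        surv,
        dirs["inputs"] / "survival_counts.tsv",
        dirs["inputs"] / "survival_pairs.tsv",
    )
    (dirs["inputs"] / "ground_truth.json").write_text(truth.to_json() + "\n")

    # --- stage 2: expression ------------------------------------------------
    logger.info("co-expression analysis")
    de = call_de(expr, fc_threshold=config.fc_threshold)
    halves = stratify_by_expression(expr)
    net = spearman_network(
        expr, rho_min=config.rho_min, p_max=config.p_max, half_labels=halves
    )
    rho_df, p_df = spearman_full(expr)
    vio.write_network(net, dirs["coexpr"] / "network.tsv")
    halves.rename_axis("gene").to_csv(dirs["coexpr"] / "halves.tsv", sep="\t")
    de_rows = [
        {"drug": drug, "direction": direction, "transcript": t}
        for direction, table in (("up", de.up), ("down", de.down))
        for drug, ts in sorted(table.items())
        for t in sorted(ts)
    ]
    vio.write_tsv(
        pd.DataFrame(de_rows, columns=["drug", "direction", "transcript"]),
        dirs["coexpr"] / "de_sets.tsv",
    )
    dist = distance_stratified_medians(net, ann)
    dist.rename_axis("distance_bin").to_csv(
        dirs["coexpr"] / "distance_medians.tsv", sep="\t"
    )
    try:
        bias_p = negative_bias_test(net)
    except ValueError:
        bias_p = float("nan")
    summary_coexpr = {
        "n_edges": int(len(net.edges)),
        "n_negative": int((net.edges.sign == "negative").sum()),
        "n_positive": int((net.edges.sign == "positive").sum()),
        "negative_bias_p": bias_p,
    }
    vio.write_json(summary_coexpr, dirs["coexpr"] / "summary.json")

    # --- stage 3: RAT signal ------------------------------------------------
    logger.info("RAT region calling")
    processed = preprocess_rat(tracks)
    rat_genes, regions, concordance = call_rat_gene_sets(
        processed, ann, config.percentiles
    )
    vio.write_tsv(regions, dirs["rat"] / "regions.tsv")
    vio.write_tsv(concordance, dirs["rat"] / "replica_concordance.tsv")
    gene_rows = [
        {"vlinc": v, "treatment": t, "percentile": pct, "level": lvl, "gene": g}
        for (v, t, pct, lvl), genes in sorted(rat_genes.items())
        for g in sorted(genes)
    ]
    vio.write_tsv(
        pd.DataFrame(gene_rows, columns=["vlinc", "treatment", "percentile", "level", "gene"]),
        dirs["rat"] / "gene_sets.tsv",
    )

    # --- stage 4: ANARS -----------------------------------------------------
    logger.info("metagene aggregation (ANARS)")
    universe = set(halves.index)
    anars_tests = []
    chrom_of = ann.chromosome_of()
    for (vlinc, treatment), slot in sorted(processed.items()):
        track = slot["averaged"]
        pos = sorted(net.partners(vlinc, "positive") & universe)
        neg = sorted(net.partners(vlinc, "negative") & universe)
        background = sorted(universe - set(pos) - set(neg))
        profiles = {}
        for group, genes in (("positive", pos), ("negative", neg), ("background", background)):
            if genes:
                profiles[group] = anars_mod.compute_anars(track, genes, ann, group=group)
        wide = {"position": np.arange(1, anars_mod.PROFILE_LEN + 1)}
        for group in sorted(profiles):
            prof = profiles[group]
            wide[f"body_{group}"] = prof.body
            wide[f"upstream_{group}"] = prof.upstream_flank
            wide[f"downstream_{group}"] = prof.downstream_flank
        vio.write_tsv(
            pd.DataFrame(wide), dirs["anars"] / f"{vlinc}_{treatment}.tsv"
        )
        for sign in ("positive", "negative"):
            if sign not in profiles or "background" not in profiles:
                continue
            for region in ("body", "upstream", "downstream"):
                p = anars_mod.top30_test(
                    profiles[sign].region(region), profiles["background"].region(region)
                )
                anars_tests.append(
                    {"vlinc": vlinc, "treatment": treatment, "region": region,
                     "comparison": f"{sign}_vs_background", "p": p}
                )
            cis_genes = sorted(
                g for g in (pos if sign == "positive" else neg)
                if chrom_of[g] == chrom_of[vlinc]
            )
            all_genes = pos if sign == "positive" else neg
            if cis_genes and all_genes:
                prof_cis = anars_mod.compute_anars(track, cis_genes, ann, group="cis")
                for region in ("body", "upstream", "downstream"):
                    p = anars_mod.cis_vs_all_test(
                        prof_cis.region(region), profiles[sign].region(region)
                    )
                    if p is not None:
                        anars_tests.append(
                            {"vlinc": vlinc, "treatment": treatment, "region": region,
                             "comparison": f"cis_{sign}_vs_all", "p": p}
                        )
    vio.write_tsv(
        pd.DataFrame(anars_tests, columns=["vlinc", "treatment", "region", "comparison", "p"]),
        dirs["anars"] / "tests.tsv",
    )

    # --- stage 5: network validation ----------------------------------------
    logger.info("network/chromatin overlap validation")
    overlap_frames = []
    for (vlinc, treatment) in sorted(processed):
        overlap_frames.append(
            val_mod.stratified_overlap(
                net, vlinc, treatment, rat_genes, halves, universe,
                percentiles=config.percentiles,
            )
        )
    overlaps = pd.concat(overlap_frames, ignore_index=True)
    vio.write_tsv(overlaps, dirs["validation"] / "overlaps.tsv")
    final = val_mod.select_final_threshold(overlaps, net, rat_genes)
    vio.write_tsv(final.choices, dirs["validation"] / "final_choices.tsv")
    validated_rows = [
        {"vlinc": v, "treatment": t, "sign": s, "gene": g}
        for (v, t, s), genes in sorted(final.validated.items())
        for g in sorted(genes)
    ]
    vio.write_tsv(
        pd.DataFrame(validated_rows, columns=["vlinc", "treatment", "sign", "gene"]),
        dirs["validation"] / "validated_genes.tsv",
    )
    stability = val_mod.network_stability(final, universe)
    vio.write_tsv(stability, dirs["validation"] / "stability.tsv")
    cis_trans = val_mod.cis_trans_comparison(final, ann, net, rat_genes, universe)
    vio.write_tsv(cis_trans["table"], dirs["validation"] / "cis_trans.tsv")
    vio.write_json(
        {k: cis_trans[k] for k in ("p", "median_cis", "median_all")},
        dirs["validation"] / "cis_trans_summary.json",
    )

    # --- stage 6: knockdown --------------------------------------------------
    logger.info("knockdown effect quantification")
    effect_frames = []
    for (vlinc, grna), table in sorted(kd_tables.items()):
        expressed = filter_expressed(table, min_fpkm=config.min_fpkm)
        rfc = relative_fold_change(table.loc[expressed])
        rfc.rename_axis("gene").to_csv(
            dirs["knockdown"] / f"rfc_{grna}.tsv", sep="\t"
        )
        rho_v = rho_df.loc[vlinc]
        p_v = p_df.loc[vlinc]
        groups = group_genes(rho_v, p_v, rho_min=config.rho_min, p_max=config.p_max)
        for mode in ("combined", "by_day"):
            eff = effect_summary(rfc, groups, mode=mode)
            eff.insert(0, "grna", grna)
            eff.insert(0, "vlinc", vlinc)
            effect_frames.append(eff)
    effects = pd.concat(effect_frames, ignore_index=True)
    vio.write_tsv(effects, dirs["knockdown"] / "effects.tsv")

    # --- stage 7: survival ---------------------------------------------------
    logger.info("survival ratio analysis")
    norm = normalize_abundance(surv.counts)
    ratios = targeting_ratios(norm, surv.pairing)
    vio.write_tsv(ratios, dirs["survival"] / "ratios.tsv")
    vio.write_tsv(summarize_ratios(ratios), dirs["survival"] / "summary.tsv")
    contrasts = []
    conds = sorted(surv.counts.condition.unique())
    if "drug_dox" in conds:
        for other in conds:
            if other == "drug_dox":
                continue
            try:
                p = condition_comparison(ratios, other, "drug_dox")
            except ValueError:
                continue
            contrasts.append({"higher": other, "lower": "drug_dox", "p": p})
    vio.write_tsv(
        pd.DataFrame(contrasts, columns=["higher", "lower", "p"]),
        dirs["survival"] / "tests.tsv",
    )

    # --- manifest -------------------------------------------------------------
    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name != "run_manifest.json"
    )
    config_echo = config.to_dict()
    config_echo.pop("outdir")  # keep the tree byte-identical across locations
    vio.write_json(
        {"config": config_echo, "outputs": files},
        out / "run_manifest.json",
    )
    return out
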