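"""Synthetic data generator: determinism, geometry and planted structure."""

import numpy as np
import pytest

from vlincnet import rat, simulate


SMALL = dict(
    n_chromosomes=2, genes_per_chromosome=12, n_vlinc=2,
    network_size_pos=3, network_size_neg=5, n_samples=16,
    gene_length=500, spacer=1500, chromatin_flank=500,
    vlinc_length=3000,
)


def test_same_seed_reproduces_every_generator():
    a, b = (simulate.SimulationSpec(seed=9, **SMALL) for _ in range(2))
    ann_a, ann_b = simulate.make_annotation(a), simulate.make_annotation(b)
    assert ann_a.df.equals(ann_b.df)
    truth_a = simulate.make_ground_truth(a, ann_a)
    truth_b = simulate.make_ground_truth(b, ann_b)
    assert truth_a.edge_set() == truth_b.edge_set()
    ea = simulate.simulate_expression(a, ann_a, truth_a)
    eb = simulate.simulate_expression(b, ann_b, truth_b)
    assert ea.values.equals(eb.values)
    ta = simulate.simulate_rat_tracks(a, ann_a, truth_a)
    tb = simulate.simulate_rat_tracks(b, ann_b, truth_b)
    for x, y in zip(ta, tb):
        assert (x.vlinc, x.treatment, x.replica, x.source) == (
            y.vlinc, y.treatment, y.replica, y.source
        )
        for c in x.scores:
            assert np.array_equal(x.scores[c], y.scores[c])


def test_generators_use_independent_random_streams():
    base = simulate.SimulationSpec(seed=9, **SMALL)
    # changing a downstream generator's parameters must not disturb the
    # expression draw
    changed = simulate.SimulationSpec(
        seed=9, **{**SMALL, "grnas_per_vlinc": 1}
    )
    ann = simulate.make_annotation(base)
    truth = simulate.make_ground_truth(base, ann)
    ea = simulate.simulate_expression(base, ann, truth)
    eb = simulate.simulate_expression(changed, ann, truth)
    assert ea.values.equals(eb.values)


def test_annotation_layout_is_disjoint_and_complete():
    spec = simulate.SimulationSpec(seed=1, **SMALL)
    ann = simulate.make_annotation(spec)
    assert ann.overlaps_ok()
    assert len(ann.genes) == spec.n_genes
    assert len(ann.vlincs) == spec.n_vlinc
    assert (ann.genes.end - ann.genes.start == spec.gene_length).all()


def test_too_small_chromosome_rejected():
    spec = simulate.SimulationSpec(seed=1, **{**SMALL, "chromosome_length": 100})
    with pytest.raises(ValueError, match="cannot hold"):
        simulate.make_annotation(spec)


def test_ground_truth_targets_are_disjoint_across_vlincs():
    spec = simulate.SimulationSpec(seed=4, **SMALL)
    ann = simulate.make_annotation(spec)
    truth = simulate.make_ground_truth(spec, ann)
    all_targets = []
    for v in truth.vlincs:
        assert len(truth.pos_targets[v]) == spec.network_size_pos
        assert len(truth.neg_targets[v]) == spec.network_size_neg
        assert not truth.pos_targets[v] & truth.neg_targets[v]
        all_targets.extend(truth.targets(v))
    assert len(all_targets) == len(set(all_targets))


def test_ground_truth_round_trips_through_json():
    spec = simulate.SimulationSpec(seed=4, **SMALL)
    ann = simulate.make_annotation(spec)
    truth = simulate.make_ground_truth(spec, ann)
    back = simulate.GroundTruth.from_json(truth.to_json())
    assert back.edge_set() == truth.edge_set()
    assert back.cis_targets == truth.cis_targets


def test_planted_pairs_correlate_near_target():
    spec = simulate.SimulationSpec(
        seed=2, **{**SMALL, "n_samples": 64, "rho_target": 0.9}
    )
    ann = simulate.make_annotation(spec)
    truth = simulate.make_ground_truth(spec, ann)
    expr = simulate.simulate_expression(spec, ann, truth)
    from scipy.stats import spearmanr

    rhos = []
    for v in truth.vlincs:
        x = expr.values.loc[v]
        for g in sorted(truth.pos_targets[v]):
            rhos.append(spearmanr(x, expr.values.loc[g]).statistic)
        for g in sorted(truth.neg_targets[v]):
            rhos.append(-spearmanr(x, expr.values.loc[g]).statistic)
    assert np.median(rhos) > 0.7
    assert abs(np.mean(rhos) - spec.rho_target) < 0.1


def test_chromatin_tracks_enriched_over_targets_and_flanks():
    spec = simulate.SimulationSpec(
        seed=3, **{**SMALL, "chromatin_enrichment": 3.0}
    )
    ann = simulate.make_annotation(spec)
    truth = simulate.make_ground_truth(spec, ann)
    tracks = simulate.simulate_rat_tracks(spec, ann, truth)
    v = truth.vlincs[0]
    t = next(
        x for x in tracks
        if (x.vlinc, x.replica, x.source) == (v, 1, rat.OLIGO_1)
    )
    ctrl = next(
        x for x in tracks
        if (x.vlinc, x.replica, x.source) == (v, 1, rat.NO_OLIGO)
    )
    genes = ann.genes.set_index("name")
    g = sorted(truth.targets(v))[0]
    row = genes.loc[g]
    lo, hi = int(row.start), int(row.end)
    body_ratio = t.scores[row.chrom][lo:hi].mean() / ctrl.scores[row.chrom][lo:hi].mean()
    assert 2.5 < body_ratio < 3.5
    flank = t.scores[row.chrom][hi : hi + spec.chromatin_flank].mean()
    assert flank / spec.rat_background_rate > 2.5
    # a non-target gene stays at background level
    bg = sorted(set(genes.index) - truth.targets(v))[0]
    row = genes.loc[bg]
    # only consider non-targets far from any target's flank
    others = {
        x for w in truth.vlincs for x in truth.targets(w)
    }
    if bg not in others:
        ratio = (
            t.scores[row.chrom][int(row.start): int(row.end)].mean()
            / spec.rat_background_rate
        )
        assert 0.8 < ratio < 1.2


def test_enrichment_one_means_flat_tracks():
    spec = simulate.SimulationSpec(
        seed=3, **{**SMALL, "chromatin_enrichment": 1.0}
    )
    ann = simulate.make_annotation(spec)
    truth = simulate.make_ground_truth(spec, ann)
    tracks = simulate.simulate_rat_tracks(spec, ann, truth)
    t = tracks[0]
    genes = ann.genes.set_index("name")
    g = sorted(truth.targets(t.vlinc))[0]
    row = genes.loc[g]
    ratio = (
        t.scores[row.chrom][int(row.start): int(row.end)].mean()
        / spec.rat_background_rate
    )
    assert 0.9 < ratio < 1.1


def test_knockdown_shifts_follow_planted_directions():
    spec = simulate.SimulationSpec(
        seed=6, **{**SMALL, "knockdown_effect": 0.4, "kd_noise_sd": 0.05}
    )
    ann = simulate.make_annotation(spec)
    truth = simulate.make_ground_truth(spec, ann)
    tables = simulate.simulate_knockdown(spec, truth)
    assert len(tables) == spec.n_vlinc * spec.grnas_per_vlinc
    (v, grna), table = sorted(tables.items())[0]
    neg_ratio = (table.T3 / table.T0)[sorted(truth.neg_targets[v])].mean()
    pos_ratio = (table.T3 / table.T0)[sorted(truth.pos_targets[v])].mean()
    assert neg_ratio > 1.2 and pos_ratio < 0.8
    # the mismatch-control arm carries no shift
    nt_ratio = (table.NT3 / table.NT0)[sorted(truth.targets(v))].mean()
    assert 0.9 < nt_ratio < 1.1
    # the vlincRNA itself is depleted in the targeting arm
    assert (table.T3 / table.T0)[v] < 1 - spec.vlinc_depletion / 2


def test_survival_counts_match_design():
    spec = simulate.SimulationSpec(seed=7, **SMALL)
    sc = simulate.simulate_survival_counts(
        spec, simulate.empty_ground_truth(simulate.make_annotation(spec)),
        n_pairs=5,
    )
    assert len(sc.pairing) == 5
    conds = set(sc.counts.condition)
    assert conds == set(spec.survival_depletion)
    per_sample = sc.counts.groupby(["condition", "replicate"]).size()
    assert (per_sample == 10).all()
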