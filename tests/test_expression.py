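"""Differential expression, Spearman networks and partner-sign statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vlincnet.expression import (
    CoexpressionNetwork,
    call_de,
    distance_stratified_medians,
    negative_bias_test,
    spearman_full,
    spearman_network,
    stratify_by_expression,
)

from conftest import make_ann, make_expression


def _meta_two_drugs():
    """4 solvent controls then drugA (DMSO) and drugB (water) at 3/6 h."""
    rows = []
    for solvent in ("DMSO", "water"):
        for tp in (3, 6):
            rows.append((solvent, tp, True, solvent))
    for drug, solvent in (("drugA", "DMSO"), ("drugB", "water")):
        for tp in (3, 6):
            rows.append((drug, tp, False, solvent))
    return rows


def test_de_requires_fold_change_at_both_time_points():
    meta = _meta_two_drugs()
    # samples: 4 controls, drugA 3h, drugA 6h, drugB 3h, drugB 6h
    expr = make_expression(
        {
            "gA": [10, 10, 10, 10, 40, 40, 10, 10],  # up at both drugA points
            "gB": [10, 10, 10, 10, 2, 10, 10, 10],   # down at 3 h only
            "gC": [10, 10, 10, 10, 40, 40, 10, 10],
        },
        {"gA": "mRNA", "gB": "mRNA", "gC": "mRNA"},
        meta,
    )
    de = call_de(expr, fc_threshold=1.5)
    assert de.up["drugA"] == {"gA", "gC"}
    assert de.down["drugA"] == set()  # gB only moved at one time point
    assert de.up["drugB"] == set() and de.down["drugB"] == set()


def test_de_down_calls_and_subthreshold_changes_excluded():
    meta = _meta_two_drugs()
    # gA drops well below 1/1.5 of control; gB rises but stays below 1.5x
    expr = make_expression(
        {
            "gA": [10.0, 10.0, 10.0, 10.0, 2.0, 2.0, 10.0, 10.0],
            "gB": [10.0, 10.0, 10.0, 10.0, 14.5, 14.5, 10.0, 10.0],
        },
        {"gA": "mRNA", "gB": "mRNA"},
        meta,
    )
    de = call_de(expr)
    assert de.down["drugA"] == {"gA"}
    assert "gB" not in de.up["drugA"]


def test_de_missing_solvent_control_is_an_error():
    rows = [("DMSO", 3, True, "DMSO"), ("DMSO", 6, True, "DMSO"),
            ("drugX", 3, False, "water"), ("drugX", 6, False, "water")]
    expr = make_expression({"g": [1.0, 1.0, 1.0, 1.0]}, {"g": "mRNA"}, rows)
    with pytest.raises(ValueError, match="drugX"):
        call_de(expr)


def test_de_single_timepoint_drug_skipped_with_warning():
    rows = [("DMSO", 3, True, "DMSO"), ("DMSO", 6, True, "DMSO"),
            ("drugY", 3, False, "DMSO")]
    expr = make_expression({"g": [1.0, 1.0, 9.0]}, {"g": "mRNA"}, rows)
    with pytest.warns(UserWarning, match="drugY"):
        de = call_de(expr)
    assert "drugY" not in de.up


def _series_matrix(rows: dict, classes: dict):
    """Expression matrix with trivial uniform metadata (correlation tests).

    Series are shifted to be non-negative (abundances), which leaves all
    rank statistics unchanged.
    """
    n = len(next(iter(rows.values())))
    meta = [("DMSO", 3, True, "DMSO")] * n
    shifted = {
        k: list(np.asarray(v, dtype=float) - min(min(v), 0.0))
        for k, v in rows.items()
    }
    return make_expression(shifted, classes, meta)


def test_spearman_matches_hand_ranked_example():
    # ranks of (1,2,3,4,5) vs (2,1,4,3,5): d^2 = (1,1,1,1,0), so
    # rho = 1 - 6*4/(5*24) = 0.8
    expr = _series_matrix(
        {"vlinc1": [1, 2, 3, 4, 5], "g1": [2, 1, 4, 3, 5]},
        {"vlinc1": "vlincRNA", "g1": "mRNA"},
    )
    rho, p = spearman_full(expr)
    assert rho.loc["vlinc1", "g1"] == pytest.approx(0.8)
    # exact permutation two-sided p over the 5! pairings
    perms_rho = []
    import itertools

    for perm in itertools.permutations([2, 1, 4, 3, 5]):
        perms_rho.append(sps.spearmanr([1, 2, 3, 4, 5], perm).statistic)
    ref = np.mean(np.abs(perms_rho) >= 0.8 - 1e-12)
    assert p.loc["vlinc1", "g1"] == pytest.approx(ref)


def test_spearman_agrees_with_scipy_at_large_n():
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    expr = _series_matrix(
        {"vlinc1": list(x), "g1": list(y)},
        {"vlinc1": "vlincRNA", "g1": "mRNA"},
    )
    rho, p = spearman_full(expr)
    ref = sps.spearmanr(x, y)
    assert rho.loc["vlinc1", "g1"] == pytest.approx(ref.statistic)
    assert p.loc["vlinc1", "g1"] == pytest.approx(ref.pvalue, rel=1e-6)


def test_spearman_constant_series_is_nan():
    expr = _series_matrix(
        {"vlinc1": list(range(12)), "g1": [5.0] * 12, "g2": list(range(12))},
        {"vlinc1": "vlincRNA", "g1": "mRNA", "g2": "mRNA"},
    )
    rho, p = spearman_full(expr)
    assert np.isnan(rho.loc["vlinc1", "g1"]) and np.isnan(p.loc["vlinc1", "g1"])
    assert rho.loc["vlinc1", "g2"] == pytest.approx(1.0)


def test_network_thresholds_and_signs():
    rng = np.random.default_rng(0)
    n = 30
    v = rng.normal(size=n)
    expr = _series_matrix(
        {
            "vlinc1": list(v),
            "g_pos": list(v + 0.1 * rng.normal(size=n)),
            "g_neg": list(-v + 0.1 * rng.normal(size=n)),
            "g_null": list(rng.normal(size=n)),
        },
        {"vlinc1": "vlincRNA", "g_pos": "mRNA", "g_neg": "mRNA", "g_null": "mRNA"},
    )
    net = spearman_network(expr)
    assert net.partners("vlinc1", "positive") == {"g_pos"}
    assert net.partners("vlinc1", "negative") == {"g_neg"}
    assert ((net.edges.rho.abs() > 0.35) & (net.edges.p < 0.01)).all()


def test_network_rejects_inconsistent_edges():
    edges = pd.DataFrame(
        [{"vlinc_id": "v", "gene_id": "g", "rho": 0.5, "p": 0.001, "sign": "negative"}]
    )
    with pytest.raises(ValueError):
        CoexpressionNetwork(edges=edges)
    weak = pd.DataFrame(
        [{"vlinc_id": "v", "gene_id": "g", "rho": 0.1, "p": 0.001, "sign": "positive"}]
    )
    with pytest.raises(ValueError):
        CoexpressionNetwork(edges=weak)


def test_expression_halves_split_by_maximum():
    expr = _series_matrix(
        {
            "vlinc1": [1, 1, 1],
            "g1": [9, 0, 0],
            "g2": [0, 7, 0],
            "g3": [5, 0, 0],
            "g4": [0, 0, 2],
            "g5": [0, 0, 0],  # never expressed: dropped
        },
        {"vlinc1": "vlincRNA", **{f"g{i}": "mRNA" for i in range(1, 6)}},
    )
    halves = stratify_by_expression(expr)
    assert "g5" not in halves.index
    # odd count: the top half gets the extra gene
    assert set(halves[halves == "top"].index) == {"g1", "g2"}
    assert set(halves[halves == "bottom"].index) == {"g3", "g4"}


def test_class_selection_preserves_row_order():
    expr = _series_matrix(
        {"gB": [1, 2], "vlinc1": [1, 2], "gA": [1, 2]},
        {"gA": "mRNA", "gB": "mRNA", "vlinc1": "vlincRNA"},
    )
    assert list(expr.of_class("mRNA").index) == ["gB", "gA"]


def test_distance_bins_use_interval_gap():
    ann = make_ann(
        [
            ("chr1", 0, 1000, "g_near", "+"),
            ("chr1", 20_000, 21_000, "g_mid", "+"),
            ("chr2", 0, 1000, "g_trans", "+"),
            ("chr1", 2000, 12_000, "vlinc1", "+"),
        ]
    )
    edges = pd.DataFrame(
        [
            {"vlinc_id": "vlinc1", "gene_id": "g_near", "rho": 0.8, "p": 1e-4, "sign": "positive"},
            {"vlinc_id": "vlinc1", "gene_id": "g_mid", "rho": 0.6, "p": 1e-3, "sign": "positive"},
            {"vlinc_id": "vlinc1", "gene_id": "g_trans", "rho": -0.9, "p": 1e-5, "sign": "negative"},
        ]
    )
    net = CoexpressionNetwork(edges=edges)
    med = distance_stratified_medians(net, ann)
    assert med["0-5000"] == pytest.approx(0.8)      # gap 1000
    assert med["5000-10000"] == pytest.approx(0.6)  # gap 8000
    assert np.isnan(med["100000-inf"])              # trans pair excluded


def test_negative_partner_excess_signed_rank():
    rows = []
    for i in range(12):
        for g in range(6):
            rows.append({"vlinc_id": f"v{i}", "gene_id": f"n{i}_{g}",
                         "rho": -0.6, "p": 1e-4, "sign": "negative"})
        for g in range(2):
            rows.append({"vlinc_id": f"v{i}", "gene_id": f"p{i}_{g}",
                         "rho": 0.6, "p": 1e-4, "sign": "positive"})
    net = CoexpressionNetwork(edges=pd.DataFrame(rows))
    assert negative_bias_test(net) < 0.01


def test_negative_bias_tied_counts_report_one():
    rows = []
    for i in range(3):
        rows.append({"vlinc_id": f"v{i}", "gene_id": f"n{i}", "rho": -0.6,
                     "p": 1e-4, "sign": "negative"})
        rows.append({"vlinc_id": f"v{i}", "gene_id": f"p{i}", "rho": 0.6,
                     "p": 1e-4, "sign": "positive"})
    net = CoexpressionNetwork(edges=pd.DataFrame(rows))
    with pytest.warns(UserWarning):
        assert negative_bias_test(net) == 1.0


def test_negative_bias_needs_two_vlincs():
    edges = pd.DataFrame(
        [{"vlinc_id": "v", "gene_id": "g", "rho": -0.5, "p": 1e-3, "sign": "negative"}]
    )
    with pytest.raises(ValueError):
        negative_bias_test(CoexpressionNetwork(edges=edges))
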