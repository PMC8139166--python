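"""RAT track processing and proximity region calling."""

import numpy as np
import pandas as pd
import pytest

from vlincnet import rat

from conftest import make_ann, region_oracle


def _track(scores, **kw):
    defaults = dict(vlinc="vlinc1", treatment="DMSO", replica=1,
                    source=rat.OLIGO_1, total_reads=100, stage="raw")
    defaults.update(kw)
    return rat.RatTrack(scores={c: np.asarray(a, dtype=float)
                                for c, a in scores.items()}, **defaults)


def test_normalize_divides_by_total_reads():
    t = _track({"chr1": [2.0, 4.0]}, total_reads=4)
    n = rat.normalize(t)
    assert np.allclose(n.scores["chr1"], [0.5, 1.0])
    assert n.stage == "normalized"
    with pytest.raises(ValueError):
        rat.normalize(_track({"chr1": [1.0]}, total_reads=0))


def test_control_subtraction_keeps_negative_values():
    t = _track({"chr1": [1.0, 0.5, 0.0]})
    c = _track({"chr1": [0.2, 1.0, 0.0]}, source=rat.NO_OLIGO)
    s = rat.subtract_control(t, c)
    assert np.allclose(s.scores["chr1"], [0.8, -0.5, 0.0])


def test_control_subtraction_checks_provenance():
    t = _track({"chr1": [1.0]})
    wrong_source = _track({"chr1": [0.1]}, source=rat.OLIGO_2)
    with pytest.raises(ValueError):
        rat.subtract_control(t, wrong_source)
    other_replica = _track({"chr1": [0.1]}, source=rat.NO_OLIGO, replica=2)
    with pytest.raises(ValueError):
        rat.subtract_control(t, other_replica)


def test_replica_average_is_per_base_mean():
    r1 = _track({"chr1": [1.0, 3.0]}, replica=1)
    r2 = _track({"chr1": [3.0, 1.0]}, replica=2)
    avg = rat.average_replicas(r1, r2)
    assert np.allclose(avg.scores["chr1"], [2.0, 2.0])
    assert avg.stage == "averaged"
    other_vlinc = _track({"chr1": [1.0, 1.0]}, vlinc="vlinc2")
    with pytest.raises(ValueError):
        rat.average_replicas(r1, other_vlinc)


def test_average_tracks_collapses_oligo_sets_and_replicas():
    tracks = [_track({"chr1": [v]}) for v in (0.0, 1.0, 2.0, 5.0)]
    avg = rat.average_tracks(tracks)
    assert avg.scores["chr1"][0] == pytest.approx(2.0)


def test_top_percentile_keeps_highest_scoring_bases():
    # ten bases scoring 1..10: top 30% = the three bases scoring 8, 9, 10
    s = _track({"chr1": list(range(1, 11))})
    o = _track({"chr1": [1.0] * 10}, source=rat.OLIGO_2)
    regions = rat.call_regions(s, o, 30)
    assert regions.intervals[["chrom", "start", "end"]].to_records(index=False).tolist() == [
        ("chr1", 7, 10)
    ]
    assert regions.intervals.mean_score.iloc[0] == pytest.approx(9.0)


def test_ties_at_the_threshold_are_kept():
    # k = ceil(0.3 * 10) = 3, third-largest score is 5 and three bases tie
    s = _track({"chr1": [1, 2, 5, 3, 5, 4, 5, 1, 2, 3]})
    o = _track({"chr1": [1.0] * 10}, source=rat.OLIGO_2)
    regions = rat.call_regions(s, o, 30)
    kept = set()
    for r in regions.intervals.itertuples():
        kept.update(range(r.start, r.end))
    assert kept == {2, 4, 6}


def test_bases_require_positive_score_in_both_oligo_sets():
    s = _track({"chr1": [5.0, 5.0, 5.0, -1.0]})
    o = _track({"chr1": [1.0, 0.0, 1.0, 1.0]}, source=rat.OLIGO_2)
    regions = rat.call_regions(s, o, 30)
    kept = set()
    for r in regions.intervals.itertuples():
        kept.update(range(r.start, r.end))
    assert 1 not in kept and 3 not in kept


def test_no_surviving_bases_yields_empty_set(caplog):
    s = _track({"chr1": [-1.0, 0.0]})
    o = _track({"chr1": [1.0, 1.0]}, source=rat.OLIGO_2)
    regions = rat.call_regions(s, o, 30)
    assert regions.intervals.empty
    assert regions.n_bases == 0


def test_unsupported_percentile_rejected():
    s = _track({"chr1": [1.0]})
    with pytest.raises(ValueError):
        rat.call_regions(s, s, 7)


def test_region_calling_matches_per_base_oracle_small_cases():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n1, n2 = rng.integers(5, 300, size=2)
        scores = {
            "chr1": (rng.poisson(3, n1) - rng.poisson(3, n1)).astype(float),
            "chr2": rng.normal(size=n2),
        }
        other = {
            "chr1": (rng.poisson(2, n1) - 1).astype(float),
            "chr2": rng.normal(size=n2),
        }
        s = _track(scores)
        o = _track(other, source=rat.OLIGO_2)
        for pct in rat.PERCENTILES:
            got = rat.call_regions(s, o, pct)
            expected = region_oracle(scores, other, pct)
            rows = [
                (r.chrom, int(r.start), int(r.end))
                for r in got.intervals.itertuples()
            ]
            assert rows == [(c, lo, hi) for c, lo, hi, _ in expected]
            means = got.intervals.mean_score.to_numpy()
            assert np.allclose(means, [m for *_, m in expected])


def test_base_wise_region_intersection():
    a = rat.RatRegionSet(intervals=pd.DataFrame(
        [("chr1", 0, 10), ("chr1", 20, 30)], columns=["chrom", "start", "end"]
    ))
    b = rat.RatRegionSet(intervals=pd.DataFrame(
        [("chr1", 5, 25), ("chr2", 0, 5)], columns=["chrom", "start", "end"]
    ))
    inter = rat.intersect_regions(a, b)
    assert inter[["chrom", "start", "end"]].to_records(index=False).tolist() == [
        ("chr1", 5, 10), ("chr1", 20, 25)
    ]


def test_gene_and_region_level_replica_support():
    ann = make_ann([
        ("chr1", 0, 100, "g1", "+"),
        ("chr1", 200, 300, "g2", "+"),
        ("chr1", 400, 500, "g3", "+"),
    ])
    r1 = rat.RatRegionSet(intervals=pd.DataFrame(
        [("chr1", 10, 20), ("chr1", 210, 220), ("chr1", 410, 420)],
        columns=["chrom", "start", "end"]))
    r2 = rat.RatRegionSet(intervals=pd.DataFrame(
        [("chr1", 15, 25), ("chr1", 250, 260)],
        columns=["chrom", "start", "end"]))
    # gene level: both replicas hit g1 and g2 (anywhere in the gene)
    assert rat.genes_with_regions(r1, r2, ann, level="gene") == {"g1", "g2"}
    # region level: only g1 has base-wise agreement (15..20)
    assert rat.genes_with_regions(r1, r2, ann, level="region") == {"g1"}
    with pytest.raises(ValueError):
        rat.genes_with_regions(r1, r2, ann, level="base")


def test_overlapping_region_set_rejected():
    with pytest.raises(ValueError):
        rat.RatRegionSet(intervals=pd.DataFrame(
            [("chr1", 0, 10), ("chr1", 5, 15)], columns=["chrom", "start", "end"]
        ))


def test_replica_concordance_perfect_agreement():
    universe = {f"g{i}" for i in range(20)}
    genes = {"g0", "g1", "g2"}
    orr, p = rat.replica_concordance(genes, genes, universe)
    assert orr > 1
    assert p < 0.01
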