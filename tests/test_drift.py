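import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txdrift import (
    DataError,
    ExpressionMatrix,
    GeneSet,
    SampleAnnotation,
    SyntheticConfig,
    bin_samples,
    build_young_reference,
    compute_drift,
    cpm_normalize,
    drift_plot_table,
    drift_variance,
    generate_transcriptome,
    leading_logfc_mds,
    robust_levene,
    subsample_genes,
)


def _dv_two_pass(values):
    """Independent two-pass oracle for the n-1-denominator drift-variance."""
    mean = sum(values) / len(values)
    return sum((v - mean) ** 2 for v in values) / (len(values) - 1)


def _drift_matrix_from(td_values, sample_ids=("s1",)):
    """Wrap raw td values into a DriftMatrix via a self-consistent cpm pair."""
    import pandas as pd

    from txdrift.drift import DriftMatrix, YoungReference

    td = np.asarray(td_values, float)
    genes = [f"g{i}" for i in range(td.shape[0])]
    ref = YoungReference(
        ref_expression=pd.Series(1.0, index=genes),
        method="holdout",
        ref_age=1.0,
        source_sample_ids=[],
        detected_all=pd.Series(True, index=genes),
    )
    return DriftMatrix(genes, list(sample_ids), td, 2.0, ref, 0.0)


class TestYoungReference:
    def test_pooled_mean_is_per_gene_mean(self, toy_cpm):
        m, anns = toy_cpm
        ref = build_young_reference(m, anns, ref_age=1)
        expected = m.to_frame()[["y1", "y2"]].mean(axis=1)
        assert np.allclose(ref.ref_expression, expected)
        assert ref.excluded_sample_ids == []

    def test_single_replicate_methods_coincide(self):
        m = cpm_normalize(
            ExpressionMatrix(["g1", "g2"], ["y", "o"], np.array([[10.0, 40.0], [30.0, 10.0]]))
        )
        anns = [SampleAnnotation("y", age=1), SampleAnnotation("o", age=5)]
        pooled = build_young_reference(m, anns, 1, "pooled_mean")
        held = build_young_reference(m, anns, 1, "holdout", holdout_ids=["y"])
        assert np.allclose(pooled.ref_expression, held.ref_expression)

    def test_holdout_sample_never_reaches_downstream(self, toy_cpm):
        m, anns = toy_cpm
        ref = build_young_reference(m, anns, 1, "holdout", holdout_ids=["y1"])
        d = compute_drift(m, ref)
        assert "y1" not in d.sample_ids
        results = drift_variance(d, {s: "grp" for s in d.sample_ids})
        assert all("y1" not in r.sample_ids for r in results)
        assert not results[0].self_referential

    def test_no_sample_at_ref_age_errors(self, toy_cpm):
        m, anns = toy_cpm
        with pytest.raises(DataError):
            build_young_reference(m, anns, ref_age=99)

    def test_holdout_wrong_age_errors(self, toy_cpm):
        m, anns = toy_cpm
        with pytest.raises(DataError, match="o1"):
            build_young_reference(m, anns, 1, "holdout", holdout_ids=["o1"])


class TestComputeDrift:
    def test_self_reference_gives_zero(self):
        m = cpm_normalize(
            ExpressionMatrix(["g1", "g2"], ["y"], np.array([[10.0], [30.0]]))
        )
        ref = build_young_reference(m, [SampleAnnotation("y", age=1)], 1)
        d = compute_drift(m, ref)
        assert np.allclose(d.td, 0.0)
        assert d.self_referential_sample_ids == ["y"]

    def test_arithmetic_forced(self):
        # cpm 200 vs ref 50 at pseudocount 0 -> log2(4) = 2
        import pandas as pd

        from txdrift.drift import YoungReference

        m = ExpressionMatrix(["g1", "g2"], ["s"], np.array([[200.0], [999800.0]]), unit="cpm")
        ref = YoungReference(
            ref_expression=pd.Series({"g1": 50.0, "g2": 999800.0}),
            method="holdout", ref_age=1.0, source_sample_ids=[],
            detected_all=pd.Series({"g1": True, "g2": True}),
        )
        d = compute_drift(m, ref, pseudocount=0.0)
        assert d.to_frame().loc["g1", "s"] == pytest.approx(2.0)

    def test_matches_hand_computation_elementwise(self, toy_cpm):
        m, anns = toy_cpm
        ref = build_young_reference(m, anns, 1)
        d = compute_drift(m, ref, log_base=2, pseudocount=0.5)
        frame = m.to_frame()
        refvals = frame[["y1", "y2"]].mean(axis=1)
        for g in d.gene_ids:
            for s in d.sample_ids:
                expected = math.log2((frame.loc[g, s] + 0.5) / (refvals[g] + 0.5))
                assert d.to_frame().loc[g, s] == pytest.approx(expected, abs=1e-12)

    def test_mean_td_of_reference_replicates_near_zero(self, rng):
        # method #1: per-gene mean of td across reference replicates ~ 0
        values = rng.poisson(500.0, size=(40, 3)).astype(float) + 1
        m = cpm_normalize(ExpressionMatrix([f"g{i}" for i in range(40)], ["a", "b", "c"], values))
        anns = [SampleAnnotation(s, age=1, replicate=i + 1) for i, s in enumerate("abc")]
        ref = build_young_reference(m, anns, 1)
        d = compute_drift(m, ref, pseudocount=0.0)
        assert np.abs(d.td.mean(axis=1)).max() < 0.01

    def test_undetected_genes_dropped_not_imputed(self):
        values = np.array([[0.0, 5.0, 9.0], [100.0, 95.0, 91.0]])
        m = cpm_normalize(ExpressionMatrix(["gz", "gk"], ["y1", "y2", "o"], values))
        anns = [
            SampleAnnotation("y1", age=1), SampleAnnotation("y2", age=1),
            SampleAnnotation("o", age=5),
        ]
        ref = build_young_reference(m, anns, 1)
        d = compute_drift(m, ref)
        assert d.gene_ids == ["gk"]

    def test_log_base_rescales_td_and_variance(self, toy_cpm):
        m, anns = toy_cpm
        ref = build_young_reference(m, anns, 1)
        d2 = compute_drift(m, ref, log_base=2)
        de = compute_drift(m, ref, log_base=math.e)
        factor = math.log(2)  # td_e = td_2 * ln2
        assert np.allclose(de.td, d2.td * factor)
        groups = {"o1": "old", "o2": "old"}
        v2 = drift_variance(d2, groups)[0].variance
        ve = drift_variance(de, groups)[0].variance
        assert ve == pytest.approx(v2 * factor**2, rel=1e-12)


class TestDriftVariance:
    def test_constant_td_zero_variance(self):
        d = _drift_matrix_from(np.full((5, 1), 3.3))
        res = drift_variance(d, {"s1": "g"})[0]
        assert res.variance == 0.0

    def test_two_values_forced(self):
        res = drift_variance(_drift_matrix_from([[0.0], [2.0]]), {"s1": "g"})[0]
        assert res.variance == pytest.approx(2.0)
        assert res.tukey.median == pytest.approx(1.0)

    def test_hand_example_four_values(self):
        res = drift_variance(_drift_matrix_from([[1.0], [2.0], [3.0], [4.0]]), {"s1": "g"})[0]
        assert res.variance == pytest.approx(5.0 / 3.0)

    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=60),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_two_pass_oracle(self, values):
        d = _drift_matrix_from(np.asarray(values)[:, None])
        res = drift_variance(d, {"s1": "g"})[0]
        assert res.variance == pytest.approx(_dv_two_pass(values), rel=1e-12, abs=1e-12)

    def test_outliers_stay_in_variance_but_not_whiskers(self):
        values = np.array([[0.1], [0.2], [0.0], [-0.1], [-0.2], [8.0]])
        res = drift_variance(_drift_matrix_from(values), {"s1": "g"})[0]
        assert res.n_outliers_omitted_for_plot == 1
        assert res.tukey.whisker_hi < 8.0
        assert res.variance == pytest.approx(_dv_two_pass(values.ravel()), abs=1e-12)

    def test_gene_set_restriction_and_zero_overlap_error(self):
        d = _drift_matrix_from(np.arange(6.0)[:, None])
        subset = GeneSet("sub", ["g0", "g1", "g2"])
        res = drift_variance(d, {"s1": "g"}, gene_set=subset)[0]
        assert res.n_values == 3
        with pytest.raises(DataError, match="nowhere"):
            drift_variance(d, {"s1": "g"}, gene_set=GeneSet("nowhere", ["zz"]))

    def test_self_referential_group_flagged(self, toy_cpm):
        m, anns = toy_cpm
        ref = build_young_reference(m, anns, 1)
        d = compute_drift(m, ref)
        res = drift_variance(d, {"y1": "young", "y2": "young", "o1": "old", "o2": "old"})
        flags = {r.group_label: r.self_referential for r in res}
        assert flags == {"young": True, "old": False}


class TestBinning:
    def test_pooled_ages_map_to_same_bin(self):
        anns = [
            SampleAnnotation("m13", age=13, age_unit="weeks"),
            SampleAnnotation("m26", age=26, age_unit="weeks"),
        ]
        bins = bin_samples(anns, [0, 30, 60], labels=["<=30", "<=60", ">60"])
        assert bins == {"m13": "<=30", "m26": "<=30"}

    def test_edge_age_goes_right_half_open(self):
        anns = [SampleAnnotation("x", age=30)]
        bins = bin_samples(anns, [0, 30, 60])
        assert bins["x"] == "[30,60)"

    def test_hours_binned_to_day_groups(self):
        hours = [8, 24, 28, 40, 52, 72, 96, 144, 196]
        anns = [SampleAnnotation(f"h{h}", age=h) for h in hours]
        bins = bin_samples(
            anns, [0, 20, 36, 60, 84, 120],
            labels=["day0", "day1", "day2", "day3", "day4", "day6"],
        )
        assert bins["h8"] == "day0"
        assert bins["h24"] == bins["h28"] == "day1"
        assert bins["h40"] == bins["h52"] == "day2"
        assert bins["h144"] == bins["h196"] == "day6"

    def test_age_below_first_edge_errors(self):
        with pytest.raises(DataError, match="below"):
            bin_samples([SampleAnnotation("x", age=1)], [5, 10])


class TestSubsampleGenes:
    def test_disjoint_exact_and_seeded(self):
        genes = [f"g{i}" for i in range(10050)]
        sets = subsample_genes(genes, n_sets=10, set_size=1000, seed=7)
        assert len(sets) == 10
        union = set().union(*(s.gene_ids for s in sets))
        assert len(union) == 10000
        again = subsample_genes(genes, 10, 1000, seed=7)
        assert [s.gene_ids for s in again] == [s.gene_ids for s in sets]

    def test_insufficient_genes_errors(self):
        with pytest.raises(DataError):
            subsample_genes(["a", "b"], n_sets=2, set_size=2, seed=0)

    def test_subsampled_sets_show_indistinguishable_drift_trajectories(self):
        # disjoint random halves of one transcriptome give statistically
        # equal drift-variance; the dispersion test must not separate them
        cfg = SyntheticConfig(n_genes=2000, ages=(1.0, 5.0), n_replicates=2, seed=11)
        m, anns, _ = generate_transcriptome(cfg)
        cpm = cpm_normalize(m)
        ref = build_young_reference(cpm, anns, 1.0)
        d = compute_drift(cpm, ref)
        halves = subsample_genes(d.gene_ids, 2, len(d.gene_ids) // 2, seed=3)
        old = [s for s in d.sample_ids if "d5" in s]
        frame = d.to_frame()
        va = frame.loc[halves[0].gene_ids, old].to_numpy().ravel()
        vb = frame.loc[halves[1].gene_ids, old].to_numpy().ravel()
        ratio = np.var(va, ddof=1) / np.var(vb, ddof=1)
        assert 0.8 < ratio < 1.25
        assert robust_levene([va, vb]).p_value > 0.01


class TestLeadingLogfcMds:
    def test_duplicate_samples_distance_zero(self):
        values = np.tile(np.array([[100.0], [300.0], [600.0]]), (1, 3))
        m = ExpressionMatrix(["g1", "g2", "g3"], ["a", "b", "c"], values)
        _, dist = leading_logfc_mds(cpm_normalize(m), top_n=2)
        assert np.allclose(dist.to_numpy(), 0.0)

    def test_matches_hand_rms_of_top_two(self):
        values = np.array(
            [
                [100.0, 400.0, 100.0],
                [200.0, 200.0, 200.0],
                [50.0, 50.0, 400.0],
                [400.0, 400.0, 400.0],
                [80.0, 80.0, 80.0],
                [170.0, 170.0, 170.0],
            ]
        )
        m = ExpressionMatrix([f"g{i}" for i in range(6)], ["a", "b", "c"], values)
        cpm = cpm_normalize(m)
        _, dist = leading_logfc_mds(cpm, top_n=2, pseudocount=0.5)
        logx = np.log2(cpm.values + 0.5)
        fc = np.sort(np.abs(logx[:, 0] - logx[:, 1]))[-2:]
        assert dist.loc["a", "b"] == pytest.approx(math.sqrt(np.mean(fc**2)))

    def test_distance_matrix_symmetric_zero_diagonal(self, rng):
        values = rng.poisson(200.0, size=(30, 5)).astype(float) + 1
        m = cpm_normalize(
            ExpressionMatrix([f"g{i}" for i in range(30)], list("abcde"), values)
        )
        coords, dist = leading_logfc_mds(m, top_n=10)
        arr = dist.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert coords.shape == (5, 2)

    def test_top_n_larger_than_universe_warns_and_uses_all(self, rng):
        values = rng.poisson(200.0, size=(10, 3)).astype(float) + 1
        m = cpm_normalize(ExpressionMatrix([f"g{i}" for i in range(10)], list("abc"), values))
        with pytest.warns(UserWarning, match="universe"):
            leading_logfc_mds(m, top_n=500)


class TestDriftPlotTable:
    def test_table_roundtrips_through_tsv(self, tmp_path, toy_cpm):
        import pandas as pd

        m, anns = toy_cpm
        ref = build_young_reference(m, anns, 1)
        d = compute_drift(m, ref)
        res = drift_variance(d, {"o1": "old", "o2": "old"})
        table = drift_plot_table(res)
        p = tmp_path / "dv.tsv"
        table.to_csv(p, sep="\t", index=False)
        back = pd.read_csv(p, sep="\t")
        assert back["variance"].iloc[0] == pytest.approx(table["variance"].iloc[0])
        assert list(back.columns) == list(table.columns)
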