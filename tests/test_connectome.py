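import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gcbold.connectome import (
    DirectedEdgeList,
    FormatError,
    RoiTimeseriesSession,
    aal116_labels,
    flow_matrix,
    group_median,
    hemisphere_flow_summary,
    ks_stationarity_fraction,
    read_roi_timeseries,
    run_connectome,
    subject_gc,
    threshold_top_fraction,
)
from gcbold.mvgc import GcMatrix, ParameterError, gc_matrix, var_parameter_count


def write_session(path, data, tr=0.72, labels=None):
    n = data.shape[1]
    labels = labels or [f"ROI{i:03d}" for i in range(n)]
    lines = ["\t".join(labels)]
    lines += ["\t".join(f"{x:.6g}" for x in row) for row in data]
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({"tr": tr}))
    return labels


class TestReader:
    def test_hcp_shaped_fixture(self, tmp_path, rng):
        labels = list(aal116_labels()["name"])
        data = rng.standard_normal((1200, 116))
        path = tmp_path / "sess1.tsv"
        write_session(path, data, labels=labels)
        sess = read_roi_timeseries(path)
        assert sess.n_rois == 116
        assert sess.n_volumes == 1200
        assert sess.tr == 0.72
        assert sess.roi_labels == labels

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(FormatError, match="empty"):
            read_roi_timeseries(p)

    def test_ragged_row_reported_with_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n3\n")
        with pytest.raises(FormatError, match=":3"):
            read_roi_timeseries(p, tr=0.72)

    def test_non_numeric_cell_reported(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\tx\n")
        with pytest.raises(FormatError, match=":2"):
            read_roi_timeseries(p, tr=0.72)

    def test_missing_tr_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("a\tb\n1\t2\n3\t4\n")
        with pytest.raises(FormatError, match="tr"):
            read_roi_timeseries(p)

    def test_constant_column_flagged(self, tmp_path, rng):
        data = rng.standard_normal((50, 3))
        data[:, 1] = 7.0
        p = tmp_path / "s.tsv"
        labels = write_session(p, data)
        sess = read_roi_timeseries(p)
        assert sess.constant_rois == [labels[1]]


class TestStationarity:
    def make_session(self, data, tr=0.72):
        return RoiTimeseriesSession(
            data=data, tr=tr,
            roi_labels=[f"r{i}" for i in range(data.shape[1])])

    def test_window_length_arithmetic(self, rng):
        # 3-minute windows at TR 0.72 are floor(180 / 0.72) = 250 volumes
        sess = self.make_session(rng.standard_normal((1200, 2)))
        _, flags = ks_stationarity_fraction(sess)
        assert flags.shape == (2, 1200 // 250)

    def test_false_flag_rate_near_alpha_on_iid_null(self):
        rng = np.random.default_rng(42)
        total, flagged = 0, 0
        for _ in range(120):
            sess = self.make_session(rng.standard_normal((1200, 3)))
            _, flags = ks_stationarity_fraction(sess, alpha=0.05)
            flagged += flags.sum()
            total += flags.size
        rate = flagged / total
        # binomial MC tolerance at ~1400 cells
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_pooled_variant_is_conservative(self):
        rng = np.random.default_rng(43)
        total, flagged = 0, 0
        for _ in range(60):
            sess = self.make_session(rng.standard_normal((1200, 3)))
            _, flags = ks_stationarity_fraction(sess, compare="full")
            flagged += flags.sum()
            total += flags.size
        assert flagged / total < 0.05

    def test_strong_trend_flags_nearly_everything(self, rng):
        t = np.arange(1200)[:, None]
        data = 0.02 * t + rng.standard_normal((1200, 2))
        _, flags = ks_stationarity_fraction(self.make_session(data))
        assert flags.mean() > 0.9

    def test_window_longer_than_series_rejected(self, rng):
        sess = self.make_session(rng.standard_normal((100, 2)))
        with pytest.raises(ParameterError):
            ks_stationarity_fraction(sess, window_seconds=600.0)


class TestSubjectGc:
    def test_single_session_equals_gc_matrix(self, rng):
        data = rng.standard_normal((400, 3))
        sess = RoiTimeseriesSession(data=data, tr=0.72,
                                    roi_labels=["a", "b", "c"])
        g1 = subject_gc([sess], order=2)
        g2 = gc_matrix(data, order=2, labels=["a", "b", "c"])
        np.testing.assert_allclose(g1.values, g2.values, atol=1e-12)

    def test_diagonal_zero(self, rng):
        sess = RoiTimeseriesSession(data=rng.standard_normal((300, 4)),
                                    tr=0.72, roi_labels=list("abcd"))
        g = subject_gc([sess], order=1)
        assert np.all(np.diag(g.values) == 0)

    def test_pooled_sessions_use_segment_bounds(self, rng):
        # pooling two sessions must differ from naive concatenation
        labels = list("abc")
        s1 = RoiTimeseriesSession(data=rng.standard_normal((200, 3)) + 5.0,
                                  tr=0.72, roi_labels=labels)
        s2 = RoiTimeseriesSession(data=rng.standard_normal((200, 3)) - 5.0,
                                  tr=0.72, roi_labels=labels)
        g_pool = subject_gc([s1, s2], order=1)
        g_naive = gc_matrix(np.vstack([s1.data, s2.data]), order=1,
                            labels=labels)
        assert not np.allclose(g_pool.values, g_naive.values)

    def test_average_mode(self, rng):
        labels = list("ab")
        sessions = [
            RoiTimeseriesSession(data=rng.standard_normal((300, 2)), tr=0.72,
                                 roi_labels=labels)
            for _ in range(2)
        ]
        g_avg = subject_gc(sessions, order=1, mode="average")
        per = [subject_gc([s], order=1) for s in sessions]
        np.testing.assert_allclose(
            g_avg.values, np.mean([p.values for p in per], axis=0), atol=1e-12)

    def test_label_mismatch_rejected(self, rng):
        s1 = RoiTimeseriesSession(data=rng.standard_normal((100, 2)), tr=0.72,
                                  roi_labels=["a", "b"])
        s2 = RoiTimeseriesSession(data=rng.standard_normal((100, 2)), tr=0.72,
                                  roi_labels=["a", "c"])
        with pytest.raises(ValueError):
            subject_gc([s1, s2])

    def test_hcp_datapoint_accounting(self):
        # 4 sessions x 1200 volumes x 116 ROIs = 556800 raw values,
        # ~12 datapoints per parameter at order 3
        n_obs = 116 * 1200 * 4
        assert n_obs == 556800
        assert round(n_obs / var_parameter_count(116, 3)) == 12


class TestGroupMedian:
    def g(self, vals):
        return GcMatrix(values=np.asarray(vals, dtype=float))

    def test_single_matrix_unchanged(self, rng):
        m = self.g(np.abs(rng.random((3, 3))))
        np.fill_diagonal(m.values, 0)
        out = group_median([m])
        np.testing.assert_array_equal(out.values, m.values)

    def test_elementwise_median(self):
        ms = [self.g([[0, v], [v, 0]]) for v in (1.0, 2.0, 9.0)]
        assert group_median(ms).values[0, 1] == 2.0

    def test_subject_order_invariance(self, rng):
        ms = [self.g(np.abs(rng.random((4, 4)))) for _ in range(5)]
        a = group_median(ms)
        b = group_median(ms[::-1])
        np.testing.assert_array_equal(a.values, b.values)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            group_median([self.g(np.zeros((2, 2))), self.g(np.zeros((3, 3)))])


class TestFlow:
    def test_symmetric_gc_gives_zero_flow(self, rng):
        v = np.abs(rng.random((4, 4)))
        v = v + v.T
        np.fill_diagonal(v, 0)
        f = flow_matrix(GcMatrix(values=v))
        assert np.abs(f.values).max() == 0.0

    def test_printed_formula_example(self):
        v = np.zeros((2, 2))
        v[0, 1] = 3.0  # source 1 -> target 0
        v[1, 0] = 1.0
        f = flow_matrix(GcMatrix(values=v))
        assert f.values[0, 1] == 0.5
        assert f.values[1, 0] == -0.5

    def test_unidirectional_pair_saturates_at_one(self):
        v = np.zeros((2, 2))
        v[1, 0] = 2.5
        f = flow_matrix(GcMatrix(values=v))
        assert f.values[1, 0] == 1.0
        assert f.values[0, 1] == -1.0

    def test_zero_pair_maps_to_zero(self):
        f = flow_matrix(GcMatrix(values=np.zeros((3, 3))))
        assert np.all(f.values == 0)

    def test_negative_gc_rejected(self):
        g = GcMatrix(values=np.zeros((2, 2)))
        g.values[0, 1] = -1.0
        with pytest.raises(ValueError):
            flow_matrix(g)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_antisymmetry_and_bounds_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        v = np.abs(rng.standard_normal((n, n)))
        v[rng.random((n, n)) < 0.3] = 0.0  # exercise zero denominators
        np.fill_diagonal(v, 0)
        f = flow_matrix(GcMatrix(values=v))
        assert np.abs(f.values + f.values.T).max() < 1e-12
        assert np.abs(f.values).max() <= 1.0
        assert np.all(np.diag(f.values) == 0)


class TestThreshold:
    def test_atlas_scale_edge_count(self, rng):
        n = 116
        v = np.abs(rng.random((n, n)))
        np.fill_diagonal(v, 0)
        edges = threshold_top_fraction(GcMatrix(values=v), 0.01)
        assert len(edges) == 133  # floor(0.01 * 116 * 115)

    def test_full_fraction_keeps_all_pairs(self, rng):
        v = np.abs(rng.random((6, 6)))
        np.fill_diagonal(v, 0)
        edges = threshold_top_fraction(GcMatrix(values=v), 1.0)
        assert len(edges) == 30

    def test_dominant_entry_survives_tiny_fraction(self):
        v = np.zeros((5, 5))
        v[2, 4] = 3.0  # source 4 -> target 2
        edges = threshold_top_fraction(GcMatrix(values=v), 1e-6)
        assert len(edges) == 1
        row = edges.edges.iloc[0]
        assert row.source == "4" and row.target == "2"
        assert row.flow == 1.0

    def test_sorted_descending_and_matches_brute_force(self, rng):
        n = 12
        v = np.abs(rng.random((n, n)))
        np.fill_diagonal(v, 0)
        g = GcMatrix(values=v)
        edges = threshold_top_fraction(g, 0.1)
        s = edges.edges.strength.to_numpy()
        assert np.all(np.diff(s) <= 1e-15)
        k = int(np.floor(0.1 * n * (n - 1)))
        mask = ~np.eye(n, dtype=bool)
        assert s.min() >= np.sort(v.T[mask])[-k]


class TestPipeline:
    def make_subjects(self, rng, n_subj=2, n_rois=5, n_vol=300):
        labels = [f"R{i}" for i in range(n_rois)]
        out = {}
        for k in range(n_subj):
            data = rng.standard_normal((n_vol, n_rois))
            out[f"s{k}"] = [
                RoiTimeseriesSession(data=data, tr=0.72, roi_labels=labels)
            ]
        return out

    def test_report_contents_and_outputs(self, tmp_path, rng):
        subjects = self.make_subjects(rng)
        report = run_connectome(subjects, order=1, out_dir=tmp_path)
        assert report["n_subjects"] == 2
        assert report["n_edges_retained"] == 1  # floor(.01*20) -> k=1 floor->0 ->1
        assert (tmp_path / "gc_median.csv").exists()
        assert (tmp_path / "flow.csv").exists()
        assert (tmp_path / "edges_top.tsv").exists()
        assert json.loads((tmp_path / "report.json").read_text())["order"] == 1

    def test_pipeline_deterministic(self, tmp_path, rng):
        subjects = self.make_subjects(rng)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        run_connectome(subjects, order=1, out_dir=d1)
        run_connectome(subjects, order=1, out_dir=d2)
        assert (d1 / "edges_top.tsv").read_bytes() == (d2 / "edges_top.tsv").read_bytes()

    def test_cross_module_ppv_consistency(self, rng):
        # thresholding the median of simulated-subject GC matrices scores the
        # same PPV as the benchmark metric on the same median matrix
        from gcbold.benchmark import ppv_top_fraction
        from gcbold.graphs import sample_uniform_digraph
        from gcbold.neural import NetworkSimParams
        from gcbold.hemo import generate_dataset, HemoParams

        net = sample_uniform_digraph(10, 9, rng)
        mats = []
        for seed in range(2):
            bold = generate_dataset(
                net, sim=NetworkSimParams(duration=120.0),
                hemo=HemoParams(burn_in=5.0), tr=0.72, n_volumes=150,
                rng=np.random.default_rng(seed), generator="var")
            mats.append(gc_matrix(bold.as_observations(), order=3))
        g = group_median(mats)
        frac = 9 / 90
        edges = threshold_top_fraction(g, frac)
        truth = {(int(r.source), int(r.target)) for _, r in edges.edges.iterrows()}
        ppv_edges = len(truth & net.edges) / len(edges)
        assert ppv_edges == pytest.approx(ppv_top_fraction(g, net, frac))


class TestAtlasMetadata:
    def test_table_shape_and_hemispheres(self):
        t = aal116_labels()
        assert len(t) == 116
        assert set(t.hemisphere) == {"L", "R", "M"}
        assert (t.hemisphere == "M").sum() == 8  # vermis

    def test_hemisphere_flow_summary(self):
        df = pd.DataFrame([
            {"source": "Angular_L", "target": "Frontal_Mid_L",
             "strength": 1.0, "flow": 0.8},
            {"source": "Angular_L", "target": "Frontal_Mid_R",
             "strength": 0.5, "flow": -0.2},
        ])
        summary = hemisphere_flow_summary(DirectedEdgeList(edges=df))
        intra = summary[summary.kind == "intra"].iloc[0]
        inter = summary[summary.kind == "inter"].iloc[0]
        assert intra.n_edges == 1 and inter.n_edges == 1
        assert intra.total_abs_flow == pytest.approx(0.8)
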