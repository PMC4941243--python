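"""ROI networks: connectivity, node strength, edge tests, behaviour."""

import numpy as np
import pandas as pd
import pytest

from alffnet import network


class TestROITable:
    def test_packaged_fixture_has_31_rois(self):
        df = network.load_roi_table()
        assert len(df) == 31
        assert df.pass_S.all()
        assert df.pass_SG.sum() == 3

    def test_rs429358_contributes_four_rois(self):
        df = network.load_roi_table()
        apoe4 = df[df.snp_id == "rs429358"]
        assert len(apoe4) == 4
        cereb = apoe4[apoe4.abbrev == "L.CRBL_Po"].iloc[0]
        assert (cereb.x, cereb.y, cereb.z) == (-36, -57, -33)
        assert cereb.cluster_size_mm3 == 2349
        assert cereb.peak_f == pytest.approx(81.78)
        assert cereb.pass_SG

    def test_empty_and_malformed_files_rejected(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("\t".join(network._ROI_COLUMNS) + "\n")
        with pytest.raises(ValueError):
            network.load_roi_table(empty)
        bad = tmp_path / "bad.tsv"
        good = network.load_roi_table()
        good["x"] = good["x"].astype(object)
        good.loc[0, "x"] = "not_a_number"
        good.to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError, match="line 2"):
            network.load_roi_table(bad)


class TestROISeries:
    def test_single_voxel_roi_is_verbatim(self, rng):
        data = rng.standard_normal((4, 4, 4, 30))
        roi = np.zeros((4, 4, 4), bool)
        roi[1, 2, 3] = True
        assert np.array_equal(network.extract_roi_series(data, roi), data[1, 2, 3])

    def test_antisymmetric_pair_cancels(self, rng):
        x = rng.standard_normal(30)
        data = np.zeros((2, 1, 1, 30))
        data[0, 0, 0], data[1, 0, 0] = x, -x
        roi = np.ones((2, 1, 1), bool)
        assert np.abs(network.extract_roi_series(data, roi)).max() < 1e-15

    def test_matches_brute_force_mean(self, rng):
        data = rng.standard_normal((5, 5, 5, 20))
        roi = rng.random((5, 5, 5)) < 0.3
        ours = network.extract_roi_series(data, roi)
        oracle = np.array(
            [data[..., t][roi].sum() / roi.sum() for t in range(20)]
        )
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_empty_roi_rejected(self, rng):
        with pytest.raises(ValueError):
            network.extract_roi_series(
                rng.standard_normal((3, 3, 3, 10)), np.zeros((3, 3, 3), bool)
            )

    def test_sphere_mask_respects_radius(self):
        affine = np.eye(4)
        affine[:3, :3] *= 3.0
        mask = network.roi_sphere_mask((0, 0, 0), 6.0, affine, (5, 5, 5))
        # voxels within 2 voxel-lengths of the origin corner
        assert mask[0, 0, 0] and mask[2, 0, 0] and not mask[3, 0, 0]


def _series_with_exact_r(rng, t, r):
    x = rng.standard_normal(t)
    x = (x - x.mean()) / x.std()
    y0 = rng.standard_normal(t)
    y0 -= y0.mean()
    y0 -= x * (x @ y0) / (x @ x)  # exactly orthogonal to x
    y0 /= y0.std()
    y = r * x + np.sqrt(1 - r**2) * y0
    return x, y


class TestConnectivity:
    def test_clipped_extremes_stay_finite(self, rng):
        x = rng.standard_normal(50)
        series = np.column_stack([x, x, -x])
        z = network.build_connectivity(series)
        lim = np.arctanh(1 - 1e-7)
        assert z[0, 1] == pytest.approx(lim)
        assert z[0, 2] == pytest.approx(-lim)
        assert np.isfinite(z).all()
        assert np.allclose(z, z.T)

    @pytest.mark.parametrize("r, z_expected", [(0.3, 0.3095), (0.5, 0.5493)])
    def test_fisher_transform_values(self, rng, r, z_expected):
        x, y = _series_with_exact_r(rng, 200, r)
        z = network.build_connectivity(np.column_stack([x, y]))
        assert z[0, 1] == pytest.approx(z_expected, abs=5e-4)

    def test_zero_variance_series_warns_and_zeroes(self, rng):
        series = np.column_stack([rng.standard_normal(30), np.full(30, 2.0)])
        with pytest.warns(UserWarning):
            z = network.build_connectivity(series)
        assert z[0, 1] == 0.0


class TestTopology:
    @pytest.mark.parametrize("n, edges", [(31, 465), (1, 0), (2, 1)])
    def test_edge_count(self, n, edges):
        assert network.count_edges(n) == edges

    def test_threshold_retention_and_nesting(self):
        r_vals = np.array(
            [[0.0, 0.2, 0.4], [0.2, 0.0, 0.8], [0.4, 0.8, 0.0]]
        )
        z = np.arctanh(r_vals)
        assert network.threshold_network(z, 0.5).sum() // 2 == 1
        assert network.threshold_network(z, 0.0).sum() // 2 == 3
        kept = [network.threshold_network(z, thr) for thr in (0.3, 0.5, 0.7)]
        assert np.all(kept[1] <= kept[0]) and np.all(kept[2] <= kept[1])

    def test_node_strength_contracts(self, rng):
        assert np.allclose(
            network.node_strength(np.ones((31, 31))), np.full(31, 30.0)
        )
        assert np.allclose(network.node_strength(np.zeros((4, 4))), 0.0)
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = [0.2, 0.3, -0.1]
        assert network.node_strength(w)[0] == pytest.approx(0.4)
        z = rng.standard_normal((10, 10))
        z = (z + z.T) / 2
        oracle = np.array([z[i].sum() - z[i, i] for i in range(10)])
        assert np.array_equal(network.node_strength(z), oracle)


class TestEdgeComparison:
    def test_null_calibration_at_nominal_rate(self, rng):
        n_nodes, reps = 31, 20
        counts = []
        for _ in range(reps):
            a = rng.standard_normal((30, n_nodes, n_nodes))
            b = rng.standard_normal((43, n_nodes, n_nodes))
            a = (a + a.transpose(0, 2, 1)) / 2
            b = (b + b.transpose(0, 2, 1)) / 2
            _, sig = network.compare_edges(a, b, (0.05,))
            counts.append(len(sig[0.05]))
        mean_count = np.mean(counts)
        expect = 465 * 0.05
        se = np.sqrt(465 * 0.05 * 0.95 / reps)
        assert abs(mean_count - expect) < 3 * se

    def test_injected_edge_shift_detected(self, rng):
        hits = 0
        for _ in range(20):
            a = rng.standard_normal((43, 5, 5))
            b = rng.standard_normal((30, 5, 5))
            a[:, 0, 1] += 2.0  # 2 pooled SDs on one edge
            a[:, 1, 0] += 2.0
            _, sig = network.compare_edges(a, b, (0.005,))
            if (0, 1) in sig[0.005]:
                hits += 1
        assert hits >= 18

    def test_significance_sets_nested_across_thresholds(self, rng):
        a = rng.standard_normal((20, 8, 8))
        b = rng.standard_normal((20, 8, 8)) + 0.5
        _, sig = network.compare_edges(a, b)
        assert set(sig[0.001]) <= set(sig[0.005]) <= set(sig[0.01]) <= set(sig[0.05])


class TestBehaviour:
    def test_affine_score_gives_unit_correlation(self, rng):
        s = pd.DataFrame({"node0": rng.standard_normal(40)})
        scores = pd.DataFrame({"mmse": 3.0 * s["node0"] - 1.0})
        out = network.behavior_correlation(s, scores)
        assert out.r.iloc[0] > 0.999

    def test_confound_removed_by_partial_correlation(self, rng):
        n = 500
        conf = rng.standard_normal(n)
        s = pd.DataFrame({"node0": conf + 0.01 * rng.standard_normal(n)})
        scores = pd.DataFrame({"mmse": conf + 0.01 * rng.standard_normal(n)})
        cov = pd.DataFrame({"c": conf})
        raw = network.behavior_correlation(s, scores)
        partial = network.behavior_correlation(s, scores, covariates=cov)
        assert raw.r.iloc[0] > 0.9
        assert abs(partial.r.iloc[0]) < 0.05

    def test_matches_residualisation_oracle(self, rng):
        n = 60
        s = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        scores = pd.DataFrame(rng.standard_normal((n, 2)), columns=["m1", "m2"])
        cov = pd.DataFrame(rng.standard_normal((n, 2)), columns=["age", "edu"])
        out = network.behavior_correlation(s, scores, covariates=cov)
        C = np.column_stack([np.ones(n), cov.to_numpy()])
        H = C @ np.linalg.inv(C.T @ C) @ C.T
        for _, row in out.iterrows():
            rs = s[row["node"]].to_numpy() - H @ s[row["node"]].to_numpy()
            ry = scores[row["score"]].to_numpy() - H @ scores[row["score"]].to_numpy()
            oracle = (rs @ ry) / np.sqrt((rs @ rs) * (ry @ ry))
            assert row.r == pytest.approx(oracle, abs=1e-10)

    def test_constant_score_rejected(self, rng):
        s = pd.DataFrame({"node0": rng.standard_normal(10)})
        with pytest.raises(ValueError):
            network.behavior_correlation(s, pd.DataFrame({"mmse": np.ones(10)}))


class TestHemisphericSummary:
    def test_mirrored_network_has_zero_laterality(self):
        out = network.hemispheric_strength_summary(
            [1.0, 2.0, 1.0, 2.0], ["L", "L", "R", "R"]
        )
        assert out["laterality_index"] == pytest.approx(0.0)

    def test_all_weight_left(self):
        out = network.hemispheric_strength_summary([3.0, 0.0], ["L", "R"])
        assert out["laterality_index"] == pytest.approx(1.0)

    def test_index_bounded_and_missing_tags_reported(self, rng):
        for _ in range(20):
            s = rng.standard_normal(6)
            tags = rng.choice(["L", "R", "B"], 6)
            out = network.hemispheric_strength_summary(s, tags)
            if not np.isnan(out["laterality_index"]):
                assert -1.0 <= out["laterality_index"] <= 1.0
        out = network.hemispheric_strength_summary([1.0], ["B"])
        assert np.isnan(out["laterality_index"])
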