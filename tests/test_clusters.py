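"""Cluster extraction, Monte-Carlo extent thresholds, two-level correction."""

import numpy as np
import pytest
from scipy import stats

from alffnet import clusters
from alffnet.interaction import StatMap


def _flood_fill_sizes(binary, connectivity):
    """Brute-force connected-component sizes via explicit flood fill."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    visited = np.zeros(binary.shape, bool)
    sizes = []
    coords = np.argwhere(binary)
    for start in map(tuple, coords):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            x, y, z = stack.pop()
            size += 1
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if (
                    0 <= p[0] < binary.shape[0]
                    and 0 <= p[1] < binary.shape[1]
                    and 0 <= p[2] < binary.shape[2]
                    and binary[p]
                    and not visited[p]
                ):
                    visited[p] = True
                    stack.append(p)
        sizes.append(size)
    return sorted(sizes)


def _statmap_from_p(p3, mask, affine=None, f3=None):
    if affine is None:
        affine = np.eye(4)
    if f3 is None:
        f3 = -np.log(p3)
    return StatMap("rs_test", f3, p3, 1, 50, affine, mask)


class TestExtractClusters:
    def test_extent_rule_keeps_only_large_blob(self):
        mask = np.ones((12, 12, 12), bool)
        p3 = np.ones(mask.shape)
        p3[1:6, 1:6, 1:3] = 1e-4  # 5*5*2 = 50 voxels
        p3[8:10, 8:13, 8:9] = 1e-4  # 2*4*1 = 8 voxels (clipped)
        recs = clusters.extract_clusters(
            _statmap_from_p(p3, mask), voxel_p=0.005, min_extent=48
        )
        assert len(recs) == 1 and recs[0].size_vox == 50

    def test_corner_touching_blobs_depend_on_connectivity(self):
        mask = np.ones((8, 8, 8), bool)
        p3 = np.ones(mask.shape)
        p3[1:3, 1:3, 1:3] = 1e-4
        p3[3:5, 3:5, 3:5] = 1e-4  # touches only at corner voxel (3,3,3)-(2,2,2)
        sm = _statmap_from_p(p3, mask)
        n26 = len(clusters.extract_clusters(sm, min_extent=1, connectivity=26))
        n18 = len(clusters.extract_clusters(sm, min_extent=1, connectivity=18))
        assert (n26, n18) == (1, 2)

    def test_peak_voxel_maps_through_affine_to_mni(self):
        affine = np.eye(4)
        affine[:3, :3] *= 3.0
        affine[:3, 3] = (-36.0, -48.0, -36.0)
        mask = np.ones((24, 28, 24), bool)
        p3 = np.ones(mask.shape)
        f3 = np.zeros(mask.shape)
        p3[4:7, 9:12, 9:12] = 1e-4
        f3[5, 10, 10] = 99.0
        recs = clusters.extract_clusters(
            _statmap_from_p(p3, mask, affine, f3), min_extent=1
        )
        assert recs[0].peak_ijk == (5, 10, 10)
        assert recs[0].peak_mm == (-21.0, -18.0, -6.0)
        assert recs[0].size_mm3 == recs[0].size_vox * 27.0

    def test_labelling_agrees_with_flood_fill_oracle(self, rng):
        for conn in (6, 18, 26):
            for _ in range(5):
                binary = rng.random((10, 10, 10)) < 0.25
                mask = np.ones(binary.shape, bool)
                p3 = np.where(binary, 1e-4, 0.9)
                recs = clusters.extract_clusters(
                    _statmap_from_p(p3, mask), min_extent=1, connectivity=conn
                )
                ours = sorted(r.size_vox for r in recs)
                assert ours == _flood_fill_sizes(binary, conn)

    def test_empty_result_allowed(self):
        mask = np.ones((5, 5, 5), bool)
        recs = clusters.extract_clusters(_statmap_from_p(np.ones(mask.shape), mask))
        assert recs == []


class TestSimulatedThreshold:
    def test_matches_independent_oracle_at_zero_fwhm(self):
        """At FWHM=0 an independent re-implementation (own standardisation,
        own thresholding, flood-fill labelling) must reproduce the identical
        null max-cluster distribution at matched seeds."""
        shape = (10, 10, 10)
        mask = np.ones(shape, bool)
        seed, n_iter, voxel_p = 123, 200, 0.005
        res = clusters.simulate_cluster_threshold(
            mask, 0.0, 3.0, voxel_p=voxel_p, n_iter=n_iter, connectivity=18, seed=seed
        )
        rng = np.random.default_rng(seed)
        z_thr = stats.norm.isf(voxel_p)
        oracle_max = []
        for _ in range(n_iter):
            field = rng.standard_normal(shape)
            z = (field - field.mean()) / field.std()
            binary = z > z_thr
            sizes = _flood_fill_sizes(binary, 18)
            oracle_max.append(sizes[-1] if sizes else 0)
        assert np.array_equal(res.max_sizes, oracle_max)
        assert res.extent_vox == clusters.extent_for_alpha(np.array(oracle_max), 0.05)

    def test_monotone_in_fwhm_and_voxel_p(self):
        mask = np.ones((12, 12, 12), bool)
        kw = dict(n_iter=200, connectivity=18, seed=5)
        t0 = clusters.simulate_cluster_threshold(mask, 0.0, 3.0, **kw).extent_vox
        t8 = clusters.simulate_cluster_threshold(mask, 8.0, 3.0, **kw).extent_vox
        assert t8 >= t0
        t_strict = clusters.simulate_cluster_threshold(
            mask, 8.0, 3.0, voxel_p=0.001, **kw
        ).extent_vox
        assert t_strict <= t8

    def test_input_validation(self):
        mask = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError):
            clusters.simulate_cluster_threshold(np.zeros((4, 4, 4), bool), 8, 3)
        with pytest.raises(ValueError):
            clusters.simulate_cluster_threshold(mask, -1, 3)
        with pytest.raises(ValueError):
            clusters.simulate_cluster_threshold(mask, 8, 3, n_iter=50)

    def test_extent_for_alpha_on_known_distribution(self):
        # 100 draws: 95 maxima of size 10, 5 of size 20 -> P(max>=11)=0.05
        sizes = np.array([10] * 95 + [20] * 5)
        assert clusters.extent_for_alpha(sizes, 0.05) == 11


class TestTwoLevelCorrection:
    def _toy_records(self, sizes, snp_id="rs1"):
        return [
            clusters.ClusterRecord(snp_id, s, s * 27.0, 10.0, (0, 0, 0), (0, 0, 0))
            for s in sizes
        ]

    def test_gene_bonferroni_alphas(self):
        gene_map = {f"rs{i}": "APOE" for i in range(5)}
        gene_map["rs_solo"] = "MTHFR"
        by_snp = {s: self._toy_records([100], s) for s in gene_map}
        ledger = clusters.correct_within_gene(
            by_snp, gene_map, null_max_sizes=np.array([10] * 99 + [200])
        )
        assert ledger.gene_alphas["APOE"] == pytest.approx(0.01)
        assert ledger.gene_alphas["MTHFR"] == pytest.approx(0.05)
        # corrected p of a 100-voxel cluster on this null = 0.01 -> passes
        # only where the gene alpha stays above it
        assert all(r.pass_S for r in by_snp["rs_solo"])
        assert not any(r.pass_S for r in by_snp["rs0"])

    def test_snp_without_gene_rejected(self):
        by_snp = {"rs_orphan": self._toy_records([100])}
        with pytest.raises(ValueError):
            clusters.correct_within_gene(by_snp, {"rs_known": "APOE"})

    def test_no_clusters_no_flags(self):
        ledger = clusters.correct_within_gene({"rs1": []}, {"rs1": "APOE"})
        assert ledger.gene_snp_counts == {"APOE": 1}

    def test_stage2_threshold_values(self):
        assert clusters.stage2_voxel_threshold(15) == pytest.approx(0.005 / 15)
        assert round(clusters.stage2_voxel_threshold(15), 4) == 0.0003
        assert clusters.stage2_voxel_threshold(1) == 0.005
        with pytest.raises(ValueError):
            clusters.stage2_voxel_threshold(0)

    def test_pass_sg_subset_of_pass_s(self):
        """A strong cluster survives both stages, a borderline one only the
        first; pass_SG never appears without pass_S."""
        mask = np.ones((14, 14, 14), bool)
        p3 = np.ones(mask.shape)
        f3 = np.zeros(mask.shape)
        p3[1:6, 1:6, 1:4] = 1e-9  # strong: survives 0.005 and 0.005/k
        f3[3, 3, 2] = 50.0
        p3[8:13, 8:13, 8:11] = 3e-3  # weak: survives 0.005 only
        f3[10, 10, 9] = 9.0
        sm1 = StatMap("rs1", f3, p3, 1, 50, np.eye(4), mask)
        # second SNP with its own strong cluster, so k = 2 and stage 2
        # tightens the voxel threshold to 0.0025
        p3b = np.ones(mask.shape)
        f3b = np.zeros(mask.shape)
        p3b[1:6, 1:6, 1:4] = 1e-9
        f3b[3, 3, 2] = 40.0
        sm2 = StatMap("rs2", f3b, p3b, 1, 50, np.eye(4), mask)
        statmaps = {"rs1": sm1, "rs2": sm2}
        by_snp = {
            s: clusters.extract_clusters(m, 0.005, min_extent=48)
            for s, m in statmaps.items()
        }
        gene_map = {"rs1": "APOE", "rs2": "LDLR"}
        ledger = clusters.correct_within_gene(by_snp, gene_map, min_extent=48)
        ledger = clusters.correct_between_genes(statmaps, by_snp, ledger, 48)
        recs = by_snp["rs1"]
        assert len(recs) == 2
        assert all(r.pass_S for r in recs)
        assert sum(r.pass_SG for r in recs) == 1  # the weak one (p=3e-3) fails
        assert all(r.pass_S for r in recs if r.pass_SG)
        assert ledger.stage2_voxel_p == pytest.approx(0.0025)

    def test_no_stage1_survivors_notes_skipped_stage2(self):
        sm = _statmap_from_p(np.ones((5, 5, 5)), np.ones((5, 5, 5), bool))
        by_snp = {"rs1": []}
        ledger = clusters.correct_within_gene(by_snp, {"rs1": "APOE"})
        ledger = clusters.correct_between_genes({"rs1": sm}, by_snp, ledger)
        assert "no stage-2 test performed" in ledger.note
        assert ledger.stage2_voxel_p is None
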