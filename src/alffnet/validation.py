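"""Calibration and parameter-recovery experiments on synthetic data.

These are the package's own end-to-end checks: type-I calibration of the
voxelwise interaction test, family-wise calibration of the Monte-Carlo
cluster correction, and recovery of an injected genotype-by-group blob by
the full simulate -> ALFF -> interaction-GLM -> cluster pipeline.  They
are exposed as library functions so the test suite and the reproduction
script exercise exactly the same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import clusters, genetics, interaction, simulate
from .alff import FWHM_TO_SIGMA, compute_alff_map, preprocess_series

__all__ = [
    "null_voxel_calibration",
    "cluster_fwe_calibration",
    "recovery_experiment",
    "RecoveryResult",
]


def _null_design(seed: int, n_amci: int = 43, n_controls: int = 30):
    """A realistic design (one mid-MAF SNP, covariates) with no interaction."""
    ss = np.random.SeedSequence(seed)
    s_geno, s_pheno = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    panel = [simulate.PanelSNP("rs_null", "NULLGENE", "CT", 0.3)]
    genotypes = simulate.generate_genotypes(n_amci + n_controls, panel, s_geno)
    phenotypes = simulate.generate_phenotypes(n_amci, n_controls, s_pheno)
    counts = genetics.genotype_counts(genotypes, panel[0].entry)
    model = genetics.select_genetic_model(genetics.compute_maf(counts).maf)
    code = genetics.code_genotypes(
        genetics.minor_allele_counts(genotypes, panel[0].entry), model.model
    )
    X, idx = interaction.build_design(phenotypes, code)
    return X, idx


def null_voxel_calibration(
    n_voxels: int = 2000, seed: int = 0, voxel_p: float = 0.005
) -> dict:
    """Fraction of null voxels with interaction p below ``voxel_p``.

    Each voxel's data carry a genuine group main effect plus noise but no
    genotype-by-group interaction, so the partial F for the interaction is
    null-distributed and the supra-threshold fraction should match the
    nominal rate.
    """
    X, idx = _null_design(seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    n = X.shape[0]
    group = X[:, 1]
    Y = 0.5 * group[:, None] + rng.standard_normal((n, n_voxels))
    gm = 0.5 + 0.1 * rng.standard_normal((n, n_voxels))
    _, p, _, _ = interaction.interaction_f_map(Y, X, idx["interaction"], gm)
    rate = float((p < voxel_p).mean())
    se = float(np.sqrt(voxel_p * (1 - voxel_p) / n_voxels))
    return {"rate": rate, "nominal": voxel_p, "binomial_se": se, "n_voxels": n_voxels}


def cluster_fwe_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (24, 28, 24),
    voxel_size_mm: float = 3.0,
    fwhm_mm: float = 8.0,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
    n_iter: int = 1000,
    connectivity: int = 18,
) -> dict:
    """Family-wise false-positive rate of the stage-1 cluster correction
    on pure-noise statistic maps.

    The cluster-extent threshold is first estimated by the Monte-Carlo
    simulation; each replicate then fits the interaction GLM to smoothed
    noise "ALFF" maps (matching the smoothness assumed by the simulation)
    and counts a family-wise error whenever any supra-threshold cluster
    reaches the extent.
    """
    mask = simulate.ellipsoid_mask(grid_shape)
    affine = simulate.default_affine(grid_shape, voxel_size_mm)
    ss = np.random.SeedSequence(seed)
    s_thr, s_design, s_reps = ss.spawn(3)
    thr = clusters.simulate_cluster_threshold(
        mask,
        fwhm_mm,
        voxel_size_mm,
        voxel_p=voxel_p,
        alpha=alpha,
        n_iter=n_iter,
        connectivity=connectivity,
        seed=int(s_thr.generate_state(1)[0] % 2**31),
    )
    X, idx = _null_design(int(s_design.generate_state(1)[0] % 2**31))
    n = X.shape[0]
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    false_positives = 0
    rep_streams = s_reps.spawn(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng(rep_streams[r])
        maps = ndimage.gaussian_filter(
            rng.standard_normal((*grid_shape, n)), sigma=(sigma, sigma, sigma, 0.0)
        )
        Y = maps[mask].T  # (n, V)
        f_flat, p_flat, df1, df2 = interaction.interaction_f_map(
            Y, X, idx["interaction"], None
        )
        f3 = np.zeros(grid_shape)
        p3 = np.ones(grid_shape)
        f3[mask] = f_flat
        p3[mask] = p_flat
        sm = interaction.StatMap("null", f3, p3, df1, df2, affine, mask)
        recs = clusters.extract_clusters(
            sm, voxel_p=voxel_p, min_extent=thr.extent_vox, connectivity=connectivity
        )
        if recs:
            false_positives += 1
    fwe = false_positives / n_replicates
    se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {
        "fwe": fwe,
        "nominal_alpha": alpha,
        "binomial_se": se,
        "extent_vox": thr.extent_vox,
        "n_replicates": n_replicates,
    }


@dataclass
class RecoveryResult:
    n_runs: int
    peak_in_blob: int
    blob_cluster_pass: int

    @property
    def peak_rate(self) -> float:
        return self.peak_in_blob / self.n_runs

    @property
    def pass_rate(self) -> float:
        return self.blob_cluster_pass / self.n_runs


def recovery_experiment(
    n_runs: int = 20,
    seed: int = 0,
    effect_size: float = 1.0,
    snp_id: str = "rs429358",
    radius_vox: float = 3.0,
    n_amci: int = 43,
    n_controls: int = 30,
    min_extent: int = clusters.DEFAULT_EXTENT_VOX,
    voxel_p: float = clusters.DEFAULT_VOXEL_P,
) -> RecoveryResult:
    """Inject one interaction blob and ask the full pipeline to find it.

    For each seeded run: simulate the dataset on the default grid, compute
    per-subject ALFF maps, scan the blob's SNP, and record whether (a) the
    peak of the interaction F map lies inside the true blob and (b) a
    cluster peaking inside the blob survives the stage-1 extent rule.
    """
    base = simulate.SimulationConfig(n_amci=n_amci, n_controls=n_controls)
    center = tuple(int(s // 2) for s in base.grid_shape)
    run_streams = np.random.SeedSequence(seed).spawn(n_runs)
    peak_hits = 0
    pass_hits = 0
    for r in range(n_runs):
        run_seed = int(run_streams[r].generate_state(1)[0] % 2**31)
        config = simulate.SimulationConfig(
            n_amci=n_amci,
            n_controls=n_controls,
            effect_blobs=[
                simulate.EffectBlob(center, radius_vox, snp_id, effect_size)
            ],
            seed=run_seed,
        )
        s_geno, s_pheno = (
            int(c.generate_state(1)[0] % 2**31)
            for c in np.random.SeedSequence(run_seed).spawn(2)
        )
        genotypes = simulate.generate_genotypes(
            n_amci + n_controls, config.snp_panel, s_geno
        )
        phenotypes = simulate.generate_phenotypes(n_amci, n_controls, s_pheno)
        mask = simulate.ellipsoid_mask(config.grid_shape)
        bm = simulate.blob_mask(config.grid_shape, center, radius_vox)
        alff_rows = []
        for _, series in simulate.iter_subject_series(config, genotypes, phenotypes):
            series, _ = preprocess_series(series, config.n_discard)
            alff = compute_alff_map(series, mask, config.tr_s)
            alff_rows.append(alff[mask])
        alff_stack = np.asarray(alff_rows)
        gm_maps = simulate.generate_gm_maps(config, phenotypes)
        gm_stack = np.asarray(
            [gm_maps[s][mask] for s in phenotypes["subject_id"]]
        )
        snp = config.panel_entry(snp_id)
        sm = interaction.run_snp_scan(
            alff_stack,
            gm_stack,
            genotypes,
            phenotypes,
            snp.entry,
            mask,
            simulate.default_affine(config.grid_shape, config.voxel_size_mm),
        )
        peak_ijk = np.unravel_index(np.argmax(np.where(mask, sm.f, -np.inf)), mask.shape)
        if bm[peak_ijk]:
            peak_hits += 1
        recs = clusters.extract_clusters(sm, voxel_p=voxel_p, min_extent=min_extent)
        if any(bm[r_.peak_ijk] for r_ in recs):
            pass_hits += 1
    return RecoveryResult(n_runs, peak_hits, pass_hits)
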