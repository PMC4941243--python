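"""Synthetic imaging-genetics datasets with known ground truth.

The generator emulates the study conditions end to end: Hardy-Weinberg
genotypes for a configurable SNP panel, two diagnostic groups (aMCI and
controls) with demographics and neuropsychological z-scores drawn from
the published group summaries, grey-matter probability maps in [0, 1],
and per-subject 4D BOLD-like volumes whose band-limited (0.01-0.08 Hz)
amplitude carries a genotype-by-group *interaction* effect inside
specified blobs.  The injected modulation multiplies the baseline
band-limited signal by 1 + effect_size * group * genotype_code, where the
genotype code matches the coding the mapping stage will apply, so
parameter recovery is a clean identity test.

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` substreams (genotypes, phenotypes, one per
subject's BOLD series, one per grey-matter map), so any stage can be
regenerated in isolation and the full dataset is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import genetics
from .alff import FWHM_TO_SIGMA

__all__ = [
    "PanelSNP",
    "EffectBlob",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "default_panel",
    "default_affine",
    "ellipsoid_mask",
    "blob_mask",
    "generate_genotypes",
    "generate_phenotypes",
    "generate_gm_maps",
    "iter_subject_series",
    "generate_bold_dataset",
    "TABLE1_STATS",
]

#: Group summaries used to parameterise the phenotype generator
#: (mean, SD per group; gender as male counts / group size).
TABLE1_STATS = {
    "age": {"aMCI": (72.00, 4.88), "control": (72.93, 3.93)},
    "education": {"aMCI": (13.58, 3.10), "control": (14.98, 2.67)},
    "mmse": {"aMCI": (27.05, 1.53), "control": (28.2, 1.37)},
    "avlt_dr": {"aMCI": (-0.64, 0.57), "control": (0.99, 0.62)},
    "reyo_dr": {"aMCI": (-0.26, 0.96), "control": (0.44, 0.91)},
    "tmt_a": {"aMCI": (0.25, 1.03), "control": (-0.37, 0.85)},
    "tmt_b": {"aMCI": (0.22, 1.11), "control": (-0.41, 0.60)},
    "sdmt": {"aMCI": (-0.24, 0.94), "control": (0.39, 0.96)},
    "cdt": {"aMCI": (-0.23, 1.14), "control": (0.29, 0.70)},
    "dst": {"aMCI": (-0.13, 0.93), "control": (0.23, 0.99)},
}
TABLE1_MALE_FRACTION = {"aMCI": 27 / 43, "control": 17 / 30}
TABLE1_CDR = {"aMCI": 0.5, "control": 0.0}

_N_SINUSOIDS = 10


@dataclass(frozen=True)
class PanelSNP:
    """A panel SNP with the minor-allele frequency used for simulation.

    The second allele character is the minor allele.
    """

    snp_id: str
    gene: str
    alleles: str
    maf: float

    @property
    def entry(self) -> genetics.SNPPanelEntry:
        return genetics.SNPPanelEntry(self.snp_id, self.gene, self.alleles)


@dataclass(frozen=True)
class EffectBlob:
    """Spherical carrier of a genotype-by-group amplitude modulation."""

    center_voxel: tuple[int, int, int]
    radius_vox: float
    snp_id: str
    effect_size: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.radius_vox <= 0:
            raise ValueError("radius_vox must be positive")


@dataclass
class SimulationConfig:
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 3.0
    tr_s: float = 3.0
    n_volumes: int = 142
    n_discard: int = 8
    n_amci: int = 43
    n_controls: int = 30
    snp_panel: Sequence[PanelSNP] | None = None
    effect_blobs: Sequence[EffectBlob] = ()
    noise_sd: float = 1.0
    smooth_fwhm_mm: float = 8.0
    gm_missing_subject: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.n_volumes <= self.n_discard:
            raise ValueError("n_volumes must exceed n_discard")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if self.snp_panel is None:
            self.snp_panel = default_panel()

    def panel_entry(self, snp_id: str) -> PanelSNP:
        for s in self.snp_panel:
            if s.snp_id == snp_id:
                return s
        raise KeyError(f"SNP {snp_id} not in simulation panel")


@dataclass
class GroundTruth:
    """Serialisable record of what was injected."""

    seed: int
    blobs: list[dict] = field(default_factory=list)
    subject_factors: dict = field(default_factory=dict)  # subject -> [per-blob factor]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "blobs": self.blobs,
                "subject_factors": self.subject_factors,
            },
            indent=2,
            sort_keys=True,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    mask: np.ndarray
    affine: np.ndarray
    gm_maps: dict  # subject_id -> 3D array (or None when withheld)
    ground_truth: GroundTruth
    volumes: dict | None = None  # subject_id -> 4D array when materialised


def default_panel() -> list[PanelSNP]:
    """The packaged 33-SNP panel with evenly spaced simulation MAFs.

    The study does not publish its allele frequencies, so the simulator
    assigns MAFs spread over [0.12, 0.48] in panel order; the spread
    exercises both the recessive and the genotypic model branches.
    """
    entries = genetics.load_panel()
    mafs = np.round(np.linspace(0.12, 0.48, len(entries)), 3)
    return [
        PanelSNP(e.snp_id, e.gene, e.alleles, float(m))
        for e, m in zip(entries, mafs)
    ]


def default_affine(shape: Sequence[int], voxel_size_mm: float) -> np.ndarray:
    """RAS affine with isotropic voxels and the grid centred on the origin."""
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    return affine


def ellipsoid_mask(shape: Sequence[int], semi_axis_fraction: float = 0.45) -> np.ndarray:
    """Central ellipsoidal brain mask."""
    shape = tuple(shape)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * semi_axis_fraction
    idx = np.indices(shape)
    d2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def blob_mask(
    shape: Sequence[int], center: Sequence[int], radius_vox: float
) -> np.ndarray:
    idx = np.indices(tuple(shape))
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius_vox**2


def _int_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _streams(config: SimulationConfig):
    root = np.random.SeedSequence(config.seed)
    geno, pheno, data, gm = root.spawn(4)
    n = config.n_amci + config.n_controls
    return geno, pheno, data.spawn(n), gm.spawn(n + 1)


def generate_genotypes(
    n_subjects: int, panel: Sequence[PanelSNP], seed: int
) -> pd.DataFrame:
    """Independent Hardy-Weinberg draws per SNP at the panel MAFs.

    Genotype probabilities are (p^2, 2pq, q^2) for (common homozygote,
    heterozygote, minor homozygote) with q the MAF of the second panel
    allele.
    """
    for snp in panel:
        if not 0.0 < snp.maf <= 0.5:
            raise ValueError(f"{snp.snp_id}: MAF must lie in (0, 0.5], got {snp.maf}")
    rng = np.random.default_rng(seed)
    data = {"subject_id": [f"S{i + 1:03d}" for i in range(n_subjects)]}
    for snp in panel:
        a, b = snp.alleles
        q = snp.maf
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        draws = rng.choice(3, size=n_subjects, p=probs)
        data[snp.snp_id] = np.array([a + a, a + b, b + b])[draws]
    return pd.DataFrame(data)


def generate_phenotypes(n_amci: int, n_controls: int, seed: int) -> pd.DataFrame:
    """Group, demographics and neuropsychological z-scores drawn from the
    published per-group means/SDs; gender Bernoulli at the printed
    male:female ratios; CDR constant per group."""
    if min(n_amci, n_controls) < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    groups = ["aMCI"] * n_amci + ["control"] * n_controls
    n = n_amci + n_controls
    rows: dict = {
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "group": groups,
    }
    gender = [
        int(rng.random() < TABLE1_MALE_FRACTION[g]) for g in groups
    ]  # 1 = male
    rows["gender"] = gender
    for var, stats_by_group in TABLE1_STATS.items():
        vals = [
            rng.normal(*stats_by_group[g]) for g in groups
        ]
        rows[var] = np.round(vals, 6)
    rows["cdr"] = [TABLE1_CDR[g] for g in groups]
    return pd.DataFrame(rows)


def _blob_factors(
    config: SimulationConfig,
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-blob voxel masks and the (n_subjects, n_blobs) amplitude factors."""
    group = (phenotypes["group"] == "aMCI").to_numpy().astype(float)
    masks, factors = [], []
    brain = ellipsoid_mask(config.grid_shape)
    for blob in config.effect_blobs:
        bm = blob_mask(config.grid_shape, blob.center_voxel, blob.radius_vox)
        if not bm.any() or (bm & ~brain).any():
            raise ValueError(
                f"effect blob at {blob.center_voxel} extends outside the brain mask"
            )
        snp = config.panel_entry(blob.snp_id)
        counts = genetics.genotype_counts(genotypes, snp.entry)
        model = genetics.select_genetic_model(
            genetics.compute_maf(counts).maf, snp.snp_id
        )
        code = genetics.code_genotypes(
            genetics.minor_allele_counts(genotypes, snp.entry), model.model
        )[:, 0]
        factors.append(1.0 + blob.effect_size * group * code)
        masks.append(bm)
    if factors:
        return masks, np.column_stack(factors)
    return masks, np.ones((len(phenotypes), 0))


def _subject_series(
    rng: np.random.Generator,
    config: SimulationConfig,
    amp_field: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """One subject's 4D series: amplitude-modulated band-limited baseline
    plus a small linear trend and white noise, spatially smoothed."""
    shape = tuple(config.grid_shape)
    n_vox = int(np.prod(shape))
    t = np.arange(config.n_volumes) * config.tr_s
    freqs = rng.uniform(0.01, 0.08, _N_SINUSOIDS)
    omega = 2 * np.pi * freqs[:, None] * t[None, :]
    basis = np.vstack([np.sin(omega), np.cos(omega)])  # (2K, T)
    phases = rng.uniform(0, 2 * np.pi, (n_vox, _N_SINUSOIDS))
    coeff = np.hstack([np.cos(phases), np.sin(phases)])  # (V, 2K)
    coeff /= np.sqrt(_N_SINUSOIDS / 2.0)  # unit total variance
    signal = (coeff @ basis).reshape(shape + (config.n_volumes,))
    signal *= amp_field[..., None]
    trend_t = (t - t.mean()) / t.std()
    trend = rng.normal(0.0, 0.05, shape)[..., None] * trend_t
    noise = rng.standard_normal(shape + (config.n_volumes,)) * config.noise_sd
    data = (signal + trend + noise).astype(np.float32)
    if config.smooth_fwhm_mm > 0:
        sigma = config.smooth_fwhm_mm * FWHM_TO_SIGMA / config.voxel_size_mm
        data = ndimage.gaussian_filter(data, sigma=(sigma, sigma, sigma, 0.0))
    data[~mask] = 0.0
    return data


def iter_subject_series(
    config: SimulationConfig,
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> Iterator[tuple[str, np.ndarray]]:
    """Yield (subject_id, 4D series) one subject at a time.

    Regenerating with the same config yields bit-identical series, so a
    second pass (e.g. ROI time-series extraction after cluster inference)
    does not require the volumes to be kept in memory or on disk.
    """
    if len(genotypes) != len(phenotypes):
        raise ValueError("genotype and phenotype tables disagree on subject count")
    mask = ellipsoid_mask(config.grid_shape)
    masks, factors = _blob_factors(config, genotypes, phenotypes)
    _, _, subj_streams, _ = _streams(config)
    for i, subject in enumerate(phenotypes["subject_id"]):
        amp = np.ones(tuple(config.grid_shape))
        for b, bm in enumerate(masks):
            amp[bm] *= factors[i, b]  # overlapping blobs compose multiplicatively
        rng = np.random.default_rng(subj_streams[i])
        yield str(subject), _subject_series(rng, config, amp, mask)


def generate_gm_maps(
    config: SimulationConfig, phenotypes: pd.DataFrame
) -> dict:
    """Smooth grey-matter probability fields in [0, 1].

    Each subject's map is a logistic squash of a shared anatomical
    pattern plus an individual smooth field; a missing map (None) for the
    first aMCI subject is produced when the config flag is set, mirroring
    a single absent anatomical scan.
    """
    shape = tuple(config.grid_shape)
    mask = ellipsoid_mask(shape)
    _, _, _, gm_streams = _streams(config)
    base = ndimage.gaussian_filter(
        np.random.default_rng(gm_streams[0]).standard_normal(shape), sigma=2.0
    )
    base /= base.std()
    gm_maps: dict = {}
    withheld = None
    if config.gm_missing_subject:
        amci_ids = phenotypes.loc[phenotypes["group"] == "aMCI", "subject_id"]
        withheld = amci_ids.iloc[0] if len(amci_ids) else None
    for i, subject in enumerate(phenotypes["subject_id"]):
        if subject == withheld:
            gm_maps[str(subject)] = None
            continue
        indiv = ndimage.gaussian_filter(
            np.random.default_rng(gm_streams[i + 1]).standard_normal(shape), sigma=2.0
        )
        indiv /= indiv.std()
        fld = 0.7 * base + 0.3 * indiv
        gm = 1.0 / (1.0 + np.exp(-fld))
        gm[~mask] = 0.0
        gm_maps[str(subject)] = gm
    return gm_maps


def generate_bold_dataset(
    config: SimulationConfig,
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    materialize: bool = True,
) -> SimulatedDataset:
    """Full synthetic dataset: volumes, mask, GM maps and ground truth."""
    if len(genotypes) != len(phenotypes):
        raise ValueError("genotype and phenotype tables disagree on subject count")
    mask = ellipsoid_mask(config.grid_shape)
    masks, factors = _blob_factors(config, genotypes, phenotypes)
    gt = GroundTruth(seed=config.seed)
    for blob, bm in zip(config.effect_blobs, masks):
        gt.blobs.append(
            {
                "snp_id": blob.snp_id,
                "center_voxel": list(blob.center_voxel),
                "radius_vox": blob.radius_vox,
                "effect_size": blob.effect_size,
                "n_voxels": int(bm.sum()),
            }
        )
    for i, subject in enumerate(phenotypes["subject_id"]):
        gt.subject_factors[str(subject)] = [float(f) for f in factors[i]]
    volumes = None
    if materialize:
        volumes = {
            subject: series
            for subject, series in iter_subject_series(config, genotypes, phenotypes)
        }
    return SimulatedDataset(
        config=config,
        mask=mask,
        affine=default_affine(config.grid_shape, config.voxel_size_mm),
        gm_maps=generate_gm_maps(config, phenotypes),
        ground_truth=gt,
        volumes=volumes,
    )
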