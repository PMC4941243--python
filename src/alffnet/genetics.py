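"""Genotype QC, genetic-model selection, design coding, and group demographics.

This module owns everything genetic that happens before the imaging GLM:
minor-allele frequencies, Hardy-Weinberg equilibrium tests, the SNP
exclusion rules (MAF < 5% and complete linkage disequilibrium), the
MAF-driven choice between a 2-df genotypic model and a 1-df recessive
model, the translation of genotypes into design-matrix columns, and the
case/control demographic comparisons (pooled t, Mann-Whitney U, and the
2x2 chi-square for gender).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SNPPanelEntry",
    "MAFResult",
    "HWEResult",
    "GeneticModelChoice",
    "load_panel",
    "load_genotypes",
    "save_genotypes",
    "genotype_counts",
    "minor_allele_counts",
    "compute_maf",
    "hwe_test",
    "filter_snps",
    "model_selection_cutoff",
    "select_genetic_model",
    "code_genotypes",
    "chi2_2x2",
    "pooled_t",
    "demographic_tests",
]

#: Default MAF below which a SNP is excluded from analysis.
MAF_EXCLUSION = 0.05

#: MAF at or above which the 2-df genotypic model is used; below it the
#: recessive model merges heterozygotes with rare homozygotes.  This is the
#: largest two-decimal q whose rare-homozygote frequency q**2 stays <= 10%.
MODEL_CUTOFF = 0.31


@dataclass(frozen=True)
class SNPPanelEntry:
    """One SNP of the candidate panel.

    ``alleles`` is a two-character string; by convention the second
    character is the allele the simulator treats as minor.
    """

    snp_id: str
    gene: str
    alleles: str

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError(f"{self.snp_id}: alleles must be a 2-character string")
        if not self.gene:
            raise ValueError(f"{self.snp_id}: gene symbol must be non-empty")


class MAFResult(NamedTuple):
    """Minor-allele frequency plus which allele is minor."""

    maf: float
    minor_first: bool  # True if the first allele of the pair is the minor one


class HWEResult(NamedTuple):
    chi2: float
    p: float


@dataclass(frozen=True)
class GeneticModelChoice:
    snp_id: str
    maf: float
    model: str  # "genotypic" | "recessive"
    design_df: int

    def __post_init__(self) -> None:
        if self.model not in ("genotypic", "recessive"):
            raise ValueError(f"unknown genetic model {self.model!r}")
        expected_df = 2 if self.model == "genotypic" else 1
        if self.design_df != expected_df:
            raise ValueError("design_df inconsistent with model")


def load_panel(path=None) -> list[SNPPanelEntry]:
    """Load the SNP panel (default: the packaged 33-SNP / 12-gene
    cholesterol-metabolism panel)."""
    if path is None:
        path = resources.files("alffnet.data") / "cholesterol_panel.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = [
        SNPPanelEntry(r.snp_id, r.gene, r.alleles) for r in df.itertuples(index=False)
    ]
    ids = [e.snp_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate snp_id in panel")
    return entries


def load_genotypes(path) -> pd.DataFrame:
    """Read a genotype TSV (subject_id column + one two-letter genotype
    column per rs id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "subject_id" not in df.columns:
        raise ValueError("genotype table must have a subject_id column")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids in genotype table")
    return df


def save_genotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _normalise_genotype(g: str, entry: SNPPanelEntry) -> str:
    """Sort the two allele characters into panel order (unordered pairs)."""
    a, b = entry.alleles
    if sorted(g) not in (sorted(a + a), sorted(a + b), sorted(b + b)):
        raise ValueError(
            f"genotype {g!r} not composed of panel alleles {entry.alleles!r} "
            f"for {entry.snp_id}"
        )
    return "".join(sorted(g, key=lambda c: entry.alleles.index(c)))


def genotype_counts(table: pd.DataFrame, entry: SNPPanelEntry) -> tuple[int, int, int]:
    """Count (n_AA, n_Aa, n_aa) where A is the first panel allele."""
    a, b = entry.alleles
    col = table[entry.snp_id].map(lambda g: _normalise_genotype(g, entry))
    counts = col.value_counts()
    return (
        int(counts.get(a + a, 0)),
        int(counts.get(a + b, 0)),
        int(counts.get(b + b, 0)),
    )


def compute_maf(counts: Sequence[int]) -> MAFResult:
    """Minor-allele frequency from genotype counts (n_AA, n_Aa, n_aa).

    Returns min(f, 1-f) where f is the frequency of the first allele,
    together with a flag identifying the minor allele.  Ties (f = 0.5)
    designate the second allele minor.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = n_aa + n_ab + n_bb
    if total == 0:
        raise ValueError("cannot compute MAF from all-zero genotype counts")
    f_first = (2 * n_aa + n_ab) / (2 * total)
    return MAFResult(min(f_first, 1.0 - f_first), f_first < 0.5)


def minor_allele_counts(table: pd.DataFrame, entry: SNPPanelEntry) -> np.ndarray:
    """Per-subject count in {0,1,2} of the empirically minor allele."""
    counts = genotype_counts(table, entry)
    minor = entry.alleles[0] if compute_maf(counts).minor_first else entry.alleles[1]
    return np.array(
        [g.count(minor) for g in table[entry.snp_id].astype(str)], dtype=np.int64
    )


def hwe_test(counts: Sequence[int]) -> HWEResult:
    """Pearson chi-square (1 df) of observed genotype counts against the
    Hardy-Weinberg expectation at the estimated allele frequency.

    Monomorphic SNPs return (0, 1) by convention: with a single observed
    allele the HWE expectation is met trivially.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    total = n_aa + n_ab + n_bb
    if total == 0:
        raise ValueError("cannot test HWE on zero genotypes")
    f = (2 * n_aa + n_ab) / (2 * total)
    if f in (0.0, 1.0):
        return HWEResult(0.0, 1.0)
    expected = np.array([f**2, 2 * f * (1 - f), (1 - f) ** 2]) * total
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(chi2, float(stats.chi2.sf(chi2, df=1)))


def filter_snps(
    table: pd.DataFrame,
    panel: Sequence[SNPPanelEntry],
    maf_threshold: float = MAF_EXCLUSION,
) -> tuple[list[str], list[dict]]:
    """Apply the two exclusion rules: MAF below threshold, and complete LD
    (r^2 = 1 between minor-allele-count vectors) with an earlier panel SNP.

    Returns (kept snp ids, exclusion log).  The LD tie-break keeps the
    first SNP in panel order.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 subjects to filter SNPs")
    kept: list[str] = []
    kept_vectors: list[tuple[str, np.ndarray]] = []
    log: list[dict] = []
    for entry in panel:
        counts = genotype_counts(table, entry)
        maf = compute_maf(counts).maf
        if maf < maf_threshold:
            log.append(
                {"snp_id": entry.snp_id, "reason": f"MAF<{maf_threshold}", "maf": maf}
            )
            continue
        vec = minor_allele_counts(table, entry).astype(float)
        ld_partner = None
        for other_id, other_vec in kept_vectors:
            v, w = vec - vec.mean(), other_vec - other_vec.mean()
            denom = float(np.sqrt((v**2).sum() * (w**2).sum()))
            if denom == 0:
                continue
            r = float((v * w).sum()) / denom
            if r**2 >= 1.0 - 1e-12:
                ld_partner = other_id
                break
        if ld_partner is not None:
            log.append(
                {"snp_id": entry.snp_id, "reason": "complete LD", "with": ld_partner}
            )
            continue
        kept.append(entry.snp_id)
        kept_vectors.append((entry.snp_id, vec))
    return kept, log


def model_selection_cutoff(rare_fraction: float = 0.10, decimals: int = 2) -> float:
    """Largest MAF q (at the given decimal precision) whose rare-homozygote
    HWE frequency q**2 does not exceed ``rare_fraction``.

    With the defaults this is 0.31 (0.31**2 = 0.0961 <= 0.10 < 0.32**2):
    below the cutoff fewer than 10% of subjects are expected to carry the
    rare homozygote, too few to estimate a separate genotype cell, so the
    recessive model is used instead.
    """
    step = 10.0**-decimals
    qs = np.round(np.arange(step, 0.5 + step / 2, step), decimals)
    ok = qs[qs**2 <= rare_fraction]
    return float(ok[-1])


def select_genetic_model(
    maf: float, snp_id: str = "", cutoff: float = MODEL_CUTOFF
) -> GeneticModelChoice:
    """Genotypic (2 df) at/above the cutoff, recessive (1 df) below it."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    if maf >= cutoff:
        return GeneticModelChoice(snp_id, maf, "genotypic", 2)
    return GeneticModelChoice(snp_id, maf, "recessive", 1)


# Orthogonal polynomial contrasts over the three minor-allele-count levels,
# normalised to unit length.
_LINEAR = {0: -1.0, 1: 0.0, 2: 1.0}
_QUADRATIC = {0: 1.0, 1: -2.0, 2: 1.0}


def code_genotypes(minor_counts: Sequence[int], model: str) -> np.ndarray:
    """Translate minor-allele counts into design columns.

    genotypic  -> two columns: linear contrast proportional to (-1, 0, 1)
                  and quadratic proportional to (1, -2, 1), each scaled to
                  unit norm over the three levels.
    recessive  -> one binary column, 1 for any minor-allele carrier.

    A genotypic request with fewer than 3 observed classes falls back to
    the single linear column with a warning; a monomorphic vector is an
    error because no contrast is estimable.
    """
    counts = np.asarray(minor_counts, dtype=np.int64)
    if counts.size == 0 or not np.isin(counts, [0, 1, 2]).all():
        raise ValueError("minor-allele counts must be a non-empty {0,1,2} sequence")
    n_classes = np.unique(counts).size
    if n_classes == 1:
        raise ValueError("all genotypes identical; no contrast is estimable")
    lin = np.array([_LINEAR[c] for c in counts]) / np.sqrt(2.0)
    if model == "recessive":
        return (counts > 0).astype(float)[:, None]
    if model == "genotypic":
        if n_classes < 3:
            warnings.warn(
                "genotypic model requested with <3 observed genotype classes; "
                "falling back to a 1-df linear contrast",
                stacklevel=2,
            )
            return lin[:, None]
        quad = np.array([_QUADRATIC[c] for c in counts]) / np.sqrt(6.0)
        return np.column_stack([lin, quad])
    raise ValueError(f"unknown genetic model {model!r}")


def chi2_2x2(table: Sequence[Sequence[float]]) -> dict:
    """Pearson chi-square for a 2x2 contingency table, without continuity
    correction, reporting both the plain statistic and the (N-1)/N-adjusted
    (Mantel-Haenszel) variant."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    n = t.sum()
    (a, b), (c, d) = t
    denom = t.sum(1).prod() * t.sum(0).prod()
    if denom == 0:
        raise ValueError("degenerate 2x2 table (empty row or column)")
    chi2 = n * (a * d - b * c) ** 2 / denom
    chi2_adj = chi2 * (n - 1) / n
    return {
        "chi2": float(chi2),
        "p": float(stats.chi2.sf(chi2, df=1)),
        "chi2_adjusted": float(chi2_adj),
        "p_adjusted": float(stats.chi2.sf(chi2_adj, df=1)),
    }


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-sample pooled-variance t-test from group summaries."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        return 0.0, 1.0
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), float(2 * stats.t.sf(abs(t), df))


def demographic_tests(
    phenotypes: pd.DataFrame,
    group_col: str = "group",
    gender_col: str = "gender",
    continuous: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variable case/control comparisons.

    Continuous variables get both a pooled-variance t-test and a
    Mann-Whitney U test (the latter is what the study reports for the
    non-normal neuropsychological scores).  Gender gets the 2x2 chi-square
    in both the plain-Pearson and (N-1)/N-adjusted flavours.
    """
    groups = sorted(phenotypes[group_col].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga = phenotypes[phenotypes[group_col] == groups[0]]
    gb = phenotypes[phenotypes[group_col] == groups[1]]
    if min(len(ga), len(gb)) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if continuous is None:
        skip = {group_col, gender_col, "subject_id"}
        continuous = [
            c
            for c in phenotypes.columns
            if c not in skip and pd.api.types.is_numeric_dtype(phenotypes[c])
        ]
    rows = []
    for col in continuous:
        x, y = ga[col].to_numpy(float), gb[col].to_numpy(float)
        t, pt = pooled_t(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
        if np.array_equal(np.sort(x), np.sort(y)):
            pu = 1.0  # identical samples: no evidence of a shift
        else:
            pu = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append(
            {"variable": col, "test": "t/mannwhitney", "t": t, "p_t": pt, "p_u": pu}
        )
    if gender_col in phenotypes.columns:
        tab = [
            [(ga[gender_col] == 1).sum(), (ga[gender_col] == 0).sum()],
            [(gb[gender_col] == 1).sum(), (gb[gender_col] == 0).sum()],
        ]
        res = chi2_2x2(tab)
        rows.append(
            {
                "variable": gender_col,
                "test": "chi2_2x2",
                "t": res["chi2"],
                "p_t": res["p"],
                "p_u": res["p_adjusted"],
            }
        )
    return pd.DataFrame(rows)
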