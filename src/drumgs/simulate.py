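"""Synthetic genotype/phenotype cohorts with a known additive architecture.

The generator emulates a post-QC genotyping-by-sequencing dataset from a
sibling-heavy aquaculture cohort: a few hundred individuals of two sexes,
tens of thousands of biallelic SNPs with MAF above 0.01, and quantitative
traits built from the additive model

    y = sex effect + sum_j dosage_ij * beta_j + e_i,

with the residual variance scaled so that the in-sample heritability hits a
target.  Because the QTL positions, effects and breeding values are
returned alongside the data, every downstream stage (QC, kinship, REML,
prediction, GWAS ranking, cross-validation) can be tested for parameter
recovery without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

__all__ = ["SimConfig", "TruthRecord", "simulate_genotypes", "simulate_phenotypes", "simulate_dataset"]


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror a small GBS-genotyped fish cohort: 371 individuals of
    two near-balanced sexes and biallelic SNPs with minor-allele frequency
    at least 0.01.  The trait architecture (50 QTL with normal effects) is
    a polygenic convention, configurable per study.
    """

    n_individuals: int = 371
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_qtl: int = 50
    qtl_effect_dist: str = "normal"  # or "laplace"
    h2_target: float = 0.5
    sex_effect: float = 0.0  # trait units added to males
    missing_rate: float = 0.0
    family_structure: tuple[int, int, int] | None = None  # (n_sires, n_dams, offspring per cross)
    seed: int = 0
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_markers <= 0:
            raise ValueError("n_individuals and n_markers must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.qtl_effect_dist not in ("normal", "laplace"):
            raise ValueError("qtl_effect_dist must be 'normal' or 'laplace'")


@dataclass
class TruthRecord:
    """Simulation ground truth used by parameter-recovery tests."""

    true_breeding_values: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    realized_h2: float
    residual_sd: float = field(default=0.0)


def _draw_frequencies(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    lo, hi = cfg.maf_range
    if lo == hi:
        return np.full(cfg.n_markers, lo)
    return rng.uniform(lo, hi, size=cfg.n_markers)


def _gene_drop(rng: np.random.Generator, cfg: SimConfig, freqs: np.ndarray) -> np.ndarray:
    """One generation of random sire x dam crosses with Mendelian segregation.

    Parents get Hardy-Weinberg haplotype pairs at the drawn frequencies;
    each offspring receives one allele sampled per locus from each parent.
    Reproduces the high-kinship, few-families structure of a hatchery cohort.
    """
    n_sires, n_dams, n_off = cfg.family_structure  # type: ignore[misc]
    if n_sires <= 0 or n_dams <= 0 or n_off <= 0:
        raise ValueError("family_structure counts must be positive")
    m = cfg.n_markers

    def haplos(n: int) -> np.ndarray:
        return (rng.random((n, 2, m)) < freqs).astype(np.int8)

    sires, dams = haplos(n_sires), haplos(n_dams)
    rows = []
    while len(rows) < cfg.n_individuals:
        s = rng.integers(n_sires)
        d = rng.integers(n_dams)
        for _ in range(n_off):
            pat = sires[s, rng.integers(0, 2, size=m), np.arange(m)]
            mat = dams[d, rng.integers(0, 2, size=m), np.arange(m)]
            rows.append(pat + mat)
            if len(rows) == cfg.n_individuals:
                break
    return np.asarray(rows, dtype=float)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw dosage genotypes under Hardy-Weinberg or family gene-dropping.

    Per marker an allele frequency is drawn uniformly from ``maf_range``;
    without ``family_structure`` the three genotype classes are sampled
    from their Hardy-Weinberg proportions, otherwise dosages come from
    Mendelian gene dropping through simulated parents.  Missing calls are
    then masked uniformly at random at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    freqs = _draw_frequencies(rng, config)
    if config.family_structure is None:
        u = rng.random((config.n_individuals, config.n_markers))
        # dosage counts the allele with frequency p: P(2)=p^2, P(1)=2p(1-p)
        p2 = freqs**2
        p1 = 2 * freqs * (1 - freqs)
        dos = np.where(u < p2, 2.0, np.where(u < p2 + p1, 1.0, 0.0))
    else:
        dos = _gene_drop(rng, config, freqs)
    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos = dos.copy()
        dos[mask] = np.nan
    n, m = dos.shape
    ids = [f"ind{i + 1}" for i in range(n)]
    mids = [f"snp{j + 1}" for j in range(m)]
    return GenotypeMatrix(
        dosages=dos,
        individual_ids=ids,
        marker_ids=mids,
        chrom=["1"] * m,
        pos=np.arange(1, m + 1) * 100,
        ref=["A"] * m,
        alt=["G"] * m,
    )


# With h2_target = 0 the heritable signal cannot be removed by zeroing the
# QTL effects (tests still need the true breeding values); instead the
# residual variance is made overwhelmingly dominant by this factor, so the
# realized h2 is ~1e-8 rather than exactly 0.
_H2_ZERO_INFLATION = 1e8


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Build phenotypes from the additive model at a target heritability.

    QTL effects are drawn first, genetic values g computed from centered
    QTL dosages, then the residual standard deviation is set to
    ``sqrt(var(g) * (1 - h2) / h2)`` so the in-sample heritability matches
    ``h2_target`` in expectation.  Sexes are assigned near 1:1 and the sex
    effect is added to males.
    """
    if genotypes.has_missing:
        raise ValueError("phenotype simulation requires complete genotypes; impute first")
    cfg = config
    if cfg.h2_target == 1.0 and cfg.n_qtl == 0:
        raise ValueError("h2_target=1 with zero QTL has no genetic variance to carry the trait")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    n, m = genotypes.dosages.shape

    qtl_idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    if cfg.qtl_effect_dist == "normal":
        effects = rng.standard_normal(cfg.n_qtl)
    else:
        effects = rng.laplace(size=cfg.n_qtl)
    qtl_dos = genotypes.dosages[:, qtl_idx]
    centered = qtl_dos - qtl_dos.mean(axis=0)
    g = centered @ effects

    var_g = float(np.var(g))
    if cfg.h2_target == 1.0:
        resid_sd = 0.0
    elif cfg.h2_target == 0.0:
        resid_sd = float(np.sqrt(max(var_g, 1.0) * _H2_ZERO_INFLATION))
    else:
        if var_g == 0:
            raise ValueError("genetic variance is zero; cannot scale residuals to h2_target")
        resid_sd = float(np.sqrt(var_g * (1 - cfg.h2_target) / cfg.h2_target))
    e = resid_sd * rng.standard_normal(n)

    sex = np.array(["M", "F"] * (n // 2 + 1))[:n]  # near 1:1, |#M - #F| <= 1
    y = g + e + np.where(sex == "M", cfg.sex_effect, 0.0)

    var_e = float(np.var(e))
    realized = var_g / (var_g + var_e) if (var_g + var_e) > 0 else 0.0
    pheno = pd.DataFrame({"id": genotypes.individual_ids, "sex": sex, cfg.trait_name: y})
    truth = TruthRecord(
        true_breeding_values=g,
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        realized_h2=realized,
        residual_sd=resid_sd,
    )
    return pheno, truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Convenience: genotypes + phenotypes in one call.

    With ``missing_rate > 0`` the phenotypes are built from the complete
    (pre-masking) dosages, so the returned truth is exact while the
    genotype matrix still carries the missing calls for the QC stage.
    """
    from dataclasses import replace as _replace

    geno = simulate_genotypes(config)
    complete = geno
    if config.missing_rate > 0:
        complete = simulate_genotypes(_replace(config, missing_rate=0.0))
    pheno, truth = simulate_phenotypes(complete, config)
    return geno, pheno, truth
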