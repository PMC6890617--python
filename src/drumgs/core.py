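"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as an individuals x markers dosage matrix of additive
codes {0, 1, 2} (count of the dosage-counted allele), with ``NaN`` marking
missing calls.  Phenotypes travel as a plain :class:`pandas.DataFrame` with
an ``id`` column, a ``sex`` column coded ``M``/``F`` and one numeric column
per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "validate_phenotypes", "PHENO_ID", "PHENO_SEX"]

PHENO_ID = "id"
PHENO_SEX = "sex"


@dataclass
class GenotypeMatrix:
    """Dosage-coded biallelic SNP genotypes for a cohort.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_individuals, n_markers)`` with entries in
        ``{0, 1, 2}`` or ``NaN`` for missing calls.  Imputed matrices may
        hold fractional dosages.
    individual_ids, marker_ids
        Row and column labels.
    chrom, pos, ref, alt
        Optional per-marker metadata (used when writing VCF).
    """

    dosages: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    ref: list[str] | None = None
    alt: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x markers array")
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError(f"{len(self.individual_ids)} individual ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        obs = self.dosages[np.isfinite(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the dosage-counted allele.

        Computed from non-missing calls only; a marker with no observed
        call yields ``NaN``.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_rates(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_markers(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            dosages=self.dosages[:, index],
            marker_ids=[self.marker_ids[i] for i in index],
            chrom=None if self.chrom is None else [self.chrom[i] for i in index],
            pos=None if self.pos is None else np.asarray(self.pos)[index],
            ref=None if self.ref is None else [self.ref[i] for i in index],
            alt=None if self.alt is None else [self.alt[i] for i in index],
        )

    def subset_individuals(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            dosages=self.dosages[index, :],
            individual_ids=[self.individual_ids[i] for i in index],
        )


def validate_phenotypes(pheno: pd.DataFrame, traits: list[str] | None = None) -> None:
    """Check the phenotype-table contract: id, sex in {M, F}, numeric traits."""
    for col in (PHENO_ID, PHENO_SEX):
        if col not in pheno.columns:
            raise ValueError(f"phenotype table lacks required column '{col}'")
    bad = set(pheno[PHENO_SEX].unique()) - {"M", "F"}
    if bad:
        raise ValueError(f"sex column must be coded M/F, found {sorted(bad)}")
    for t in traits or []:
        if t not in pheno.columns:
            raise ValueError(f"trait column '{t}' not in phenotype table")
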