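"""Genomic relationship matrix (VanRaden method 1) and conditioning.

G = (B - 2P)(B - 2P)' / (2 * sum_j p_j (1 - p_j)),

where B is the individuals x markers dosage matrix, p_j the frequency of
the dosage-counted allele at marker j and 2P the matrix of column means
under those frequencies.  G estimates realized additive kinship; it is the
covariance structure of the genetic values in the GBLUP mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

__all__ = ["GRM", "vanraden_grm", "blend_grm"]


@dataclass
class GRM:
    """A genomic relationship matrix with its construction ingredients.

    ``centering_freqs`` and ``denominator`` are kept so the matrix is
    recheckable against its defining formula and so that marker-effect
    models can use the identical centering and scale.
    """

    matrix: np.ndarray
    centering_freqs: np.ndarray
    denominator: float
    individual_ids: list[str]

    @property
    def n_markers_used(self) -> int:
        return self.centering_freqs.size

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.matrix, index=self.individual_ids, columns=self.individual_ids).to_csv(
            path, sep="\t", index_label="id"
        )


def vanraden_grm(genotypes: GenotypeMatrix, freqs: np.ndarray | None = None) -> GRM:
    """Build G from complete dosages.

    Frequencies default to the observed sample frequencies of the
    dosage-counted allele; markers monomorphic under the frequencies used
    are rejected (run QC first), since they contribute nothing to the
    denominator and a zero-variance column to the numerator.
    """
    if genotypes.has_missing:
        raise ValueError("GRM requires complete dosages; impute missing calls first")
    B = genotypes.dosages
    p = genotypes.allele_frequencies() if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (genotypes.n_markers,):
        raise ValueError("freqs must give one frequency per marker")
    if np.any((p <= 0) | (p >= 1)):
        bad = int(np.flatnonzero((p <= 0) | (p >= 1))[0])
        raise ValueError(
            f"marker '{genotypes.marker_ids[bad]}' is monomorphic under the centering "
            "frequencies; run QC (MAF filter) before building the GRM"
        )
    W = B - 2.0 * p
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry against rounding
    return GRM(matrix=G, centering_freqs=p, denominator=denom, individual_ids=list(genotypes.individual_ids))


def centered_dosages(genotypes: GenotypeMatrix, freqs: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Centered dosage matrix W = B - 2P and the GRM denominator 2*sum p(1-p).

    Shared by RRBLUP and the Bayesian samplers so that marker-effect models
    and GBLUP operate on the identical centering and scale.
    """
    if genotypes.has_missing:
        raise ValueError("centered dosages require complete genotypes")
    p = genotypes.allele_frequencies() if freqs is None else np.asarray(freqs, dtype=float)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    return genotypes.dosages - 2.0 * p, denom


def blend_grm(grm: GRM, epsilon: float = 0.01) -> GRM:
    """Shrink G toward the identity: (1 - eps) G + eps I.

    Guarantees positive definiteness for any positive semi-definite input
    (the spectrum shifts to >= eps), which the mixed-model equations need
    because G is rank-deficient whenever individuals outnumber markers or
    share exact linear dependencies.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    n = grm.matrix.shape[0]
    blended = (1.0 - epsilon) * grm.matrix + epsilon * np.eye(n)
    return GRM(
        matrix=blended,
        centering_freqs=grm.centering_freqs,
        denominator=grm.denominator,
        individual_ids=list(grm.individual_ids),
    )


def grm_from_tsv(path: str) -> GRM:
    """Read a GRM written by :meth:`GRM.to_tsv` (frequencies not recoverable)."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    return GRM(
        matrix=df.to_numpy(float),
        centering_freqs=np.array([]),
        denominator=float("nan"),
        individual_ids=[str(i) for i in df.index],
    )
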