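"""Marker quality control: MAF / missingness / Hardy-Weinberg filters.

Mirrors the standard pre-analysis SNP filter chain of PLINK-style QC
(``--maf --geno --hwe`` on biallelic calls) plus a naive per-marker
imputation used in place of haplotype-based imputation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

__all__ = ["QCParams", "hwe_exact_test", "filter_markers", "impute_missing"]


@dataclass
class QCParams:
    """Thresholds of the marker filter chain.

    Defaults are the common GBS QC choice: minor-allele frequency >= 0.01,
    per-marker missingness <= 0.1, Hardy-Weinberg exact-test p >= 1e-5,
    biallelic markers only.
    """

    maf_min: float = 0.01
    missing_max: float = 0.1
    hwe_p_min: float = 1e-5
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test (Levene-Haldane).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    the observed one (plain exact test, no mid-p correction).  The
    unnormalised probabilities are exact integers

        w(k) = n! / (n1! k! n2!) * 2^k,

    with n1/n2 the homozygote counts implied by k, so ties are resolved
    exactly and the returned p-value carries only one final rounding.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count is zero")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # copies of the rarer allele
    if rare == 0:
        return 1.0  # monomorphic: only one configuration possible

    def weight(k: int) -> int:
        n1 = (rare - k) // 2
        n2 = n - n1 - k
        return math.factorial(n) // (math.factorial(n1) * math.factorial(k) * math.factorial(n2)) * (2**k)

    ks = range(rare % 2, rare + 1, 2)
    weights = {k: weight(k) for k in ks}
    w_obs = weights[n_Aa]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(num / sum(weights.values()))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[np.isfinite(col)]
    if not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
        raise ValueError("HWE testing requires raw integer dosage calls in {0, 1, 2}")
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def filter_markers(
    genotypes: GenotypeMatrix, params: QCParams | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the MAF -> missingness -> HWE filter chain.

    Returns the filtered matrix and a per-marker report stating MAF,
    missing rate, HWE p-value and — for dropped markers — the first rule
    that failed, in the fixed order MAF, missingness, HWE (deterministic
    reports regardless of how many rules a marker violates).
    """
    params = params or QCParams()
    dos = genotypes.dosages
    n, m = dos.shape
    freqs = genotypes.allele_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    miss = genotypes.missing_rates()

    reasons: list[str | None] = [None] * m
    hwe_p = np.full(m, np.nan)
    keep = np.ones(m, dtype=bool)
    for j in range(m):
        if not np.isfinite(maf[j]) or maf[j] < params.maf_min:
            keep[j], reasons[j] = False, "maf"
            continue
        if miss[j] > params.missing_max:
            keep[j], reasons[j] = False, "missing"
            continue
        hwe_p[j] = hwe_exact_test(*_genotype_counts(dos[:, j]))
        if hwe_p[j] < params.hwe_p_min:
            keep[j], reasons[j] = False, "hwe"

    report = pd.DataFrame(
        {
            "marker_id": genotypes.marker_ids,
            "kept": keep,
            "drop_reason": reasons,
            "maf": maf,
            "missing_rate": miss,
            "hwe_p": hwe_p,
        }
    )
    if not keep.any():
        warnings.warn("all markers removed by QC filters", stacklevel=2)
    return genotypes.subset_markers(keep), report


def impute_missing(genotypes: GenotypeMatrix, mode: str = "mean") -> GenotypeMatrix:
    """Fill missing calls per marker with the mean or modal dosage.

    ``mean`` fills the arithmetic mean of observed dosages (a real number);
    ``mode`` fills the most frequent observed dosage, breaking ties toward
    the lower dosage.  A marker with no observed call raises, naming it.
    """
    if mode not in ("mean", "mode"):
        raise ValueError("mode must be 'mean' or 'mode'")
    if not genotypes.has_missing:
        return genotypes
    dos = genotypes.dosages.copy()
    all_missing = np.isnan(dos).all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        raise ValueError(f"marker '{genotypes.marker_ids[j]}' has no observed calls")
    for j in np.flatnonzero(np.isnan(dos).any(axis=0)):
        col = dos[:, j]
        obs = col[np.isfinite(col)]
        if mode == "mean":
            fill = obs.mean()
        else:
            counts = [(obs == d).sum() for d in (0.0, 1.0, 2.0)]
            fill = float(int(np.argmax(counts)))  # argmax takes the first (lowest) tie
        col[np.isnan(col)] = fill
    from dataclasses import replace

    return replace(genotypes, dosages=dos)
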