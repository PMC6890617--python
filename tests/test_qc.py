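"""QC filters: exact HWE test, filter chain, naive imputation."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drumgs import GenotypeMatrix, QCParams, filter_markers, hwe_exact_test, impute_missing


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Full enumeration of the Levene-Haldane conditional distribution with
    exact rational arithmetic; independent of the implementation."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    rare = min(nA, na)

    def prob(k):
        n_hom_rare = (rare - k) // 2
        n_hom_common = n - n_hom_rare - k
        num = Fraction(factorial(n), factorial(n_hom_rare) * factorial(k) * factorial(n_hom_common)) * 2**k
        den = Fraction(factorial(2 * n), factorial(nA) * factorial(na))
        return num / den

    ks = list(range(rare % 2, rare + 1, 2))
    probs = {k: prob(k) for k in ks}
    assert sum(probs.values()) == 1
    return float(sum(p for p in probs.values() if p <= probs[n_Aa]))


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(25, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 13) == 1.0


def test_hwe_all_heterozygous_matches_enumeration():
    assert hwe_exact_test(0, 10, 0) == pytest.approx(hwe_oracle(0, 10, 0), abs=1e-12)


def test_hwe_perfect_proportions_near_one():
    assert hwe_exact_test(25, 50, 25) > 0.9


def test_hwe_matches_enumeration_everywhere_small():
    """Exhaustive agreement with the rational-arithmetic oracle, n <= 12."""
    for n in range(1, 13):
        for n_AA in range(n + 1):
            for n_Aa in range(n - n_AA + 1):
                n_aa = n - n_AA - n_Aa
                assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                    hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12
                )


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 120), st.integers(0, 120), st.integers(0, 120))
def test_hwe_matches_enumeration_property(n_AA, n_Aa, n_aa):
    if n_AA + n_Aa + n_aa == 0:
        with pytest.raises(ValueError):
            hwe_exact_test(n_AA, n_Aa, n_aa)
        return
    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
        hwe_oracle(n_AA, n_Aa, n_aa), rel=1e-10, abs=1e-12
    )


def _matrix_from_columns(cols):
    dos = np.column_stack(cols).astype(float)
    n, m = dos.shape
    return GenotypeMatrix(
        dosages=dos,
        individual_ids=[f"i{k}" for k in range(n)],
        marker_ids=[f"m{k}" for k in range(m)],
    )


def test_filter_chain_on_constructed_counts():
    """One marker violating each rule, three passing; hand-checked counts."""
    n = 40
    passing = [1.0] * 20 + [0.0] * 10 + [2.0] * 10          # maf 0.5, HWE p moderate
    hwe_ok = [0.0] * 10 + [1.0] * 20 + [2.0] * 10           # perfect HWE
    passing3 = [0.0] * 30 + [1.0] * 9 + [2.0] * 1           # maf 0.1375, in HWE-ish
    monomorphic = [0.0] * n                                  # maf 0 -> dropped by MAF
    gappy = [np.nan] * 6 + [0.0] * 17 + [1.0] * 17           # 15% missing -> missingness
    het_excess = [1.0] * n                                   # all het -> HWE failure
    gm = _matrix_from_columns([passing, monomorphic, hwe_ok, gappy, het_excess, passing3])
    kept, report = filter_markers(gm, QCParams())
    assert kept.marker_ids == ["m0", "m2", "m5"]
    assert report.set_index("marker_id")["drop_reason"].to_dict() == {
        "m0": None, "m1": "maf", "m2": None, "m3": "missing", "m4": "hwe", "m5": None,
    }
    assert hwe_exact_test(0, n, 0) < 1e-5  # confirms the het-excess column fails HWE


def test_filter_is_idempotent(small_dataset):
    _, geno, _, _ = small_dataset
    once, _ = filter_markers(geno)
    twice, rep = filter_markers(once)
    assert twice.marker_ids == once.marker_ids
    assert rep["kept"].all()


def test_all_markers_dropped_warns_not_raises():
    gm = _matrix_from_columns([[0.0] * 10, [2.0] * 10])
    with pytest.warns(UserWarning):
        kept, _ = filter_markers(gm)
    assert kept.n_markers == 0


def test_mean_imputation_value_and_identity():
    gm = _matrix_from_columns([[0.0, 2.0, np.nan]])
    out = impute_missing(gm, "mean")
    assert out.dosages[2, 0] == pytest.approx(1.0)
    complete = _matrix_from_columns([[0.0, 1.0, 2.0]])
    assert impute_missing(complete, "mean") is complete


def test_mode_imputation_tie_goes_low():
    gm = _matrix_from_columns(
        [[0.0, 0.0, 1.0, np.nan], [0.0, 1.0, 1.0, np.nan], [0.0, 1.0, np.nan, np.nan]]
    )
    out = impute_missing(gm, "mode")
    assert out.dosages[3, 0] == 0.0   # 0 twice vs 1 once
    assert out.dosages[3, 1] == 1.0   # 1 twice vs 0 once
    assert out.dosages[2, 2] == 0.0   # exact tie resolved toward lower dosage


def test_mean_imputation_preserves_marker_means(small_dataset):
    cfg, *_ = small_dataset
    from dataclasses import replace

    from drumgs import simulate_genotypes

    gm = simulate_genotypes(replace(cfg, missing_rate=0.1))
    out = impute_missing(gm, "mean")
    np.testing.assert_allclose(
        np.nanmean(gm.dosages, axis=0), out.dosages.mean(axis=0), atol=1e-12
    )
    assert not out.has_missing


def test_all_missing_marker_named_in_error():
    gm = _matrix_from_columns([[0.0, 1.0], [np.nan, np.nan]])
    with pytest.raises(ValueError, match="m1"):
        impute_missing(gm)
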