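"""Cross-validation harness and summary arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

from drumgs import (
    ReferenceSizeQuery,
    SimConfig,
    cross_validate,
    derive_ratio_traits,
    expected_accuracy,
    method_spread,
    panel_curve,
    predictive_ability,
    required_reference_size,
    simulate_dataset,
    summarize_phenotypes,
)


def test_predictive_ability_examples():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    assert predictive_ability(v, v) == pytest.approx(1.0)
    assert predictive_ability(v, -v) == pytest.approx(-1.0)
    assert predictive_ability(v, np.array([2.0, 1.0, 4.0, 3.0])) == pytest.approx(0.6)
    with pytest.raises(ValueError):
        predictive_ability(v, np.zeros(4))
    with pytest.raises(ValueError):
        predictive_ability(v[:2], v[:2])


def test_oracle_predictor_perfect(small_dataset):
    _, geno, pheno, _ = small_dataset
    cv = cross_validate(geno, pheno, "trait", "oracle", n_reps=5, seed=1)
    assert cv.replicate_abilities == [pytest.approx(1.0)] * 5


def test_cv_deterministic_and_recomputable(small_dataset):
    _, geno, pheno, _ = small_dataset
    a = cross_validate(geno, pheno, "trait", "GBLUP", n_reps=4, seed=9)
    b = cross_validate(geno, pheno, "trait", "GBLUP", n_reps=4, seed=9)
    assert a.replicate_abilities == b.replicate_abilities
    arr = np.asarray(a.replicate_abilities)
    assert a.mean_ability == pytest.approx(float(arr.mean()))
    assert a.se_ability == pytest.approx(float(arr.std(ddof=1) / math.sqrt(arr.size)))
    assert (a.n_reference, a.n_testing) == (180, 20)


def test_cv_rejects_tiny_test_set(small_dataset):
    _, geno, pheno, _ = small_dataset
    with pytest.raises(ValueError):
        cross_validate(geno, pheno, "trait", "oracle", n_reps=2, test_fraction=0.005)


def test_rrblup_and_gblup_cv_agree(small_dataset):
    _, geno, pheno, _ = small_dataset
    g = cross_validate(geno, pheno, "trait", "GBLUP", n_reps=3, seed=2)
    r = cross_validate(geno, pheno, "trait", "RRBLUP", n_reps=3, seed=2)
    # same splits, equivalent models up to GRM blending
    assert g.mean_ability == pytest.approx(r.mean_ability, abs=0.03)


def test_reference_fraction_monotone():
    """Bigger reference sets help: mean GBLUP ability rises with the
    training fraction on simulated data."""
    geno, pheno, _ = simulate_dataset(
        SimConfig(n_individuals=250, n_markers=800, h2_target=0.6, seed=33)
    )
    means = [
        cross_validate(
            geno, pheno, "trait", "GBLUP", n_reps=15, test_fraction=f, seed=5
        ).mean_ability
        for f in (0.5, 0.3, 0.1)
    ]
    assert means[0] < means[-1]


def test_method_spread_published_columns():
    bl = {
        "BayesA": 0.361,
        "BayesB": {"pi=0.001": 0.240, "pi=0.01": 0.334, "pi=0.1": 0.362},
        "BayesCpi": 0.396, "MMixp": 0.378, "RRBLUP": 0.380, "GBLUP": 0.378, "CNN": 0.392,
    }
    diff, pct = method_spread(bl)
    assert (round(diff, 3), round(pct, 1)) == (0.035, 8.8)


def test_method_spread_invariants():
    assert method_spread({"a": 0.3, "b": 0.3}) == (0.0, 0.0)
    d1 = method_spread({"a": 0.2, "b": 0.4, "c": 0.3})
    d2 = method_spread({"c": 0.3, "a": 0.2, "b": 0.4})
    assert d1 == d2
    with pytest.raises(ValueError):
        method_spread({"only": 0.5})


def test_summarize_phenotypes_welch_and_stars():
    pheno = pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(6)],
            "sex": ["M", "M", "M", "F", "F", "F"],
            "t1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "t2": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
        }
    )
    out = summarize_phenotypes(pheno, ["t1", "t2"]).set_index("trait")
    # hand-computed Welch t for (1,2,3) vs (4,5,6): means 2 and 5, s^2 = 1
    t_hand = (2.0 - 5.0) / math.sqrt(1.0 / 3 + 1.0 / 3)
    assert out.loc["t1", "t_stat"] == pytest.approx(t_hand)
    assert out.loc["t2", "t_stat"] == pytest.approx(0.0)
    assert out.loc["t2", "significance"] == "(-)"


def test_star_thresholds():
    from drumgs.evaluate import _stars

    assert _stars(0.005) == "*"
    assert _stars(0.0005) == "**"
    assert _stars(0.02) == "(-)"
    assert _stars(0.01) == "(-)"  # boundary: strictly below 0.01 earns a star


def test_ratio_trait_definitions():
    out = derive_ratio_traits(
        body_weight_g=np.array([100.0]),
        bladder_weight_g=np.array([0.72]),
        gonad_weight_g=np.array([1.11]),
        body_length_mm=np.array([210.0]),
        body_height_mm=np.array([70.0]),
    )
    assert out.loc[0, "SBI"] == pytest.approx(0.72)
    assert out.loc[0, "LHR"] == pytest.approx(3.0)
    assert out.loc[0, "GWI"] == pytest.approx(1.11)
    with pytest.raises(ValueError):
        derive_ratio_traits(
            np.array([0.0]), np.array([1.0]), np.array([1.0]), np.array([1.0]), np.array([1.0])
        )


def test_required_reference_size_formula():
    q = ReferenceSizeQuery(h2=0.5, Me=1_000, target_accuracy=0.8)
    assert required_reference_size(q) == 3_556
    # cross-check by pushing N back through the forward accuracy formula
    assert expected_accuracy(3_556, 0.5, 1_000) >= 0.8
    assert expected_accuracy(3_555, 0.5, 1_000) < 0.8
    assert required_reference_size(ReferenceSizeQuery(h2=0.5, Me=1_000, target_accuracy=0.0)) == 0


def test_required_reference_size_decreasing_in_h2():
    sizes = [
        required_reference_size(ReferenceSizeQuery(h2=h, Me=500, target_accuracy=0.7))
        for h in (0.2, 0.4, 0.6, 0.8)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_panel_curve_full_size_modes_coincide(small_dataset):
    _, geno, pheno, _ = small_dataset
    m = geno.n_markers
    out = panel_curve(geno, pheno, "trait", sizes=[m], n_reps=3, seed=4)
    means = out.set_index("mode")["mean_ability"]
    assert means["informative"] == pytest.approx(means["random"], abs=1e-10)


def test_tiny_random_panels_carry_no_signal():
    geno, pheno, _ = simulate_dataset(
        SimConfig(n_individuals=250, n_markers=1_000, h2_target=0.5, seed=55)
    )
    out = panel_curve(geno, pheno, "trait", sizes=[5], modes=("random",), n_reps=20, seed=6)
    assert abs(out.loc[0, "mean_ability"]) < 0.1
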