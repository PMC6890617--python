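"""GEBV prediction: MME solutions, ridge identities, Gibbs samplers."""

import numpy as np
import pytest

from drumgs import (
    BayesHyper,
    GenotypeMatrix,
    ModelMatrices,
    SimConfig,
    VarianceComponents,
    bayes_sampler,
    bayes_scale_param,
    blend_grm,
    build_model_matrices,
    centered_dosages,
    gblup_predict,
    reml_fit,
    rrblup_fit,
    simulate_dataset,
    vanraden_grm,
)
from drumgs.kinship import GRM


def _vc(sg2, se2):
    h2 = sg2 / (sg2 + se2)
    return VarianceComponents(sg2, se2, h2, 0, 0, 0, 0.0, 0, True)


def test_gblup_matches_hand_solved_mme():
    """3 individuals, identity-blended G, one fixed effect: the V-form
    solution must equal the explicitly inverted mixed-model equations."""
    G = np.array([[1.0, 0.2, 0.1], [0.2, 1.0, 0.3], [0.1, 0.3, 1.0]])
    grm = GRM(matrix=G, centering_freqs=np.array([0.5]), denominator=0.5,
              individual_ids=["a", "b", "c"])
    y = np.array([1.0, 2.0, 4.0])
    X = np.ones((3, 1))
    vc = _vc(2.0, 1.0)
    mm = ModelMatrices(y=y, X=X, Z=np.eye(3), grm=grm)
    res = gblup_predict(mm, vc, epsilon=None)
    lam = vc.shrinkage_lambda
    lhs = np.block([[X.T @ X, X.T], [X, np.eye(3) + np.linalg.inv(G) * lam]])
    rhs = np.concatenate([X.T @ y, y])
    sol = np.linalg.solve(lhs, rhs)
    np.testing.assert_allclose(res.fixed_effects, sol[:1], atol=1e-10)
    np.testing.assert_allclose(res.gebv, sol[1:], atol=1e-10)


def test_complete_shrinkage_limit():
    """h2 -> 0 (huge lambda) drives every GEBV to zero."""
    G = np.eye(4)
    grm = GRM(matrix=G, centering_freqs=np.array([0.5]), denominator=0.5,
              individual_ids=list("abcd"))
    mm = ModelMatrices(y=np.array([3.0, -1.0, 2.0, 0.5]), X=np.ones((4, 1)), Z=np.eye(4), grm=grm)
    res = gblup_predict(mm, _vc(1e-10, 1.0), epsilon=None)
    assert np.abs(res.gebv).max() < 1e-8


def test_gblup_rrblup_equivalence(small_dataset, small_grm):
    _, geno, pheno, _ = small_dataset
    mm = build_model_matrices(pheno, "trait", small_grm)
    vc = reml_fit(build_model_matrices(pheno, "trait", blend_grm(small_grm)))
    res_g = gblup_predict(mm, vc, epsilon=None)
    W, denom = centered_dosages(geno)
    _, res_r = rrblup_fit(mm.y, mm.X, W, vc.shrinkage_lambda * denom)
    diff = res_g.gebv - res_r.gebv
    assert np.corrcoef(res_g.gebv, res_r.gebv)[0, 1] >= 0.9999
    assert np.abs(diff - diff.mean()).max() < 1e-6


def test_scalar_ridge_closed_form():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(20)
    x -= x.mean()
    y = 0.8 * x + rng.standard_normal(20)
    lam = 3.7
    beta, _ = rrblup_fit(y, np.zeros((20, 0)), x[:, None], lam)
    assert beta[0] == pytest.approx(float(x @ y / (x @ x + lam)), rel=1e-12)


def test_rrblup_matches_dense_normal_equations():
    rng = np.random.default_rng(2)
    W = rng.standard_normal((8, 5))
    X = np.column_stack([np.ones(8), rng.standard_normal(8)])
    y = rng.standard_normal(8)
    lam = 1.3
    beta, res = rrblup_fit(y, X, W, lam)
    lhs = np.block([[X.T @ X, X.T @ W], [W.T @ X, W.T @ W + lam * np.eye(5)]])
    sol = np.linalg.solve(lhs, np.concatenate([X.T @ y, W.T @ y]))
    np.testing.assert_allclose(res.fixed_effects, sol[:2], atol=1e-10)
    np.testing.assert_allclose(beta, sol[2:], atol=1e-10)


def test_rrblup_zero_penalty_is_ols():
    rng = np.random.default_rng(3)
    W = rng.standard_normal((30, 4))
    y = rng.standard_normal(30)
    beta, _ = rrblup_fit(y, np.ones((30, 1)), W, 0.0)
    Xfull = np.column_stack([np.ones(30), W])
    ols = np.linalg.lstsq(Xfull, y, rcond=None)[0]
    np.testing.assert_allclose(beta, ols[1:], atol=1e-8)


def test_rrblup_rejects_empty_markers():
    with pytest.raises(ValueError):
        rrblup_fit(np.ones(5), np.ones((5, 1)), np.ones((5, 0)), 1.0)


def test_bayes_scale_param_arithmetic():
    # plug-in: sb2 = 1/(0.01*100) = 1, s2 = 1 * 2.2/4.2
    s2 = bayes_scale_param(1.0, 4.2, 0.01, 100.0)
    assert s2 == pytest.approx(2.2 / 4.2, rel=1e-12)
    # prior-mean identity: E[sb2] = v s2 / (v - 2) must return the target
    assert 4.2 * s2 / 2.2 == pytest.approx(1.0, rel=1e-12)
    # v -> infinity: s2 -> sb2
    assert bayes_scale_param(1.0, 1e9, 0.01, 100.0) == pytest.approx(1.0, rel=1e-6)
    # pi = 1 reproduces the all-markers (BayesA) scale
    assert bayes_scale_param(2.0, 4.2, 1.0, 100.0) == pytest.approx(0.02 * 2.2 / 4.2, rel=1e-12)
    with pytest.raises(ValueError):
        bayes_scale_param(1.0, 2.0, 0.01, 100.0)


@pytest.fixture(scope="module")
def sampler_data(small_dataset):
    _, geno, pheno, truth = small_dataset
    W, denom = centered_dosages(geno)
    y = pheno["trait"].to_numpy()
    X = np.column_stack([np.ones(y.size), (pheno["sex"] == "M").to_numpy(float)])
    sg2 = float(np.var(truth.true_breeding_values))
    return y, X, W, denom, sg2


def test_bayesb_pi_one_collapses_to_bayesa(sampler_data):
    y, X, W, denom, sg2 = sampler_data
    s2 = bayes_scale_param(sg2, 4.2, 1.0, denom)
    hyper = dict(v=4.2, s2=s2, n_iter=2_000, burn_in=500, thin=5, seed=11)
    _, res_a = bayes_sampler(y, X, W, "BayesA", BayesHyper(pi=1.0, **hyper))
    _, res_b = bayes_sampler(y, X, W, "BayesB", BayesHyper(pi=1.0, **hyper))
    assert np.corrcoef(res_a.gebv, res_b.gebv)[0, 1] >= 0.95


def test_chain_determinism(sampler_data):
    y, X, W, denom, sg2 = sampler_data
    s2 = bayes_scale_param(sg2, 4.2, 0.1, denom)
    hyper = BayesHyper(pi=0.1, s2=s2, n_iter=600, burn_in=100, thin=2, seed=42)
    p1, r1 = bayes_sampler(y, X, W, "BayesB", hyper)
    p2, r2 = bayes_sampler(y, X, W, "BayesB", hyper)
    np.testing.assert_array_equal(p1.effect_mean, p2.effect_mean)
    np.testing.assert_array_equal(r1.gebv, r2.gebv)


def test_marker_order_permutation_stable(sampler_data):
    """Posterior-mean GEBVs agree within Monte-Carlo error when the marker
    columns are permuted (chains differ realization-wise)."""
    y, X, W, denom, sg2 = sampler_data
    s2 = bayes_scale_param(sg2, 4.2, 1.0, denom)
    hyper = BayesHyper(pi=1.0, s2=s2, n_iter=3_000, burn_in=1_000, thin=4, seed=5)
    rng = np.random.default_rng(0)
    perm = rng.permutation(W.shape[1])
    _, res = bayes_sampler(y, X, W, "BayesA", hyper)
    _, res_p = bayes_sampler(y, X, W[:, perm], "BayesA", hyper)
    assert np.corrcoef(res.gebv, res_p.gebv)[0, 1] > 0.98


def test_all_samplers_shrink_null_trait(sampler_data):
    """On a pure-noise phenotype every model's GEBV variance collapses
    relative to the phenotype variance."""
    y, X, W, denom, _ = sampler_data
    rng = np.random.default_rng(9)
    noise = rng.standard_normal(y.size)
    for model in ("BayesA", "BayesB", "BayesCpi", "MMixp"):
        s2 = bayes_scale_param(0.01 * float(np.var(noise)), 4.2, 1.0, denom)
        hyper = BayesHyper(pi=0.05 if model == "BayesB" else 0.5, s2=s2,
                           n_iter=1_500, burn_in=500, thin=2, seed=3)
        _, res = bayes_sampler(noise, X, W, model, hyper)
        assert np.var(res.gebv) < 0.2 * np.var(noise)


def test_mmixp_tracks_polygenic_signal(sampler_data):
    y, X, W, denom, sg2 = sampler_data
    s2 = bayes_scale_param(sg2, 4.2, 1.0, denom)
    hyper = BayesHyper(pi=0.5, s2=s2, n_iter=2_000, burn_in=500, thin=5, seed=21)
    _, res = bayes_sampler(y, X, W, "MMixp", hyper)
    assert np.corrcoef(res.gebv, y)[0, 1] > 0.5


def test_unknown_model_rejected(sampler_data):
    y, X, W, *_ = sampler_data
    with pytest.raises(ValueError):
        bayes_sampler(y, X, W, "BayesR", BayesHyper())
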