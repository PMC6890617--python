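"""Genomic breeding-value prediction: GBLUP, RRBLUP and Bayesian samplers.

GBLUP solves the mixed-model equations

    [ X'X        X'Z      ] [a]   [X'y]
    [ Z'X   Z'Z + G^-1 l  ] [g] = [Z'y],      l = se2/sg2 = (1-h2)/h2,

jointly over training and prediction individuals (prediction individuals
simply have no records in Z), so their genetic values are carried by the
relationship matrix.  RRBLUP is the equivalent marker-effect ridge
formulation; when the marker penalty is l * (2 sum p(1-p)) and the
centering matches the GRM, the two produce identical GEBVs.  The Bayesian
alphabet replaces the common ridge prior with heavy-tailed or
spike-and-slab marker priors sampled by single-site Gibbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _gibbs
from .kinship import GRM, blend_grm
from .varcomp import ModelMatrices, VarianceComponents

__all__ = [
    "GEBVResult",
    "BayesHyper",
    "MarkerEffectsPosterior",
    "gblup_predict",
    "rrblup_fit",
    "bayes_scale_param",
    "bayes_sampler",
]

_MODEL_CODES = {
    "BayesA": _gibbs.MODEL_BAYES_A,
    "BayesB": _gibbs.MODEL_BAYES_B,
    "BayesCpi": _gibbs.MODEL_BAYES_CPI,
    "MMixp": _gibbs.MODEL_MMIXP,
}


@dataclass
class GEBVResult:
    """Predicted genetic values for a set of individuals."""

    gebv: np.ndarray
    ids: list[str]
    fixed_effects: np.ndarray
    method: str
    hyperparams: dict = field(default_factory=dict)


@dataclass
class BayesHyper:
    """Chain controls and prior hyperparameters for the Gibbs samplers.

    ``pi`` is the prior inclusion probability (spike-and-slab models) or
    the initial large-class probability (scale-mixture model); ``v`` the
    inverse-chi-square degrees of freedom of the effect-variance prior
    (must exceed 2 for the prior mean to exist) and ``s2`` its scale.
    ``var_ratio`` is the large:small variance ratio of the scale-mixture
    model.
    """

    pi: float = 0.01
    v: float = 4.2
    s2: float | None = None
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0
    var_ratio: float = 100.0
    ve_df: float = 4.0
    ve_scale: float | None = None  # defaults to var(y)/2 at fit time

    def __post_init__(self) -> None:
        if not 0.0 < self.pi <= 1.0:
            raise ValueError("pi must lie in (0, 1]")
        if self.v <= 2.0:
            raise ValueError("v must exceed 2 (inverse-chi-square prior mean undefined otherwise)")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1 or self.var_ratio <= 1.0:
            raise ValueError("thin >= 1 and var_ratio > 1 required")


@dataclass
class MarkerEffectsPosterior:
    effect_mean: np.ndarray
    inclusion_prob: np.ndarray
    pi_posterior: float
    chain_summaries: dict


def gblup_predict(
    mm: ModelMatrices,
    vc: VarianceComponents,
    predict_ids: list[str] | None = None,
    epsilon: float | None = 0.01,
) -> GEBVResult:
    """Solve the mixed-model equations at l = se2/sg2.

    ``mm.Z`` maps the training records onto the GRM's individuals;
    individuals without records receive GEBVs through the relationship
    matrix.  ``epsilon`` blends G toward the identity first (pass
    ``None``/0 to use the raw G, e.g. when checking the exact RRBLUP
    equivalence).

    Internally the equations are solved in their equivalent
    variance-component form

        a = (X' V^-1 X)^-1 X' V^-1 y,   g = sg2 G Z' V^-1 (y - X a),

    with V = Z G Z' sg2 + I se2: identical to eliminating the MME when G
    is invertible, and still well defined when G is singular (the sample
    GRM always is, since centered dosage columns sum to zero).
    """
    grm = mm.grm if not epsilon else blend_grm(mm.grm, epsilon)
    lam = vc.shrinkage_lambda
    X, Z, y = mm.X, mm.Z, mm.y
    K = grm.matrix
    V = (Z @ K @ Z.T) * vc.sigma_g2 + np.eye(y.size) * vc.sigma_e2
    try:
        Vc = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "phenotypic covariance V is not positive definite; check the "
            "variance components (se2 must be positive) or blend the GRM"
        ) from err
    solve = lambda b: np.linalg.solve(Vc.T, np.linalg.solve(Vc, b))  # noqa: E731
    Viy, ViX = solve(y), solve(X)
    alpha = np.linalg.solve(X.T @ ViX, X.T @ Viy)
    resid = y - X @ alpha
    g = vc.sigma_g2 * (K @ (Z.T @ solve(resid)))
    ids = list(grm.individual_ids)
    if predict_ids is not None:
        pos = {iid: k for k, iid in enumerate(ids)}
        idx = [pos[i] for i in predict_ids]
        g, ids = g[idx], list(predict_ids)
    return GEBVResult(
        gebv=g, ids=ids, fixed_effects=alpha, method="GBLUP",
        hyperparams={"lambda": lam, "epsilon": epsilon},
    )


def rrblup_fit(
    y: np.ndarray,
    X: np.ndarray,
    dosages: np.ndarray,
    lambda_marker: float,
    predict_dosages: np.ndarray | None = None,
) -> tuple[np.ndarray, GEBVResult]:
    """Ridge-regression BLUP of marker effects with unpenalised fixed effects.

    ``dosages`` are centered training dosages W; the penalty
    ``lambda_marker = se2 / sb2`` with ``sb2 = sg2 / (2 sum p(1-p))``
    reproduces GBLUP exactly when the centering frequencies match the GRM.
    Returns the effect estimates and GEBVs for ``predict_dosages`` (the
    training W by default).
    """
    W = np.asarray(dosages, float)
    if W.ndim != 2 or W.shape[1] == 0:
        raise ValueError("dosages must be a 2-D matrix with at least one marker")
    if lambda_marker < 0:
        raise ValueError("lambda_marker must be nonnegative")
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.size == 0:
        X = np.zeros((y.size, 0))
    p, m = X.shape[1], W.shape[1]
    lhs = np.zeros((p + m, p + m))
    lhs[:p, :p] = X.T @ X
    lhs[:p, p:] = X.T @ W
    lhs[p:, :p] = W.T @ X
    lhs[p:, p:] = W.T @ W + lambda_marker * np.eye(m)
    rhs = np.concatenate([X.T @ y, W.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    alpha, beta = sol[:p], sol[p:]
    Wp = W if predict_dosages is None else np.asarray(predict_dosages, float)
    gebv = Wp @ beta
    res = GEBVResult(
        gebv=gebv, ids=[str(i) for i in range(Wp.shape[0])], fixed_effects=alpha,
        method="RRBLUP", hyperparams={"lambda_marker": lambda_marker},
    )
    return beta, res


def bayes_scale_param(sigma_g2: float, v: float, pi: float, sum2pq: float) -> float:
    """Scale s2 of the scaled-inv-chi2 effect-variance prior.

    The per-marker prior variance target is sb2 = sg2 / (pi * sum2pq)
    (only a fraction pi of markers carry effects); setting
    s2 = sb2 (v - 2) / v makes the prior mean v s2 / (v - 2) equal sb2.
    """
    if v <= 2:
        raise ValueError("v must exceed 2 for the inverse-chi-square mean to exist")
    if not 0 < pi <= 1:
        raise ValueError("pi must lie in (0, 1]")
    if sum2pq <= 0:
        raise ValueError("sum2pq must be positive")
    sb2 = sigma_g2 / (pi * sum2pq)
    return sb2 * (v - 2.0) / v


def bayes_sampler(
    y: np.ndarray,
    X: np.ndarray,
    dosages: np.ndarray,
    model: str,
    hyper: BayesHyper,
    predict_dosages: np.ndarray | None = None,
) -> tuple[MarkerEffectsPosterior, GEBVResult]:
    """Whole-genome regression by single-site Gibbs sampling.

    ``dosages`` are centered training dosages.  Posterior means over the
    post-burn-in thinned draws give the marker effects; GEBVs score
    ``predict_dosages`` (training rows by default) with those means.
    Chains are deterministic given ``hyper.seed``.
    """
    if model not in _MODEL_CODES:
        raise ValueError(f"unknown model '{model}'; choose from {sorted(_MODEL_CODES)}")
    y = np.ascontiguousarray(np.asarray(y, float).ravel())
    W = np.ascontiguousarray(np.asarray(dosages, float))
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, float)))
    if W.shape[0] != y.size or X.shape[0] != y.size:
        raise ValueError("y, X and dosages must agree on record count")
    s2 = hyper.s2
    if s2 is None:
        # default the prior scale to half the phenotypic variance split
        # across the expected pi * m nonzero markers
        sum_wtw = float((W**2).sum(axis=0).mean() * W.shape[1])
        s2 = bayes_scale_param(0.5 * float(np.var(y)), hyper.v, hyper.pi, max(sum_wtw / y.size, 1e-12))
    ve_scale = hyper.ve_scale if hyper.ve_scale is not None else float(np.var(y)) / 2.0
    pi_init = hyper.pi if model != "BayesA" else 1.0

    beta, incl, pi_post, alpha, se2, n_saved = _gibbs.gibbs_chain(
        y, X, W, _MODEL_CODES[model], pi_init, float(hyper.v), float(s2),
        float(hyper.var_ratio), float(hyper.ve_df), float(ve_scale),
        int(hyper.n_iter), int(hyper.burn_in), int(hyper.thin),
        int(hyper.seed) % (2**32),
    )
    if not np.isfinite(se2) or not np.all(np.isfinite(beta)):
        raise FloatingPointError(
            f"{model} chain diverged (non-finite state); posterior mean residual "
            f"variance {se2!r} — check the prior scale and the phenotype scale"
        )
    post = MarkerEffectsPosterior(
        effect_mean=beta,
        inclusion_prob=incl,
        pi_posterior=float(pi_post),
        chain_summaries={"sigma_e2_mean": float(se2), "n_saved": int(n_saved)},
    )
    Wp = W if predict_dosages is None else np.asarray(predict_dosages, float)
    res = GEBVResult(
        gebv=Wp @ beta, ids=[str(i) for i in range(Wp.shape[0])], fixed_effects=alpha,
        method=model,
        hyperparams={"pi": hyper.pi, "v": hyper.v, "s2": s2, "n_iter": hyper.n_iter},
    )
    return post, res
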