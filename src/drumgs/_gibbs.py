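"""Single-site Gibbs kernels for the Bayesian-alphabet samplers (numba).

One compiled routine covers the four whole-genome regression priors; the
``model`` code selects the conditional updates:

  0  all markers in, one effect variance per marker (scaled-inv-chi2 prior)
  1  spike-and-slab with fixed inclusion probability pi, per-marker slab
     variances
  2  spike-and-slab with a common slab variance and pi sampled from its
     Beta posterior
  3  two-component normal scale mixture: every marker has an effect, drawn
     from a large- or small-variance class; the large-class probability is
     sampled

State is kept as the running residual e = y - X alpha - W beta, updated in
place marker by marker, which makes each sweep O(n m).
"""

import numpy as np
from numba import njit

MODEL_BAYES_A = 0
MODEL_BAYES_B = 1
MODEL_BAYES_CPI = 2
MODEL_MMIXP = 3


@njit(cache=True)
def _sample_scaled_inv_chi2(df, scale_sum):
    """Draw from scaled-inv-chi2: scale_sum / chi2_df (scale_sum = df * s2 form)."""
    return scale_sum / np.random.chisquare(df)


@njit(cache=True)
def _log_marginal_ratio(r, wtw, sb2, se2):
    """log p(resid | beta ~ N(0, sb2)) - log p(resid | beta = 0).

    r is w'e with the marker's own effect removed from e.
    """
    t = wtw * sb2 / se2
    return -0.5 * np.log1p(t) + 0.5 * r * r * sb2 / (se2 * (se2 + wtw * sb2))


@njit(cache=True)
def gibbs_chain(y, X, W, model, pi_init, v, s2, ratio, ve_df, ve_scale,
                n_iter, burn_in, thin, seed):
    """Run one chain; return posterior means over post-burn-in thinned draws.

    Returns (beta_mean, incl_mean, pi_mean, alpha_mean, se2_mean, n_saved).
    For model 3 ``incl_mean`` is the posterior probability of the
    large-variance class.
    """
    np.random.seed(seed)
    n = y.shape[0]
    m = W.shape[1]
    p = X.shape[1]

    wtw = np.empty(m)
    for j in range(m):
        acc = 0.0
        for i in range(n):
            acc += W[i, j] * W[i, j]
        wtw[j] = acc
    xtx = np.empty(p)
    for k in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, k] * X[i, k]
        xtx[k] = acc

    beta = np.zeros(m)
    delta = np.ones(m, dtype=np.int64)  # inclusion / large-class indicator
    alpha = np.zeros(p)
    sb2 = np.full(m, s2 * v / max(v - 2.0, 0.1))  # per-marker variances (models 0,1)
    sb2_common = s2 * v / max(v - 2.0, 0.1)       # common slab (model 2) / large class (3)
    pi = pi_init
    se2 = ve_scale if ve_scale > 0 else 1.0
    e = y.copy()

    beta_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    alpha_sum = np.zeros(p)
    pi_sum = 0.0
    se2_sum = 0.0
    n_saved = 0

    for it in range(n_iter):
        # --- fixed effects, flat prior, coordinate-wise
        for k in range(p):
            if xtx[k] <= 0.0:
                continue
            r = 0.0
            for i in range(n):
                r += X[i, k] * e[i]
            r += xtx[k] * alpha[k]
            mean = r / xtx[k]
            newa = mean + np.sqrt(se2 / xtx[k]) * np.random.standard_normal()
            diff = newa - alpha[k]
            for i in range(n):
                e[i] -= X[i, k] * diff
            alpha[k] = newa

        # --- marker effects
        sum_b2_in = 0.0       # slab sum of squares (model 2)
        sum_b2_mix = 0.0      # sigma_L2-scaled sum of squares (model 3)
        n_in = 0
        for j in range(m):
            if wtw[j] <= 0.0:
                beta[j] = 0.0
                delta[j] = 0
                continue
            # residual with marker j's own contribution restored
            r = 0.0
            for i in range(n):
                r += W[i, j] * e[i]
            r += wtw[j] * beta[j]

            old = beta[j]
            if model == MODEL_BAYES_A:
                c = wtw[j] + se2 / sb2[j]
                newb = r / c + np.sqrt(se2 / c) * np.random.standard_normal()
                delta[j] = 1
            elif model == MODEL_BAYES_B or model == MODEL_BAYES_CPI:
                var_j = sb2[j] if model == MODEL_BAYES_B else sb2_common
                logbf = _log_marginal_ratio(r, wtw[j], var_j, se2)
                logit = np.log(pi / (1.0 - pi)) + logbf if pi < 1.0 else 1e30
                pr = 1.0 / (1.0 + np.exp(-logit)) if logit < 30.0 else 1.0
                if np.random.random() < pr:
                    c = wtw[j] + se2 / var_j
                    newb = r / c + np.sqrt(se2 / c) * np.random.standard_normal()
                    delta[j] = 1
                    n_in += 1
                else:
                    newb = 0.0
                    delta[j] = 0
            else:  # MODEL_MMIXP
                var_l = sb2_common
                var_s = sb2_common / ratio
                log_l = np.log(pi) + _log_marginal_ratio(r, wtw[j], var_l, se2)
                log_s = np.log(1.0 - pi) + _log_marginal_ratio(r, wtw[j], var_s, se2)
                dmax = log_l if log_l > log_s else log_s
                pr = np.exp(log_l - dmax) / (np.exp(log_l - dmax) + np.exp(log_s - dmax))
                if np.random.random() < pr:
                    var_j = var_l
                    delta[j] = 1
                    n_in += 1
                else:
                    var_j = var_s
                    delta[j] = 0
                c = wtw[j] + se2 / var_j
                newb = r / c + np.sqrt(se2 / c) * np.random.standard_normal()

            if newb != old:
                diff = newb - old
                for i in range(n):
                    e[i] -= W[i, j] * diff
            beta[j] = newb

            # per-marker variance updates (models 0 and 1)
            if model == MODEL_BAYES_A:
                sb2[j] = _sample_scaled_inv_chi2(v + 1.0, v * s2 + beta[j] * beta[j])
            elif model == MODEL_BAYES_B:
                if delta[j] == 1:
                    sb2[j] = _sample_scaled_inv_chi2(v + 1.0, v * s2 + beta[j] * beta[j])
                else:
                    sb2[j] = _sample_scaled_inv_chi2(v, v * s2)
            elif model == MODEL_BAYES_CPI:
                if delta[j] == 1:
                    sum_b2_in += beta[j] * beta[j]
            else:
                if delta[j] == 1:
                    sum_b2_mix += beta[j] * beta[j]
                else:
                    sum_b2_mix += beta[j] * beta[j] * ratio

        # --- hyperparameters
        if model == MODEL_BAYES_CPI:
            sb2_common = _sample_scaled_inv_chi2(v + n_in, v * s2 + sum_b2_in)
            pi = np.random.beta(n_in + 1.0, m - n_in + 1.0)
            if pi >= 1.0:
                pi = 1.0 - 1e-12
            if pi <= 0.0:
                pi = 1e-12
        elif model == MODEL_MMIXP:
            sb2_common = _sample_scaled_inv_chi2(v + m, v * s2 + sum_b2_mix)
            pi = np.random.beta(n_in + 1.0, m - n_in + 1.0)
            if pi >= 1.0:
                pi = 1.0 - 1e-12
            if pi <= 0.0:
                pi = 1e-12

        # --- residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        se2 = _sample_scaled_inv_chi2(n + ve_df, sse + ve_df * ve_scale)

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_saved += 1
            pi_sum += pi
            se2_sum += se2
            for j in range(m):
                beta_sum[j] += beta[j]
                incl_sum[j] += delta[j]
            for k in range(p):
                alpha_sum[k] += alpha[k]

    return (beta_sum / n_saved, incl_sum / n_saved, pi_sum / n_saved,
            alpha_sum / n_saved, se2_sum / n_saved, n_saved)
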