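"""Mixed-model single-marker association scan and low-density panel choice.

The scan follows the two-stage strategy of population-structure-aware GWAS
tools: variance components are estimated once under the null animal model,
the phenotype and designs are whitened by the resulting covariance
V = G sg2 + I se2 (up to a scale re-estimated per marker), and each marker
is tested by a generalized-least-squares t-test of its additive dosage
coefficient.  The resulting p-values are used only to rank markers for
informative low-density panels; smaller p first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinship import GRM
from .varcomp import ModelMatrices, VarianceComponents, reml_fit

__all__ = ["PanelSpec", "mlm_scan", "select_panel"]


@dataclass
class PanelSpec:
    """How to build one low-density SNP panel."""

    mode: str  # "informative" or "random"
    size: int
    source_pvalues: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("informative", "random"):
            raise ValueError("mode must be 'informative' or 'random'")
        if self.size < 1:
            raise ValueError("panel size must be >= 1")


def mlm_scan(
    y: np.ndarray,
    X: np.ndarray,
    dosages: np.ndarray,
    grm: GRM,
    vc: VarianceComponents | None = None,
) -> np.ndarray:
    """Per-marker two-sided p-values from the mixed-model scan.

    The null covariance structure H = (G sg2 + I se2)/se2 is held fixed
    across markers; the residual scale is re-estimated per marker, so with
    G = I the test reduces exactly to the ordinary fixed-effect regression
    t-test.  A marker collinear with the covariates gets p = 1 with a
    warning.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    W = np.asarray(dosages, float)
    n = y.size
    if W.shape[0] != n or X.shape[0] != n:
        raise ValueError("y, X and dosages must agree on record count")
    if vc is None:
        vc = reml_fit(ModelMatrices(y=y, X=X, Z=np.eye(n), grm=grm))
    # whiten by V^{-1/2} via the eigendecomposition of G
    d, U = np.linalg.eigh((grm.matrix + grm.matrix.T) / 2.0)
    v = vc.sigma_g2 * np.clip(d, 0.0, None) + vc.sigma_e2
    scale = 1.0 / np.sqrt(v)
    ys = (U.T @ y) * scale
    Xs = (U.T @ X) * scale[:, None]
    Ws = (U.T @ W) * scale[:, None]
    # partial out the covariates once
    Q, _ = np.linalg.qr(Xs)
    ry = ys - Q @ (Q.T @ ys)
    Rw = Ws - Q @ (Q.T @ Ws)
    wss = np.einsum("ij,ij->j", Rw, Rw)
    dof = n - X.shape[1] - 1
    if dof < 1:
        raise ValueError("not enough records for the per-marker test")
    pvals = np.ones(W.shape[1])
    ok = wss > 1e-10 * max(float(wss.max()), 1.0)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} markers collinear with covariates; p set to 1", stacklevel=2)
    beta = np.zeros_like(wss)
    beta[ok] = (Rw[:, ok].T @ ry) / wss[ok]
    rss = float(ry @ ry) - beta**2 * wss
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / np.sqrt(np.maximum(rss, 0.0) / dof / wss)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), dof)
    return pvals


def select_panel(spec: PanelSpec, marker_ids: list[str]) -> list[str]:
    """Pick a panel of marker ids.

    Informative panels take the ``size`` smallest p-values (ties broken by
    genome order, so panels of growing size are nested); random panels are
    a uniform sample without replacement driven by ``spec.seed``.
    """
    m = len(marker_ids)
    if spec.size > m:
        raise ValueError(f"panel size {spec.size} exceeds marker count {m}")
    if spec.mode == "informative":
        if spec.source_pvalues is None:
            raise ValueError("informative panels need source_pvalues")
        p = np.asarray(spec.source_pvalues, float)
        if p.size != m:
            raise ValueError("source_pvalues length must match marker_ids")
        order = np.argsort(p, kind="stable")[: spec.size]
        return [marker_ids[i] for i in order]
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(m, size=spec.size, replace=False)
    return [marker_ids[i] for i in idx]
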