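"""Cross-validated predictive ability and the study's summary arithmetic.

Predictive ability is the Pearson correlation between GEBVs and observed
phenotypes in a held-out test set, averaged over repeated random splits of
the cohort into a reference (training) and a testing group.  The module
also carries the small arithmetic surrounding such an evaluation: per-sex
phenotype summaries with Welch t-tests, ratio-trait derivation,
best-versus-worst method spread, and the deterministic reference-size
formula r = sqrt(N h2 / (N h2 + Me)) inverted for N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import PHENO_ID, PHENO_SEX, GenotypeMatrix, validate_phenotypes
from .gwas import PanelSpec, mlm_scan, select_panel
from .kinship import GRM, blend_grm, centered_dosages, vanraden_grm
from .predict import BayesHyper, bayes_sampler, bayes_scale_param, gblup_predict, rrblup_fit
from .varcomp import ModelMatrices, VarianceComponents, reml_fit

__all__ = [
    "CVResult",
    "ReferenceSizeQuery",
    "cross_validate",
    "predictive_ability",
    "method_spread",
    "summarize_phenotypes",
    "derive_ratio_traits",
    "required_reference_size",
    "expected_accuracy",
    "panel_curve",
]

BAYES_MODELS = ("BayesA", "BayesB", "BayesCpi", "MMixp")


@dataclass
class CVResult:
    trait: str
    method: str
    replicate_abilities: list[float]
    n_reference: int
    n_testing: int
    panel: PanelSpec | None = None

    @property
    def mean_ability(self) -> float:
        return float(np.mean(self.replicate_abilities))

    @property
    def se_ability(self) -> float:
        """Standard error over replicates: SD / sqrt(n_reps)."""
        a = np.asarray(self.replicate_abilities)
        return float(a.std(ddof=1) / math.sqrt(a.size))


@dataclass
class ReferenceSizeQuery:
    """Inputs of the deterministic accuracy formula."""

    h2: float
    Me: float
    target_accuracy: float

    def __post_init__(self) -> None:
        if self.h2 <= 0 or self.Me <= 0:
            raise ValueError("h2 and Me must be positive")
        if not 0.0 <= self.target_accuracy < 1.0:
            raise ValueError("target_accuracy must lie in [0, 1)")


def predictive_ability(gebv: np.ndarray, phenotype: np.ndarray) -> float:
    """Pearson correlation between GEBVs and phenotypes."""
    gebv = np.asarray(gebv, float).ravel()
    phenotype = np.asarray(phenotype, float).ravel()
    if gebv.size != phenotype.size or gebv.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(gebv) == 0 or np.std(phenotype) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(stats.pearsonr(gebv, phenotype)[0])


def _build_design(pheno: pd.DataFrame, trait: str, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    tab = pheno.set_index(PHENO_ID).loc[ids]
    y = tab[trait].to_numpy(float)
    X = np.column_stack([np.ones(y.size), (tab[PHENO_SEX] == "M").to_numpy(float)])
    return y, X


def _predict_one_split(
    method: str,
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    grm: GRM,
    train: np.ndarray,
    test: np.ndarray,
    vc: VarianceComponents | None,
    hyper: BayesHyper | None,
    rep_seed: int,
    epsilon: float,
) -> np.ndarray:
    """GEBVs of the test individuals for one reference/testing split."""
    n = y.size
    if method == "oracle":
        return y[test]
    work_grm = blend_grm(grm, epsilon) if epsilon else grm
    if vc is None:
        Z_tr = np.eye(n)[train]
        vc = reml_fit(ModelMatrices(y=y[train], X=X[train], Z=Z_tr, grm=work_grm))
    if method == "GBLUP":
        Z_tr = np.eye(n)[train]
        mm = ModelMatrices(y=y[train], X=X[train], Z=Z_tr, grm=work_grm)
        ids = [grm.individual_ids[i] for i in test]
        return gblup_predict(mm, vc, predict_ids=ids, epsilon=None).gebv
    if method == "RRBLUP":
        lam_marker = vc.shrinkage_lambda * grm.denominator
        _, res = rrblup_fit(y[train], X[train], W[train], lam_marker, predict_dosages=W[test])
        return res.gebv
    if method in BAYES_MODELS:
        hyper = hyper or BayesHyper()
        if hyper.s2 is None:
            pi_eff = 1.0 if method in ("BayesA", "MMixp") else hyper.pi
            s2 = bayes_scale_param(vc.sigma_g2, hyper.v, pi_eff, grm.denominator)
            hyper = replace(hyper, s2=s2, seed=rep_seed)
        else:
            hyper = replace(hyper, seed=rep_seed)
        _, res = bayes_sampler(y[train], X[train], W[train], method, hyper, predict_dosages=W[test])
        return res.gebv
    raise ValueError(f"unknown method '{method}'")


def cross_validate(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    method: str = "GBLUP",
    n_reps: int = 100,
    test_fraction: float = 0.1,
    seed: int = 0,
    hyper: BayesHyper | None = None,
    epsilon: float = 0.01,
    paper_mode: bool = False,
    adjust_sex: bool = False,
) -> CVResult:
    """Repeated random-split cross-validation of one (trait, method) pair.

    Each replicate draws a test set of ``round(n * test_fraction)``
    individuals; the model is trained on the remaining reference set
    (variance components re-estimated per replicate unless ``paper_mode``
    reuses a single whole-data REML fit) and scored by the Pearson
    correlation of test-set GEBVs with test-set phenotypes.  The ability
    is computed against the raw phenotype; ``adjust_sex`` subtracts the
    reference-set sex means first, for methodological comparisons.
    """
    if genotypes.has_missing:
        raise ValueError("cross-validation requires complete (imputed) genotypes")
    validate_phenotypes(pheno, [trait])
    n = genotypes.n_individuals
    n_test = int(round(n * test_fraction))
    if n_test < 3:
        raise ValueError("test set smaller than 3; raise test_fraction")
    grm = vanraden_grm(genotypes)
    W, _ = centered_dosages(genotypes)
    y, X = _build_design(pheno, trait, genotypes.individual_ids)

    vc_fixed = None
    if paper_mode and method != "oracle":
        vc_fixed = reml_fit(ModelMatrices(y=y, X=X, Z=np.eye(n), grm=blend_grm(grm, epsilon)))

    rng = np.random.default_rng(seed)
    abilities = []
    for rep in range(n_reps):
        perm = rng.permutation(n)
        test, train = np.sort(perm[:n_test]), np.sort(perm[n_test:])
        rep_seed = int(rng.integers(2**31 - 1))
        gebv = _predict_one_split(
            method, y, X, W, grm, train, test, vc_fixed, hyper, rep_seed, epsilon
        )
        target = y[test]
        if adjust_sex:
            male = X[:, 1] == 1.0
            mu_m = y[train][male[train]].mean()
            mu_f = y[train][~male[train]].mean()
            target = target - np.where(male[test], mu_m, mu_f)
        abilities.append(predictive_ability(gebv, target))
    return CVResult(
        trait=trait,
        method=method,
        replicate_abilities=abilities,
        n_reference=n - n_test,
        n_testing=n_test,
    )


def method_spread(
    abilities: dict[str, float | dict[str, float]],
) -> tuple[float, float]:
    """Best-to-worst spread of per-method mean abilities for one trait.

    Methods given as a dict of hyperparameter variants are first reduced
    to their best variant; the spread is (max - min, and that difference
    as a percentage of the maximum).
    """
    if len(abilities) < 2:
        raise ValueError("need at least two methods")
    reduced = {
        k: (max(v.values()) if isinstance(v, dict) else float(v)) for k, v in abilities.items()
    }
    hi, lo = max(reduced.values()), min(reduced.values())
    diff = hi - lo
    pct = 0.0 if hi == 0 else 100.0 * diff / hi
    return diff, pct


def _stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.01:
        return "*"
    return "(-)"


def summarize_phenotypes(pheno: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Per-sex mean +/- SD and a Welch t-test of the sex effect, per trait.

    Stars code the two-sided p-value: '*' below 0.01, '**' below 0.001,
    '(-)' otherwise.
    """
    validate_phenotypes(pheno, traits)
    rows = []
    for trait in traits:
        m = pheno.loc[pheno[PHENO_SEX] == "M", trait].dropna()
        f = pheno.loc[pheno[PHENO_SEX] == "F", trait].dropna()
        if len(m) < 2 or len(f) < 2:
            raise ValueError(f"trait '{trait}': each sex needs at least 2 records")
        t, p = stats.ttest_ind(m, f, equal_var=False)
        rows.append(
            {
                "trait": trait,
                "n_male": len(m),
                "mean_male": m.mean(),
                "sd_male": m.std(ddof=1),
                "n_female": len(f),
                "mean_female": f.mean(),
                "sd_female": f.std(ddof=1),
                "t_stat": float(t),
                "p_value": float(p),
                "significance": _stars(float(p)),
            }
        )
    return pd.DataFrame(rows)


def derive_ratio_traits(
    body_weight_g: np.ndarray,
    bladder_weight_g: np.ndarray,
    gonad_weight_g: np.ndarray,
    body_length_mm: np.ndarray,
    body_height_mm: np.ndarray,
) -> pd.DataFrame:
    """Derived ratio traits: SBI (%), LHR (unitless), GWI (%).

    SBI and GWI are the swim-bladder and gonad weights as a percentage of
    body weight; LHR is body length over body height.
    """
    bw = np.asarray(body_weight_g, float)
    bh = np.asarray(body_height_mm, float)
    if np.any(bw <= 0) or np.any(bh <= 0):
        raise ValueError("body weight and body height must be positive")
    return pd.DataFrame(
        {
            "SBI": 100.0 * np.asarray(bladder_weight_g, float) / bw,
            "LHR": np.asarray(body_length_mm, float) / bh,
            "GWI": 100.0 * np.asarray(gonad_weight_g, float) / bw,
        }
    )


def expected_accuracy(n_reference: float, h2: float, Me: float) -> float:
    """Deterministic GEBV accuracy r = sqrt(N h2 / (N h2 + Me))."""
    return math.sqrt(n_reference * h2 / (n_reference * h2 + Me))


def required_reference_size(q: ReferenceSizeQuery) -> int:
    """Reference-population size achieving a target accuracy.

    Inverts r = sqrt(N h2 / (N h2 + Me)) to N = Me r^2 / (h2 (1 - r^2)),
    rounded up.
    """
    r2 = q.target_accuracy**2
    return math.ceil(q.Me * r2 / (q.h2 * (1.0 - r2)))


def panel_curve(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    sizes: list[int],
    modes: tuple[str, ...] = ("informative", "random"),
    n_reps: int = 20,
    test_fraction: float = 0.1,
    seed: int = 0,
    epsilon: float = 0.01,
    paper_mode: bool = False,
) -> pd.DataFrame:
    """GBLUP predictive ability across low-density panel sizes (both modes).

    For each replicate split, informative panels are ranked by a
    mixed-model scan run on the reference individuals only (no test-set
    leakage); ``paper_mode`` instead ranks once on the full data.  Random
    panels redraw per replicate.  All (mode, size) cells share the same
    split sequence, so the curves are directly comparable.
    """
    if genotypes.has_missing:
        raise ValueError("panel evaluation requires complete genotypes")
    m = genotypes.n_markers
    if max(sizes) > m:
        raise ValueError("panel size exceeds marker count")
    n = genotypes.n_individuals
    n_test = int(round(n * test_fraction))
    if n_test < 3:
        raise ValueError("test set smaller than 3")
    y, X = _build_design(pheno, trait, genotypes.individual_ids)

    pvals_full = None
    if paper_mode and "informative" in modes:
        grm_full = blend_grm(vanraden_grm(genotypes), epsilon)
        pvals_full = mlm_scan(y, X, genotypes.dosages, grm_full)

    rng = np.random.default_rng(seed)
    cells: dict[tuple[str, int], list[float]] = {(mo, s): [] for mo in modes for s in sizes}
    for rep in range(n_reps):
        perm = rng.permutation(n)
        test, train = np.sort(perm[:n_test]), np.sort(perm[n_test:])
        rep_seed = int(rng.integers(2**31 - 1))
        if "informative" in modes:
            if paper_mode:
                pv = pvals_full
            else:
                # full-sample centering frequencies: keeps every post-QC
                # marker polymorphic even when it is fixed within one
                # reference draw (genotype frequencies carry no phenotype
                # information, so this leaks nothing)
                ref = genotypes.subset_individuals(train)
                grm_ref = blend_grm(
                    vanraden_grm(ref, freqs=genotypes.allele_frequencies()), epsilon
                )
                pv = mlm_scan(y[train], X[train], ref.dosages, grm_ref)
        for mode in modes:
            for size in sizes:
                if mode == "informative":
                    spec = PanelSpec(mode="informative", size=size, source_pvalues=pv)
                else:
                    spec = PanelSpec(mode="random", size=size, seed=rep_seed)
                panel_ids = select_panel(spec, genotypes.marker_ids)
                pos = {mid: k for k, mid in enumerate(genotypes.marker_ids)}
                sub = genotypes.subset_markers([pos[mid] for mid in panel_ids])
                grm_panel = vanraden_grm(sub)
                Zt = np.eye(n)[train]
                work = blend_grm(grm_panel, epsilon)
                vc = reml_fit(ModelMatrices(y=y[train], X=X[train], Z=Zt, grm=work))
                mm = ModelMatrices(y=y[train], X=X[train], Z=Zt, grm=work)
                ids = [genotypes.individual_ids[i] for i in test]
                gebv = gblup_predict(mm, vc, predict_ids=ids, epsilon=None).gebv
                cells[(mode, size)].append(predictive_ability(gebv, y[test]))
    rows = [
        {
            "mode": mo,
            "size": s,
            "mean_ability": float(np.mean(v)),
            "se_ability": float(np.std(v, ddof=1) / math.sqrt(len(v))),
        }
        for (mo, s), v in cells.items()
    ]
    return pd.DataFrame(rows).sort_values(["mode", "size"]).reset_index(drop=True)
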