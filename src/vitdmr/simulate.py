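"""Synthetic two-sample GWAS cohorts with known ground truth.

Generates two disjoint individual-level cohorts — an exposure cohort with a
standardized continuous trait (a stand-in for standardized log-25OHD) and
an outcome cohort with a four-level ordinal symptom frequency report
(dichotomizable at any level) — plus per-SNP summary statistics from the
cohorts, so every pipeline stage downstream of data production can be
exercised against known parameters.

The genetic architecture mimics the seven-SNP 25OHD instrument panel:
independent biallelic SNPs in Hardy-Weinberg proportions, jointly
explaining ~5% of exposure variance, with strongly heterogeneous per-SNP
effect sizes (the published panel spans an order of magnitude, one dominant
common signal plus smaller ones). The ordinal outcome follows a
cumulative-logit (proportional-odds) construction whose linear predictor
carries the causal effect of the latent exposure, optional per-SNP direct
(pleiotropic) effects and an optional shared confounder; the three
thresholds are solved numerically so the marginal category frequencies
match the configured targets, top-category prevalence ~6% by default.
Dichotomizing at the top category therefore yields an exact logistic model
for the binary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .sumstats import SnpAssociation, SummaryStatsSet

__all__ = [
    "CATEGORY_LABELS",
    "DEFAULT_CATEGORY_PROBS",
    "SimulationConfig",
    "SyntheticCohort",
    "DichotomizeResult",
    "simulate_cohorts",
    "gwas_continuous",
    "gwas_logistic",
    "dichotomize",
]

CATEGORY_LABELS = ("not_at_all", "several_days", "more_than_half_the_days", "nearly_every_day")

# marginal frequencies of the four symptom-report categories (proportions)
DEFAULT_CATEGORY_PROBS = (0.4731, 0.4098, 0.0575, 0.0596)

_NON_PALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a pair of disjoint cohorts.

    ``causal_beta`` is the true effect of a 1-SD *decrease* in the
    standardized exposure on the outcome log-odds (the direction the
    pipeline reports). ``target_r2`` is the variance in the exposure
    jointly explained by the instruments; ``effect_size_spread`` the
    lognormal sigma of the raw per-SNP effect magnitudes before scaling.
    ``pleiotropy_mean``/``pleiotropy_sd`` parameterize per-SNP direct
    effects on the outcome log-odds (InSIDE holds: drawn independently of
    instrument strength). ``confounder_effect_*`` load one shared standard-
    normal confounder on exposure and outcome.
    """

    seed: int = 0
    n_exposure_cohort: int = 20000
    n_outcome_cohort: int = 50000
    n_snps: int = 7
    maf_range: tuple = (0.05, 0.45)
    target_r2: float = 0.05
    causal_beta: float = 0.0
    target_prevalence: float = 0.0596
    category_probs: tuple = DEFAULT_CATEGORY_PROBS
    effect_size_spread: float = 1.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    confounder_effect_exposure: float = 0.0
    confounder_effect_outcome: float = 0.0
    n_covariates: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.target_r2 < 1):
            raise SimulationError("target_r2 must be in (0, 1)")
        if not (0 < self.target_prevalence < 1):
            raise SimulationError("target_prevalence must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5)")
        if self.n_exposure_cohort <= 0 or self.n_outcome_cohort <= 0:
            raise SimulationError("cohort sizes must be positive")
        if self.n_snps < 1:
            raise SimulationError("n_snps must be >= 1")
        if len(self.category_probs) != 4 or abs(sum(self.category_probs) - 1.0) > 1e-6:
            raise SimulationError("category_probs must be 4 proportions summing to 1")
        if self.target_r2 + self.confounder_effect_exposure**2 >= 1.0:
            raise SimulationError("target_r2 + confounder loading^2 must be < 1")

    @property
    def effective_category_probs(self) -> tuple:
        """Category proportions with the top category pinned to ``target_prevalence``."""
        top = self.target_prevalence
        lower = np.asarray(self.category_probs[:3], dtype=float)
        lower = lower / lower.sum() * (1.0 - top)
        return (*map(float, lower), float(top))


@dataclass
class SyntheticCohort:
    """Individual-level data for one cohort, with the generating truth attached."""

    genotypes: np.ndarray  # person x SNP dosages in {0, 1, 2}
    rsids: list
    alleles: list  # (effect_allele, other_allele) per SNP; dosage counts effect allele
    covariates: pd.DataFrame
    truth: dict
    exposure: np.ndarray | None = None
    outcome_ordinal: np.ndarray | None = None  # levels 0..3

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def genotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genotypes, columns=self.rsids)


def _draw_covariates(rng: np.random.Generator, n: int, n_covariates: int) -> pd.DataFrame:
    cov = {
        "sex": rng.integers(0, 2, n),
        "centre": rng.integers(0, 4, n),
    }
    for j in range(n_covariates):
        cov[f"pc{j + 1}"] = rng.normal(size=n)
    return pd.DataFrame(cov)


def _solve_threshold(eta: np.ndarray, tail: float) -> float:
    """Intercept alpha with mean(expit(alpha + eta)) == tail."""

    def f(alpha: float) -> float:
        return float(np.mean(special.expit(alpha + eta))) - tail

    try:
        return float(optimize.brentq(f, -40.0, 40.0, xtol=1e-12))
    except ValueError as exc:
        raise SimulationError(
            f"cannot reach tail probability {tail} with the configured effects"
        ) from exc


def simulate_cohorts(config: SimulationConfig):
    """Generate ``(exposure_cohort, outcome_cohort)`` under ``config``.

    The two cohorts share the generating parameters (mafs, per-SNP effects)
    but are fully disjoint samples with independent noise, enforcing the
    two-sample design. Identical seed and config give bit-identical data.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], m)
    raw = rng.lognormal(0.0, config.effect_size_spread, m) * rng.choice([-1.0, 1.0], m)
    var_per_allele = 2.0 * maf * (1.0 - maf)
    scale = np.sqrt(config.target_r2 / np.sum(raw**2 * var_per_allele))
    beta_snp = raw * scale  # per-allele effect on the standardized exposure

    rsids = [f"rs{9100000 + j}" for j in range(m)]
    alleles = [
        _NON_PALINDROMIC_PAIRS[int(rng.integers(0, len(_NON_PALINDROMIC_PAIRS)))] for _ in range(m)
    ]
    delta = config.pleiotropy_mean + config.pleiotropy_sd * rng.normal(size=m)

    cx = config.confounder_effect_exposure
    cy = config.confounder_effect_outcome
    noise_var = 1.0 - config.target_r2 - cx**2
    if noise_var <= 0:
        raise SimulationError("non-genetic exposure variance must be positive")

    truth = {
        "maf": maf,
        "beta_snp": beta_snp,
        "delta": delta,
        "theta": config.causal_beta,
        "rsids": rsids,
        "alleles": alleles,
        "config": config,
    }

    # exposure cohort: observed continuous trait
    n1 = config.n_exposure_cohort
    g1 = rng.binomial(2, maf, size=(n1, m)).astype(np.int8)
    u1 = rng.normal(size=n1)
    x1 = (g1 - 2 * maf) @ beta_snp + cx * u1 + np.sqrt(noise_var) * rng.normal(size=n1)
    cov1 = _draw_covariates(rng, n1, config.n_covariates)

    # outcome cohort: latent exposure analogue, ordinal outcome
    n2 = config.n_outcome_cohort
    g2 = rng.binomial(2, maf, size=(n2, m)).astype(np.int8)
    u2 = rng.normal(size=n2)
    x2 = (g2 - 2 * maf) @ beta_snp + cx * u2 + np.sqrt(noise_var) * rng.normal(size=n2)
    # pleiotropic effects act per copy of the exposure-decreasing allele, so a
    # nonzero pleiotropy_mean is directional on the harmonized orientation
    g2_decreasing = np.where(beta_snp < 0, g2, 2 - g2)
    eta = -config.causal_beta * x2 + g2_decreasing @ delta + cy * u2

    probs = config.effective_category_probs
    tails = (1.0 - probs[0], probs[2] + probs[3], probs[3])  # P(Y>=1), P(Y>=2), P(Y>=3)
    alphas = [_solve_threshold(eta, t) for t in tails]
    u = rng.uniform(size=n2)
    y = np.zeros(n2, dtype=np.int8)
    for alpha in alphas:  # nested tails -> counting crossings gives the level
        y += (u < special.expit(alpha + eta)).astype(np.int8)
    cov2 = _draw_covariates(rng, n2, config.n_covariates)
    truth["thresholds"] = alphas

    exposure_cohort = SyntheticCohort(
        genotypes=g1, rsids=rsids, alleles=alleles, covariates=cov1, truth=truth, exposure=x1
    )
    outcome_cohort = SyntheticCohort(
        genotypes=g2, rsids=rsids, alleles=alleles, covariates=cov2, truth=truth, outcome_ordinal=y
    )
    return exposure_cohort, outcome_cohort


def _covariate_matrix(cohort: SyntheticCohort) -> np.ndarray:
    cov = pd.get_dummies(cohort.covariates, columns=["centre"], drop_first=True)
    return cov.to_numpy(dtype=float)


def gwas_continuous(
    cohort: SyntheticCohort,
    trait: np.ndarray | None = None,
    adjust_covariates: bool = False,
    study_label: str = "synthetic_exposure_gwas",
) -> SummaryStatsSet:
    """Per-SNP ordinary least squares of a continuous trait on dosage.

    With ``adjust_covariates`` the trait and dosages are first residualized
    on the covariate matrix (Frisch-Waugh), with degrees of freedom adjusted
    accordingly. Monomorphic SNPs are skipped (beta not estimable) and
    reported via ``SummaryStatsSet``'s missing rsids.
    """
    y = cohort.exposure if trait is None else np.asarray(trait, dtype=float)
    if y is None:
        raise ValueError("cohort has no continuous trait")
    g = cohort.genotypes.astype(float)
    n, m = g.shape
    df_adjust = 0
    if adjust_covariates:
        C = np.column_stack([np.ones(n), _covariate_matrix(cohort)])
        coef_y, *_ = np.linalg.lstsq(C, y, rcond=None)
        y = y - C @ coef_y
        coef_g, *_ = np.linalg.lstsq(C, g, rcond=None)
        g = g - C @ coef_g
        df_adjust = C.shape[1] - 1

    yc = y - y.mean()
    gc = g - g.mean(axis=0)
    sxx = np.sum(gc**2, axis=0)
    assocs = []
    df = n - 2 - df_adjust
    for j in range(m):
        if sxx[j] == 0:
            continue  # monomorphic: not estimable
        beta = float(np.sum(gc[:, j] * yc) / sxx[j])
        rss = float(np.sum(yc**2) - beta**2 * sxx[j])
        se = float(np.sqrt(max(rss, 0.0) / df / sxx[j]))
        se = max(se, np.finfo(float).tiny)  # exact fits: SE ~ 0 but must stay positive
        tstat = beta / se
        p = float(max(2.0 * stats.t.sf(abs(tstat), df), np.finfo(float).tiny))
        ea, oa = cohort.alleles[j]
        assocs.append(
            SnpAssociation(
                rsid=cohort.rsids[j],
                effect_allele=ea,
                other_allele=oa,
                beta=beta,
                se=se,
                eaf=float(cohort.genotypes[:, j].mean() / 2.0),
                pvalue=p,
                n=n,
            )
        )
    return SummaryStatsSet.from_associations(assocs, study_label=study_label, trait="exposure")


def _logistic_newton(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 25):
    """Maximum-likelihood logistic fit by Newton-Raphson.

    Returns ``(beta, se, converged)``; convergence is gradient max-norm
    below ``tol``. Separation shows up as non-convergence or a singular
    information matrix.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    beta[0] = np.log(ybar / (1.0 - ybar))
    for _ in range(max_iter):
        mu = special.expit(X @ beta)
        grad = X.T @ (y - mu)
        W = mu * (1.0 - mu)
        info = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        if np.max(np.abs(beta)) > 15:  # diverging log-odds: (quasi-)separation
            return beta, None, False
        if np.max(np.abs(grad)) < tol:
            mu = special.expit(X @ beta)
            W = mu * (1.0 - mu)
            info = X.T @ (X * W[:, None])
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            return beta, se, True
    return beta, None, False


def gwas_logistic(
    cohort: SyntheticCohort,
    dichotomize_at: str | int = "nearly_every_day",
    adjust_covariates: bool = False,
    study_label: str = "synthetic_outcome_gwas",
) -> SummaryStatsSet:
    """Per-SNP logistic regression of the dichotomized ordinal outcome.

    Wald betas/SEs on the log-odds scale. SNPs whose fit does not converge
    (e.g. separation) are skipped and left out of the returned set.
    """
    if cohort.outcome_ordinal is None:
        raise ValueError("cohort has no ordinal outcome")
    y = dichotomize(cohort.outcome_ordinal, dichotomize_at).binary.astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise SimulationError("dichotomization leaves an empty outcome class")
    g = cohort.genotypes.astype(float)
    n, m = g.shape
    base = [np.ones(n)]
    if adjust_covariates:
        base.append(_covariate_matrix(cohort))
        base = [np.column_stack(base)]
    base_mat = base[0] if adjust_covariates else np.ones((n, 1))

    assocs = []
    for j in range(m):
        X = np.column_stack([base_mat, g[:, j]])
        beta, se, converged = _logistic_newton(X, y)
        if not converged or se is None:
            continue  # separation or non-convergence: SE not reportable
        b, s = float(beta[-1]), float(se[-1])
        z = b / s
        p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
        ea, oa = cohort.alleles[j]
        assocs.append(
            SnpAssociation(
                rsid=cohort.rsids[j],
                effect_allele=ea,
                other_allele=oa,
                beta=b,
                se=s,
                eaf=float(cohort.genotypes[:, j].mean() / 2.0),
                pvalue=p,
                n=n,
            )
        )
    return SummaryStatsSet.from_associations(assocs, study_label=study_label, trait="outcome")


@dataclass
class DichotomizeResult:
    binary: np.ndarray
    counts: dict
    threshold: str
    proportion: float


def dichotomize(outcome_ordinal: Sequence, threshold: str | int) -> DichotomizeResult:
    """Binary indicator of category >= ``threshold``, with the category table.

    ``threshold`` may be a category label or an integer level 0-3. At the
    default top level this reproduces the 'symptoms nearly every day versus
    less often' case definition.
    """
    if isinstance(threshold, str):
        if threshold not in CATEGORY_LABELS:
            raise ValueError(f"unknown category label {threshold!r}; expected one of {CATEGORY_LABELS}")
        level = CATEGORY_LABELS.index(threshold)
    else:
        level = int(threshold)
        if not 0 <= level <= 3:
            raise ValueError(f"threshold level {level} outside 0..3")
    y = np.asarray(outcome_ordinal)
    if y.size and (y.min() < 0 or y.max() > 3):
        raise ValueError("ordinal outcome contains levels outside 0..3")
    binary = (y >= level).astype(np.int8)
    counts = {lab: int(np.sum(y == k)) for k, lab in enumerate(CATEGORY_LABELS)}
    return DichotomizeResult(
        binary=binary,
        counts=counts,
        threshold=CATEGORY_LABELS[level],
        proportion=float(binary.mean()) if y.size else 0.0,
    )
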