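"""Two-sample MR estimators and heterogeneity statistics.

All estimators consume harmonized instruments (exposure-decreasing allele,
``beta_exposure`` > 0) and return causal effects on the log-odds scale per
1-SD decrease in the standardized log-scale exposure. The per-SNP Wald
ratio is ``beta_outcome / beta_exposure``; IVW pools the ratios with
inverse-variance weights ``w_j = beta_exposure_j**2 / se_outcome_j**2``
(first-order weights, exposure uncertainty ignored); MR-Egger is a weighted
linear regression with intercept, whose intercept estimates the average
directional pleiotropic effect; the weighted median takes the 50% point of
the weighted empirical ratio distribution, with a parametric-bootstrap SE.

Statistical conventions: two-sided p-values; 95% normal CIs; the
multiplicative-random-effects IVW and the Egger fit scale their standard
errors by the residual standard deviation floored at 1 (under-dispersion is
never allowed to shrink a CI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

__all__ = [
    "MrEstimate",
    "EggerResult",
    "HeterogeneityResult",
    "OddsRatioScale",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
]

_Z95 = stats.norm.ppf(0.975)


class OddsRatioScale(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate on the log-odds scale, with OR view."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.method}: se must be > 0")
        if not self.ci_low < self.ci_high:
            raise ValueError(f"{self.method}: malformed CI [{self.ci_low}, {self.ci_high}]")

    @property
    def or_scale(self) -> OddsRatioScale:
        return OddsRatioScale(math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))


@dataclass(frozen=True)
class EggerResult:
    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float
    i_squared: float
    tau_squared: float


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_exposure for h in instruments], dtype=float)
    sx = np.array([h.se_exposure for h in instruments], dtype=float)
    by = np.array([h.beta_outcome for h in instruments], dtype=float)
    sy = np.array([h.se_outcome for h in instruments], dtype=float)
    return bx, sx, by, sy


def _estimate(method: str, beta: float, se: float, n_snps: int) -> MrEstimate:
    z = beta / se
    return MrEstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        n_snps=n_snps,
    )


def wald_ratio(snp: HarmonizedInstrument) -> MrEstimate:
    """Single-SNP causal estimate: outcome effect over exposure effect.

    SE by the first-order delta method, ``se_outcome / |beta_exposure|``
    (exposure-side uncertainty neglected; adequate while the instrument's
    coefficient of variation is small).
    """
    if snp.beta_exposure == 0:
        raise ZeroDivisionError(f"{snp.rsid}: Wald ratio undefined for beta_exposure = 0")
    beta = snp.beta_outcome / snp.beta_exposure
    se = snp.se_outcome / abs(snp.beta_exposure)
    return _estimate("wald_ratio", beta, se, 1)


def ivw(instruments: Sequence[HarmonizedInstrument], variant: str = "fixed") -> MrEstimate:
    """Inverse-variance-weighted mean of the per-SNP Wald ratios.

    ``variant="fixed"`` uses ``se = (sum w_j)**-0.5``;
    ``variant="multiplicative_random"`` scales that SE by the residual
    standard deviation of the weighted through-origin regression, floored
    at 1. The point estimate is identical for both variants.
    """
    if len(instruments) < 2:
        raise ValueError("ivw needs >= 2 instruments; use wald_ratio for a single SNP")
    if variant not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown ivw variant {variant!r}")
    bx, _, by, sy = _arrays(instruments)
    r = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if variant == "multiplicative_random":
        k = len(instruments)
        sigma2 = float(np.sum(w * (r - beta) ** 2) / (k - 1))
        se *= max(1.0, math.sqrt(sigma2))
    method = "ivw_fixed" if variant == "fixed" else "ivw_mre"
    return _estimate(method, beta, se, len(instruments))


def mr_egger(
    instruments: Sequence[HarmonizedInstrument],
    reference: str = "normal",
) -> EggerResult:
    """Weighted regression of outcome betas on exposure betas with intercept.

    Weights are ``1 / se_outcome**2``; the slope is the pleiotropy-robust
    causal estimate (valid under the InSIDE assumption), the intercept the
    average directional pleiotropic effect. ``reference`` selects the
    sampling distribution for p-values and CIs: ``"normal"`` (default) or
    ``"t"`` for Student t with k-2 degrees of freedom. Standard errors are
    scaled by the residual standard deviation floored at 1.
    """
    if len(instruments) < 3:
        raise ValueError("mr_egger needs >= 3 instruments to identify slope and intercept")
    if reference not in ("normal", "t"):
        raise ValueError(f"unknown reference {reference!r}")
    import statsmodels.api as sm

    bx, _, by, sy = _arrays(instruments)
    if np.any(bx <= 0):
        raise ValueError("mr_egger requires the decreasing-allele orientation (beta_exposure > 0)")
    k = len(instruments)
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    intercept, slope = (float(v) for v in fit.params)
    # unit-variance SEs times max(1, residual sigma); robust to sigma = 0
    sigma = math.sqrt(float(fit.scale))
    unit_se = np.sqrt(np.diag(fit.normalized_cov_params))
    se_intercept, se_slope = (float(v) * max(1.0, sigma) for v in unit_se)

    if reference == "t":
        dist = stats.t(k - 2)
    else:
        dist = stats.norm
    crit = float(dist.ppf(0.975))

    def pval(est, se):
        return float(2.0 * dist.sf(abs(est / se)))

    slope_est = MrEstimate(
        method="egger_slope",
        beta=slope,
        se=se_slope,
        ci_low=slope - crit * se_slope,
        ci_high=slope + crit * se_slope,
        pvalue=pval(slope, se_slope),
        n_snps=k,
    )
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_pvalue=pval(intercept, se_intercept),
    )


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios ``r`` with weights ``w``."""
    order = np.argsort(r)
    r_s = r[order]
    w_s = w[order] / np.sum(w)
    p = np.cumsum(w_s) - 0.5 * w_s
    if 0.5 <= p[0]:
        return float(r_s[0])
    if 0.5 >= p[-1]:
        return float(r_s[-1])
    return float(np.interp(0.5, p, r_s))


def _weighted_median_rows(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted medians for (B, k) ratio/weight arrays."""
    order = np.argsort(r, axis=1)
    r_s = np.take_along_axis(r, order, axis=1)
    w_s = np.take_along_axis(w, order, axis=1)
    w_s = w_s / np.sum(w_s, axis=1, keepdims=True)
    p = np.cumsum(w_s, axis=1) - 0.5 * w_s
    B, k = r.shape
    idx = np.sum(p < 0.5, axis=1)  # first index with p >= 0.5
    out = np.empty(B)
    lo_edge = idx == 0
    hi_edge = idx == k
    out[lo_edge] = r_s[lo_edge, 0]
    out[hi_edge] = r_s[hi_edge, -1]
    mid = ~(lo_edge | hi_edge)
    i = idx[mid]
    rows = np.nonzero(mid)[0]
    p_hi = p[rows, i]
    p_lo = p[rows, i - 1]
    r_hi = r_s[rows, i]
    r_lo = r_s[rows, i - 1]
    frac = (0.5 - p_lo) / (p_hi - p_lo)
    out[mid] = r_lo + frac * (r_hi - r_lo)
    return out


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 5000,
    seed: int | None = None,
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the weighted empirical distribution of
    Wald ratios at probability 0.5 (consistent when valid instruments carry
    more than half the weight). The SE is the SD of the estimate across
    ``n_boot`` draws resampling each study's betas from
    ``Normal(observed, se)``; ``seed`` is required for reproducibility.
    """
    if len(instruments) < 3:
        raise ValueError("weighted_median needs >= 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives an unstable bootstrap SE")
    if seed is None:
        raise ValueError("seed is required for the bootstrap SE")
    bx, sx, by, sy = _arrays(instruments)
    r = by / bx
    w = bx**2 / sy**2
    point = _weighted_median_point(r, w)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(instruments)))
    by_star = rng.normal(by, sy, size=(n_boot, len(instruments)))
    r_star = by_star / bx_star
    w_star = bx_star**2 / sy**2
    boot = _weighted_median_rows(r_star, w_star)
    se = float(np.std(boot, ddof=1))
    return _estimate("weighted_median", point, se, len(instruments))


def cochran_q(
    instruments: Sequence[HarmonizedInstrument],
    reference_beta: float,
) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios about ``reference_beta``.

    ``Q = sum w_j (r_j - reference_beta)**2`` with IVW weights; p-value
    from chi-square on k-1 df; I-squared as the excess-over-df share of Q;
    tau-squared by the DerSimonian-Laird moment estimator.
    """
    if len(instruments) < 2:
        raise ValueError("cochran_q needs >= 2 instruments")
    bx, _, by, sy = _arrays(instruments)
    r = by / bx
    w = bx**2 / sy**2
    k = len(instruments)
    Q = float(np.sum(w * (r - reference_beta) ** 2))
    df = k - 1
    pvalue = float(stats.chi2.sf(Q, df))
    i_squared = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau_squared = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, pvalue=pvalue, i_squared=i_squared, tau_squared=tau_squared)
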