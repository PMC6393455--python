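"""MR power for a binary outcome and random-effects meta-analysis of SMDs.

Power follows the analytic binary-outcome approximation used by the mRnd
calculator: with case proportion K, odds ratio OR per 1-SD exposure change,
outcome-study size N and instrument variance explained r², the attenuated
risk-difference analogue is ``b = K*(OR/(1 + K*(OR-1)) - 1)``, its sampling
variance ``v = (K*(1-K) - b**2) / (N*r2)``, and power is the upper tail of
a non-central chi-square(1, ncp=b**2/v) beyond the central critical value.

The meta-analysis is the DerSimonian-Laird moment procedure on standardized
mean differences, with SEs recovered from 95% CIs via z = 1.96 when not
given directly; the fixed-effect pooled result is retained alongside the
random-effects one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PowerParams",
    "MetaStudy",
    "MetaResult",
    "se_from_ci",
    "power_binary_mr",
    "dl_meta",
]


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the binary-outcome MR power approximation."""

    n: int
    alpha: float = 0.05
    k_prev: float = 0.0596
    odds_ratio: float = 1.10
    r2: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.k_prev < 1):
            raise ValueError("k_prev must be in (0, 1)")
        if not self.odds_ratio > 0:
            raise ValueError("odds_ratio must be > 0")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must be in (0, 1)")


def power_binary_mr(params: PowerParams) -> float:
    """Statistical power of an MR analysis with a binary outcome."""
    K, OR = params.k_prev, params.odds_ratio
    b = K * (OR / (1.0 + K * (OR - 1.0)) - 1.0)
    v = (K * (1.0 - K) - b * b) / (params.n * params.r2)
    ncp = b * b / v
    crit = stats.chi2.ppf(1.0 - params.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def se_from_ci(low: float, high: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal confidence interval."""
    if not high > low:
        raise ValueError(f"need high > low, got ({low}, {high})")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float((high - low) / (2.0 * z))


@dataclass(frozen=True)
class MetaStudy:
    """One study's standardized mean difference, with CI or SE."""

    label: str
    smd: float
    ci_low: float | None = None
    ci_high: float | None = None
    se: float | None = None

    def __post_init__(self) -> None:
        if self.se is None and (self.ci_low is None or self.ci_high is None):
            raise ValueError(f"{self.label}: provide either se or a 95% CI")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low < self.smd < self.ci_high:
                raise ValueError(f"{self.label}: SMD must lie inside its CI")
        if self.se is not None and not self.se > 0:
            raise ValueError(f"{self.label}: se must be > 0")

    @property
    def standard_error(self) -> float:
        if self.se is not None:
            return self.se
        return se_from_ci(self.ci_low, self.ci_high)


@dataclass(frozen=True)
class MetaResult:
    pooled_smd: float
    se: float
    ci_low: float
    ci_high: float
    Q: float
    df: int
    p_het: float
    i_squared: float
    tau_squared: float
    pooled_smd_fixed: float
    se_fixed: float
    ci_low_fixed: float
    ci_high_fixed: float
    degenerate: bool = False


_Z95 = stats.norm.ppf(0.975)


def dl_meta(studies: Sequence[MetaStudy]) -> MetaResult:
    """DerSimonian-Laird random-effects meta-analysis of SMDs.

    Fixed weights ``1/se**2`` give Q and the moment estimate
    ``tau2 = max(0, (Q - df) / (sum(w) - sum(w**2)/sum(w)))``; random-
    effects weights ``1/(se**2 + tau2)`` give the pooled SMD with a normal
    95% CI. A single study yields a degenerate (flagged) result.
    """
    if len(studies) == 0:
        raise ValueError("dl_meta needs at least one study")
    y = np.array([s.smd for s in studies], dtype=float)
    se = np.array([s.standard_error for s in studies], dtype=float)
    w = 1.0 / se**2

    if len(studies) == 1:
        warnings.warn("single-study meta-analysis is degenerate", stacklevel=2)
        return MetaResult(
            pooled_smd=float(y[0]),
            se=float(se[0]),
            ci_low=float(y[0] - _Z95 * se[0]),
            ci_high=float(y[0] + _Z95 * se[0]),
            Q=0.0,
            df=0,
            p_het=1.0,
            i_squared=0.0,
            tau_squared=0.0,
            pooled_smd_fixed=float(y[0]),
            se_fixed=float(se[0]),
            ci_low_fixed=float(y[0] - _Z95 * se[0]),
            ci_high_fixed=float(y[0] + _Z95 * se[0]),
            degenerate=True,
        )

    fixed = float(np.sum(w * y) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    df = len(studies) - 1
    Q = float(np.sum(w * (y - fixed) ** 2))
    p_het = float(stats.chi2.sf(Q, df))
    i_squared = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau_squared = max(0.0, (Q - df) / denom) if denom > 0 else 0.0

    w_re = 1.0 / (se**2 + tau_squared)
    pooled = float(np.sum(w_re * y) / np.sum(w_re))
    se_re = float(np.sum(w_re) ** -0.5)
    return MetaResult(
        pooled_smd=pooled,
        se=se_re,
        ci_low=pooled - _Z95 * se_re,
        ci_high=pooled + _Z95 * se_re,
        Q=Q,
        df=df,
        p_het=p_het,
        i_squared=i_squared,
        tau_squared=tau_squared,
        pooled_smd_fixed=fixed,
        se_fixed=se_fixed,
        ci_low_fixed=fixed - _Z95 * se_fixed,
        ci_high_fixed=fixed + _Z95 * se_fixed,
        degenerate=False,
    )
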