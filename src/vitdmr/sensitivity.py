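"""Sensitivity analyses: leave-one-out, single-SNP forests, bidirectional
MR orchestration, and polygenic-score confounder checks.

The PRS confounder check mirrors the instrument-validity diagnostic:
combine the instruments into a per-person weighted allele score on the
exposure scale, then regress the score on candidate confounders (factor
coding for categorical ones) and report the overall model F-test p-value —
an association would flag a violated independence assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import estimators
from .estimators import MrEstimate
from .harmonize import HarmonizedInstrument, harmonize

__all__ = [
    "LeaveOneOutRow",
    "ConfounderCheckResult",
    "leave_one_out",
    "single_snp_forest",
    "bidirectional_mr",
    "build_prs",
    "confounder_check",
]

_METHOD_MIN_SNPS = {"ivw_fixed": 2, "ivw_mre": 2, "weighted_median": 3, "egger_slope": 3}


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_rsid: str
    estimate: MrEstimate


@dataclass
class ConfounderCheckResult:
    covariate: str
    model_pvalue: float
    group_means: dict | None  # level -> (mean, sd, n) for categorical covariates


def _run_method(
    instruments: Sequence[HarmonizedInstrument],
    method: str,
    n_boot: int,
    seed: int | None,
) -> MrEstimate:
    if method in ("ivw_fixed", "ivw_mre"):
        variant = "fixed" if method == "ivw_fixed" else "multiplicative_random"
        return estimators.ivw(instruments, variant=variant)
    if method == "weighted_median":
        return estimators.weighted_median(instruments, n_boot=n_boot, seed=seed)
    if method == "egger_slope":
        return estimators.mr_egger(instruments).slope
    raise ValueError(f"unknown estimator tag {method!r}")


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    method: str = "ivw_fixed",
    n_boot: int = 5000,
    seed: int | None = None,
) -> list:
    """Re-estimate the causal effect omitting each instrument in turn."""
    if len(instruments) < 3:
        raise ValueError("leave_one_out needs >= 3 instruments")
    needed = _METHOD_MIN_SNPS.get(method)
    if needed is None:
        raise ValueError(f"unknown estimator tag {method!r}")
    if len(instruments) - 1 < needed:
        raise ValueError(f"{method} needs {needed} instruments after omission")
    rows = []
    for i, snp in enumerate(instruments):
        remaining = [h for k, h in enumerate(instruments) if k != i]
        rows.append(
            LeaveOneOutRow(
                omitted_rsid=snp.rsid,
                estimate=_run_method(remaining, method, n_boot, seed),
            )
        )
    return rows


def single_snp_forest(instruments: Sequence[HarmonizedInstrument]) -> list:
    """Per-SNP Wald ratios with CIs, in input order (forest-plot table)."""
    if not instruments:
        raise ValueError("single_snp_forest needs >= 1 instrument")
    return [(h.rsid, estimators.wald_ratio(h)) for h in instruments]


def bidirectional_mr(
    forward: tuple,
    reverse: tuple,
    methods: Sequence[str] = ("ivw_fixed",),
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
    n_boot: int = 5000,
    seed: int | None = None,
) -> dict:
    """Run harmonization + estimation in both causal directions.

    ``forward`` and ``reverse`` are ``(exposure_set, outcome_set)`` pairs
    with independently selected instruments. Overlapping instrument sets
    between the directions trigger a warning (shared variants undermine the
    interpretation of the reverse analysis) but not an error.
    """
    fwd_exp, _ = forward
    rev_exp, _ = reverse
    overlap = set(fwd_exp.rsids) & set(rev_exp.rsids)
    if overlap:
        warnings.warn(
            f"instrument sets overlap between directions: {sorted(overlap)}",
            stacklevel=2,
        )
    result = {}
    for label, (exp_set, out_set) in (("forward", forward), ("reverse", reverse)):
        instruments, report = harmonize(
            exp_set, out_set, palindrome_policy=palindrome_policy, eaf_window=eaf_window
        )
        estimates = [_run_method(instruments, m, n_boot, seed) for m in methods]
        result[label] = {
            "instruments": instruments,
            "report": report,
            "estimates": estimates,
        }
    return result


def build_prs(
    genotypes: pd.DataFrame,
    weights: Mapping[str, float] | pd.Series,
    mean_impute: bool = False,
) -> pd.Series:
    """Weighted allele score per person, on the exposure scale.

    ``genotypes`` is a person x SNP dosage frame (dosages in [0, 2], NaN
    allowed); ``weights`` maps rsid to the per-allele exposure beta. A
    person with any missing dosage gets a missing score unless
    ``mean_impute`` replaces missing dosages by the column mean.
    """
    w = pd.Series(dict(weights), dtype=float)
    missing = [rsid for rsid in w.index if rsid not in genotypes.columns]
    if missing:
        raise KeyError(f"weight rsids absent from genotypes: {missing}")
    dosages = genotypes[list(w.index)].astype(float)
    arr = dosages.to_numpy()
    valid = np.isnan(arr) | ((arr >= 0) & (arr <= 2))
    if not valid.all():
        raise ValueError("dosages must lie in [0, 2]")
    if mean_impute:
        dosages = dosages.fillna(dosages.mean())
    score = dosages @ w
    score.name = "prs"
    return score


def confounder_check(
    prs: pd.Series,
    covariate: pd.Series,
    categorical: bool | None = None,
) -> ConfounderCheckResult:
    """Linear regression of the PRS on one candidate confounder.

    Categorical covariates enter as factor (dummy) variables and the
    overall model F-test p-value is reported, with per-level PRS mean/SD;
    continuous covariates use the same F-test on the single slope.
    ``categorical=None`` auto-detects from the covariate dtype.
    """
    import statsmodels.api as sm

    if len(prs) != len(covariate):
        raise ValueError("prs and covariate must be the same length")
    data = pd.DataFrame({"prs": np.asarray(prs, dtype=float), "cov": covariate.to_numpy()})
    data = data.dropna()
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(covariate) or pd.api.types.is_bool_dtype(
            covariate
        )
    name = covariate.name or "covariate"

    if categorical:
        levels = data["cov"].unique()
        if len(levels) < 2:
            raise ValueError(f"{name}: categorical covariate has a single level")
        X = pd.get_dummies(data["cov"].astype("category"), drop_first=True, dtype=float)
        group_means = {
            str(level): (
                float(sub.mean()),
                float(sub.std(ddof=1)) if len(sub) > 1 else float("nan"),
                int(len(sub)),
            )
            for level, sub in data.groupby("cov")["prs"]
        }
    else:
        X = data[["cov"]].astype(float)
        group_means = None
    fit = sm.OLS(data["prs"].to_numpy(), sm.add_constant(X.to_numpy())).fit()
    return ConfounderCheckResult(
        covariate=str(name),
        model_pvalue=float(fit.f_pvalue),
        group_means=group_means,
    )
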