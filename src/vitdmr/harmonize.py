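"""Align exposure and outcome summary statistics to a common orientation.

Two-sample MR requires the exposure and outcome effect estimates of every
instrument to refer to the same allele. This module (i) matches allele
pairs between studies, flipping the outcome effect when its effect allele
is the exposure's other allele, and (ii) re-orients every instrument so the
effect allele is the *exposure-decreasing* allele. After orientation
``beta_exposure`` is stored as a positive magnitude — the SD decrease in
the standardized log-scale exposure per copy of the effect allele — so the
MR slope ``beta_outcome / beta_exposure`` is the causal log-odds per 1-SD
*decrease* in the exposure, matching the direction the downstream odds
ratios are reported on.

Palindromic SNPs (A/T, C/G) are strand-ambiguous; they are either dropped
or oriented by comparing effect-allele frequencies between the two studies,
with an ambiguity window around 0.5 inside which no call is made.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .sumstats import SnpAssociation, SummaryStatsSet, SumstatsValidationError

__all__ = [
    "HarmonizedInstrument",
    "HarmonizationReport",
    "HarmonizationError",
    "harmonize",
    "rescale_external_beta",
    "harmonized_to_sets",
    "write_harmonized",
    "read_harmonized",
]

_PALINDROMIC_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))


class HarmonizationError(ValueError):
    pass


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Paired exposure/outcome statistics for one SNP, decreasing-allele oriented.

    ``beta_exposure`` > 0 is the SD decrease in exposure per effect-allele
    copy; ``beta_outcome`` is the log-odds change per copy of that same
    allele.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float

    def __post_init__(self) -> None:
        if not self.beta_exposure > 0:
            raise HarmonizationError(f"{self.rsid}: beta_exposure must be > 0 after orientation")
        if not self.se_exposure > 0:
            raise HarmonizationError(f"{self.rsid}: se_exposure must be > 0")
        if not self.se_outcome > 0:
            raise HarmonizationError(f"{self.rsid}: se_outcome must be > 0")


@dataclass
class HarmonizationReport:
    n_input: int = 0
    n_flipped: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_unmatched: int = 0
    dropped_rsids: list = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dropped_rsids is None:
            self.dropped_rsids = []

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_dropped_palindromic - self.n_dropped_unmatched

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_flipped": self.n_flipped,
            "n_dropped_palindromic": self.n_dropped_palindromic,
            "n_dropped_unmatched": self.n_dropped_unmatched,
            "dropped_rsids": list(self.dropped_rsids),
        }


def _is_palindromic(assoc: SnpAssociation) -> bool:
    return assoc.alleles in _PALINDROMIC_PAIRS


def harmonize(
    exposure: SummaryStatsSet,
    outcome: SummaryStatsSet,
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
):
    """Harmonize two studies onto the exposure-decreasing allele.

    Returns ``(instruments, report)``. Instruments are the rsid
    intersection, in exposure order. SNPs whose allele pairs disagree
    between studies, or palindromic SNPs that cannot be oriented under the
    chosen policy (``"drop"`` or ``"infer_by_eaf"``), are dropped and
    reported rather than raising.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    if len(exposure) == 0 or len(outcome) == 0:
        raise HarmonizationError("both summary-statistics sets must be non-empty")

    report = HarmonizationReport(n_input=len(exposure))
    instruments: list[HarmonizedInstrument] = []

    for exp in exposure:
        if exp.rsid not in outcome:
            report.n_dropped_unmatched += 1
            report.dropped_rsids.append(exp.rsid)
            continue
        out = outcome[exp.rsid]

        if out.alleles != exp.alleles:
            report.n_dropped_unmatched += 1
            report.dropped_rsids.append(exp.rsid)
            continue

        palindromic = _is_palindromic(exp)
        if palindromic and palindrome_policy == "drop":
            report.n_dropped_palindromic += 1
            report.dropped_rsids.append(exp.rsid)
            continue

        # label alignment: express the outcome on the exposure's effect allele
        flipped_labels = out.effect_allele != exp.effect_allele
        out_aligned = out.flipped() if flipped_labels else out

        if palindromic:
            # labels carry no strand information for A/T and C/G SNPs:
            # orient by frequency, refusing a call near 0.5
            if exp.eaf is None or out.eaf is None:
                report.n_dropped_palindromic += 1
                report.dropped_rsids.append(exp.rsid)
                continue
            if abs(exp.eaf - 0.5) < eaf_window or abs(out.eaf - 0.5) < eaf_window:
                report.n_dropped_palindromic += 1
                report.dropped_rsids.append(exp.rsid)
                continue
            if (exp.eaf < 0.5) != (out_aligned.eaf < 0.5):
                out_aligned = out_aligned.flipped()  # strand flip: swap back
                out_aligned = replace(
                    out_aligned,
                    effect_allele=exp.effect_allele,
                    other_allele=exp.other_allele,
                )
                flipped_labels = not flipped_labels

        if exp.beta == 0:
            raise HarmonizationError(
                f"{exp.rsid}: exposure beta is exactly zero; not a usable instrument"
            )

        if exp.beta < 0:
            # effect allele already decreases the exposure
            effect, other = exp.effect_allele, exp.other_allele
            beta_exp = -exp.beta
            beta_out = out_aligned.beta
            oriented_swap = False
        else:
            # swap to the other allele, which decreases the exposure
            effect, other = exp.other_allele, exp.effect_allele
            beta_exp = exp.beta
            beta_out = -out_aligned.beta
            oriented_swap = True

        if flipped_labels or oriented_swap:
            report.n_flipped += 1

        instruments.append(
            HarmonizedInstrument(
                rsid=exp.rsid,
                effect_allele=effect,
                other_allele=other,
                beta_exposure=beta_exp,
                se_exposure=exp.se,
                beta_outcome=beta_out,
                se_outcome=out_aligned.se,
            )
        )
    return instruments, report


def rescale_external_beta(
    target: SnpAssociation,
    shared_source: Sequence[SnpAssociation],
    shared_reference: Sequence[SnpAssociation],
) -> SnpAssociation:
    """Rescale an externally sourced association onto the reference GWAS scale.

    A through-origin least-squares slope ``s = sum(ref*src) / sum(src**2)``
    is fitted over SNPs shared between the external source study and the
    reference study (alleles pre-aligned, same rsids in the same order);
    the target's beta and SE are both multiplied by the slope. Used for the
    low-frequency CYP2R1 variant whose effect estimate comes from a
    different GWAS than the other six instruments.
    """
    if len(shared_source) < 2 or len(shared_reference) < 2:
        raise HarmonizationError("rescaling needs at least 2 shared SNPs")
    if len(shared_source) != len(shared_reference):
        raise HarmonizationError("shared_source and shared_reference differ in length")
    for s, r in zip(shared_source, shared_reference):
        if s.rsid != r.rsid:
            raise HarmonizationError(f"shared SNPs misordered: {s.rsid} vs {r.rsid}")
    src = np.array([a.beta for a in shared_source], dtype=float)
    ref = np.array([a.beta for a in shared_reference], dtype=float)
    denom = float(np.sum(src * src))
    if denom == 0.0:
        raise HarmonizationError("zero-variance source betas; slope undefined")
    slope = float(np.sum(ref * src)) / denom
    return replace(target, beta=target.beta * slope, se=target.se * abs(slope))


def harmonized_to_sets(
    instruments: Iterable[HarmonizedInstrument],
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
):
    """Express harmonized instruments back as two raw summary-stats sets.

    The exposure beta is written as ``-beta_exposure`` (raw semantics: the
    effect allele *decreases* the exposure), so re-harmonizing the returned
    sets reproduces the same instruments (idempotence).
    """
    exp = SummaryStatsSet.from_associations(
        (
            SnpAssociation(
                rsid=h.rsid,
                effect_allele=h.effect_allele,
                other_allele=h.other_allele,
                beta=-h.beta_exposure,
                se=h.se_exposure,
            )
            for h in instruments
        ),
        study_label=exposure_label,
    )
    out = SummaryStatsSet.from_associations(
        (
            SnpAssociation(
                rsid=h.rsid,
                effect_allele=h.effect_allele,
                other_allele=h.other_allele,
                beta=h.beta_outcome,
                se=h.se_outcome,
            )
            for h in instruments
        ),
        study_label=outcome_label,
    )
    return exp, out


_HARMONIZED_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
)


def write_harmonized(instruments: Sequence[HarmonizedInstrument], path) -> None:
    if not instruments:
        raise SumstatsValidationError("refusing to write an empty harmonized set")
    lines = ["\t".join(_HARMONIZED_COLUMNS)]
    for h in instruments:
        lines.append(
            "\t".join(
                [
                    h.rsid,
                    h.effect_allele,
                    h.other_allele,
                    format(h.beta_exposure, ".10g"),
                    format(h.se_exposure, ".10g"),
                    format(h.beta_outcome, ".10g"),
                    format(h.se_outcome, ".10g"),
                ]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_harmonized(path) -> list:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    for col in _HARMONIZED_COLUMNS:
        if col not in frame.columns:
            raise SumstatsValidationError(f"{path}: missing column {col!r}")
    return [
        HarmonizedInstrument(
            rsid=str(rec["rsid"]),
            effect_allele=str(rec["effect_allele"]),
            other_allele=str(rec["other_allele"]),
            beta_exposure=float(rec["beta_exposure"]),
            se_exposure=float(rec["se_exposure"]),
            beta_outcome=float(rec["beta_outcome"]),
            se_outcome=float(rec["se_outcome"]),
        )
        for rec in frame.to_dict("records")
    ]
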