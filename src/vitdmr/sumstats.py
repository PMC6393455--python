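"""GWAS summary-statistics containers and TSV input/output.

The canonical on-disk dialect is a UTF-8, tab-separated table with a header
row and the columns::

    rsid  effect_allele  other_allele  eaf  beta  se  pvalue  n

Missing values are written as ``NA``. ``rsid``, ``effect_allele``,
``other_allele``, ``beta`` and ``se`` are mandatory; ``eaf``, ``pvalue`` and
``n`` may be missing per row or absent as columns. A user-supplied column
map translates other dialects onto the canonical names at read time.

Betas are interpreted per copy of the effect allele: SD units of the
standardized log-transformed exposure (circulating 25OHD) for an exposure
study, log-odds units for a binary outcome study.
"""

from __future__ import annotations

import importlib.resources
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SnpAssociation",
    "SummaryStatsSet",
    "SumstatsError",
    "SumstatsFormatError",
    "SumstatsValidationError",
    "read_sumstats",
    "write_sumstats",
    "load_instrument_fixture",
]

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

CANONICAL_COLUMNS = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n")
MANDATORY_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se")


class SumstatsError(ValueError):
    """Base class for summary-statistics errors."""


class SumstatsFormatError(SumstatsError):
    """The file does not conform to the expected tabular layout."""


class SumstatsValidationError(SumstatsError):
    """A row violates a field invariant (alleles, SE, frequency, ...)."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association summary in one study.

    ``beta`` is the effect per copy of ``effect_allele``; ``se`` its standard
    error (> 0). ``eaf`` is the effect-allele frequency, optional but needed
    for frequency-based palindromic-SNP inference downstream.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in VALID_ALLELES:
            raise SumstatsValidationError(
                f"{self.rsid}: effect_allele {self.effect_allele!r} is not a single-nucleotide allele"
            )
        if self.other_allele not in VALID_ALLELES:
            raise SumstatsValidationError(
                f"{self.rsid}: other_allele {self.other_allele!r} is not a single-nucleotide allele"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsValidationError(f"{self.rsid}: effect and other allele are identical")
        if not np.isfinite(self.beta):
            raise SumstatsValidationError(f"{self.rsid}: beta is not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise SumstatsValidationError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SumstatsValidationError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise SumstatsValidationError(f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]")
        if self.n is not None and self.n <= 0:
            raise SumstatsValidationError(f"{self.rsid}: n must be positive, got {self.n}")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    def flipped(self) -> "SnpAssociation":
        """The same association expressed on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class SummaryStatsSet:
    """An ordered, rsid-keyed collection of :class:`SnpAssociation`."""

    study_label: str = ""
    trait: str = ""
    associations: "OrderedDict[str, SnpAssociation]" = field(default_factory=OrderedDict)

    @classmethod
    def from_associations(
        cls, assocs: Iterable[SnpAssociation], study_label: str = "", trait: str = ""
    ) -> "SummaryStatsSet":
        out: "OrderedDict[str, SnpAssociation]" = OrderedDict()
        for a in assocs:
            if a.rsid in out:
                raise SumstatsValidationError(f"duplicate rsid {a.rsid}")
            out[a.rsid] = a
        return cls(study_label=study_label, trait=trait, associations=out)

    def __len__(self) -> int:
        return len(self.associations)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.associations.values())

    def __getitem__(self, rsid: str) -> SnpAssociation:
        return self.associations[rsid]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.associations

    @property
    def rsids(self) -> list:
        return list(self.associations)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": a.rsid,
                "effect_allele": a.effect_allele,
                "other_allele": a.other_allele,
                "eaf": a.eaf,
                "beta": a.beta,
                "se": a.se,
                "pvalue": a.pvalue,
                "n": a.n,
            }
            for a in self
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _parse_optional_float(value, row: int, name: str) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SumstatsFormatError(f"row {row}: cannot parse {name}={value!r} as a number") from None


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    study_label: str | None = None,
    trait: str = "",
) -> SummaryStatsSet:
    """Read a tab-separated summary-statistics table.

    ``column_map`` maps file column names onto the canonical names, e.g.
    ``{"SNP": "rsid", "A1": "effect_allele"}``. Rows violating a field
    invariant raise :class:`SumstatsValidationError` citing the 1-based data
    row; a missing mandatory column raises :class:`SumstatsFormatError`
    naming the column.
    """
    try:
        frame = pd.read_csv(path, sep="\t", na_values=["NA"], dtype=str)
    except pd.errors.EmptyDataError:
        raise SumstatsFormatError(f"{path}: file is empty") from None
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise SumstatsFormatError(f"{path}: missing mandatory column {col!r}")

    assocs: "OrderedDict[str, SnpAssociation]" = OrderedDict()
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        rsid = rec["rsid"]
        if rsid is None or (isinstance(rsid, float) and np.isnan(rsid)):
            raise SumstatsValidationError(f"row {i}: missing rsid")
        if rsid in assocs:
            raise SumstatsValidationError(f"row {i}: duplicate rsid {rsid}")
        beta = _parse_optional_float(rec.get("beta"), i, "beta")
        se = _parse_optional_float(rec.get("se"), i, "se")
        if beta is None or se is None:
            raise SumstatsValidationError(f"row {i} ({rsid}): beta and se are mandatory")
        n = _parse_optional_float(rec.get("n"), i, "n")
        try:
            assoc = SnpAssociation(
                rsid=str(rsid),
                effect_allele=rec.get("effect_allele"),
                other_allele=rec.get("other_allele"),
                beta=beta,
                se=se,
                eaf=_parse_optional_float(rec.get("eaf"), i, "eaf"),
                pvalue=_parse_optional_float(rec.get("pvalue"), i, "pvalue"),
                n=None if n is None else int(round(n)),
            )
        except SumstatsValidationError as exc:
            raise SumstatsValidationError(f"row {i}: {exc}") from None
        assocs[assoc.rsid] = assoc
    label = study_label if study_label is not None else str(path)
    return SummaryStatsSet(study_label=label, trait=trait, associations=assocs)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return format(float(value), ".10g")


def write_sumstats(sset: SummaryStatsSet, path) -> None:
    """Write ``sset`` in the canonical dialect (see module docstring)."""
    if len(sset) == 0:
        raise SumstatsValidationError("refusing to write an empty summary-statistics set")
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for a in sset:
        lines.append(
            "\t".join(
                [
                    a.rsid,
                    a.effect_allele,
                    a.other_allele,
                    _fmt(a.eaf),
                    _fmt(a.beta),
                    _fmt(a.se),
                    _fmt(a.pvalue),
                    _fmt(a.n),
                ]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_instrument_fixture() -> SummaryStatsSet:
    """The seven-SNP 25OHD instrument panel with synthetic effect sizes.

    The rsids are the seven published 25OHD instruments (GC, DHCR7, CYP2R1
    x2, CYP24A1, SEC23A, AMDHD1); the alleles, frequencies and effect
    estimates are simulated stand-ins, since the original supplementary
    effect estimates are not redistributed here. The panel mimics the
    published structure — one dominant common signal and one low-frequency
    larger-effect variant — and supports format, harmonization and pipeline
    tests, not reproduction of the published causal estimates.
    """
    ref = importlib.resources.files("vitdmr").joinpath("data/instruments_25ohd_synthetic.tsv")
    with importlib.resources.as_file(ref) as p:
        return read_sumstats(p, study_label="synthetic_25ohd_panel", trait="25OHD")
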