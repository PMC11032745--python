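"""Lethality Ratio, SDLI and SALI construction.

The index is built in five steps from a reference year (2017 in the original
Ohio application, the peak overdose year there):

1. count unintentional overdose deaths attributable to exactly one drug
   category ("single-drug deaths"), per drug;
2. count seizure events in which exactly one drug category was identified
   ("single-drug / pure seizures"), per drug;
3. Lethality Ratio LR = single-drug deaths / single-drug seizures;
4. Street-Drug Lethality Index SDLI(drug, year) = LR(drug) × all seizures of
   that drug in the year, counting mixed seizures once per involved drug;
5. Summed Annual Lethality Index SALI(year) = Σ_drug SDLI(drug, year).

Only seizure counts vary by year: deaths enter solely through the
reference-year lethality ratios.  LR values are carried at full floating
precision; reporting rounds to 3 decimals half-away-from-zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, UndefinedRatioError
from .records import DeathRecord, SeizureRecord, is_other

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (spreadsheet-style), e.g. 0.0435 → 0.044."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def effective_substances(substances: frozenset[str], ignore_other: bool = False) -> frozenset[str]:
    """Substance set used for counting; optionally ignores ``other:*`` categories.

    By default non-indexed substances count against single-drug status (a
    fentanyl + alcohol toxicology is not a single-drug fentanyl death); with
    ``ignore_other=True`` they are disregarded.
    """
    if not ignore_other:
        return substances
    return frozenset(s for s in substances if not is_other(s))


def count_single_drug_deaths(
    deaths: Iterable[DeathRecord],
    drug: str,
    year: int,
    ignore_other: bool = False,
) -> int:
    """Step 1: deaths in ``year`` whose toxicology is exactly ``{drug}``.

    Callers are expected to pass records already filtered to unintentional
    causes (X40–X44).
    """
    n = 0
    for d in deaths:
        if d.year == year and effective_substances(d.tox_substances, ignore_other) == frozenset({drug}):
            n += 1
    return n


def count_single_drug_seizures(
    seizures: Iterable[SeizureRecord],
    drug: str,
    year: int,
    ignore_other: bool = False,
) -> int:
    """Step 2: seizures in ``year`` in which only ``drug`` was identified."""
    n = 0
    for s in seizures:
        if s.year == year and effective_substances(s.substances, ignore_other) == frozenset({drug}):
            n += 1
    return n


def count_all_seizures(
    seizures: Iterable[SeizureRecord],
    drug: str,
    year: int,
    ignore_other: bool = False,
) -> int:
    """All seizures (single + mixed) of ``drug`` in ``year``.

    A mixed seizure containing k indexed drugs contributes 1 to each of the
    k drugs' totals.
    """
    n = 0
    for s in seizures:
        if s.year == year and drug in effective_substances(s.substances, ignore_other):
            n += 1
    return n


def lethality_ratio(single_deaths: int, single_seizures: int, drug: str | None = None) -> float:
    """Step 3: single-drug deaths per single-drug seizure (full precision)."""
    if single_seizures <= 0:
        raise UndefinedRatioError(
            f"lethality ratio undefined for {drug or 'drug'}: "
            f"zero single-drug seizures in the reference year"
        )
    if single_deaths < 0:
        raise ValueError("single_deaths must be non-negative")
    return single_deaths / single_seizures


@dataclass(frozen=True)
class LethalityEntry:
    """Steps 1–3 for one drug: counts and the exact (unrounded) ratio."""

    drug: str
    single_deaths: int
    single_seizures: int
    lr: float

    @property
    def lr_3dp(self) -> float:
        return round_half_up(self.lr, 3)


@dataclass(frozen=True)
class LethalityTable:
    """Per-drug lethality ratios anchored to one reference year."""

    reference_year: int
    entries: tuple[LethalityEntry, ...]

    def __post_init__(self) -> None:
        drugs = [e.drug for e in self.entries]
        if len(drugs) != len(set(drugs)):
            raise ConfigurationError("duplicate drug in lethality table")

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(e.drug for e in self.entries)

    def lr(self, drug: str) -> float:
        for e in self.entries:
            if e.drug == drug:
                return e.lr
        raise KeyError(drug)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.drug, e.single_deaths, e.single_seizures, e.lr) for e in self.entries],
            columns=["drug", "single_deaths", "single_seizures", "lr"],
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["lr"] = df["lr"].map(lambda v: f"{round_half_up(v, 3):.3f}")
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class SDLIEntry:
    """Step 4 for one (drug, year): LR × all seizures of the drug that year."""

    drug: str
    year: int
    all_seizures: int
    sdli: float


@dataclass(frozen=True)
class SALISeries:
    """Step 5: year → summed annual lethality index (regression predictor)."""

    values: dict[int, float]
    drugs_included: frozenset[str]
    entries: tuple[SDLIEntry, ...] = field(default_factory=tuple)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(y, self.values[y]) for y in self.years], columns=["year", "sali"]
        )

    def entries_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.drug, e.year, e.all_seizures, e.sdli) for e in self.entries],
            columns=["drug", "year", "all_seizures", "sdli"],
        )


def build_lethality_table(
    deaths: Iterable[DeathRecord],
    seizures: Iterable[SeizureRecord],
    reference_year: int,
    drugs: Sequence[str],
    ignore_other: bool = False,
) -> LethalityTable:
    """Compute Steps 1–3 for each drug in the reference year.

    ``deaths`` must already be filtered to unintentional causes.  Drugs with
    zero single-drug seizures in the reference year are excluded (with a
    warning) rather than assigned a fabricated ratio.
    """
    if not drugs:
        raise ConfigurationError("empty drug list for lethality table")
    deaths = list(deaths)
    seizures = list(seizures)
    entries = []
    for drug in drugs:
        n_deaths = count_single_drug_deaths(deaths, drug, reference_year, ignore_other)
        n_seizures = count_single_drug_seizures(seizures, drug, reference_year, ignore_other)
        if n_seizures == 0:
            logger.warning(
                "drug %s: no single-drug seizures in %d; excluded from lethality table",
                drug, reference_year,
            )
            continue
        entries.append(
            LethalityEntry(drug, n_deaths, n_seizures, lethality_ratio(n_deaths, n_seizures, drug))
        )
    return LethalityTable(reference_year, tuple(entries))


def compute_sali_series(
    table: LethalityTable,
    seizures: Iterable[SeizureRecord],
    years: Sequence[int],
    ignore_other: bool = False,
) -> SALISeries:
    """Steps 4–5: per-drug SDLI and the annual sum over the table's drugs.

    Drugs absent from the table contribute nothing; deaths never enter here —
    only the fixed reference-year ratios and each year's seizure counts.
    """
    if not years:
        raise ConfigurationError("empty year list for SALI series")
    if not table.entries:
        raise ConfigurationError("empty lethality table")
    seizures = list(seizures)
    sdli_entries: list[SDLIEntry] = []
    values: dict[int, float] = {}
    for year in years:
        total = 0.0
        for entry in table.entries:
            n_all = count_all_seizures(seizures, entry.drug, year, ignore_other)
            sdli = entry.lr * n_all
            sdli_entries.append(SDLIEntry(entry.drug, year, n_all, sdli))
            total += sdli
        values[year] = total
    return SALISeries(values, frozenset(table.drugs), tuple(sdli_entries))
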