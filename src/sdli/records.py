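"""Case-level seizure and death records: reading, validation, normalization.

The analytic unit throughout the package is the *drug category*, not the raw
substance name reported by a crime lab or a toxicology panel.  Six categories
are indexed (fentanyl, cocaine, prescription opioids, heroin, amphetamines,
benzodiazepines); anything else is carried as an ``other:<token>`` category or
dropped, depending on the mapping policy.

Unintentional overdose deaths are identified by ICD-10 underlying cause of
death codes X40–X44 (accidental poisoning by drugs).  Matching is on the first
three characters, case-insensitively, so registry exports with decimal
suffixes ("X42.1") are accepted.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, FormatError, RowParseError

logger = logging.getLogger(__name__)

#: The six analytic drug categories, in reporting order.
ANALYTIC_CATEGORIES: tuple[str, ...] = (
    "fentanyl",
    "cocaine",
    "prescription_opioids",
    "heroin",
    "amphetamines",
    "benzodiazepines",
)

OTHER_PREFIX = "other:"

_UNINTENTIONAL_RE = re.compile(r"^X4[0-4]", re.IGNORECASE)

#: The five ICD-10 three-character categories for accidental drug poisoning.
UNINTENTIONAL_ICD10 = ("X40", "X41", "X42", "X43", "X44")


def other_category(token: str) -> str:
    """Return the open-escape category for an unmapped substance name."""
    return OTHER_PREFIX + token.strip().lower()


def is_other(category: str) -> bool:
    return category.startswith(OTHER_PREFIX)


def is_analytic(category: str) -> bool:
    return category in ANALYTIC_CATEGORIES


@dataclass(frozen=True)
class SubstanceMapping:
    """Raw substance name → drug category lookup.

    Parameters
    ----------
    entries
        Mapping from (case-folded, trimmed) raw names to categories.  Loaded
        from a user-editable two-column CSV rather than hard-coded, because
        lab naming conventions vary by jurisdiction.
    unmapped_policy
        What to do with a raw name absent from ``entries``:
        ``"keep_as_other"`` (default) carries it as ``other:<name>``,
        ``"drop"`` discards it, and ``None`` raises a configuration error.
    """

    entries: Mapping[str, str] = field(default_factory=dict)
    unmapped_policy: str | None = "keep_as_other"

    def __post_init__(self) -> None:
        if self.unmapped_policy not in ("drop", "keep_as_other", None):
            raise ConfigurationError(
                f"unknown unmapped_policy {self.unmapped_policy!r}; "
                "expected 'drop', 'keep_as_other' or None"
            )
        # normalize keys once so lookups are case/whitespace-insensitive
        normalized = {k.strip().lower(): v.strip().lower() for k, v in self.entries.items()}
        object.__setattr__(self, "entries", normalized)

    @classmethod
    def from_csv(cls, path: str | Path, unmapped_policy: str | None = "keep_as_other") -> "SubstanceMapping":
        """Load a two-column ``raw_name,category`` CSV."""
        df = pd.read_csv(path, dtype=str)
        required = {"raw_name", "category"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"substance mapping {path} must have columns raw_name,category; "
                f"found {list(df.columns)}"
            )
        return cls(dict(zip(df["raw_name"], df["category"])), unmapped_policy)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["raw_name", "category"])
            for raw, cat in sorted(self.entries.items()):
                w.writerow([raw, cat])

    @classmethod
    def default(cls, unmapped_policy: str | None = "keep_as_other") -> "SubstanceMapping":
        """Identity mapping over the six analytic categories.

        Suitable for data (e.g. the synthetic generator's output) whose
        substance field already uses category tokens.
        """
        return cls({c: c for c in ANALYTIC_CATEGORIES}, unmapped_policy)


def normalize_substance(raw: str, mapping: SubstanceMapping) -> str | None:
    """Map one raw substance name to a drug category.

    Lookup is case-insensitive and whitespace-trimmed.  Returns ``None`` when
    the name is unmapped and the policy is ``"drop"``; raises
    :class:`ConfigurationError` when unmapped and no policy is set.
    """
    key = raw.strip().lower()
    if not key:
        raise ConfigurationError("empty substance name")
    if key in mapping.entries:
        return mapping.entries[key]
    if mapping.unmapped_policy == "keep_as_other":
        return other_category(key)
    if mapping.unmapped_policy == "drop":
        return None
    raise ConfigurationError(
        f"substance {raw!r} is not in the mapping and no unmapped_policy is set"
    )


@dataclass(frozen=True, order=True)
class SeizureRecord:
    """One lab-confirmed seizure event.

    ``substances`` is the deduplicated set of drug categories identified in
    the exhibit(s); single-drug status is defined at the category level, after
    normalization.
    """

    seizure_id: str
    date: _dt.date
    substances: frozenset[str] = field(compare=False)
    county: str | None = None

    def __post_init__(self) -> None:
        if not self.substances:
            raise ValueError(f"seizure {self.seizure_id}: empty substance set")

    @property
    def is_single_drug(self) -> bool:
        return len(self.substances) == 1

    @property
    def year(self) -> int:
        return self.date.year


@dataclass(frozen=True, order=True)
class DeathRecord:
    """One decedent: ICD-10 underlying cause plus toxicology substance set."""

    death_id: str
    date_of_death: _dt.date
    icd10_underlying: str
    tox_substances: frozenset[str] = field(compare=False)

    def __post_init__(self) -> None:
        if not self.tox_substances:
            raise ValueError(f"death {self.death_id}: empty toxicology set")

    @property
    def is_single_drug(self) -> bool:
        return len(self.tox_substances) == 1

    @property
    def is_unintentional(self) -> bool:
        """True when the underlying cause is X40–X44 (first three characters)."""
        return bool(_UNINTENTIONAL_RE.match(self.icd10_underlying.strip()))

    @property
    def year(self) -> int:
        return self.date_of_death.year


# ---------------------------------------------------------------------------
# CSV reading/writing
# ---------------------------------------------------------------------------

SEIZURE_COLUMNS = ("seizure_id", "date", "county", "substances")
DEATH_COLUMNS = ("death_id", "date_of_death", "icd10_underlying", "tox_substances")
SUBSTANCE_DELIM = "|"


def _parse_date(value: str) -> _dt.date:
    return _dt.date.fromisoformat(str(value).strip())


def _normalize_set(raw_field: str, mapping: SubstanceMapping) -> frozenset[str]:
    cats = set()
    for name in str(raw_field).split(SUBSTANCE_DELIM):
        if not name.strip():
            continue
        cat = normalize_substance(name, mapping)
        if cat is not None:
            cats.add(cat)
    return frozenset(cats)


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"expected {list(required)}"
        )
    return df


def read_seizures(path: str | Path, mapping: SubstanceMapping) -> list[SeizureRecord]:
    """Read a seizure CSV into normalized records.

    One record per ``seizure_id``: duplicate rows are merged (substance-set
    union) with a warning.  Rows whose substance set is empty after mapping
    (all names dropped) are dropped with a warning.  Unparseable dates raise a
    :class:`RowParseError` listing the offending row numbers (1-based data
    rows).
    """
    df = _read_table(path, SEIZURE_COLUMNS)
    bad_rows: list[int] = []
    by_id: dict[str, SeizureRecord] = {}
    n_dropped = 0
    n_merged = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            date = _parse_date(row.date)
        except ValueError:
            bad_rows.append(i)
            continue
        subs = _normalize_set(row.substances, mapping)
        if not subs:
            n_dropped += 1
            logger.warning(
                "seizure %s (row %d): empty substance set after mapping; dropped",
                row.seizure_id, i,
            )
            continue
        county = str(row.county).strip() or None
        sid = str(row.seizure_id).strip()
        if sid in by_id:
            prev = by_id[sid]
            by_id[sid] = SeizureRecord(sid, prev.date, prev.substances | subs, prev.county)
            n_merged += 1
            logger.warning("duplicate seizure_id %s (row %d): merged substance sets", sid, i)
        else:
            by_id[sid] = SeizureRecord(sid, date, subs, county)
    if bad_rows:
        raise RowParseError(f"{path}: unparseable date(s)", bad_rows)
    logger.info(
        "read %d seizure rows from %s: %d records, %d dropped, %d merged",
        len(df), path, len(by_id), n_dropped, n_merged,
    )
    return sorted(by_id.values(), key=lambda r: r.seizure_id)


def read_deaths(path: str | Path, mapping: SubstanceMapping) -> list[DeathRecord]:
    """Read a death-record CSV into normalized records.

    No cause-of-death filtering happens here; see :func:`filter_unintentional`.
    """
    df = _read_table(path, DEATH_COLUMNS)
    bad_rows: list[int] = []
    by_id: dict[str, DeathRecord] = {}
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            date = _parse_date(row.date_of_death)
        except ValueError:
            bad_rows.append(i)
            continue
        subs = _normalize_set(row.tox_substances, mapping)
        if not subs:
            n_dropped += 1
            logger.warning(
                "death %s (row %d): empty toxicology set after mapping; dropped",
                row.death_id, i,
            )
            continue
        did = str(row.death_id).strip()
        if did in by_id:
            prev = by_id[did]
            by_id[did] = DeathRecord(did, prev.date_of_death, prev.icd10_underlying,
                                     prev.tox_substances | subs)
            logger.warning("duplicate death_id %s (row %d): merged toxicology sets", did, i)
        else:
            by_id[did] = DeathRecord(did, date, str(row.icd10_underlying).strip(), subs)
    if bad_rows:
        raise RowParseError(f"{path}: unparseable date(s)", bad_rows)
    logger.info(
        "read %d death rows from %s: %d records, %d dropped",
        len(df), path, len(by_id), n_dropped,
    )
    return sorted(by_id.values(), key=lambda r: r.death_id)


def filter_unintentional(deaths: Iterable[DeathRecord]) -> list[DeathRecord]:
    """Keep only deaths with ICD-10 underlying cause X40–X44.

    Idempotent; output is always a subset of the input.
    """
    kept = [d for d in deaths if d.is_unintentional]
    return kept


def write_seizures(records: Iterable[SeizureRecord], path: str | Path) -> None:
    """Write seizure records to the canonical CSV dialect (sorted by id)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SEIZURE_COLUMNS)
        for r in sorted(records, key=lambda r: r.seizure_id):
            w.writerow([
                r.seizure_id,
                r.date.isoformat(),
                r.county or "",
                SUBSTANCE_DELIM.join(sorted(r.substances)),
            ])


def write_deaths(records: Iterable[DeathRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DEATH_COLUMNS)
        for r in sorted(records, key=lambda r: r.death_id):
            w.writerow([
                r.death_id,
                r.date_of_death.isoformat(),
                r.icd10_underlying,
                SUBSTANCE_DELIM.join(sorted(r.tox_substances)),
            ])
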