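"""Core domain objects: traits, growth habits, study metadata and the
plot-level phenotype dataset.

A *record* is one plot-level observation of one trait for one accession in one
harvest year.  Records live in a pandas DataFrame with the canonical columns
``accession_id`` (str), ``harvest_year`` (int), ``value`` (float) and
``replicate_index`` (int, 1-based within accession x year).  Winter and spring
material are never pooled in one dataset: flowering time is counted from
different reference dates for the two habits.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import HistphenoError

RECORD_COLUMNS = ["accession_id", "harvest_year", "value", "replicate_index"]


class Trait(enum.Enum):
    """Traits assessed during seed regeneration.

    FT: flowering time in days (after Jan 1 for winter habit, after sowing for
    spring habit).  PH: plant height in cm.  TGW: thousand grain weight in g.
    """

    FT = "FT"
    PH = "PH"
    TGW = "TGW"

    @classmethod
    def coerce(cls, value: "Trait | str") -> "Trait":
        if isinstance(value, cls):
            return value
        return cls[str(value).upper()]


class Habit(enum.Enum):
    """Growth habit: spring (no vernalization requirement) or winter."""

    SPRING = "spring"
    WINTER = "winter"

    @classmethod
    def coerce(cls, value: "Habit | str") -> "Habit":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass
class StudyRow:
    """Accession-level metadata from a study file.

    ``accession_id`` is the stable, unique genebank code; ``accession_number``
    is the mutable researcher-facing code.  ``sowing_date`` is kept as the
    textual "day.month.year" plus a parsed (day, month, year) triple; no
    calendar arithmetic is ever done with it.
    """

    accession_id: str
    accession_number: str = ""
    sowing_date: str = ""
    harvest_year: int | None = None
    country: str = ""
    comment: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not str(self.accession_id).strip():
            raise HistphenoError("accession_id must be non-empty")
        self.accession_id = str(self.accession_id)

    @property
    def sowing_dmy(self) -> tuple[int, int, int] | None:
        """Parsed (day, month, year) of the sowing date, or None."""
        parts = str(self.sowing_date).split(".")
        if len(parts) == 3:
            try:
                d, m, y = (int(p) for p in parts)
                return (d, m, y)
            except ValueError:
                return None
        return None


def records_frame(rows) -> pd.DataFrame:
    """Build a canonical record DataFrame from an iterable of
    (accession_id, harvest_year, value) or (..., replicate_index) tuples.

    When replicate_index is omitted it is assigned by order of appearance
    within each (accession, year) cell, starting at 1.
    """
    rows = list(rows)
    if not rows:
        return pd.DataFrame(columns=RECORD_COLUMNS).astype(
            {"accession_id": str, "harvest_year": int, "value": float, "replicate_index": int}
        )
    width = len(rows[0])
    if width == 3:
        df = pd.DataFrame(rows, columns=RECORD_COLUMNS[:3])
        df["replicate_index"] = df.groupby(["accession_id", "harvest_year"]).cumcount() + 1
    elif width == 4:
        df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    else:
        raise HistphenoError("record rows must have 3 or 4 fields")
    df["accession_id"] = df["accession_id"].astype(str)
    df["harvest_year"] = df["harvest_year"].astype(int)
    df["value"] = df["value"].astype(float)
    df["replicate_index"] = df["replicate_index"].astype(int)
    return df


@dataclass
class HistoricalDataset:
    """A collection of plot-level records for one trait x growth habit.

    ``study`` maps accession_id -> :class:`StudyRow` and may be absent (None).
    ``rejections`` documents input rows that were refused by a reader; it is
    provenance, not data, and defaults to empty.
    """

    trait: Trait
    habit: Habit
    records: pd.DataFrame
    study: Mapping[str, StudyRow] | None = None
    rejections: pd.DataFrame | None = None

    def __post_init__(self):
        self.trait = Trait.coerce(self.trait)
        self.habit = Habit.coerce(self.habit)
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise HistphenoError(f"records frame lacks columns: {missing}")
        self.records = self.records.reset_index(drop=True)

    # -- basic views -------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def accessions(self) -> list[str]:
        return sorted(self.records["accession_id"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.records["harvest_year"].unique())

    def validate(self) -> None:
        """Check dataset invariants; raise :class:`HistphenoError` on failure."""
        df = self.records
        vals = df["value"].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise HistphenoError("non-finite trait values present")
        if np.any(vals <= 0):
            raise HistphenoError("trait values must be strictly positive")
        key = ["accession_id", "harvest_year", "replicate_index"]
        if df.duplicated(key).any():
            dupes = df[df.duplicated(key, keep=False)].head()
            raise HistphenoError(f"duplicate (accession, year, replicate) keys:\n{dupes}")
        if self.study is not None:
            missing = set(df["accession_id"]) - set(self.study)
            if missing:
                raise HistphenoError(
                    f"{len(missing)} accession(s) absent from study metadata, "
                    f"e.g. {sorted(missing)[:5]}"
                )

    def subset(self, keep_mask) -> "HistoricalDataset":
        """New dataset restricted to records where ``keep_mask`` is True."""
        return HistoricalDataset(
            trait=self.trait,
            habit=self.habit,
            records=self.records[np.asarray(keep_mask, bool)].reset_index(drop=True),
            study=self.study,
        )

    def cell_means(self) -> pd.DataFrame:
        """Accession x year table of within-cell (replicate-averaged) means."""
        return (
            self.records.groupby(["accession_id", "harvest_year"])["value"]
            .mean()
            .unstack("harvest_year")
        )

    def records_per_accession(self) -> pd.Series:
        return self.records.groupby("accession_id").size()

    def distinct_years_per_accession(self) -> pd.Series:
        return self.records.groupby("accession_id")["harvest_year"].nunique()
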