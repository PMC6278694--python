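"""Readers and writers for the tab-delimited study/assay files and the
pipeline outputs.

The on-disk layout follows the ISA-Tab habit of the deposited genebank files:
UTF-8, tab-delimited, one header line, one row per entity.  Study files carry
accession metadata; assay files carry one row per plot-level observation with
one column per trait.  Column headers are matched case-insensitively through a
configurable alias map, since real-world files vary between "accession_id" and
"Accession ID" styles.  Decimal separators must be "."; a "," decimal is
rejected with a clear error rather than guessed at.

Readers never silently drop data: rows that cannot be parsed are returned as a
rejections report alongside the accepted records, and the two always add up to
the row count of the file.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .curation import OutlierReport
from .datatypes import Habit, HistoricalDataset, StudyRow, Trait, records_frame
from .errors import DataFormatError, RowParseError
from . import mm_engine
from .mm_engine import FitResult

STUDY_COLUMNS = ["accession_id", "accession_number", "sowing_date",
                 "harvest_year", "country", "comment"]

#: normalized header -> canonical study column
DEFAULT_STUDY_ALIASES = {
    "accession_id": "accession_id",
    "accession_number": "accession_number",
    "sowing_date": "sowing_date",
    "harvest_year": "harvest_year",
    "country": "country",
    "comment": "comment",
}

#: normalized header -> canonical assay column (trait columns by trait name)
DEFAULT_ASSAY_ALIASES = {
    "accession_id": "accession_id",
    "harvest_year": "harvest_year",
    "year": "harvest_year",
    "ft": "FT",
    "flowering_time": "FT",
    "ph": "PH",
    "plant_height": "PH",
    "tgw": "TGW",
    "thousand_grain_weight": "TGW",
}

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")
_MISSING = {"", "na", "n/a", "nan", "."}


def _normalize_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


def _parse_number(text: str, line_number: int) -> float:
    text = text.strip()
    if _DECIMAL_COMMA.match(text):
        raise RowParseError(
            f"value {text!r} uses a ',' decimal separator; files must use '.'",
            line_number,
        )
    try:
        return float(text)
    except ValueError:
        raise RowParseError(f"non-numeric value {text!r}", line_number) from None


def _read_table(path: Path) -> tuple[list[str], list[list[str]]]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise DataFormatError(f"{path}: file is empty (no header line)")
    header = lines[0].rstrip("\n").split("\t")
    rows = []
    for line in lines[1:]:
        if line.strip() == "":
            continue
        cells = line.split("\t")
        cells += [""] * (len(header) - len(cells))  # tolerate short rows
        rows.append(cells)
    return header, rows


# ---------------------------------------------------------------------------
# study files
# ---------------------------------------------------------------------------

def read_study(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    year_bounds: tuple[int, int] | None = (1946, 2015),
) -> list[StudyRow]:
    """Read a study file into :class:`StudyRow` objects, order preserved.

    Unknown columns are preserved in each row's ``extras`` map.  A missing
    ``accession_id`` column is a format error; an unparseable harvest year is
    a row-level error carrying the line number.  ``year_bounds`` bounds the
    harvest years (None disables the check).
    """
    aliases = {**DEFAULT_STUDY_ALIASES, **(aliases or {})}
    header, rows = _read_table(Path(path))
    mapped = [aliases.get(_normalize_header(h), None) for h in header]
    if "accession_id" not in mapped:
        raise DataFormatError(
            f"{path}: mandatory column 'accession_id' not found in header {header}"
        )
    out = []
    for lineno, cells in enumerate(rows, start=2):
        fields: dict = {"extras": {}}
        for raw_name, canon, cell in zip(header, mapped, cells):
            cell = cell.strip()
            if canon is None:
                fields["extras"][raw_name] = cell
            elif canon == "harvest_year":
                if cell.lower() in _MISSING:
                    fields[canon] = None
                    continue
                try:
                    year = int(cell)
                except ValueError:
                    raise RowParseError(
                        f"unparseable harvest_year {cell!r}", lineno) from None
                if year_bounds and not (year_bounds[0] <= year <= year_bounds[1]):
                    raise RowParseError(
                        f"harvest_year {year} outside bounds {year_bounds}", lineno)
                fields[canon] = year
            else:
                fields[canon] = cell
        out.append(StudyRow(**fields))
    return out


def write_study(rows: Iterable[StudyRow], path: str | Path) -> Path:
    """Write study rows in the canonical column order (round-trips with
    :func:`read_study`)."""
    rows = list(rows)
    extra_cols: list[str] = []
    for r in rows:
        for k in r.extras:
            if k not in extra_cols:
                extra_cols.append(k)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(STUDY_COLUMNS + extra_cols) + "\n")
        for r in rows:
            cells = [
                r.accession_id, r.accession_number, r.sowing_date,
                "" if r.harvest_year is None else str(r.harvest_year),
                r.country, r.comment,
            ] + [str(r.extras.get(c, "")) for c in extra_cols]
            fh.write("\t".join(cells) + "\n")
    return path


# ---------------------------------------------------------------------------
# assay files
# ---------------------------------------------------------------------------

def read_assay(
    path: str | Path,
    trait: Trait | str,
    habit: Habit | str,
    aliases: Mapping[str, str] | None = None,
) -> HistoricalDataset:
    """Read plot-level observations of one trait from an assay file.

    ``replicate_index`` is assigned by order of appearance within each
    (accession, year) cell, so duplicate rows are retained as distinct plots.
    Rows with a missing, non-numeric or non-positive trait value are rejected
    into the dataset's ``rejections`` report (columns: line, accession_id,
    harvest_year, raw_value, reason) — never silently dropped.
    """
    trait = Trait.coerce(trait)
    habit = Habit.coerce(habit)
    aliases = {**DEFAULT_ASSAY_ALIASES, **(aliases or {})}
    header, rows = _read_table(Path(path))
    mapped = [aliases.get(_normalize_header(h), None) for h in header]
    for needed in ("accession_id", "harvest_year", trait.value):
        if needed not in mapped:
            raise DataFormatError(
                f"{path}: column for {needed!r} not found in header {header}")
    idx = {name: mapped.index(name) for name in
           ("accession_id", "harvest_year", trait.value)}

    accepted: list[tuple] = []
    rejected: list[dict] = []
    for lineno, cells in enumerate(rows, start=2):
        acc = cells[idx["accession_id"]].strip()
        raw_year = cells[idx["harvest_year"]].strip()
        raw_val = (cells[idx[trait.value]].strip()
                   if idx[trait.value] < len(cells) else "")
        try:
            year = int(raw_year)
        except ValueError:
            raise RowParseError(f"unparseable harvest_year {raw_year!r}", lineno) from None
        if raw_val.lower() in _MISSING:
            rejected.append({"line": lineno, "accession_id": acc,
                             "harvest_year": year, "raw_value": raw_val,
                             "reason": "missing value"})
            continue
        try:
            value = _parse_number(raw_val, lineno)
        except RowParseError as exc:
            rejected.append({"line": lineno, "accession_id": acc,
                             "harvest_year": year, "raw_value": raw_val,
                             "reason": str(exc)})
            continue
        if not (value > 0) or value != value:
            rejected.append({"line": lineno, "accession_id": acc,
                             "harvest_year": year, "raw_value": raw_val,
                             "reason": "non-positive value"})
            continue
        accepted.append((acc, year, value))

    dataset = HistoricalDataset(
        trait=trait, habit=habit, records=records_frame(accepted),
        rejections=pd.DataFrame(
            rejected, columns=["line", "accession_id", "harvest_year",
                               "raw_value", "reason"]),
    )
    return dataset


def write_assay(dataset: HistoricalDataset, path: str | Path) -> Path:
    """Write a dataset as an assay file (accession_id, harvest_year, <trait>);
    row order is the record order, which round-trips with :func:`read_assay`."""
    path = Path(path)
    trait_col = dataset.trait.value
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"accession_id\tharvest_year\t{trait_col}\n")
        for row in dataset.records.itertuples(index=False):
            fh.write(f"{row.accession_id}\t{row.harvest_year}\t{row.value:g}\n")
    return path


# ---------------------------------------------------------------------------
# pipeline outputs
# ---------------------------------------------------------------------------

def write_outputs(fit: FitResult, report: OutlierReport,
                  out_dir: str | Path) -> set[Path]:
    """Write the enhanced records and the final BLUEs in the deposited layout.

    Produces ``Data.corrected.<trait>.txt`` (the enhanced dataset) and
    ``BLUEs.<trait>.txt`` (one row per accession), both tab-delimited with a
    header, sorted by accession id (then year, replicate) so re-runs are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trait = report.enhanced.trait.value

    corrected = out_dir / f"Data.corrected.{trait}.txt"
    recs = report.enhanced.records.sort_values(
        ["accession_id", "harvest_year", "replicate_index"])
    with corrected.open("w", encoding="utf-8") as fh:
        fh.write(f"accession_id\tharvest_year\treplicate_index\t{trait}\n")
        for row in recs.itertuples(index=False):
            fh.write(f"{row.accession_id}\t{row.harvest_year}\t"
                     f"{row.replicate_index}\t{row.value:g}\n")

    blues_path = out_dir / f"BLUEs.{trait}.txt"
    blues = mm_engine.blues(fit)
    with blues_path.open("w", encoding="utf-8") as fh:
        fh.write(f"accession_id\tBLUE_{trait}\n")
        for acc in sorted(blues):
            fh.write(f"{acc}\t{blues[acc]:.6f}\n")

    return {corrected, blues_path}


def write_outlier_audit(report: OutlierReport, path: str | Path) -> Path:
    """Tab-delimited per-record audit: key, residual diagnostics, p, flag."""
    path = Path(path)
    cols = ["accession_id", "harvest_year", "replicate_index", "value",
            "residual", "standardized_residual", "rescaled_residual",
            "p_value", "outlier"]
    report.table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
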