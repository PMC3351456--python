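"""Spreadsheet I/O: column-per-set input, per-region tables, summaries.

Input files hold one column per set; with a header row, row 1 carries
the set names.  XLSX reading touches only the first worksheet.  Cells
are read as text verbatim — identifiers may be numeric-looking and are
never reformatted as floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .setcore import (
    MAX_SETS,
    MIN_SETS,
    CanonicalizationOptions,
    InputCollection,
    Partition,
    UnsupportedSetCountError,
    classify_region,
    signature_names,
)

#: Joiner for set names in region-column headers, e.g. "3:A∩B".
SIG_JOIN = "∩"


@dataclass(frozen=True)
class TableDialect:
    """File format and header convention for set-collection tables."""

    format: str = "auto"  # one of {"auto", "xlsx", "csv", "tsv"}
    header_row: bool = True

    def resolve_format(self, path: Path) -> str:
        if self.format != "auto":
            return self.format
        suffix = path.suffix.lower()
        if suffix in (".xlsx", ".xlsm"):
            return "xlsx"
        if suffix == ".tsv":
            return "tsv"
        return "csv"


def _cell_text(value: object) -> str:
    """Stringify a cell verbatim; integral floats lose the spurious '.0'."""
    if value is None:
        return ""
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def _read_columns(path: Path, dialect: TableDialect) -> List[List[str]]:
    fmt = dialect.resolve_format(path)
    if fmt == "xlsx":
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        try:
            ws = wb.worksheets[0]  # first sheet only; others are ignored
            rows = [[_cell_text(c) for c in row] for row in ws.iter_rows(values_only=True)]
        finally:
            wb.close()
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
        rows = df.values.tolist()
    if not rows:
        return []
    width = max(len(r) for r in rows)
    cols = [[_cell_text(r[j]) if j < len(r) else "" for r in rows] for j in range(width)]
    # drop columns that are entirely blank (trailing padding in spreadsheets)
    return [c for c in cols if any(cell.strip() for cell in c)]


def read_collection(
    path: str | Path,
    dialect: TableDialect | None = None,
    options: CanonicalizationOptions | None = None,
) -> InputCollection:
    """Read a 2-6 column set collection from XLSX/CSV/TSV.

    Column order is preserved as set order (first column = set 1).
    Without a header row, sets are named ``Set1``..``SetN``.
    """
    path = Path(path)
    dialect = dialect or TableDialect()
    cols = _read_columns(path, dialect)
    if not MIN_SETS <= len(cols) <= MAX_SETS:
        raise UnsupportedSetCountError(
            f"{path.name}: found {len(cols)} data columns, need {MIN_SETS}-{MAX_SETS}"
        )
    if dialect.header_row:
        names = [c[0].strip() for c in cols]
        bodies = [c[1:] for c in cols]
        if any(not n for n in names):
            raise ValueError(f"{path.name}: blank set name in header row")
        if len(set(names)) != len(names):
            raise ValueError(f"{path.name}: duplicate set names {names}")
    else:
        names = [f"Set{i + 1}" for i in range(len(cols))]
        bodies = cols
    return InputCollection.from_lists(list(zip(names, bodies)), options)


@dataclass
class RegionTable:
    """Per-region membership columns, ordered by ascending region index."""

    columns: List[Tuple[int, Tuple[str, ...], List[str]]]

    def headers(self) -> List[str]:
        return [f"{idx}:{SIG_JOIN.join(names)}" for idx, names, _ in self.columns]


def region_table(partition: Partition, include_empty: bool = False) -> RegionTable:
    """Lay the partition out one column per region, index-ordered."""
    cols = []
    for mask in sorted(partition.regions):
        members = partition.regions[mask]
        if not members and not include_empty:
            continue
        cols.append((mask, signature_names(mask, partition.collection), list(members)))
    return RegionTable(columns=cols)


def _table_frame(table: RegionTable) -> pd.DataFrame:
    depth = max((len(m) for _, _, m in table.columns), default=0)
    data = {
        header: members + [""] * (depth - len(members))
        for header, (_, _, members) in zip(table.headers(), table.columns)
    }
    return pd.DataFrame(data)


def write_region_table(
    partition: Partition, path: str | Path, include_empty: bool = False
) -> RegionTable:
    """Write the per-region membership table as XLSX or CSV (by extension)."""
    path = Path(path)
    table = region_table(partition, include_empty=include_empty)
    frame = _table_frame(table)
    if path.suffix.lower() == ".xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return table


def write_summary(
    partition: Partition, reference_index: int, path: str | Path
) -> pd.DataFrame:
    """Write one row per signature: index, signature, size, category code."""
    path = Path(path)
    n = partition.n
    rows = []
    for mask in sorted(partition.regions):
        rows.append(
            {
                "region_index": mask,
                "signature": SIG_JOIN.join(signature_names(mask, partition.collection)),
                "size": len(partition.regions[mask]),
                "category_code": classify_region(mask, reference_index, n).value,
            }
        )
    frame = pd.DataFrame(rows)
    if path.suffix.lower() == ".xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return frame


def write_collection(
    collection: InputCollection, path: str | Path
) -> None:
    """Write a collection back out column-per-set (fixture/export helper)."""
    path = Path(path)
    depth = max(len(s) for s in collection.sets)
    data = {
        name: sorted(members) + [""] * (depth - len(members))
        for name, members in zip(collection.names, collection.sets)
    }
    frame = pd.DataFrame(data)
    if path.suffix.lower() == ".xlsx":
        frame.to_excel(path, index=False)
    elif path.suffix.lower() == ".tsv":
        frame.to_csv(path, index=False, sep="\t")
    else:
        frame.to_csv(path, index=False)
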