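"""CSV input/output for print and reference tables.

Field data arrives in heterogeneous spreadsheets, so column names are matched
case-insensitively against a small alias list (``mrb``/``MRB``/
``mean_ridge_breadth`` ...).  Files are comma-separated UTF-8 with a header.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .datatypes import PrintRecord, ReferenceRecord, normalize_sex

logger = logging.getLogger(__name__)

_PRINT_ALIASES = {
    "id": {"id", "print_id", "sample", "sample_id", "name"},
    "mrb": {"mrb", "mean_ridge_breadth", "meanridgebreadth", "mrb_mm"},
    "n_ridges": {"n_ridges", "nridges", "num_ridges", "ridges", "ridge_count",
                 "n_ridges_averaged"},
    "rd": {"rd", "ridge_density"},
    "category": {"category", "class", "artifact_category", "type"},
}
_REFERENCE_ALIASES = {
    "age": {"age", "age_years", "years"},
    "sex": {"sex", "gender"},
    "mrb": {"mrb", "mean_ridge_breadth", "meanridgebreadth"},
}


@dataclass
class BadRow:
    line: int      # 1-based line number in the file (header = line 1)
    reason: str


def _resolve_columns(columns, aliases, required, path):
    lower = {str(c).strip().lower(): c for c in columns}
    mapping = {}
    for canonical, names in aliases.items():
        found = [lower[n] for n in names if n in lower]
        if found:
            mapping[canonical] = found[0]
    missing = [c for c in required if c not in mapping]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"accepted aliases: { {m: sorted(aliases[m]) for m in missing} }"
        )
    return mapping


def read_prints(path: str | Path, collect_errors: bool = True
                ) -> tuple[list[PrintRecord], list[BadRow]]:
    """Read a prints CSV into records, preserving row order.

    Returns ``(records, bad_rows)``: malformed rows (non-numeric MRB,
    non-positive values ...) are reported with their 1-based line numbers
    rather than aborting the read.  Missing required columns are a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, _PRINT_ALIASES, ("mrb", "n_ridges"), path)
    records: list[PrintRecord] = []
    bad: list[BadRow] = []
    if df.empty:
        logger.warning("read_prints: %s contains a header but no data rows", path)
        return records, bad
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            mrb = float(row[cols["mrb"]])
            n_ridges = int(float(row[cols["n_ridges"]]))
            rid = str(row[cols["id"]]) if "id" in cols and row[cols["id"]] != "" else f"row{line}"
            rd_raw = row[cols["rd"]] if "rd" in cols else ""
            rd = float(rd_raw) if rd_raw != "" else None
            cat_raw = row[cols["category"]] if "category" in cols else ""
            category = cat_raw if cat_raw != "" else None
            records.append(PrintRecord(id=rid, mrb=mrb, n_ridges=n_ridges,
                                       rd=rd, category=category))
        except (ValueError, TypeError) as exc:
            if not collect_errors:
                raise ValueError(f"{path}:{line}: {exc}") from exc
            bad.append(BadRow(line=line, reason=str(exc)))
    for b in bad:
        logger.warning("read_prints: %s line %d skipped: %s", path, b.line, b.reason)
    return records, bad


def read_reference(path: str | Path) -> list[ReferenceRecord]:
    """Read a reference-population CSV (age, sex, mrb).

    Sex labels (``F``/``M``/``female``/``male``/1/2) are normalized to the
    internal {1 = female, 2 = male} coding; an unrecognized label is a hard
    error listing the accepted spellings.  Reference individuals carry no id,
    so duplicate rows are legal.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = _resolve_columns(df.columns, _REFERENCE_ALIASES, ("age", "sex", "mrb"), path)
    records = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            records.append(ReferenceRecord(
                age=float(row[cols["age"]]),
                sex=normalize_sex(row[cols["sex"]]),
                mrb=float(row[cols["mrb"]]),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}:{line}: {exc}") from exc
    return records


def write_prints(prints: Sequence[PrintRecord], path: str | Path) -> None:
    """Write prints to CSV at full float precision (repr round-trip)."""
    df = pd.DataFrame(
        {
            "id": [p.id for p in prints],
            "mrb": [p.mrb for p in prints],
            "n_ridges": [p.n_ridges for p in prints],
            "rd": [p.rd for p in prints],
            "category": [p.category for p in prints],
        }
    )
    df.to_csv(path, index=False, float_format=None)


def write_reference(records: Sequence[ReferenceRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "mrb": [r.mrb for r in records],
        }
    ).to_csv(path, index=False)
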