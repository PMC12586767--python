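"""CSV interchange: aggregate count tables in and tidy results out.

The canonical dialect is comma-separated UTF-8 with a header row and
columns ``age, cause, deaths, person_years`` — one row per (age, cause).
A column-mapping dictionary adapts files with different headers without
code changes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .rates import AgeCauseTable

CANONICAL_COLUMNS = ("age", "cause", "deaths", "person_years")


def read_counts_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    causes: Sequence[str] | None = None,
) -> AgeCauseTable:
    """Read and validate an aggregate count table.

    ``column_map`` maps canonical names to the file's actual headers,
    e.g. ``{"person_years": "py"}``.  Validation errors carry row
    numbers of the offending lines (0-based data rows).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"counts file not found: {path}")
    df = pd.read_csv(path)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        missing = [v for v in column_map.values() if v not in df.columns]
        if missing:
            raise ValidationError(f"{path}: mapped columns not in file: {missing}")
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing columns {missing}; present: {list(df.columns)}"
        )
    try:
        return AgeCauseTable(df, causes=causes)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_counts_csv(table: AgeCauseTable, path: str | Path) -> None:
    """Write the canonical long-format dialect (round-trips exactly)."""
    table.to_frame().to_csv(path, index=False)


def write_frame(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
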