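"""Shared helpers for the package's tab-separated formats.

Convention: UTF-8, a single ``#``-prefixed header line naming the columns,
``.`` for missing values, tab delimiters throughout.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

from .errors import ParseError

MISSING = "."


def read_hashed_tsv(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            header_idx = i  # last comment line before data is the column header
            if i + 1 < len(lines) and not lines[i + 1].startswith("#"):
                break
        elif line.strip():
            break
    if header_idx is None:
        raise ParseError(f"{path}: no '#'-prefixed header line found")
    columns = lines[header_idx].lstrip("#").strip().split("\t")
    body = "".join(ln for ln in lines[header_idx + 1 :] if not ln.startswith("#"))
    df = pd.read_csv(
        io.StringIO(body),
        sep="\t",
        names=columns,
        na_values=[MISSING],
        keep_default_na=False,
        dtype=str,
        header=None,
        skip_blank_lines=True,
    )
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")
    return df


def write_hashed_tsv(df: pd.DataFrame, path: str | Path, preamble: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in preamble or []:
            fh.write(f"# {line}\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        out = df.copy()
        for col in out.columns:
            out[col] = out[col].map(lambda v: MISSING if v is None or (isinstance(v, float) and pd.isna(v)) else v)
        out.to_csv(fh, sep="\t", header=False, index=False, na_rep=MISSING)
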