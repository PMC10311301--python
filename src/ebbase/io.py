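"""Reading and writing allelic counts tables, results, and run configs.

Counts-table dialect: wide, tab-separated, UTF-8.  Header row is
``gene_id`` [``chromosome``] then a ``<sample>_mat`` / ``<sample>_pat``
column pair per library; one row per gene; non-negative integer counts
with zeros written explicitly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountsTable

__all__ = [
    "CountsTableFormatError",
    "read_counts",
    "write_counts",
    "counts_from_dataframe",
    "counts_to_dataframe",
    "read_config",
]

MAT_SUFFIX = "_mat"
PAT_SUFFIX = "_pat"


class CountsTableFormatError(ValueError):
    """Malformed counts-table file (message carries row/column context)."""


def counts_from_dataframe(df: pd.DataFrame) -> CountsTable:
    """Validate and convert a wide counts frame into a CountsTable."""
    cols = list(df.columns)
    if not cols or cols[0] != "gene_id":
        raise CountsTableFormatError(
            f"first column must be 'gene_id'; header starts with {cols[:2]}"
        )
    has_chrom = len(cols) > 1 and cols[1] == "chromosome"
    count_cols = cols[2:] if has_chrom else cols[1:]

    samples: list[str] = []
    for c in count_cols:
        if c.endswith(MAT_SUFFIX):
            samples.append(c[: -len(MAT_SUFFIX)])
        elif not c.endswith(PAT_SUFFIX):
            raise CountsTableFormatError(
                f"column {c!r} is neither *{MAT_SUFFIX} nor *{PAT_SUFFIX}"
            )
    missing = [
        s for s in samples if f"{s}{PAT_SUFFIX}" not in count_cols
    ] + [
        c[: -len(PAT_SUFFIX)]
        for c in count_cols
        if c.endswith(PAT_SUFFIX) and c[: -len(PAT_SUFFIX)] not in samples
    ]
    if missing:
        raise CountsTableFormatError(
            f"incomplete maternal/paternal column pairs for samples: {sorted(set(missing))}"
        )
    if not samples:
        raise CountsTableFormatError("no sample count columns found")

    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        first = dup.iloc[0]
        raise CountsTableFormatError(
            f"duplicate gene_id {first!r} (data row {int(dup.index[0]) + 1})"
        )

    for c in count_cols:
        col = df[c]
        as_num = pd.to_numeric(col, errors="coerce")
        bad = as_num.isna() | (as_num != as_num.round()) | (as_num < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CountsTableFormatError(
                f"count in column {c!r}, data row {row + 1} is not a "
                f"non-negative integer: {col.iloc[row]!r}"
            )

    idx = pd.Index(df["gene_id"].astype(str), name="gene_id")
    m = pd.DataFrame(
        {s: pd.to_numeric(df[f"{s}{MAT_SUFFIX}"]).astype(np.int64).to_numpy() for s in samples},
        index=idx,
    )
    p = pd.DataFrame(
        {s: pd.to_numeric(df[f"{s}{PAT_SUFFIX}"]).astype(np.int64).to_numpy() for s in samples},
        index=idx,
    )
    chrom = (
        pd.Series(df["chromosome"].astype(str).to_numpy(), index=idx, name="chromosome")
        if has_chrom
        else None
    )
    return CountsTable(m, p, chrom)


def counts_to_dataframe(table: CountsTable) -> pd.DataFrame:
    out = {"gene_id": table.gene_ids.astype(str)}
    if table.chromosome is not None:
        out["chromosome"] = table.chromosome.to_numpy()
    for s in table.samples:
        out[f"{s}{MAT_SUFFIX}"] = table.m[s].to_numpy()
        out[f"{s}{PAT_SUFFIX}"] = table.p[s].to_numpy()
    return pd.DataFrame(out)


def read_counts(path: str | Path) -> CountsTable:
    """Read a wide TSV counts table, validating the dialect."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CountsTableFormatError(f"{path}: empty file, expected a header row")
    return counts_from_dataframe(df)


def write_counts(table: CountsTable, path: str | Path) -> Path:
    """Write the wide TSV dialect; round-trips bit-exactly through read_counts."""
    path = Path(path)
    counts_to_dataframe(table).to_csv(path, sep="\t", index=False)
    return path


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out
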