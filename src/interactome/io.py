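"""File readers and writers for the pipeline's plain-text formats.

Dialects are fixed once: TSV (tab) for matrices and clinical tables, CSV
(comma) for pair/score tables, UTF-8, '.' decimal, no thousands
separators.  All writers go through :func:`atomic_write` (temp file then
rename) so a failed run never leaves a partial artifact behind.

Expression matrices are pandas DataFrames with genes as the index and
samples as columns; purity is a Series indexed by sample; compartment
profiles are a DataFrame indexed by gene with columns ``e_tumor``,
``e_stroma`` and (after fitting) ``residual_ss``.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "atomic_write",
    "read_catalog",
    "read_clinical",
    "read_expression",
    "read_gene_set",
    "read_profiles",
    "read_purity",
    "read_rc_table",
    "validate_expression",
    "write_catalog",
    "write_clinical",
    "write_expression",
    "write_gene_set",
    "write_profiles",
    "write_purity",
    "write_rc_table",
]


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates its contract."""


@contextmanager
def atomic_write(path: str | Path) -> Iterator[Path]:
    """Yield a temporary path; rename onto ``path`` only on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    tmp_path = Path(tmp)
    try:
        yield tmp_path
        os.replace(tmp_path, path)
    finally:
        if tmp_path.exists():
            tmp_path.unlink()


def validate_expression(expr: pd.DataFrame) -> None:
    """Check an expression matrix: unique labels, finite nonnegative values."""
    dup_genes = expr.index[expr.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValidationError(f"duplicate gene symbols: {dup_genes}")
    dup_samples = expr.columns[expr.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ValidationError(f"duplicate sample IDs: {dup_samples}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("expression matrix contains non-numeric values")
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite expression at gene {expr.index[bad[0]]!r}, "
            f"sample {expr.columns[bad[1]]!r}"
        )
    if (values < 0).any():
        bad = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative expression at gene {expr.index[bad[0]]!r}, "
            f"sample {expr.columns[bad[1]]!r}"
        )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample expression TSV (first column ``gene``)."""
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.columns[0] != "gene":
        raise ValidationError(
            f"{path}: first column must be 'gene', found {raw.columns[0]!r}"
        )
    expr = raw.set_index("gene")
    for col in expr.columns:
        converted = pd.to_numeric(expr[col], errors="coerce")
        bad = converted.isna() & expr[col].notna()
        if bad.any():
            gene = expr.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        expr[col] = converted
    expr = expr.astype(float)
    validate_expression(expr)
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    validate_expression(expr)
    with atomic_write(path) as tmp:
        expr.to_csv(tmp, sep="\t", index_label="gene")


def read_purity(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample, purity) into a Series in [0, 1]."""
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    if table.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns (sample, purity)")
    purity = pd.Series(
        pd.to_numeric(table.iloc[:, 1], errors="coerce").to_numpy(),
        index=pd.Index(table.iloc[:, 0], name="sample"),
        name="purity",
    )
    if purity.isna().any():
        raise ValidationError(f"{path}: non-numeric purity values")
    if purity.index.duplicated().any():
        dups = purity.index[purity.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample IDs {dups}")
    if ((purity < 0) | (purity > 1)).any():
        raise ValidationError(f"{path}: purity values outside [0, 1]")
    return purity


def write_purity(purity: pd.Series, path: str | Path) -> None:
    with atomic_write(path) as tmp:
        purity.rename("purity").to_csv(tmp, sep="\t", index_label="sample")


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a ligand-receptor catalog CSV.

    Multi-subunit complex entries (symbols containing '+') are rejected:
    the RC model is single-ligand/single-receptor.
    """
    table = pd.read_csv(path, dtype=str)
    required = {"ligand", "receptor"}
    if not required.issubset(table.columns):
        raise ValidationError(f"{path}: catalog needs columns {sorted(required)}")
    for col in ("ligand", "receptor"):
        complexed = table[col].str.contains(r"\+", na=False)
        if complexed.any():
            offenders = table.loc[complexed, col].tolist()[:5]
            raise ValidationError(
                f"{path}: multi-subunit complex entries are not supported in RC "
                f"scoring (single ligand/receptor genes only): {offenders}"
            )
        if (table[col].isna() | (table[col].str.strip() == "")).any():
            raise ValidationError(f"{path}: empty {col} symbols")
    if table.duplicated(subset=["ligand", "receptor"]).any():
        dups = table[table.duplicated(subset=["ligand", "receptor"])]
        raise ValidationError(
            f"{path}: duplicate ligand-receptor pairs, e.g. "
            f"{tuple(dups.iloc[0][['ligand', 'receptor']])}"
        )
    if "planted_axis" not in table.columns:
        table["planted_axis"] = ""
    table["planted_axis"] = table["planted_axis"].fillna("")
    return table[["ligand", "receptor", "planted_axis"]].reset_index(drop=True)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    out = catalog.copy()
    if "planted_axis" not in out.columns:
        out["planted_axis"] = ""
    with atomic_write(path) as tmp:
        out[["ligand", "receptor", "planted_axis"]].to_csv(tmp, index=False)


CLINICAL_COLUMNS = ["os_months", "os_event", "dfs_months", "dfs_event"]


def read_clinical(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a clinical TSV indexed by sample.

    ``column_map`` renames source columns onto the canonical schema
    (``sample``, ``os_months``, ``os_event``, ``dfs_months``,
    ``dfs_event``), supporting externally exported clinical tables whose
    field names differ.
    """
    table = pd.read_csv(path, sep="\t")
    if column_map:
        table = table.rename(columns=column_map)
    if "sample" not in table.columns:
        raise ValidationError(f"{path}: missing 'sample' column")
    table = table.set_index("sample")
    present = [c for c in CLINICAL_COLUMNS if c in table.columns]
    if not present:
        raise ValidationError(
            f"{path}: no endpoint columns found (expected some of {CLINICAL_COLUMNS})"
        )
    if table.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample IDs")
    for col in present:
        table[col] = pd.to_numeric(table[col], errors="coerce")
        if col.endswith("_months") and (table[col].dropna() < 0).any():
            raise ValidationError(f"{path}: negative times in {col}")
    return table[present]


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as tmp:
        clinical.to_csv(tmp, sep="\t", index_label="sample")


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene set file ('#' starts a comment)."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            symbol = line.split("#", 1)[0].strip().upper()
            if symbol:
                genes.add(symbol)
    return genes


def write_gene_set(genes: Iterator[str] | set[str], path: str | Path) -> None:
    with atomic_write(path) as tmp:
        tmp.write_text("\n".join(sorted(genes)) + "\n", encoding="utf-8")


def read_profiles(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene": str}).set_index("gene")
    for col in ("e_tumor", "e_stroma"):
        if col not in table.columns:
            raise ValidationError(f"{path}: missing profile column {col!r}")
        if (table[col] < 0).any():
            raise ValidationError(f"{path}: negative values in {col}")
    return table


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as tmp:
        profiles.to_csv(tmp, sep="\t", index_label="gene")


def read_rc_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"ligand": str, "receptor": str})


def write_rc_table(table: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as tmp:
        table.to_csv(tmp, index=False)
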