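"""Tabular readers and writers for the pipeline's plain-text formats.

All files are tab-separated UTF-8 with ``.`` as the decimal mark; blank
cells are missing.  The peptide table dialect follows MaxQuant's
``peptides.txt``: one row per (aggregated) peptide sequence, ``Proteins``
as a ``;``-joined accession list, ``Reverse`` / ``Contaminant`` flagged
with ``+``, and one ``Reporter intensity <channel>`` column per sample.
A reporter intensity of 0 means "no signal detected" and is read as
missing, never as a measured zero.

In memory a peptide table is a :class:`pandas.DataFrame` with columns
``sequence`` (str), ``proteins`` (list of accessions), ``pep`` (float),
``reverse`` / ``contaminant`` (bool), ``length`` (int), plus one float
column per sample id holding linear-scale intensities with NaN for
missing.  An expression matrix is a features x samples float DataFrame of
log2 intensities.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SampleDesign

__all__ = [
    "PEPTIDE_META_COLUMNS",
    "read_peptide_table",
    "write_peptide_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_mapping_table",
    "write_mapping_table",
]

PEPTIDE_META_COLUMNS = ["sequence", "proteins", "pep", "reverse", "contaminant", "length"]

_REQUIRED = ("Sequence", "Proteins", "PEP", "Reverse", "Contaminant")


def reporter_column(channel: str) -> str:
    return f"Reporter intensity {channel}"


def _split_accessions(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    parts = [p.strip() for p in str(value).split(";")]
    return [p for p in parts if p]


def read_peptide_table(path: str | Path, design: SampleDesign) -> pd.DataFrame:
    """Read a MaxQuant-style peptide TSV into the internal peptide table.

    Raises
    ------
    ValueError
        If a required column or any reporter-intensity column for the
        design is absent, if a peptide sequence occurs more than once, or
        if a reporter intensity is negative.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"Sequence": str})
    for col in _REQUIRED:
        if col not in raw.columns:
            raise ValueError(f"peptide table {path} is missing required column {col!r}")
    rep_cols = {}
    for sid, ch in zip(design.sample_ids, design.channel_labels):
        col = reporter_column(ch)
        if col not in raw.columns:
            raise ValueError(f"peptide table {path} is missing required column {col!r}")
        rep_cols[sid] = col

    seqs = raw["Sequence"].astype(str)
    dup = seqs[seqs.duplicated()]
    if len(dup):
        raise ValueError(
            f"duplicate peptide sequence rows (sequences must be pre-aggregated): "
            f"{sorted(set(dup))[:5]}")

    table = pd.DataFrame({
        "sequence": seqs,
        "proteins": raw["Proteins"].map(_split_accessions),
        "pep": pd.to_numeric(raw["PEP"], errors="raise").astype(float),
        "reverse": raw["Reverse"].fillna("").astype(str).str.strip().eq("+"),
        "contaminant": raw["Contaminant"].fillna("").astype(str).str.strip().eq("+"),
    })
    if "Length" in raw.columns:
        table["length"] = pd.to_numeric(raw["Length"], errors="raise").astype(int)
    else:
        table["length"] = seqs.str.len().astype(int)

    for sid, col in rep_cols.items():
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric reporter intensity at row {row}, column {col!r}")
        if (vals.dropna() < 0).any():
            raise ValueError(f"negative reporter intensity in column {col!r}")
        # MaxQuant writes 0 for channels without reporter signal
        table[sid] = vals.where(vals > 0, np.nan).astype(float)

    table.index = pd.RangeIndex(len(table))
    return table


def write_peptide_table(table: pd.DataFrame, path: str | Path,
                        design: SampleDesign) -> None:
    """Write the internal peptide table back to the MaxQuant-style dialect.

    Missing intensities are serialized as 0, mirroring how the reader
    interprets zero; a write/read round trip preserves both values and the
    missingness pattern exactly.
    """
    out = pd.DataFrame({
        "Sequence": table["sequence"],
        "Proteins": table["proteins"].map(";".join),
        "PEP": table["pep"],
        "Reverse": np.where(table["reverse"], "+", ""),
        "Contaminant": np.where(table["contaminant"], "+", ""),
        "Length": table["length"],
    })
    for sid, ch in zip(design.sample_ids, design.channel_labels):
        out[reporter_column(ch)] = table[sid].fillna(0.0)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV of log2 intensities (blank = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate feature ids in {path}: {dups[:5]}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            feat = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(f"non-numeric value at feature {feat!r}, column {col!r}")
        df[col] = vals.astype(float)
    return df


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path,
                            index_label: str = "feature") -> None:
    matrix.to_csv(path, sep="\t", na_rep="", index_label=index_label,
                  float_format="%.10g")


def read_mapping_table(path: str | Path) -> pd.DataFrame:
    """Read a probe-to-protein mapping TSV (columns probe_id, protein_id).

    Many-to-many mappings are allowed; exact duplicate pairs collapse to one.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"mapping table {path} needs two columns (probe, protein)")
    df = df.iloc[:, :2]
    df.columns = ["probe_id", "protein_id"]
    df = df.dropna().drop_duplicates(ignore_index=True)
    if df.empty:
        raise ValueError(f"mapping table {path} is empty")
    return df


def write_mapping_table(mapping: pd.DataFrame, path: str | Path) -> None:
    mapping[["probe_id", "protein_id"]].to_csv(path, sep="\t", index=False)


_MOD_PAREN = re.compile(r"\([^)]*\)")


def strip_modifications(sequence: str) -> str:
    """Normalize a peptide sequence for cross-study matching.

    Removes parenthesized modification annotations and punctuation such
    as flanking underscores, then uppercases.  Isoleucine and leucine
    remain distinct.
    """
    s = _MOD_PAREN.sub("", str(sequence))
    return re.sub(r"[^A-Za-z0-9]", "", s).upper()
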