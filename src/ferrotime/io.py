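"""Shared file I/O: typed TSV tables, GMT gene sets, FASTA and coordinate tables.

All tabular files use one dialect: UTF-8, tab-separated, a header row,
``.`` as decimal separator and ``NA`` for missing values.  Readers validate
types and report the offending 1-based line number on failure, so that a
malformed input fails loudly at the boundary rather than deep inside a
numerical routine.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NA_VALUES = ["NA"]


class TableFormatError(ValueError):
    """A tabular input file violates the documented dialect."""


def read_tsv(
    path: str | os.PathLike,
    columns: Mapping[str, type] | None = None,
) -> pd.DataFrame:
    """Read a typed TSV table.

    Parameters
    ----------
    path:
        File to read.
    columns:
        Optional mapping of required column name -> Python type
        (``float``, ``int``, ``str`` or ``bool``).  Missing columns raise
        :class:`TableFormatError`; unparsable cells raise it with the
        1-based line number of the first offending row.
    """
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    if columns is None:
        return df
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    for name, typ in columns.items():
        if typ in (float, int):
            coerced = pd.to_numeric(df[name], errors="coerce")
            bad = coerced.isna() & df[name].notna()
            if bad.any():
                # +2: one for the header row, one for 1-based numbering
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise TableFormatError(
                    f"{path}: non-numeric value {df[name][bad].iloc[0]!r} "
                    f"in column '{name}' at line {line}"
                )
            df[name] = coerced if typ is float else coerced.astype("Int64")
        elif typ is bool:
            df[name] = df[name].astype(str).str.lower().isin(("true", "1", "yes"))
        else:
            df[name] = df[name].astype(str)
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> dict[str, dict]:
    """Read a GMT file into ``{set_id: {"description": str, "genes": list}}``."""
    sets: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableFormatError(
                    f"{path}: GMT line {lineno} has fewer than 3 fields"
                )
            set_id, desc, *genes = parts
            genes = [g for g in genes if g]
            sets[set_id] = {"description": desc, "genes": genes}
    return sets


def write_gmt(sets: Mapping[str, Mapping], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, payload in sets.items():
            desc = payload.get("description", "")
            genes = payload["genes"]
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# FASTA and gene-coordinate tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into ``{record_id: sequence}`` (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


GENE_COORD_COLUMNS = {
    "gene_id": str,
    "contig": str,
    "start": int,
    "end": int,
    "strand": str,
}


def read_gene_coords(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GFF-like coordinate table (1-based inclusive start/end, +/- strand)."""
    df = read_tsv(path, GENE_COORD_COLUMNS)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise TableFormatError(
            f"{path}: strand must be '+' or '-', got {df['strand'][bad].iloc[0]!r}"
        )
    return df


def ensure_dir(path: str | os.PathLike) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
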