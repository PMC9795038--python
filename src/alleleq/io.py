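"""File-format adapters: FASTA/FASTQ via Biopython, tables via pandas/scipy."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    pass


def _open_text(path: str | Path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (name, uppercased sequence)."""
    with _open_text(path) as fh:
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def iter_fastq_reads(*paths: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, bases) across one or more FASTQ files (gz ok)."""
    for path in paths:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq).upper()


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV mapping cell_id -> group [-> fastq path(s), ';'-separated].

    Relative FASTQ paths are resolved against the manifest's directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}")
    if df.empty:
        raise FormatError("empty manifest")
    if "fastq" in df.columns:
        base = Path(path).resolve().parent
        df["fastq"] = [
            ";".join(
                str(p if Path(p).is_absolute() else base / p)
                for p in str(entry).split(";")
                if p and p != "nan"
            )
            for entry in df["fastq"]
        ]
    return df


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Cell x gene counts from delimited text or an MTX triplet.

    Delimited: cells in rows, first column cell ids, header row of gene ids.
    MTX: pass the .mtx path; `<stem>.rows.txt` (cells) and `<stem>.cols.txt`
    (genes) must sit beside it.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        m = mmread(path).toarray()
        cells = Path(str(path)[: -len(".mtx")] + ".rows.txt").read_text().split()
        genes = Path(str(path)[: -len(".mtx")] + ".cols.txt").read_text().split()
        if m.shape != (len(cells), len(genes)):
            raise FormatError("MTX shape disagrees with row/col index files")
        return pd.DataFrame(m, index=cells, columns=genes)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise FormatError(f"empty count table {path}")
    return df


def read_qpcr_table(path: str | Path) -> dict[str, dict[str, list[float]]]:
    """qPCR plate: columns sample, role (target|reference), ct."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample", "role", "ct"}
    if not required.issubset(df.columns):
        raise FormatError(f"qPCR table must have columns {sorted(required)}")
    out: dict[str, dict[str, list[float]]] = {}
    for (sample, role), sub in df.groupby(["sample", "role"]):
        if role not in ("target", "reference"):
            raise FormatError(f"unknown qPCR role {role!r}")
        out.setdefault(str(sample), {})[str(role)] = [float(x) for x in sub["ct"]]
    return out
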