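"""Shared readers and writers: FASTA, TSV matrices, evidence tables, newick."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqfilter import TranscriptRecord

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a (possibly wrapped) FASTA file into transcript records.

    Sequences are uppercased; duplicate ids and blank sequences are errors.
    An empty file yields an empty list with a warning.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"record {rec.id!r} in {path} has a blank sequence")
        records.append(TranscriptRecord(id=rec.id, sequence=seq))
    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return records


def write_fasta(
    records: Sequence[TranscriptRecord] | Mapping[str, str],
    path: str | Path,
    width: int = 70,
) -> None:
    if isinstance(records, Mapping):
        items = [(k, v) for k, v in records.items()]
    else:
        items = [(r.id, r.sequence) for r in records]
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_matrix_tsv(
    path: str | Path, integer: bool = False, allow_negative: bool = False
) -> pd.DataFrame:
    """Read a labelled TSV matrix (rows = features, header row = sample ids).

    With ``integer=True`` all cells must be integral counts; negative values
    are rejected unless ``allow_negative``.  Malformed cells raise a
    :class:`ParseError` naming the 1-based file line.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty and df.columns.empty:
        raise ParseError(f"{path}: empty matrix")
    values = np.empty(df.shape, dtype=float)
    for i, (row_label, row) in enumerate(df.iterrows()):
        line_no = i + 2  # header is line 1
        for j, cell in enumerate(row):
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}:{line_no}: non-numeric cell {cell!r} in row {row_label!r}"
                ) from None
            if integer and v != int(v):
                raise ParseError(
                    f"{path}:{line_no}: non-integral count {cell!r} in row {row_label!r}"
                )
            if v < 0 and not allow_negative:
                raise ParseError(
                    f"{path}:{line_no}: negative value {cell!r} in row {row_label!r}"
                )
            values[i, j] = v
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    if integer:
        out = out.astype(np.int64)
    if out.index.duplicated().any():
        dups = out.index[out.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate row ids {dups[:3]}")
    return out


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, float_fmt: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_fmt)


EVIDENCE_COLUMNS = [
    "query_id",
    "taxon_group",
    "method",
    "evalue",
    "bitscore",
    "aln_len",
    "ref_len",
]


def read_evidence_tsv(path: str | Path) -> pd.DataFrame:
    """Read a BLAST-outfmt-6-style evidence table with a taxon_group column."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing evidence columns {missing}")
    return df


def write_evidence_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample sheet: columns sample, tissue, colony."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "tissue", "colony"):
        if col not in df.columns:
            raise ParseError(f"{path}: sample metadata needs a {col!r} column")
    return df.set_index("sample")
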