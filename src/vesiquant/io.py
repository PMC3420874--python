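"""Format readers and writers shared across the pipeline.

Tables are tab-separated UTF-8 with a header row and '.' decimals; FASTA
is wrapped at 60 columns with decoy ids prefixed ``DECOY_``.  All writers
go through an atomic temp-then-rename so no partial file is ever left at
the target path.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ProteinRecord
from .synthetic import PSM_COLUMNS, SyntheticTruth


class FormatError(ValueError):
    """Malformed input file."""


class atomic_write:
    """Context manager yielding a temp path renamed into place on success."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def __enter__(self) -> Path:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=self.path.parent,
                                   prefix=f".{self.path.name}.")
        os.close(fd)
        self._tmp = Path(tmp)
        return self._tmp

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            self._tmp.unlink(missing_ok=True)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein FASTA into records; ids end at the first whitespace.

    ``symbol=`` and ``category=`` tokens in the description are honoured;
    sequences are upper-cased and molecular weight is computed from the
    sequence.  Raises :class:`FormatError` with a line number on malformed
    input.
    """
    path = Path(path)
    with open(path) as fh:
        first = None
        for line_no, line in enumerate(fh, start=1):
            if line.strip():
                first = (line_no, line)
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise FormatError(
                f"{path}:{first[0]}: expected a '>' header, got "
                f"{first[1].strip()[:30]!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()[1:]
        fields = dict(t.split("=", 1) for t in tokens if "=" in t)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        try:
            records.append(ProteinRecord(
                id=rec.id,
                sequence=seq,
                symbol=fields.get("symbol", ""),
                category=fields.get("category", ""),
                is_decoy=rec.id.startswith("DECOY_"),
            ))
        except ValueError as err:
            raise FormatError(f"{path}: record {rec.id!r}: {err}") from err
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records wrapped at 60 columns, keeping symbol/category tokens."""
    def seqrecords() -> Iterator[SeqRecord]:
        for rec in records:
            desc = []
            if rec.symbol:
                desc.append(f"symbol={rec.symbol}")
            if rec.category:
                desc.append(f"category={rec.category.replace(' ', '_')}")
            yield SeqRecord(Seq(rec.sequence), id=rec.id,
                            description=" ".join(desc))

    with atomic_write(path) as tmp:
        with open(tmp, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
            writer.write_file(seqrecords())


def write_psms(psms: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in PSM_COLUMNS if c in psms.columns]
    with atomic_write(path) as tmp:
        psms[cols].to_csv(tmp, sep="\t", index=False)


def read_psms(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "proteins": str})
    required = {"peptide", "proteins", "charge", "score", "spi",
                "fraction", "replicate", "is_decoy"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing PSM columns {sorted(missing)}")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    if "is_noise" in df:
        df["is_noise"] = df["is_noise"].astype(bool)
    return df


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with atomic_write(path) as tmp:
        truth.table.to_csv(tmp, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    with atomic_write(path) as tmp:
        df.to_csv(tmp, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_mapping(path: str | Path, key: str, value: str) -> dict[str, str]:
    """Two columns of a TSV as a dict (e.g. protein -> category)."""
    df = read_table(path)
    for col in (key, value):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(df[key].astype(str), df[value].astype(str)))


def read_flat_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{line_no}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            out[key] = value
    return out
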