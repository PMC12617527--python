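"""Readers and writers for the pipeline's plain-text formats.

Everything on disk is FASTA or TSV.  TSV files carry a single ``#`` header
comment line with the schema name, a schema version and the configuration
hash of the run that produced them, so outputs are diff-able and
self-describing; all coordinate-bearing files use 0-based half-open
coordinates.  Readers validate per record and report the offending file and
line on failure.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_metrics import CdsError, CodingSequence

__all__ = [
    "SCHEMA_VERSION",
    "InputError",
    "config_hash",
    "read_cds_fasta",
    "write_cds_fasta",
    "write_tsv",
    "read_tsv",
    "read_alignments",
    "setup_logging",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


class InputError(ValueError):
    """Malformed input file; the message names the file and record."""


def config_hash(config: object) -> str:
    """Short stable hash of a configuration object (dataclass or mapping)."""
    if is_dataclass(config) and not isinstance(config, type):
        payload = repr(sorted(asdict(config).items()))
    elif isinstance(config, Mapping):
        payload = repr(sorted(config.items()))
    else:
        payload = repr(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_cds_fasta(
    path: str | Path, delimiter: str = "|"
) -> dict[str, list[CodingSequence]]:
    """Read a multi-FASTA of CDSs into per-gene transcript lists.

    Headers follow ``gene_id<delimiter>transcript_id``; a header without the
    delimiter is taken as a gene with a same-named single transcript.
    Sequences are uppercased and validated (frame, alphabet) per record;
    all per-record problems are collected into one error report.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    genes: dict[str, list[CodingSequence]] = {}
    seen: set[tuple[str, str]] = set()
    problems: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        if delimiter in header:
            gene_id, transcript_id = header.split(delimiter, 1)
        else:
            gene_id = transcript_id = header
        key = (gene_id, transcript_id)
        if key in seen:
            raise InputError(
                f"{path}: duplicate record {gene_id}{delimiter}{transcript_id}"
            )
        seen.add(key)
        try:
            cds = CodingSequence(gene_id, transcript_id, str(record.seq))
        except CdsError as exc:
            problems.append(str(exc))
            continue
        genes.setdefault(gene_id, []).append(cds)
    if problems:
        raise InputError(
            f"{path}: {len(problems)} invalid record(s):\n  "
            + "\n  ".join(problems)
        )
    if not genes:
        raise InputError(f"{path}: no FASTA records found")
    return genes


def write_cds_fasta(
    cds_set: Sequence[CodingSequence] | Mapping[str, CodingSequence],
    path: str | Path,
    delimiter: str = "|",
) -> None:
    """Write CDSs as multi-FASTA with ``gene_id|transcript_id`` headers."""
    if isinstance(cds_set, Mapping):
        cds_set = [cds_set[k] for k in sorted(cds_set)]
    records = [
        SeqRecord(
            Seq(c.sequence),
            id=f"{c.gene_id}{delimiter}{c.transcript_id}",
            description="",
        )
        for c in cds_set
    ]
    SeqIO.write(records, str(path), "fasta")


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    schema: str,
    cfg_hash: str = "-",
) -> None:
    """Write a TSV with the standard one-line ``#`` schema header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# sercodon schema={schema} version={SCHEMA_VERSION} "
            f"config={cfg_hash} coords=0-based-half-open\n"
        )
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(
    path: str | Path,
    required_columns: Sequence[str] = (),
    schema: str | None = None,
) -> pd.DataFrame:
    """Read a ``#``-headed TSV, checking required columns (and, when given,
    that the header's schema name matches)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    with open(path) as fh:
        first = fh.readline()
        if schema is not None and first.startswith("#"):
            if f"schema={schema}" not in first:
                raise InputError(
                    f"{path}:1: expected schema={schema}, got: {first.strip()}"
                )
        fh.seek(0)
        try:
            df = pd.read_csv(
                fh, sep="\t", comment="#", float_precision="round_trip"
            )
        except Exception as exc:  # parser errors carry their own line info
            raise InputError(f"{path}: {exc}") from exc
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_alignments(path: str | Path) -> pd.DataFrame:
    """Read footprint alignments (transcript_id, start, end) with per-line
    validation of coordinate sanity."""
    df = read_tsv(path, required_columns=("transcript_id", "start", "end"))
    offset = 2  # header comment + column line precede data rows
    for col in ("start", "end"):
        bad = df.index[~df[col].apply(lambda v: float(v).is_integer())]
        if len(bad):
            raise InputError(
                f"{path}:{bad[0] + offset + 1}: non-integer {col!r}"
            )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df.index[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        row = df.loc[bad[0]]
        raise InputError(
            f"{path}:{bad[0] + offset + 1}: invalid interval "
            f"[{row['start']}, {row['end']})"
        )
    return df


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging with parameter-trail friendly formatting."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
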