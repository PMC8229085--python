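"""Sequence and survey-metadata IO.

Reads multi-record FASTA (via Bio.SeqIO) with strict IUPAC validation,
reads the tab-separated specimen metadata table, and joins the two into
:class:`SpecimenRecord` objects keyed by specimen id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, DataError, ParseError
from .iupac import first_invalid

logger = logging.getLogger(__name__)

SETTINGS = ("greenhouse", "open_field", "weed", "unknown")

#: mandatory metadata columns (TSV header)
REQUIRED_COLUMNS = ("specimen_id", "region", "host_plant", "setting", "year")


@dataclass(frozen=True)
class SpecimenRecord:
    """One collected individual: sequence plus survey metadata.

    ``sequence`` is empty on metadata-only stubs (before the join with the
    FASTA records).
    """

    specimen_id: str
    sequence: str = ""
    region: str = ""
    locality: str = ""
    host_plant: str = ""
    setting: str = "unknown"
    year: int = 0

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise DataError(
                f"specimen {self.specimen_id!r}: setting {self.setting!r} "
                f"not one of {SETTINGS}"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered ``(id, sequence)`` pairs.

    Ids are the header token before the first whitespace; sequences are
    uppercased, and wrapped lines are joined.  Any character outside the
    IUPAC nucleotide alphabet (plus ``-``) raises :class:`ParseError`
    naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"FASTA file not found: {path}")
    pairs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = first_invalid(seq)
        if bad is not None:
            pos, char = bad
            raise ParseError(
                f"{path}: record {rec.id!r} contains illegal character "
                f"{char!r} at sequence position {pos + 1}"
            )
        pairs.append((rec.id, seq))
    if not pairs:
        raise ParseError(f"{path}: no FASTA records found")
    return pairs


def write_fasta(path: str | Path, pairs: list[tuple[str, str]], width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA (UTF-8, LF)."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in pairs]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata TSV into sequence-less stubs.

    Unknown ``setting`` values are mapped to ``"unknown"`` with a warning;
    a missing mandatory column is a :class:`ConfigurationError`, a duplicate
    specimen id a :class:`DataError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: metadata table missing mandatory column(s): {', '.join(missing)}"
        )
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dupes:
        raise DataError(f"{path}: duplicate specimen_id(s): {sorted(set(dupes))}")
    stubs: list[SpecimenRecord] = []
    for row in df.itertuples(index=False):
        setting = str(row.setting)
        if setting not in SETTINGS:
            logger.warning(
                "specimen %s: unknown setting %r mapped to 'unknown'",
                row.specimen_id, setting,
            )
            setting = "unknown"
        try:
            year = int(row.year) if str(row.year).strip() else 0
        except ValueError as exc:
            raise DataError(
                f"{path}: specimen {row.specimen_id!r}: non-integer year {row.year!r}"
            ) from exc
        stubs.append(
            SpecimenRecord(
                specimen_id=str(row.specimen_id),
                region=str(row.region),
                locality=str(getattr(row, "locality", "")),
                host_plant=str(row.host_plant),
                setting=setting,
                year=year,
            )
        )
    return stubs


def write_metadata(path: str | Path, records: list[SpecimenRecord]) -> None:
    """Write specimen metadata as a TSV matching :func:`read_metadata`."""
    df = pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "region": r.region,
                "locality": r.locality,
                "host_plant": r.host_plant,
                "setting": r.setting,
                "year": r.year,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def join_sequences_metadata(
    seqs: list[tuple[str, str]], stubs: list[SpecimenRecord]
) -> list[SpecimenRecord]:
    """Inner-join sequences and metadata stubs on specimen id.

    Ids are matched case-sensitively.  Unmatched ids on either side are
    counted and logged; an empty intersection is a :class:`DataError`.
    Output order follows the sequence list.
    """
    by_id = {s.specimen_id: s for s in stubs}
    joined: list[SpecimenRecord] = []
    unmatched_seqs = 0
    for name, seq in seqs:
        stub = by_id.pop(name, None)
        if stub is None:
            unmatched_seqs += 1
            continue
        joined.append(replace(stub, sequence=seq))
    if unmatched_seqs or by_id:
        logger.info(
            "join: %d sequence id(s) without metadata, %d metadata row(s) "
            "without sequence", unmatched_seqs, len(by_id),
        )
    if not joined:
        raise DataError("join: no specimen ids shared between sequences and metadata")
    return joined
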