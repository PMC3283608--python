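"""FASTA and label-manifest I/O.

The FASTA dialect: a record starts at a line whose first column is ">"; the
first whitespace-delimited token after ">" is the sequence id; sequence
lines are concatenated until the next ">" or end of stream.  Reading is done
with a small line-tracking parser so malformed input (content before the
first ">", an empty sequence block) is reported with a line number; writing
wraps at 60 columns via Bio.SeqIO.

The label manifest is two-column tab-separated text (id, label), "#"
comments and an optional ``id<TAB>label`` header line tolerated, labels
drawn from the closed vocabulary {nonNR, NR1..NR6, NR0}.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO as BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import DuplicateId, MalformedFasta, MissingSequence, UnknownLabel

#: Closed label vocabulary: the negative class plus the seven subfamilies.
NON_NR_LABEL = "nonNR"
SUBFAMILIES: tuple[str, ...] = ("NR1", "NR2", "NR3", "NR4", "NR5", "NR6", "NR0")
ALL_LABELS: tuple[str, ...] = (NON_NR_LABEL,) + SUBFAMILIES

SUBFAMILY_DESCRIPTIONS: dict[str, str] = {
    "NR1": "thyroid hormone like",
    "NR2": "HNF4-like",
    "NR3": "estrogen like",
    "NR4": "nerve growth factor IB-like",
    "NR5": "fushi tarazu-F1 like",
    "NR6": "germ cell nuclear factor like",
    "NR0": "knirps like",
}


@dataclass(frozen=True)
class FastaRecord:
    header: str  # free text after ">", without the marker
    sequence: str

    @property
    def id(self) -> str:
        """First whitespace-delimited token of the header."""
        return self.header.split()[0]


@dataclass(frozen=True)
class LabelManifest:
    entries: dict[str, str]  # id -> label

    def __getitem__(self, seq_id: str) -> str:
        return self.entries[seq_id]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SequenceDataset:
    """Labeled sequences in FASTA file order."""

    ids: list[str]
    sequences: list[str]
    labels: list[str]
    headers: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.headers:
            self.headers = list(self.ids)
        assert len(self.ids) == len(self.sequences) == len(self.labels)

    def __len__(self) -> int:
        return len(self.ids)


def _open_text(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=None), True
    return source, False


def read_fasta(source: str | Path | IO[str]) -> list[FastaRecord]:
    """Parse FASTA records, validating the dialect with line numbers."""
    stream, close = _open_text(source)
    try:
        records: list[FastaRecord] = []
        header: str | None = None
        header_line = 0
        chunks: list[str] = []

        def flush():
            if header is None:
                return
            seq = "".join(chunks)
            if not seq.strip():
                rec_id = header.split()[0]
                raise MalformedFasta(f"record {rec_id!r} has an empty sequence", header_line)
            records.append(FastaRecord(header=header, sequence=seq))

        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\r\n")
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise MalformedFasta("empty FASTA header", lineno)
            else:
                if not line.strip():
                    continue
                if header is None:
                    raise MalformedFasta("sequence data before the first '>' header", lineno)
                chunks.append(line.strip())
        flush()
        if not records:
            raise MalformedFasta("no FASTA records found")
        return records
    finally:
        if close:
            stream.close()


def write_fasta(records: Iterable[FastaRecord], dest: str | Path | IO[str]) -> None:
    """Write records wrapped at 60 columns."""
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.header[len(r.id):].strip())
        for r in records
    ]
    stream, close = _open_text(dest, "w")
    try:
        BioSeqIO.write(bio, stream, "fasta")
    finally:
        if close:
            stream.close()


def read_manifest(source: str | Path | IO[str]) -> LabelManifest:
    """Parse the two-column label manifest with closed-vocabulary validation."""
    stream, close = _open_text(source)
    try:
        entries: dict[str, str] = {}
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise MalformedFasta(f"expected 'id<TAB>label', got {line!r}", lineno)
            seq_id, label = parts
            if lineno == 1 and (seq_id, label) == ("id", "label"):
                continue  # optional header row
            if label not in ALL_LABELS:
                raise UnknownLabel(
                    f"line {lineno}: label {label!r} not in {sorted(ALL_LABELS)}"
                )
            if seq_id in entries:
                raise DuplicateId(f"line {lineno}: duplicate sequence id {seq_id!r}")
            entries[seq_id] = label
        return LabelManifest(entries=entries)
    finally:
        if close:
            stream.close()


def write_manifest(manifest: LabelManifest | dict[str, str], dest: str | Path | IO[str]) -> None:
    entries = manifest.entries if isinstance(manifest, LabelManifest) else manifest
    stream, close = _open_text(dest, "w")
    try:
        for seq_id, label in entries.items():
            stream.write(f"{seq_id}\t{label}\n")
    finally:
        if close:
            stream.close()


def join_dataset(
    records: list[FastaRecord],
    manifest: LabelManifest,
    strict: bool = True,
) -> SequenceDataset:
    """Join FASTA records with manifest labels, preserving FASTA order.

    In strict mode the record ids and manifest ids must match exactly
    (:class:`MissingSequence` lists the unmatched ids); in intersection mode
    unmatched entries on either side are dropped with a warning.
    """
    record_ids = {r.id for r in records}
    no_seq = [i for i in manifest.entries if i not in record_ids]
    no_label = [r.id for r in records if r.id not in manifest.entries]
    if strict and (no_seq or no_label):
        raise MissingSequence(
            f"unmatched ids — manifest entries without sequences: {no_seq}; "
            f"sequences without labels: {no_label}"
        )
    if no_seq or no_label:
        warnings.warn(
            f"intersection join: dropping {len(no_seq)} manifest entr(ies) and "
            f"{len(no_label)} unlabeled record(s)"
        )

    ids, seqs, labels, headers = [], [], [], []
    for r in records:
        label = manifest.entries.get(r.id)
        if label is None:
            continue
        ids.append(r.id)
        seqs.append(r.sequence)
        labels.append(label)
        headers.append(r.header)
    return SequenceDataset(ids=ids, sequences=seqs, labels=labels, headers=headers)
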