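"""Sequence and annotation I/O.

Reads protein sequences (FASTA), per-protein disordered-region intervals and
Pfam assignments (TSV), and extracts disordered segments (IDDs) subject to the
minimum-length filter. Disorder prediction itself is an input contract: any
predictor's intervals can be supplied, in 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import AMINO_ACIDS

logger = logging.getLogger(__name__)

_STANDARD = set(AMINO_ACIDS)


@dataclass(frozen=True)
class SequenceRecord:
    """A protein (or segment) sequence over the 20 standard residues.

    ``set_label`` tags which comparison set the record belongs to
    (``"set_a"``, ``"set_b"`` or ``"ordered"``); it is optional plumbing and
    does not affect any computation.
    """

    id: str
    residues: str
    set_label: str | None = None
    removed: int = 0  # non-standard residues stripped at parse time

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty after sanitization")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DisorderInterval:
    """A predicted disordered region, 1-based inclusive on its protein."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"invalid interval [{self.start},{self.end}] on {self.protein_id!r}"
                " (need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IDDSegment:
    """A disordered segment cut out of its parent protein."""

    id: str
    residues: str
    parent: str

    def __len__(self) -> int:
        return len(self.residues)


def _sanitize(raw: str, rec_id: str) -> tuple[str, int]:
    upper = raw.upper()
    kept = [c for c in upper if c in _STANDARD]
    removed = len(upper) - len(kept)
    if removed:
        logger.warning(
            "record %s: removed %d non-standard residue(s)", rec_id, removed
        )
    return "".join(kept), removed


def read_fasta(path: str | Path, set_label: str | None = None) -> list[SequenceRecord]:
    """Parse a FASTA file into sanitized :class:`SequenceRecord` objects.

    Residues are upper-cased; characters outside the 20 standard one-letter
    codes (B, J, O, U, X, Z, ``*``, gaps, ...) are removed, with a logged
    warning and a per-record removal count. Duplicate ids and empty files are
    errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id {entry.id}")
        seen.add(entry.id)
        residues, removed = _sanitize(str(entry.seq), entry.id)
        records.append(
            SequenceRecord(
                id=entry.id, residues=residues, set_label=set_label, removed=removed
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord | IDDSegment], path: str | Path) -> None:
    """Write records (or segments) as FASTA."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def _read_tsv_rows(path: str | Path, columns: Sequence[str]) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        names = header.rstrip("\n").split("\t")
        if names != list(columns):
            raise ValueError(
                f"{path}: expected header {list(columns)}, found {names}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(columns)} fields, found {len(fields)}"
                )
            yield lineno, fields


def read_intervals(path: str | Path) -> list[DisorderInterval]:
    """Read disordered-region intervals from a TSV (protein_id/start/end)."""
    out: list[DisorderInterval] = []
    for lineno, (pid, start, end) in (
        (ln, f) for ln, f in _read_tsv_rows(path, ("protein_id", "start", "end"))
    ):
        try:
            iv = DisorderInterval(pid, int(start), int(end))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        out.append(iv)
    return out


def write_intervals(intervals: Iterable[DisorderInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\n")
        for iv in intervals:
            fh.write(f"{iv.protein_id}\t{iv.start}\t{iv.end}\n")


def read_pfam(path: str | Path) -> list[tuple[str, str]]:
    """Read (protein_id, pfam_id) assignment pairs from a TSV."""
    out: list[tuple[str, str]] = []
    for lineno, (pid, pfam) in (
        (ln, f) for ln, f in _read_tsv_rows(path, ("protein_id", "pfam_id"))
    ):
        if not pid or not pfam:
            raise ValueError(f"{path}:{lineno}: blank field")
        out.append((pid, pfam))
    return out


def write_pfam(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tpfam_id\n")
        for pid, pfam in pairs:
            fh.write(f"{pid}\t{pfam}\n")


def extract_idd_segments(
    proteins: Sequence[SequenceRecord],
    intervals: Iterable[DisorderInterval],
    min_len: int = 30,
) -> list[IDDSegment]:
    """Cut disordered segments out of their parent proteins.

    Only intervals of length ``end - start + 1 >= min_len`` (default 30, the
    conventional minimum for calling a disordered segment a domain) are
    retained. Output is ordered by the parent protein's position in
    ``proteins``, then by interval start. Overlapping intervals are passed
    through unmerged.
    """
    by_id = {p.id: p for p in proteins}
    order = {p.id: i for i, p in enumerate(proteins)}
    kept: list[IDDSegment] = []
    for iv in intervals:
        prot = by_id.get(iv.protein_id)
        if prot is None:
            raise KeyError(f"interval references unknown protein {iv.protein_id!r}")
        if iv.end > len(prot):
            raise ValueError(
                f"interval [{iv.start},{iv.end}] out of bounds for "
                f"{iv.protein_id!r} (length {len(prot)})"
            )
        if iv.length >= min_len:
            kept.append(
                IDDSegment(
                    id=f"{iv.protein_id}:{iv.start}-{iv.end}",
                    residues=prot.residues[iv.start - 1 : iv.end],
                    parent=iv.protein_id,
                )
            )
    kept.sort(key=lambda s: (order[s.parent], int(s.id.rsplit(":", 1)[1].split("-")[0])))
    return kept


def segment_parent(segment_id: str) -> str:
    """Recover the parent protein id from a segment id ``"<pid>:<start>-<end>"``."""
    return segment_id.rsplit(":", 1)[0]
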