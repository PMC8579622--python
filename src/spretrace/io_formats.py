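"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open. The 1-based
formats (RepeatMasker .out, tabular hit output) are converted at this boundary
and nowhere else.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO

from ._dna import normalize

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised for malformed external files; message names the offending record."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker-style repeat locus."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class_family: str = "other"

    def __post_init__(self):
        if not self.repeat_name:
            raise ValueError("repeat_name must be non-empty")


@dataclass(frozen=True)
class RepeatFamily:
    """A named repeat-family consensus sequence.

    repeat_class keeps the raw classification string (e.g. "LTR", "LTR/ERVK",
    "SINE/MIR"); LTR-type families are detected by prefix match. Unknown
    classes are normalized to "other", never dropped, so class-fraction
    denominators stay complete.
    """

    family_id: str
    name: str
    repeat_class: str
    consensus: str

    def __post_init__(self):
        if not self.consensus:
            raise ValueError(f"family {self.family_id}: empty consensus")
        object.__setattr__(self, "consensus", normalize(self.consensus))

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def is_ltr(self) -> bool:
        return self.repeat_class.upper().startswith("LTR")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file to [(id, normalized sequence)], in file order."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
        if head and head != ">":
            raise FormatError(f"{path}: not a FASTA file (first char {head!r})")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        seq = normalize(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Dfam-style EMBL flat file (minimal ID / NM / DE / CC / SQ subset)


def read_dfam_embl(path: PathLike) -> list[RepeatFamily]:
    """Parse a Dfam-style EMBL flat file into repeat families.

    Only the subset Dfam uses is understood: ``ID`` (accession), ``NM`` or
    ``DE`` (name), ``CC`` classification comments carrying ``Type:`` /
    ``SubType:``, the ``SQ`` sequence block, and the ``//`` terminator.
    Entries whose classification cannot be parsed get class "other".
    """
    families: list[RepeatFamily] = []
    cur_id = cur_name = None
    cur_type = cur_subtype = None
    seq_parts: list[str] = []
    in_seq = False
    open_entry = False

    def finish():
        nonlocal cur_id, cur_name, cur_type, cur_subtype, seq_parts, in_seq, open_entry
        if cur_id is None:
            raise FormatError(f"{path}: entry terminator without ID line")
        cls = cur_type or "other"
        if cur_type and cur_subtype:
            cls = f"{cur_type}/{cur_subtype}"
        seq = "".join(seq_parts)
        families.append(
            RepeatFamily(
                family_id=cur_id,
                name=cur_name or cur_id,
                repeat_class=cls,
                consensus=seq,
            )
        )
        cur_id = cur_name = cur_type = cur_subtype = None
        seq_parts = []
        in_seq = False
        open_entry = False

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("//"):
                finish()
                continue
            if line.startswith("ID"):
                open_entry = True
                rest = line[2:].strip()
                cur_id = rest.split(";")[0].split()[0] if rest else None
            elif line.startswith("NM"):
                cur_name = line[2:].strip().rstrip(";")
            elif line.startswith("DE") and cur_name is None:
                cur_name = line[2:].strip()
            elif line.startswith("CC"):
                body = line[2:].strip()
                if body.startswith("Type:"):
                    val = body[len("Type:") :].strip()
                    cur_type = val or None
                elif body.startswith("SubType:"):
                    val = body[len("SubType:") :].strip()
                    cur_subtype = val or None
            elif line.startswith("SQ"):
                in_seq = True
            elif in_seq:
                # sequence lines: bases in space-separated chunks + position number
                seq_parts.append(
                    "".join(c for c in line if c.isalpha())
                )
    if open_entry:
        raise FormatError(f"{path}: truncated entry {cur_id!r} (missing //)")
    return families


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER_LINES = 3


def read_repeatmasker_out(path: PathLike) -> list[RepeatAnnotation]:
    """Parse RepeatMasker .out annotations to 0-based half-open intervals.

    The .out layout gives 1-based inclusive query coordinates and uses "C"
    for the minus strand; both are converted here.
    """
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= _RM_HEADER_LINES or not line.strip():
                continue
            cols = line.split()
            if len(cols) < 11:
                raise FormatError(f"{path}:{lineno}: expected >=11 columns")
            try:
                begin = int(cols[5])
                end = int(cols[6])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate"
                ) from exc
            strand = "-" if cols[8] == "C" else "+"
            annotations.append(
                RepeatAnnotation(
                    interval=GenomicInterval(cols[4], begin - 1, end, strand),
                    repeat_name=cols[9],
                    repeat_class_family=cols[10],
                )
            )
    return annotations


def write_repeatmasker_out(annotations: Sequence[RepeatAnnotation], path: PathLike) -> None:
    """Write a minimal RepeatMasker-style .out file (inverse of the reader)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching"
            "       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    repeat"
            "         class/family         begin  end (left)   ID\n\n"
        )
        for i, ann in enumerate(annotations, start=1):
            iv = ann.interval
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f"  255   0.0  0.0  0.0  {iv.seq_id} {iv.start + 1} {iv.end} (0) "
                f"{strand} {ann.repeat_name} {ann.repeat_class_family} 1 {len(iv)} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# BED6


def read_bed6(path: PathLike) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            start, end = int(cols[1]), int(cols[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            intervals.append(GenomicInterval(cols[0], start, end, cols[5]))
    return intervals


def write_bed6(
    intervals: Sequence[GenomicInterval],
    path: PathLike,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Tabular hit output

HIT_TABLE_COLUMNS = ("target", "S", "E", "strand", "bit_score", "e_value")


def write_hit_table(hits, path: PathLike) -> None:
    """Write hits as TSV, 1-based inclusive S <= E, sorted by E-value ascending."""
    rows = sorted(hits, key=lambda h: (h.e_value, h.target_id, h.S))
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_TABLE_COLUMNS) + "\n")
        for h in rows:
            fh.write(
                f"{h.target_id}\t{h.S}\t{h.E}\t{h.strand}\t"
                f"{h.bit_score:.2f}\t{h.e_value:.3g}\n"
            )
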