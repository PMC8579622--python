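"""Step 1 of the two-step search: exact motif matching over a consensus
library and extraction of core-anchored flanking windows.

The 17-nt core motif is too short to search sensitively on its own; exact
matching over consensus sequences yields the seed families, and fixed-width
windows (core + both flanks, default 40 + 17 + 40 = 97 columns) anchored on
the core provide the first alignment for profile construction. Because the
windows are fixed-width and core-anchored, the first-cycle alignment is
anchor-based (core fixed, flanks ungapped) rather than delegated to a
general multiple aligner, which keeps it deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._dna import revcomp
from .io_formats import RepeatFamily

DEFAULT_CORE_MOTIF = "TCAGCAGGAAGCAGTTA"
DEFAULT_FLANK = 40
GAP = "-"


@dataclass(frozen=True)
class MotifHit:
    """An exact occurrence of the core motif in a family consensus.

    Coordinates are 0-based half-open on the consensus plus strand; a
    minus-strand hit means the reverse complement of the motif occurs there.
    """

    family_id: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class AnchoredWindow:
    """A fixed-width, core-anchored window around a motif hit.

    ``columns`` reads 5'->3' in the hit's orientation, so the core always
    spells the motif at columns [flank, flank + core_len). Flanks truncated
    by the consensus edge are padded with gap characters.
    """

    source: MotifHit
    columns: str
    flank: int
    core_len: int

    @property
    def core(self) -> str:
        return self.columns[self.flank : self.flank + self.core_len]


@dataclass
class Alignment:
    """A rectangular gapped alignment (rows over {A,C,G,T,N,-})."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if self.rows:
            w = len(self.rows[0])
            if any(len(r) != w for r in self.rows):
                raise ValueError("alignment rows have unequal width")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def window_width(core_len: int, flank_5: int, flank_3: int | None = None) -> int:
    """Total width of a core-anchored window: flank_5 + core + flank_3."""
    if flank_3 is None:
        flank_3 = flank_5
    if core_len <= 0 or flank_5 < 0 or flank_3 < 0:
        raise ValueError("core_len must be positive and flanks non-negative")
    return flank_5 + core_len + flank_3


def find_exact_motif(
    library: Iterable[RepeatFamily],
    motif: str = DEFAULT_CORE_MOTIF,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Every exact occurrence of ``motif`` in the library.

    N never matches. With ``both_strands``, occurrences of the reverse
    complement are reported with strand "-" (coordinates stay on the plus
    strand of the consensus).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    rc = revcomp(motif)
    hits: list[MotifHit] = []
    for fam in library:
        seq = fam.consensus
        for strand, pat in (("+", motif), ("-", rc)):
            if strand == "-" and not both_strands:
                continue
            if strand == "-" and rc == motif:
                continue  # palindromic motif: avoid duplicate reports
            pos = seq.find(pat)
            while pos != -1:
                hits.append(MotifHit(fam.family_id, pos, pos + len(pat), strand))
                pos = seq.find(pat, pos + 1)
    hits.sort(key=lambda h: (h.family_id, h.start, h.strand))
    return hits


def families_with_hit(hits: Iterable[MotifHit]) -> set[str]:
    """Distinct family ids among hits."""
    return {h.family_id for h in hits}


def extract_window(
    family: RepeatFamily, hit: MotifHit, flank: int = DEFAULT_FLANK
) -> AnchoredWindow:
    """Extract the core-anchored window around a hit, gap-padded to fixed width.

    Minus-strand hits are reverse-complemented so the core reads 5'->3' as
    the motif; their 5' flank therefore comes from the 3' side of the plus
    strand.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    seq = family.consensus
    if not (0 <= hit.start < hit.end <= len(seq)):
        raise ValueError(
            f"hit {hit.start}-{hit.end} outside consensus of {family.family_id}"
        )
    core_len = hit.end - hit.start
    left = seq[max(0, hit.start - flank) : hit.start]
    core = seq[hit.start : hit.end]
    right = seq[hit.end : hit.end + flank]
    window = GAP * (flank - len(left)) + left + core + right + GAP * (flank - len(right))
    if hit.strand == "-":
        window = _revcomp_gapped(window)
    return AnchoredWindow(source=hit, columns=window, flank=flank, core_len=core_len)


def _revcomp_gapped(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", GAP: GAP}
    return "".join(comp[c] for c in reversed(s))


def anchor_align(windows: Sequence[AnchoredWindow]) -> Alignment:
    """Stack fixed-width anchored windows into an alignment (one row each)."""
    if not windows:
        raise ValueError("no windows to align")
    width = len(windows[0].columns)
    if any(len(w.columns) != width for w in windows):
        raise ValueError("windows have mismatched widths")
    ids = [
        f"{w.source.family_id}:{w.source.start}-{w.source.end}({w.source.strand})"
        for w in windows
    ]
    return Alignment(ids=ids, rows=[w.columns for w in windows])
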