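"""Downstream analytics: position-bias scores, strand-aware interval
extension, stranded intersection against repeat annotations, per-family
tallies, LTR-fraction summaries, and a relative codon-frequency utility.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, RepeatAnnotation, RepeatFamily


def relative_position_score(S: int, E: int, L: int, strand: str = "+") -> float:
    """Hit midpoint as a fraction of element length: [(S + E)/2] / L.

    S and E are 1-based inclusive, L the length of the containing sequence.
    Strandness is considered: a minus-strand hit is scored 1 - midpoint/L so
    the score always measures position along the element's own 5'->3'
    reading (values near 1 = 3'-terminal). Pass strand="+" to reproduce the
    unreflected value.
    """
    if not (1 <= S <= E <= L):
        raise ValueError(f"require 1 <= S <= E <= L, got S={S} E={E} L={L}")
    score = ((S + E) / 2.0) / L
    if strand == "-":
        score = 1.0 - score
    return score


def extend_interval(
    iv: GenomicInterval,
    amount: int = 50,
    direction: str = "3p",
    chrom_len: int | None = None,
) -> GenomicInterval:
    """Extend an interval by ``amount`` nt in its own 5' or 3' direction.

    Directions are read along the feature's strand: for a plus-strand
    interval 3' extension grows the end; for a minus-strand interval it
    grows past the start. Results are clamped to [0, chrom_len].
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    if direction not in ("5p", "3p"):
        raise ValueError("direction must be '5p' or '3p'")
    grow_right = (direction == "3p") == (iv.strand == "+")
    start, end = iv.start, iv.end
    if grow_right:
        end += amount
    else:
        start -= amount
    start = max(0, start)
    if chrom_len is not None:
        end = min(end, chrom_len)
    return GenomicInterval(iv.seq_id, start, end, iv.strand)


def stranded_intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[RepeatAnnotation],
    stranded: bool = True,
) -> list[tuple[GenomicInterval, RepeatAnnotation]]:
    """All (a, b) pairs overlapping by >= 1 nt on the same sequence (and the
    same strand when ``stranded``); both records reported per pair."""
    trees: dict[tuple, IntervalTree] = {}
    for ann in b:
        iv = ann.interval
        key = (iv.seq_id, iv.strand) if stranded else (iv.seq_id,)
        trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, ann)
    pairs = []
    for x in a:
        key = (x.seq_id, x.strand) if stranded else (x.seq_id,)
        tree = trees.get(key)
        if tree is None:
            continue
        for node in sorted(tree.overlap(x.start, x.end)):
            pairs.append((x, node.data))
    return pairs


def overlap_summary(
    hits: Sequence[GenomicInterval],
    annotations: Sequence[RepeatAnnotation],
    amount: int = 50,
    stranded: bool = True,
    chrom_lens: dict[str, int] | None = None,
) -> list[tuple[str, int, int]]:
    """Count hits overlapping any annotation, as-is and after 50-nt
    directional extensions: rows (variant, n_overlapping, n_total) for
    variants "SPRE", "SPRE+5", "SPRE+3"."""
    rows = []
    for variant, direction in (("SPRE", None), ("SPRE+5", "5p"), ("SPRE+3", "3p")):
        if direction is None:
            query = list(hits)
        else:
            query = [
                extend_interval(
                    h, amount, direction,
                    chrom_lens.get(h.seq_id) if chrom_lens else None,
                )
                for h in hits
            ]
        pairs = stranded_intersect(query, annotations, stranded=stranded)
        hit_with = {(q.seq_id, q.start, q.end, q.strand) for q, _ in pairs}
        rows.append((variant, len(hit_with), len(hits)))
    return rows


def tally_by_repeat(
    pairs: Iterable[tuple[GenomicInterval, RepeatAnnotation]],
) -> list[tuple[str, int]]:
    """Counts of annotation records per repeat_name among pairs, descending."""
    counts = Counter(ann.repeat_name for _, ann in pairs)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def ltr_fraction(families_hit: Sequence[RepeatFamily]) -> float:
    """Percent of families whose repeat class is LTR-type (prefix match)."""
    if not families_hit:
        raise ValueError("empty family list")
    n_ltr = sum(1 for f in families_hit if f.is_ltr)
    return 100.0 * n_ltr / len(families_hit)


_CODON_TO_AA: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TO_AA:
        std = CodonTable.unambiguous_dna_by_id[1]
        _CODON_TO_AA.update(std.forward_table)
        for stop in std.stop_codons:
            _CODON_TO_AA[stop] = "*"
    return _CODON_TO_AA


def relative_codon_frequencies(cds: str) -> dict[str, float]:
    """Relative synonymous codon frequencies of a coding sequence.

    For each amino acid, codon counts are normalized to sum to 1 within its
    synonymous family; codons of unused families get 0. The terminal stop
    codon (if present) is counted in the stop family; internal stops raise.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    table = _codon_table()
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if table.get(c) == "*":
            raise ValueError(f"internal stop codon {c} at codon {i + 1}")
    counts = Counter(c for c in codons if c in table)
    aa_totals: Counter = Counter()
    for codon, n in counts.items():
        aa_totals[table[codon]] += n
    freqs = {}
    for codon, aa in table.items():
        total = aa_totals.get(aa, 0)
        freqs[codon] = counts.get(codon, 0) / total if total else 0.0
    return freqs
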