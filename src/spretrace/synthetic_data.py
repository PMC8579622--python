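"""Ground-truth synthetic data: consensus libraries in which a subset of
LTR-class families carry a 3'-biased SPRE-like element, genomes with
diverged inserted copies plus matching repeat-annotation tracks, and decoy
sequence sets with hard negatives.

The element is tripartite: a 5' C-rich motif, the 17-nt core, and a 3'
C-rich motif, separated by short random spacers. The C-rich motif defaults
are synthetic stand-ins chosen for their composition class, not claims about
the real element's consensus. The element midpoint's relative position
within a family is drawn from Beta(5, 1.5) (mean ~0.77), a declared stand-in
for the strong 3'-terminal bias observed in real repeat families.

Every generator is a pure function of its parameters and seed and returns a
machine-readable truth table alongside the sequences, so recall/FDR in tests
are computed from truth + pipeline output only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._dna import BASES, mutate, random_seq, revcomp
from .io_formats import GenomicInterval, RepeatAnnotation, RepeatFamily
from .seed_search import DEFAULT_CORE_MOTIF

DEFAULT_FIVE_PRIME_MOTIF = "CCTCCCC"
DEFAULT_THREE_PRIME_MOTIF = "CCCACCC"


@dataclass(frozen=True)
class ElementSpec:
    """Parameters of the planted SPRE-like element."""

    core: str = DEFAULT_CORE_MOTIF
    five_prime_motif: str = DEFAULT_FIVE_PRIME_MOTIF
    three_prime_motif: str = DEFAULT_THREE_PRIME_MOTIF
    spacer_len_5: tuple[int, int] = (3, 6)  # inclusive range
    spacer_len_3: tuple[int, int] = (3, 6)
    per_base_mutation_rate: float = 0.10  # flanking motifs/spacers only
    indel_rate: float = 0.0  # geometric-length indels, flanks only
    core_max_mutations: int = 0  # per-copy core substitutions, 0..this

    def __post_init__(self):
        for r in (self.per_base_mutation_rate, self.indel_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must be in [0, 1)")
        if any(c not in BASES for c in self.core):
            raise ValueError("core must be over ACGT")


@dataclass(frozen=True)
class TruthRecord:
    """Where one element copy was planted."""

    container_id: str
    interval: GenomicInterval
    element_variant: str = "full"
    n_core_mutations: int = 0


def _indels(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:  # deletion
            continue
        out.append(ch)
        if r >= rate / 2 and r < rate:  # insertion, geometric length
            n = rng.geometric(0.5)
            out.append(random_seq(rng, int(n)))
    return "".join(out)


def build_element(
    rng: np.random.Generator, spec: ElementSpec
) -> tuple[str, int]:
    """One mutated element copy; returns (sequence, n_core_mutations)."""
    sp5 = random_seq(rng, int(rng.integers(spec.spacer_len_5[0], spec.spacer_len_5[1] + 1)))
    sp3 = random_seq(rng, int(rng.integers(spec.spacer_len_3[0], spec.spacer_len_3[1] + 1)))
    rate = spec.per_base_mutation_rate
    left = _indels(rng, mutate(rng, spec.five_prime_motif + sp5, rate), spec.indel_rate)
    right = _indels(rng, mutate(rng, sp3 + spec.three_prime_motif, rate), spec.indel_rate)
    core = spec.core
    n_core = 0
    if spec.core_max_mutations > 0:
        n_core = int(rng.integers(0, spec.core_max_mutations + 1))
        pos = rng.choice(len(core), size=n_core, replace=False)
        cl = list(core)
        for p in pos:
            alts = [b for b in BASES if b != cl[p]]
            cl[p] = alts[rng.integers(3)]
        core = "".join(cl)
    return left + core + right, n_core


def make_library(
    n_families: int = 50,
    frac_with_element: float = 0.2,
    frac_ltr: float = 0.5,
    length_range: tuple[int, int] = (800, 1200),
    position_beta: tuple[float, float] = (5.0, 1.5),
    spec: ElementSpec = ElementSpec(),
    seed: int = 42,
) -> tuple[list[RepeatFamily], list[TruthRecord]]:
    """A consensus library with planted elements and known truth.

    Carrier families are predominantly LTR-class; the element's midpoint
    relative position along the consensus is Beta(alpha, beta)-distributed
    (3'-biased with the defaults) and its strand is random. Insertion
    replaces the background at the chosen locus, so family lengths come from
    ``length_range`` exactly.
    """
    if not (0.0 <= frac_with_element <= 1.0 and 0.0 <= frac_ltr <= 1.0):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_carriers = int(round(n_families * frac_with_element))
    families: list[RepeatFamily] = []
    truth: list[TruthRecord] = []
    other_classes = ["SINE/MIR", "LINE/L1", "DNA/hAT", "other"]
    for i in range(n_families):
        fid = f"SYNFAM{i:04d}"
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = random_seq(rng, L)
        is_carrier = i < n_carriers
        if is_carrier:
            repeat_class = "LTR/ERV" if rng.random() < 0.95 else "SINE/MIR"
        else:
            repeat_class = (
                "LTR/ERV" if rng.random() < frac_ltr
                else other_classes[int(rng.integers(len(other_classes)))]
            )
        if is_carrier:
            elem, n_core = build_element(rng, spec)
            pos = rng.beta(*position_beta)  # along the element's own 5'->3'
            strand = "+" if rng.random() < 0.5 else "-"
            # a minus-strand element reads right-to-left on the consensus,
            # so its own 3' bias lands near the consensus 5' end
            mid = (pos if strand == "+" else 1.0 - pos) * L
            start = int(round(mid - len(elem) / 2.0))
            start = max(0, min(start, L - len(elem)))
            planted = elem if strand == "+" else revcomp(elem)
            seq = seq[:start] + planted + seq[start + len(elem) :]
            truth.append(
                TruthRecord(
                    container_id=fid,
                    interval=GenomicInterval(fid, start, start + len(elem), strand),
                    element_variant="full",
                    n_core_mutations=n_core,
                )
            )
        families.append(
            RepeatFamily(family_id=fid, name=fid, repeat_class=repeat_class, consensus=seq)
        )
    return families, truth


def make_genome(
    families: list[RepeatFamily],
    truth: list[TruthRecord],
    n_copies_per_family: int = 1,
    genome_len: int = 1_000_000,
    divergence: float = 0.0,
    seed: int = 42,
    chrom_id: str = "chr1",
) -> tuple[
    list[tuple[str, str]], list[TruthRecord], list[RepeatAnnotation]
]:
    """A genome with diverged, non-overlapping inserted family copies.

    Each copy gets a RepeatMasker-style annotation covering its whole span;
    element truth intervals (for carrier families) are lifted through the
    insertion, composing the insertion strand with the element strand.
    Divergence is applied uniformly over the copy (core included).
    """
    rng = np.random.default_rng(seed)
    elem_by_family = {t.container_id: t for t in truth}
    inserts = []  # (family, copy_seq, strand, elem_iv_on_copy or None)
    for fam in families:
        for _ in range(n_copies_per_family):
            copy = mutate(rng, fam.consensus, divergence)
            strand = "+" if rng.random() < 0.5 else "-"
            inserts.append((fam, copy, strand))
    total = sum(len(c) for _, c, _ in inserts)
    if total > genome_len:
        raise ValueError(
            f"total insert length {total} exceeds genome length {genome_len}"
        )
    genome = list(random_seq(rng, genome_len))
    # sample non-overlapping loci
    taken: list[tuple[int, int]] = []
    placements = []
    for fam, copy, strand in inserts:
        for _ in range(10_000):
            start = int(rng.integers(0, genome_len - len(copy) + 1))
            end = start + len(copy)
            if all(end <= s or start >= e for s, e in taken):
                taken.append((start, end))
                placements.append((fam, copy, strand, start))
                break
        else:
            raise ValueError("could not place all inserts without overlap")
    annotations: list[RepeatAnnotation] = []
    genome_truth: list[TruthRecord] = []
    for fam, copy, strand, start in placements:
        placed = copy if strand == "+" else revcomp(copy)
        genome[start : start + len(copy)] = placed
        annotations.append(
            RepeatAnnotation(
                interval=GenomicInterval(chrom_id, start, start + len(copy), strand),
                repeat_name=fam.name,
                repeat_class_family=fam.repeat_class,
            )
        )
        t = elem_by_family.get(fam.family_id)
        if t is not None:
            s, e = t.interval.start, t.interval.end
            if strand == "+":
                gs, ge = start + s, start + e
                gstrand = t.interval.strand
            else:
                gs, ge = start + len(copy) - e, start + len(copy) - s
                gstrand = "-" if t.interval.strand == "+" else "+"
            genome_truth.append(
                TruthRecord(
                    container_id=chrom_id,
                    interval=GenomicInterval(chrom_id, gs, ge, gstrand),
                    element_variant=t.element_variant,
                    n_core_mutations=t.n_core_mutations,
                )
            )
    annotations.sort(key=lambda a: a.interval.start)
    genome_truth.sort(key=lambda t: t.interval.start)
    return [(chrom_id, "".join(genome))], genome_truth, annotations


def make_adjacent_genome(
    n_elements: int = 20,
    gap: int = 30,
    annotation_len: int = 300,
    genome_len: int = 200_000,
    spec: ElementSpec = ElementSpec(per_base_mutation_rate=0.0),
    element_seqs: list[str] | None = None,
    seed: int = 42,
    chrom_id: str = "chr1",
) -> tuple[
    list[tuple[str, str]], list[GenomicInterval], list[RepeatAnnotation]
]:
    """A genome where every element sits exactly ``gap`` nt upstream (5') of
    an LTR-labelled annotation on the same strand — the construction in
    which unextended elements overlap nothing while 3'-extended ones all do.

    ``element_seqs`` plants the given sequences (cycled to ``n_elements``);
    pass the anchored windows a model was trained on so its alignments end
    at the planted boundaries. With None, bare elements from ``spec`` are
    planted instead.
    """
    rng = np.random.default_rng(seed)
    genome = list(random_seq(rng, genome_len))
    taken: list[tuple[int, int]] = []
    elements: list[GenomicInterval] = []
    annotations: list[RepeatAnnotation] = []
    for i in range(n_elements):
        if element_seqs:
            elem = element_seqs[i % len(element_seqs)]
        else:
            elem, _ = build_element(rng, spec)
        block = len(elem) + gap + annotation_len
        for _ in range(10_000):
            start = int(rng.integers(0, genome_len - block + 1))
            end = start + block
            if all(end <= s or start >= e for s, e in taken):
                taken.append((start, end))
                break
        else:
            raise ValueError("could not place all elements")
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            e_iv = GenomicInterval(chrom_id, start, start + len(elem), "+")
            a_iv = GenomicInterval(
                chrom_id, e_iv.end + gap, e_iv.end + gap + annotation_len, "+"
            )
            genome[e_iv.start : e_iv.end] = elem
        else:
            # element 3' direction points left on the genome
            a_iv = GenomicInterval(chrom_id, start, start + annotation_len, "-")
            e_start = a_iv.end + gap
            e_iv = GenomicInterval(chrom_id, e_start, e_start + len(elem), "-")
            genome[e_iv.start : e_iv.end] = revcomp(elem)
        elements.append(e_iv)
        annotations.append(
            RepeatAnnotation(
                interval=a_iv, repeat_name=f"SYNLTR{i}", repeat_class_family="LTR/ERV"
            )
        )
    elements.sort(key=lambda iv: iv.start)
    annotations.sort(key=lambda a: a.interval.start)
    return [(chrom_id, "".join(genome))], elements, annotations


def make_decoys(
    n: int = 30,
    length: int = 500,
    spec: ElementSpec = ElementSpec(),
    seed: int = 42,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Background decoys plus hard negatives, cycling three categories:
    plain background, core-only (exact core, no C-rich flanks), and a full
    element whose core has been shuffled. Returns (records, categories)."""
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    categories: list[str] = []
    kinds = ("background", "core_only", "shuffled_core")
    for i in range(n):
        kind = kinds[i % len(kinds)]
        seq = random_seq(rng, length)
        if kind == "core_only":
            pos = int(rng.integers(0, length - len(spec.core) + 1))
            seq = seq[:pos] + spec.core + seq[pos + len(spec.core) :]
        elif kind == "shuffled_core":
            idx = rng.permutation(len(spec.core))
            shuffled_spec = replace(spec, core="".join(spec.core[j] for j in idx))
            elem, _ = build_element(rng, shuffled_spec)
            pos = int(rng.integers(0, length - len(elem) + 1))
            seq = seq[:pos] + elem + seq[pos + len(elem) :]
        records.append((f"decoy{i:03d}_{kind}", seq))
        categories.append(kind)
    return records, categories
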