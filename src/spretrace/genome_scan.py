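"""Apply a frozen, selected-cycle model to long targets (genomes or viral
sequence sets) in overlapping chunks, with global E-value statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .profile_hmm import HmmHit, ProfileHMM, search_sequence


@dataclass
class ScanResult:
    hits: list[HmmHit]
    near_threshold: list[HmmHit] = field(default_factory=list)
    n_residues: int = 0


def scan(
    model: ProfileHMM,
    targets: list[tuple[str, str]],
    e_threshold: float = 1e-5,
    chunk: int = 100_000,
    overlap: int = 500,
    near_threshold: float = 0.01,
) -> ScanResult:
    """Scan targets in overlapping chunks on both strands.

    Chunk-local coordinates are lifted to target coordinates. Duplicates in
    overlap zones (identical target/span/strand) are removed, and same-strand
    hits overlapping by >= 1 nt are merged keeping the lower E-value, which
    also absorbs boundary-truncated alignments of an element straddling a
    chunk edge (its complete copy in the neighbouring chunk wins). N_eff is
    set to total scanned residues / model length before E-values are
    computed, so E-values reflect the whole scan rather than one chunk.

    Hits with e_threshold <= E < ``near_threshold`` are reported separately
    (sub-threshold candidates worth a manual look) and excluded from the
    main table.
    """
    if not model.calibrated:
        raise RuntimeError("model must be calibrated before scanning")
    if overlap < model.M:
        raise ValueError(
            f"overlap ({overlap}) must be >= model length ({model.M}); "
            "hits could be split across chunks"
        )
    if chunk <= overlap:
        raise ValueError("chunk must be > overlap")
    total_residues = sum(len(seq) for _, seq in targets)
    model.n_eff = max(total_residues / model.M, 1.0)

    seen: set[tuple[str, int, int, str]] = set()
    main: list[HmmHit] = []
    near: list[HmmHit] = []
    for target_id, seq in targets:
        step = chunk - overlap
        for off in range(0, max(len(seq) - overlap, 1), step):
            piece = seq[off : off + chunk]
            if len(piece) < model.M:
                continue
            for h in search_sequence(
                model, piece, target_id, e_threshold=near_threshold
            ):
                h.S += off
                h.E += off
                key = (h.target_id, h.S, h.E, h.strand)
                if key in seen:
                    continue
                seen.add(key)
                if h.e_value < e_threshold:
                    main.append(h)
                elif h.e_value < near_threshold:
                    near.append(h)
    from .iterative_search import _merge_hits

    main = _merge_hits(main)
    near = [
        h for h in _merge_hits(near)
        if not any(
            h.target_id == m.target_id and h.strand == m.strand
            and h.S <= m.E and m.S <= h.E
            for m in main
        )
    ]
    near.sort(key=lambda h: (h.target_id, h.S, h.strand))
    return ScanResult(hits=main, near_threshold=near, n_residues=total_residues)


def per_target_counts(
    hits: list[HmmHit], target_ids: list[str]
) -> list[tuple[str, int]]:
    """Hit counts per target, zero-filled for hitless targets."""
    counts = {t: 0 for t in target_ids}
    for h in hits:
        counts[h.target_id] = counts.get(h.target_id, 0) + 1
    return [(t, counts[t]) for t in counts]
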