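"""Step 2: iterative profile refinement (search -> threshold -> realign ->
rebuild), tracking per-cycle hit counts and selecting the peak cycle.

Each cycle scans the whole library on both strands with the current model,
keeps hits below the E-value threshold, realigns them in model-column
coordinates and rebuilds the profile for the next cycle. The cycle with the
most hits is adopted (earliest cycle on ties), mirroring the strategy of
running a fixed number of cycles and taking the peak. Iteration stops early
when a cycle yields no hits or exactly reproduces the previous hit set,
which cannot change the selected cycle under the tie rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_overlap import relative_position_score
from .io_formats import RepeatFamily
from .profile_hmm import (
    DEFAULT_SEED,
    HmmHit,
    ProfileHMM,
    build_hmm,
    calibrate,
    hits_to_alignment,
    search_sequence,
)
from .seed_search import Alignment
from ._dna import BASES


@dataclass
class CycleRecord:
    """Outcome of one refinement cycle."""

    cycle_index: int  # 1-based
    n_hits: int
    n_families: int  # distinct targets with >= 1 hit
    model_snapshot: ProfileHMM
    hit_table: list[HmmHit]


def _merge_hits(hits: list[HmmHit]) -> list[HmmHit]:
    """Merge same-target same-strand hits overlapping by >= 1 nt, keeping the
    lower E-value (prevents double counting after mask-and-rescan)."""
    by_key: dict[tuple[str, str], list[HmmHit]] = {}
    for h in hits:
        by_key.setdefault((h.target_id, h.strand), []).append(h)
    merged: list[HmmHit] = []
    for group in by_key.values():
        group.sort(key=lambda h: (h.S, h.E))
        kept: list[HmmHit] = []
        for h in group:
            if kept and h.S <= kept[-1].E:  # 1-based inclusive overlap
                if h.e_value < kept[-1].e_value:
                    kept[-1] = h
            else:
                kept.append(h)
        merged.extend(kept)
    merged.sort(key=lambda h: (h.target_id, h.S, h.strand))
    return merged


def run_cycle(
    model: ProfileHMM,
    library: list[RepeatFamily],
    e_threshold: float = 1e-5,
) -> CycleRecord:
    """Scan every library sequence (both strands) with a calibrated model."""
    if not model.calibrated:
        raise RuntimeError("model must be calibrated before searching")
    model.n_eff = 2.0 * max(len(library), 1)  # sequences x strands
    hits: list[HmmHit] = []
    for fam in library:
        hits.extend(
            search_sequence(
                model, fam.consensus, fam.family_id, e_threshold=e_threshold
            )
        )
    hits = _merge_hits(hits)
    return CycleRecord(
        cycle_index=0,
        n_hits=len(hits),
        n_families=len({h.target_id for h in hits}),
        model_snapshot=model,
        hit_table=hits,
    )


def _hit_key(hits) -> frozenset:
    return frozenset((h.target_id, h.S, h.E, h.strand) for h in hits)


def iterate(
    seed_alignment: Alignment,
    library: list[RepeatFamily],
    max_cycles: int = 10,
    e_threshold: float = 1e-5,
    seed: int = DEFAULT_SEED,
    gap_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    calibration_samples: int = 1000,
    early_stop: bool = True,
) -> tuple[list[CycleRecord], int]:
    """Run the refinement loop; returns (cycle records, selected cycle index).

    Cycle 1's model is built from the seed alignment, cycle c's from cycle
    c-1's realigned hits. The model is recalibrated every cycle with the
    same seed (its length and information content change as it refines).
    """
    if seed_alignment.n_rows == 0:
        raise ValueError("empty seed alignment")
    records: list[CycleRecord] = []
    alignment = seed_alignment
    prev_key = None
    for cycle in range(1, max_cycles + 1):
        model = build_hmm(
            alignment,
            gap_threshold=gap_threshold,
            pseudocount=pseudocount,
            background=background,
        )
        calibrate(model, n_samples=calibration_samples, seed=seed)
        rec = run_cycle(model, library, e_threshold=e_threshold)
        rec.cycle_index = cycle
        records.append(rec)
        if rec.n_hits == 0:
            break
        key = _hit_key(rec.hit_table)
        if early_stop and key == prev_key:
            break
        prev_key = key
        alignment = hits_to_alignment(rec.hit_table)
    selected = max(records, key=lambda r: (r.n_hits, -r.cycle_index)).cycle_index
    return records, selected


def positions_report(
    selected: CycleRecord, library: list[RepeatFamily]
) -> list[tuple[str, float]]:
    """Relative position score [(S+E)/2]/L (strand-aware) for every hit."""
    lengths = {fam.family_id: fam.length for fam in library}
    out = []
    for h in selected.hit_table:
        L = lengths[h.target_id]
        out.append(
            (h.target_id, relative_position_score(h.S, h.E, L, h.strand))
        )
    return out


def column_frequency_report(selected: CycleRecord) -> np.ndarray:
    """Per-model-column residue frequencies (M x 4 over A,C,G,T) from the
    selected cycle's hit alignment; rows sum to 1 over non-gap counts.
    This is the numeric table a sequence logo would be drawn from."""
    if not selected.hit_table:
        raise ValueError("selected cycle has no hits")
    aln = hits_to_alignment(selected.hit_table)
    M = aln.width
    counts = np.zeros((M, 4))
    idx = {b: i for i, b in enumerate(BASES)}
    for row in aln.rows:
        for c, ch in enumerate(row):
            if ch in idx:
                counts[c, idx[ch]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return freqs
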