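"""Shared fixtures: a default synthetic library and the refined model built
from it. Session-scoped because iteration (with per-cycle calibration) is
the expensive step most tests share."""

from __future__ import annotations

import numpy as np
import pytest

from spretrace import (
    anchor_align,
    extract_window,
    find_exact_motif,
    iterate,
    make_library,
)
from spretrace.profile_hmm import background_from_seqs


@pytest.fixture(scope="session")
def default_library():
    """50 families, 20% carriers, 10% flank divergence, intact cores."""
    return make_library(seed=1)


@pytest.fixture(scope="session")
def seed_alignment(default_library):
    library, _ = default_library
    fam = {f.family_id: f for f in library}
    hits = find_exact_motif(library)
    windows = [extract_window(fam[h.family_id], h) for h in hits]
    return anchor_align(windows)


@pytest.fixture(scope="session")
def library_background(default_library):
    library, _ = default_library
    return background_from_seqs(f.consensus for f in library)


@pytest.fixture(scope="session")
def iterated(default_library, seed_alignment, library_background):
    library, _ = default_library
    records, selected = iterate(
        seed_alignment, library, seed=7, background=library_background
    )
    return records, selected


@pytest.fixture(scope="session")
def selected_model(iterated):
    records, selected = iterated
    return next(r for r in records if r.cycle_index == selected).model_snapshot


@pytest.fixture(scope="session")
def planted_genome(default_library):
    """400 kb genome with 2 zero-divergence copies of each carrier (20 total)."""
    from spretrace.synthetic_data import make_genome

    library, truth = default_library
    carriers = [f for f in library
                if f.family_id in {t.container_id for t in truth}]
    return make_genome(carriers, truth, n_copies_per_family=2,
                       genome_len=400_000, divergence=0.0, seed=11)


def random_profile_hmm(M: int, rng: np.random.Generator, exit_prob: float = 0.1):
    """A random valid model, for oracle and property tests."""
    from spretrace.profile_hmm import ProfileHMM

    me = rng.dirichlet(np.ones(4), size=M)
    ie = np.vstack(
        [np.full((1, 4), 0.25)]
        + [rng.dirichlet(np.ones(4))[None, :] for _ in range(max(M - 1, 0))]
        + [np.full((1, 4), 0.25)]
    )
    t_mm = np.zeros(M); t_mi = np.zeros(M); t_md = np.zeros(M); t_me = np.zeros(M)
    t_im = np.zeros(M); t_ii = np.zeros(M)
    t_dm = np.zeros(M); t_dd = np.zeros(M)
    for j in range(M - 1):
        m = rng.dirichlet(np.ones(3)) * (1 - exit_prob)
        t_mm[j], t_mi[j], t_md[j] = m
        t_me[j] = exit_prob
        t_im[j], t_ii[j] = rng.dirichlet(np.ones(2))
        t_dm[j], t_dd[j] = rng.dirichlet(np.ones(2))
    t_me[M - 1] = 1.0
    if M > 1:
        t_dm[M - 1] = 1.0
    model = ProfileHMM(
        match_emissions=me, insert_emissions=ie,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_me=t_me,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        entry=np.full(M, 1.0 / M),
    )
    model.validate()
    return model


def enumerate_local_paths(hmm, target: str) -> list[float]:
    """Log2-odds of every legal local path of ``hmm`` over ``target``.

    Independent of the DP implementation: recursive enumeration over entry
    point, start position and state sequence. Exponential; use only for
    tiny models and targets.
    """
    import math

    from spretrace._dna import BASES

    M, L, q = hmm.M, len(target), hmm.background
    bi = {b: i for i, b in enumerate(BASES)}
    out: list[float] = []

    def ext(state, j, pos, logp):
        if state == "M":
            if hmm.t_me[j - 1] > 0:
                out.append(logp + math.log2(hmm.t_me[j - 1]))
            if j < M:
                if pos < L and hmm.t_mm[j - 1] > 0:
                    c = bi[target[pos]]
                    e = hmm.match_emissions[j, c]
                    if e > 0:
                        ext("M", j + 1, pos + 1,
                            logp + math.log2(hmm.t_mm[j - 1]) + math.log2(e / q[c]))
                if pos < L and hmm.t_mi[j - 1] > 0:
                    c = bi[target[pos]]
                    e = hmm.insert_emissions[j, c]
                    if e > 0:
                        ext("I", j, pos + 1,
                            logp + math.log2(hmm.t_mi[j - 1]) + math.log2(e / q[c]))
                if hmm.t_md[j - 1] > 0:
                    ext("D", j + 1, pos, logp + math.log2(hmm.t_md[j - 1]))
        elif state == "I":
            if pos < L and hmm.t_im[j - 1] > 0:
                c = bi[target[pos]]
                e = hmm.match_emissions[j, c]
                if e > 0:
                    ext("M", j + 1, pos + 1,
                        logp + math.log2(hmm.t_im[j - 1]) + math.log2(e / q[c]))
            if pos < L and hmm.t_ii[j - 1] > 0:
                c = bi[target[pos]]
                e = hmm.insert_emissions[j, c]
                if e > 0:
                    ext("I", j, pos + 1,
                        logp + math.log2(hmm.t_ii[j - 1]) + math.log2(e / q[c]))
        else:  # D, silent
            if j < M:
                if pos < L and hmm.t_dm[j - 1] > 0:
                    c = bi[target[pos]]
                    e = hmm.match_emissions[j, c]
                    if e > 0:
                        ext("M", j + 1, pos + 1,
                            logp + math.log2(hmm.t_dm[j - 1]) + math.log2(e / q[c]))
                if hmm.t_dd[j - 1] > 0:
                    ext("D", j + 1, pos, logp + math.log2(hmm.t_dd[j - 1]))

    for s in range(L):
        for j0 in range(1, M + 1):
            c = bi[target[s]]
            e = hmm.match_emissions[j0 - 1, c]
            if e > 0 and hmm.entry[j0 - 1] > 0:
                ext("M", j0, s + 1,
                    math.log2(hmm.entry[j0 - 1]) + math.log2(e / q[c]))
    return out


def write_dfam_embl(path, families, motif_note: bool = False) -> None:
    """Serialize families as a minimal Dfam-style EMBL flat file."""
    with open(path, "w") as fh:
        for fam in families:
            fh.write(f"ID   {fam.family_id}; SV 1; linear; DNA; STD; UNC; "
                     f"{fam.length} BP.\n")
            fh.write(f"NM   {fam.name}\n")
            parts = fam.repeat_class.split("/")
            fh.write(f"CC        Type: {parts[0]}\n")
            if len(parts) > 1:
                fh.write(f"CC        SubType: {parts[1]}\n")
            fh.write(f"SQ   Sequence {fam.length} BP;\n")
            seq = fam.consensus.lower()
            for i in range(0, len(seq), 60):
                chunk = seq[i : i + 60]
                fh.write(f"     {chunk} {min(i + 60, len(seq))}\n")
            fh.write("//\n")
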