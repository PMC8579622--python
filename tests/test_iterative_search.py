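import numpy as np
import pytest

from spretrace import (
    anchor_align,
    extract_window,
    families_with_hit,
    find_exact_motif,
    iterate,
    make_library,
    run_cycle,
)
from spretrace.iterative_search import (
    column_frequency_report,
    positions_report,
    _merge_hits,
)
from spretrace.io_formats import RepeatFamily
from spretrace.profile_hmm import HmmHit, background_from_seqs
from spretrace.seed_search import DEFAULT_CORE_MOTIF
from spretrace.synthetic_data import ElementSpec


def seed_aln_for(library):
    fam = {f.family_id: f for f in library}
    hits = find_exact_motif(library)
    return anchor_align(
        [extract_window(fam[h.family_id], h) for h in hits]
    )


class TestRunCycle:
    def test_zero_divergence_planted_library(self, iterated, default_library):
        """10 of 50 families carry the element; cycle search finds exactly
        those families."""
        library, truth = default_library
        records, _ = iterated
        rec = records[0]
        assert rec.n_families == len(truth) == 10
        assert {h.target_id for h in rec.hit_table} == {
            t.container_id for t in truth
        }

    def test_uncalibrated_model_is_an_error(self, seed_alignment, default_library):
        from spretrace.profile_hmm import build_hmm

        library, _ = default_library
        model = build_hmm(seed_alignment)
        with pytest.raises(RuntimeError, match="calibrat"):
            run_cycle(model, library)

    def test_empty_library_zero_hits(self, selected_model):
        rec = run_cycle(selected_model, [])
        assert rec.n_hits == 0 and rec.n_families == 0

    def test_duplicate_family_adds_its_hits(self, selected_model, default_library):
        library, truth = default_library
        rec0 = run_cycle(selected_model, library)
        carrier = next(
            f for f in library if f.family_id == truth[0].container_id
        )
        dup = RepeatFamily("DUP", "DUP", carrier.repeat_class, carrier.consensus)
        rec1 = run_cycle(selected_model, library + [dup])
        per_target = {}
        for h in rec0.hit_table:
            per_target[h.target_id] = per_target.get(h.target_id, 0) + 1
        assert rec1.n_hits == rec0.n_hits + per_target[carrier.family_id]


class TestMergeHits:
    def _hit(self, s, e, ev, strand="+", t="x"):
        return HmmHit(t, s, e, strand, 10.0, ev)

    def test_overlapping_same_strand_merged_keeping_best(self):
        merged = _merge_hits([self._hit(1, 50, 1e-3), self._hit(40, 90, 1e-8)])
        assert len(merged) == 1 and merged[0].e_value == 1e-8

    def test_opposite_strands_not_merged(self):
        merged = _merge_hits(
            [self._hit(1, 50, 1e-3), self._hit(40, 90, 1e-8, strand="-")]
        )
        assert len(merged) == 2

    def test_disjoint_kept(self):
        merged = _merge_hits([self._hit(1, 50, 1e-3), self._hit(51, 90, 1e-8)])
        assert len(merged) == 2


class TestIterate:
    def test_fixed_point_on_exact_copies(self):
        """Library of exact element copies: cycle 2 reproduces cycle 1's
        hit set, iteration stops early, earliest cycle selected."""
        rng = np.random.default_rng(0)
        spec = ElementSpec(per_base_mutation_rate=0.0, spacer_len_5=(4, 4),
                          spacer_len_3=(4, 4))
        library, truth = make_library(
            n_families=12, frac_with_element=1.0, spec=spec, seed=3
        )
        aln = seed_aln_for(library)
        records, selected = iterate(aln, library, seed=5)
        assert selected == 1
        assert len(records) <= 3  # early stop after a repeated hit set
        assert records[0].n_hits == records[-1].n_hits

    def test_tie_broken_by_earliest_cycle(self, iterated):
        records, selected = iterated
        best = max(r.n_hits for r in records)
        first_best = min(r.cycle_index for r in records if r.n_hits == best)
        assert selected == first_best

    def test_lower_threshold_never_increases_hits(
        self, seed_alignment, default_library, library_background
    ):
        library, _ = default_library
        loose, _ = iterate(seed_alignment, library, max_cycles=1,
                           e_threshold=1e-3, seed=7,
                           background=library_background)
        strict, _ = iterate(seed_alignment, library, max_cycles=1,
                            e_threshold=1e-9, seed=7,
                            background=library_background)
        assert strict[0].n_hits <= loose[0].n_hits

    def test_determinism(self, seed_alignment, default_library, library_background):
        library, _ = default_library
        a, sa = iterate(seed_alignment, library, max_cycles=2, seed=7,
                        background=library_background)
        b, sb = iterate(seed_alignment, library, max_cycles=2, seed=7,
                        background=library_background)
        assert sa == sb
        assert [(r.n_hits, r.n_families) for r in a] == [
            (r.n_hits, r.n_families) for r in b]
        assert [
            (h.target_id, h.S, h.E, h.strand, h.bit_score)
            for h in a[0].hit_table
        ] == [
            (h.target_id, h.S, h.E, h.strand, h.bit_score)
            for h in b[0].hit_table
        ]

    def test_empty_seed_alignment_is_an_error(self, default_library):
        from spretrace.seed_search import Alignment

        library, _ = default_library
        with pytest.raises(ValueError):
            iterate(Alignment(ids=[], rows=[]), library)

    def test_recovers_core_mutated_carriers_beyond_exact_match(self):
        """Graded divergence with some mutated cores: profile search
        recovers strictly more families than step-1 exact matching."""
        spec = ElementSpec(per_base_mutation_rate=0.15, core_max_mutations=2)
        library, truth = make_library(
            n_families=50, frac_with_element=0.4, spec=spec, seed=21
        )
        assert any(t.n_core_mutations > 0 for t in truth)
        step1 = families_with_hit(find_exact_motif(library))
        truth_ids = {t.container_id for t in truth}
        assert step1 < truth_ids  # exact match misses mutated cores
        aln = seed_aln_for(library)
        bg = background_from_seqs(f.consensus for f in library)
        records, selected = iterate(aln, library, seed=9, background=bg)
        sel = next(r for r in records if r.cycle_index == selected)
        found = {h.target_id for h in sel.hit_table}
        assert len(found & truth_ids) > len(step1)
        assert found >= step1


class TestReports:
    def test_positions_report_in_unit_interval(self, iterated, default_library):
        library, _ = default_library
        records, selected = iterated
        sel = next(r for r in records if r.cycle_index == selected)
        scores = [s for _, s in positions_report(sel, library)]
        assert len(scores) == sel.n_hits
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_column_frequencies_modal_residues_spell_core(self, iterated):
        records, selected = iterated
        sel = next(r for r in records if r.cycle_index == selected)
        freqs = column_frequency_report(sel)
        assert freqs.shape[1] == 4
        assert np.allclose(freqs.sum(axis=1), 1.0)
        modal = "".join("ACGT"[i] for i in freqs.argmax(axis=1))
        assert DEFAULT_CORE_MOTIF in modal

    def test_column_frequencies_order_invariant(self, iterated):
        import copy

        records, selected = iterated
        sel = next(r for r in records if r.cycle_index == selected)
        shuffled = copy.copy(sel)
        shuffled.hit_table = list(reversed(sel.hit_table))
        assert np.allclose(
            column_frequency_report(sel), column_frequency_report(shuffled)
        )

    def test_one_hot_for_identical_hits(self):
        hits = [
            HmmHit("a", 1, 4, "+", 10.0, 1e-9, aligned_row="ACGT"),
            HmmHit("b", 1, 4, "+", 10.0, 1e-9, aligned_row="ACGT"),
        ]
        from spretrace.iterative_search import CycleRecord

        rec = CycleRecord(1, 2, 2, None, hits)
        freqs = column_frequency_report(rec)
        assert np.allclose(freqs.max(axis=1), 1.0)
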