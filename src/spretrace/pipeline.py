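"""End-to-end orchestration of the synthetic discovery run:
simulate -> seed -> iterate -> scan -> overlap -> report.

A run is a plain directory with one JSON manifest recording the
configuration and the SHA-256 of every output file; rerunning with the same
configuration is byte-identical, and a rerun over a tampered directory
fails loudly on the hash mismatch.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import annotation_overlap, genome_scan, io_formats, iterative_search
from . import profile_hmm, seed_search, synthetic_data

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "motif": seed_search.DEFAULT_CORE_MOTIF,
    "flank": 40,
    "library": {
        "n_families": 50,
        "frac_with_element": 0.2,
        "frac_ltr": 0.5,
        "length_range": [800, 1200],
        "position_beta": [5.0, 1.5],
        "per_base_mutation_rate": 0.10,
        "core_max_mutations": 0,
    },
    "iterate": {
        "max_cycles": 10,
        "e_threshold": 1e-5,
        "calibration_samples": 1000,
        "early_stop": True,
    },
    "genome": {
        "genome_len": 1_000_000,
        "n_copies_per_family": 1,
        "divergence": 0.0,
        "carriers_only": True,
        "n_copies_background": 0,
    },
    "scan": {"e_threshold": 1e-5, "chunk": 100_000, "overlap": 500},
    "overlap": {"amount": 50, "stranded": True},
}


class PipelineError(RuntimeError):
    pass


def _merged(config: dict | None) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def verify_manifest(rundir: Path) -> None:
    manifest_path = rundir / "manifest.json"
    if not manifest_path.exists():
        return
    manifest = json.loads(manifest_path.read_text())
    for rel, digest in manifest.get("files", {}).items():
        p = rundir / rel
        if p.exists() and _sha256(p) != digest:
            raise PipelineError(
                f"intermediate file {rel} does not match the recorded hash; "
                "the run directory was modified"
            )


def run_all(config: dict | None, outdir) -> dict:
    """Execute all stages into ``outdir``; returns the summary report."""
    cfg = _merged(config)
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    verify_manifest(rundir)
    seed = int(cfg["seed"])
    files: dict[str, str] = {}

    def emit(rel: str, writer) -> None:
        path = rundir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        files[rel] = _sha256(path)

    # --- stage 1: simulate library
    lib_cfg = cfg["library"]
    spec = synthetic_data.ElementSpec(
        core=cfg["motif"],
        per_base_mutation_rate=lib_cfg["per_base_mutation_rate"],
        core_max_mutations=lib_cfg["core_max_mutations"],
    )
    library, truth = synthetic_data.make_library(
        n_families=lib_cfg["n_families"],
        frac_with_element=lib_cfg["frac_with_element"],
        frac_ltr=lib_cfg["frac_ltr"],
        length_range=tuple(lib_cfg["length_range"]),
        position_beta=tuple(lib_cfg["position_beta"]),
        spec=spec,
        seed=seed,
    )
    emit("library.fa", lambda p: io_formats.write_fasta(
        [(f.family_id, f.consensus) for f in library], p))
    emit("library_truth.bed", lambda p: io_formats.write_bed6(
        [t.interval for t in truth], p,
        names=[t.element_variant for t in truth]))

    # --- stage 2: seed search
    motif_hits = seed_search.find_exact_motif(library, cfg["motif"])
    if not motif_hits:
        raise PipelineError("seed stage produced no exact-match hits")
    fam_by_id = {f.family_id: f for f in library}
    windows = [
        seed_search.extract_window(fam_by_id[h.family_id], h, cfg["flank"])
        for h in motif_hits
    ]
    seed_aln = seed_search.anchor_align(windows)
    emit("seed_windows.afa", lambda p: io_formats.write_fasta(
        list(zip(seed_aln.ids, seed_aln.rows)), p))

    # --- stage 3: iterative refinement
    background = profile_hmm.background_from_seqs(
        [f.consensus for f in library])
    it_cfg = cfg["iterate"]
    records, selected = iterative_search.iterate(
        seed_aln, library,
        max_cycles=it_cfg["max_cycles"],
        e_threshold=it_cfg["e_threshold"],
        seed=seed,
        background=background,
        calibration_samples=it_cfg["calibration_samples"],
        early_stop=it_cfg["early_stop"],
    )
    sel = next(r for r in records if r.cycle_index == selected)

    def write_cycles(p: Path) -> None:
        with open(p, "w") as fh:
            fh.write("cycle\tn_hits\tn_families\n")
            for r in records:
                fh.write(f"{r.cycle_index}\t{r.n_hits}\t{r.n_families}\n")

    emit("cycles.tsv", write_cycles)
    emit("selected_model.hmm", lambda p: sel.model_snapshot.save(p))
    emit("selected_hits.tsv", lambda p: io_formats.write_hit_table(
        sel.hit_table, p))

    hit_families = {h.target_id for h in sel.hit_table}
    truth_families = {t.container_id for t in truth}
    recall = (len(hit_families & truth_families) / len(truth_families)
              if truth_families else float("nan"))
    fdr = (len(hit_families - truth_families) / len(hit_families)
           if hit_families else 0.0)
    step1_recall = (
        len(seed_search.families_with_hit(motif_hits) & truth_families)
        / len(truth_families) if truth_families else float("nan"))

    scores = [s for _, s in iterative_search.positions_report(sel, library)]

    # --- stage 4: simulate genome (carrier families by default)
    g_cfg = cfg["genome"]
    carriers = [f for f in library if f.family_id in truth_families]
    genome_families = carriers if g_cfg["carriers_only"] else library
    genome, genome_truth, annotations = synthetic_data.make_genome(
        genome_families, truth,
        n_copies_per_family=g_cfg["n_copies_per_family"],
        genome_len=g_cfg["genome_len"],
        divergence=g_cfg["divergence"],
        seed=seed + 1,
    )
    emit("genome.fa", lambda p: io_formats.write_fasta(genome, p))
    emit("genome_truth.bed", lambda p: io_formats.write_bed6(
        [t.interval for t in genome_truth], p))
    emit("genome_annotations.out", lambda p: io_formats.write_repeatmasker_out(
        annotations, p))

    # --- stage 5: genome scan with the frozen selected model
    s_cfg = cfg["scan"]
    result = genome_scan.scan(
        sel.model_snapshot, genome,
        e_threshold=s_cfg["e_threshold"],
        chunk=s_cfg["chunk"], overlap=s_cfg["overlap"],
    )
    emit("scan_hits.tsv", lambda p: io_formats.write_hit_table(result.hits, p))
    emit("scan_hits.bed", lambda p: io_formats.write_bed6(
        [h.interval for h in result.hits], p,
        names=[f"hit{i}" for i in range(len(result.hits))],
        scores=[h.bit_score for h in result.hits]))

    # --- stage 6: overlap analytics
    o_cfg = cfg["overlap"]
    chrom_lens = {cid: len(s) for cid, s in genome}
    summary_rows = annotation_overlap.overlap_summary(
        [h.interval for h in result.hits], annotations,
        amount=o_cfg["amount"], stranded=o_cfg["stranded"],
        chrom_lens=chrom_lens)

    def write_overlap(p: Path) -> None:
        with open(p, "w") as fh:
            fh.write("variant\tn_overlapping\tn_total\n")
            for variant, n_over, n_tot in summary_rows:
                fh.write(f"{variant}\t{n_over}\t{n_tot}\n")

    emit("overlap_summary.tsv", write_overlap)

    genome_recovered = _n_recovered(result.hits, genome_truth)
    report = {
        "config": cfg,
        "n_seed_families": len(seed_search.families_with_hit(motif_hits)),
        "cycles": [
            {"cycle": r.cycle_index, "n_hits": r.n_hits,
             "n_families": r.n_families} for r in records],
        "selected_cycle": selected,
        "library_recall": recall,
        "library_fdr": fdr,
        "step1_recall": step1_recall,
        "mean_position_score": float(np.mean(scores)) if scores else None,
        "genome_n_hits": len(result.hits),
        "genome_n_truth": len(genome_truth),
        "genome_n_recovered": genome_recovered,
        "overlap_summary": summary_rows,
    }
    emit("report.json", lambda p: p.write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"))

    manifest = {"config": cfg, "files": files}
    (rundir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report


def _n_recovered(hits, truth_records) -> int:
    """Truth intervals overlapped by at least one same-strand hit."""
    n = 0
    for t in truth_records:
        iv = t.interval
        for h in hits:
            if (h.target_id == iv.seq_id and h.strand == iv.strand
                    and h.S - 1 < iv.end and iv.start < h.E):
                n += 1
                break
    return n
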