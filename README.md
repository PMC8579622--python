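# spretrace

Discovery of SPRE-like retroviral RNA elements in repeat consensus
libraries and genomes, as a tested, reusable Python pipeline.

The SPRE (syncytin post-transcriptional regulatory element) is a short
tripartite RNA element found near the 3' ends of endogenous retrovirus
(ERV) families: a 17-nt core motif, `5'-TCAGCAGGAAGCAGTTA-3'`, flanked by
two C-rich motifs. Searching for it directly is hopeless — 17 nt is too
short for sensitive homology search — so `spretrace` implements the
two-step strategy used to discover it:

1. **Seed:** exact-match the core motif over a repeat-family consensus
   library (both strands), and extract fixed 97-nt windows (40-nt 5' flank
   + 17-nt core + 40-nt 3' flank) anchored on each hit.
2. **Refine:** build a nucleotide profile HMM from the anchored windows,
   search the whole library, keep hits at E < 1e-5, realign them, rebuild,
   and repeat; adopt the cycle with the most hits.

Around that core the package provides genome scanning with a frozen model
(chunked, both strands, Gumbel-calibrated E-values), the downstream
analytics of the original analysis — the strand-aware relative position
score `[(S+E)/2]/L` that exposes the elements' 3'-terminal bias,
strand-aware 50-nt interval extension and stranded intersection against
RepeatMasker tracks, per-repeat tallies, LTR-class fractions, relative
synonymous codon frequencies — and a synthetic-data module that generates
libraries, genomes, annotations and decoys with known planted truth, so
every claim the pipeline makes is checked against ground truth.

The profile HMM is a Plan-7-style local model (match/insert/delete states,
local entry/exit, mask-and-rescan multi-hit); E-values come from a
maximum-likelihood Gumbel fit to best-per-sequence background scores,
`E(s) = N_eff (1 − exp(−exp(−λ(s − μ))))`. See `docs/methods.md` for the
full model description and design rationale.

For whom: computational biologists who want to rerun or adapt the
element-discovery analysis (other motifs, other libraries), and anyone who
needs a small, well-tested nucleotide profile-HMM search core with honest
E-value calibration.

## Worked example

```python
from spretrace import (anchor_align, extract_window, families_with_hit,
                       find_exact_motif, iterate, make_genome, make_library)
from spretrace.genome_scan import scan
from spretrace.iterative_search import positions_report
from spretrace.profile_hmm import background_from_seqs

# A synthetic library: 50 repeat families, 10 of them carrying a planted
# SPRE-like element at a 3'-biased position.
library, truth = make_library(seed=42)

hits = find_exact_motif(library)
print("step-1:", len(hits), "exact hits in",
      len(families_with_hit(hits)), "families")

fam = {f.family_id: f for f in library}
aln = anchor_align([extract_window(fam[h.family_id], h) for h in hits])
bg = background_from_seqs(f.consensus for f in library)
records, selected = iterate(aln, library, seed=42, background=bg)
for r in records:
    print(f"cycle {r.cycle_index}: {r.n_hits} hits in {r.n_families} families")
print("selected cycle:", selected)

sel = next(r for r in records if r.cycle_index == selected)
scores = [s for _, s in positions_report(sel, library)]
print("mean position score: %.3f" % (sum(scores) / len(scores)))

carriers = [f for f in library if f.family_id in {t.container_id for t in truth}]
genome, gtruth, anns = make_genome(carriers, truth, n_copies_per_family=2,
                                   genome_len=1_000_000, seed=43)
result = scan(sel.model_snapshot, genome, e_threshold=1e-5)
print("genome scan:", len(result.hits), "hits;", len(gtruth), "planted")
```

prints

```
step-1: 10 exact hits in 10 families
cycle 1: 10 hits in 10 families
cycle 2: 10 hits in 10 families
selected cycle: 1
mean position score: 0.758
genome scan: 20 hits; 20 planted
```

Step 1 finds exactly the 10 planted carriers; the refinement loop confirms
them, reaches a fixed point after two cycles and selects cycle 1 (earliest
peak). The mean relative position score of ~0.76 reflects the 3'-biased
placement the generator plants (Beta(5, 1.5), mean ≈ 0.77). The frozen
model then recovers all 20 diverged copies planted in a 1-Mb genome with
no false calls at E < 1e-5.

The same stages are available from the shell:

```bash
spretrace simulate library --seed 42 --out sim/
spretrace seed    --library sim/library.fa --out seedout/
spretrace iterate --library sim/library.fa --cycles 10 --evalue 1e-5 --out it/
spretrace scan    --model it/cycle1.hmm --targets genome.fa --tsv hits.tsv --bed hits.bed
spretrace overlap --hits hits.bed --annotations rm.out --extend 50 --out overlap.tsv
spretrace run-all --config config.json --out rundir/
```

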