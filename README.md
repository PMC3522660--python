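# mitopool

A desk-scale toolkit for **tag-free multiplex sequencing of complete
mitochondrial genomes**. Instead of ligating synthetic barcodes, divergent
specimens are pooled in a single sequencing run and their mitogenomes are
separated afterwards by sequence alone: the mitochondrial sequences act as
their own tags, because every pooled pair was chosen divergent enough that no
read-length stretch of the two genomes is identical. Assembled contigs are
then attributed to specimens by comparing them with reference markers (COI
and/or 12S/16S/CYTB) in a reference database.

The package is aimed at molecular systematists and biodiversity labs planning
such runs: it answers *which specimens may share a run*, *how many genomes a
run can yield at what cost*, and *whether the pooled data would assemble and
demultiplex*, the last question via in-silico simulation.

## What it computes

- **Divergence screening** (`divergence`). For a pair of genomes linearized
  at the COI start, the p-distance (fraction of differing sites among
  comparable, gap-free sites) is computed on the Folmer COI fragment
  (positions 50–700 of the gene, 651 bp — the standard animal barcode) as a
  cheap proxy, and along the whole alignment in sliding windows of 150 bp
  (step 15) or 450 bp (step 45), matching short- and long-read platforms.
  Windows where fewer than half the columns are comparable (typically a long
  deletion in one genome) are flagged `low_info` rather than reported as
  spuriously zero divergence.
- **Pool design** (`pool_design`). A pair is compatible when its COI proxy is
  ≥ 15%, or — preferred when a window profile exists — when no 450 bp window
  falls below 5% divergence. The largest feasible pool is a maximum clique of
  the compatibility graph (exact up to 25 specimens); a full sample set is
  split into fewest runs by DSATUR colouring of the incompatibility graph.
- **Run capacity** (`pool_design.run_capacity`). With genome length `G`
  (default 17,000 bp), enrichment mito-fraction `f` (default 0.5), platform
  throughput `T` and coverage `c`:
  `genomes/run = round(T·f / (G·c))`, `cost/genome = run cost / (T·f/(G·c))`.
- **Read simulation** (`read_sim`). Reads are drawn uniformly from the
  *circle* (origin-spanning reads included, full truth tracking per read):
  per-base substitution error 0.02, one mutated haplotype per genome per run
  (site mutation rate 0.001, 1/10 indels, geometric extension 0.3), random
  contamination reads with probability 0.05, single- or paired-end, uniform
  coverage or a 10× + 2× per-genome ladder. Exact circular tilings are also
  available for assembler baselines.
- **Baseline assembly** (`assembly_baseline`). A deterministic canonical
  de Bruijn unitig assembler (k = 31) with abundance pruning; isolated simple
  cycles — fully reconstructed circular genomes — are emitted with a circular
  flag. Externally assembled contig FASTA is accepted for evaluation too.
- **Demultiplexing and evaluation** (`demux_eval`). Contigs are scored
  against each taxon by canonical 15-mer containment in its reference
  markers, assigned when the best score clears 0.2 and doubles the runner-up;
  in simulations contigs are mapped back to truth genomes (wrap-aware, edit
  distance identity), chimeras are flagged, and per-genome best-contig
  overlap fractions are summarised against each genome's own length or a
  fixed 16,400 bp average.
- **Synthetic families** (`synthetic_family`). Annotated ~15.6 kb circular
  mitogenomes (13 protein-coding genes with COI first, 2 rRNAs, 22 tRNAs,
  control region) evolved from a random ancestor on a star phylogeny with
  exact per-region substitution counts, so every pipeline stage is testable
  without downloads.

## Worked example

```python
import mitopool as mp

genomes, truth = mp.make_family(mp.FamilySpec(n_taxa=4, target_divergence=0.12, seed=7))
print(truth[["idA", "idB", "folmer_proxy"]].to_string(index=False))

matrix = mp.build_compatibility(genomes, mp.CompatPolicy(mode="proxy_only"))
pool = mp.max_pool(matrix)
print("pool:", pool.members, "min pairwise divergence:", round(pool.min_pairwise, 3))

cap = mp.run_capacity(mp.RunSpec(throughput_bp=35e6, run_cost=1100, coverage=20))
print(f"454 GS Junior at 20x: {cap.genomes_per_run} genomes/run, ${cap.cost_per_genome}/genome")

reads = mp.simulate_pool(genomes, mp.CoveragePlan.uniform(40), read_length=150,
                         model=mp.ErrorModel(), seed=7)
contigs = [c for c in mp.assemble(reads, k=31) if len(c) >= 100]
report = mp.assign_contigs(contigs, mp.ReferenceDB.from_genomes(genomes))
placements = mp.map_contigs_to_truth(contigs, genomes)
by_pl = {p.contig_id: p for p in placements}
n_ok = sum(1 for a in report.assigned()
           if a.contig_id in by_pl and by_pl[a.contig_id].genome == a.best_taxon)
print(f"assigned contigs: {len(report.assigned())}, correctly demultiplexed: {n_ok}")
summary = mp.overlap_summary(placements, genomes)
for gid, go in sorted(summary.per_genome.items()):
    print(f"{gid}: best contig covers {go.best_fraction:.1%} "
          f"({go.covered_fraction:.1%} total)")
```

Output:

```
    idA     idB  folmer_proxy
taxon01 taxon02      0.238095
taxon01 taxon03      0.239631
taxon01 taxon04      0.222734
taxon02 taxon03      0.248848
taxon02 taxon04      0.242704
taxon03 taxon04      0.233487
pool: ['taxon01', 'taxon02', 'taxon03', 'taxon04'] min pairwise divergence: 0.223
454 GS Junior at 20x: 51 genomes/run, $21.37/genome
assigned contigs: 4, correctly demultiplexed: 4
taxon01: best contig covers 25.8% (96.1% total)
taxon02: best contig covers 54.3% (95.3% total)
taxon03: best contig covers 60.7% (95.3% total)
taxon04: best contig covers 54.6% (96.6% total)
```

All four specimens clear the 15% COI rule (proxies 0.22–0.25), so one pooled
run suffices; at 40× with 2% sequencing error each genome is ~95% covered by
contigs that demultiplex to the right specimen with no cross-assignments.
The best *single* contig spans 26–61% of each genome: the strict unitig
assembler breaks at every k-mer shared between pool members (conserved rRNA
and tRNA stretches), which is the expected behaviour of a baseline without
graph cleaning — see `docs/methods.md`.

A `mitopool` command-line interface wraps the same operations
(`mitopool synth`, `proxy`, `windows`, `plan`, `capacity`, `simulate`,
`assemble`, `demux`, `evaluate`); run `mitopool --help`.

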