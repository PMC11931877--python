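# glycochrom

Tools for analysing the genomic occupancy of O-GlcNAc-modified proteins
(and, generally, any CUT&RUN/ChIP-seq peak set) in relation to chromatin
state, co-bound factors, and gene expression.

O-GlcNAc is a single-sugar modification of nuclear and cytosolic proteins;
profiling it genome-wide (e.g. with a pan-O-GlcNAc CUT&RUN assay) yields a
peak set whose interpretation requires answering four questions this package
implements as a reproducible pipeline:

1. **Where do the peaks sit in chromatin?**  Seven functional genomic
   compartments are built by fixed rules from histone-mark / factor peak
   sets and gene anchors — active promoters (H3K27ac peaks overlapping
   TSS ± 1 kb), transcription initiation (TSS ± 1 kb windows overlapping
   Ser5-phosphorylated RNA Pol II peaks), heterochromatin (H3K9me3 peaks),
   bivalent promoters (TSS windows carrying both H3K4me3 and H3K27me3),
   Polycomb domains (base-pair intersections of Suz12 and RING1B peaks),
   transcription elongation (Ser2P peaks over the gene body from TSS + 1 kb
   to the TES), and transcription termination (the 50 bp downstream of each
   TES).  Query peaks are classified with multi-membership and summarised
   as upset-style exclusive-combination counts plus marginal totals.
2. **Which factors co-occupy the same promoters?**  For a library of
   reference peak sets, the screen reports the percentage of
   promoter-restricted query peaks hit by each reference, ranked, with
   per-reference fold changes between two conditions.
3. **How does occupancy change after a perturbation?**  Fragment intervals
   are converted to 1×-normalised coverage (RPGC: mean coverage over the
   effective genome is exactly 1), extracted into peak-centred or
   scaled-gene signal matrices, clustered with k-means (default k = 5), and
   each cluster is called gain / loss / unchanged from the log2 ratio of
   its after/before mean signal.
4. **Is occupancy linked to expression?**  Promoters are stratified by peak
   occupancy into n-matched groups (occupied / unoccupied / random) and
   compared with a two-sided Mann–Whitney–Wilcoxon test; externally
   computed differential-expression tables are intersected with peaks to
   call direct targets.

A synthetic-data module generates toy genomes, mark constellations, query
peaks, fragment sets and expression tables with planted ground truth, so the
entire pipeline is testable without any sequencing data.

## Worked example

```python
from glycochrom import (CompartmentRules, build_compartments,
                        classify_peaks, upset_table)
from glycochrom.simulate import (SimulationConfig, simulate_genome_and_genes,
                                 simulate_compartment_marks, simulate_query_peaks)

cfg = SimulationConfig(seed=1)
genome, genes = simulate_genome_and_genes(cfg)
marks, planted = simulate_compartment_marks(cfg, genes, genome)
query, truth = simulate_query_peaks(cfg, planted, genome)

cmap = build_compartments(CompartmentRules(marks=marks, genes=genes, genome=genome))
combos, singles = upset_table(classify_peaks(query, cmap))
print(singles.to_string(index=False))
```

prints

```
             compartment  count
          ActivePromoter     40
 TranscriptionInitiation     30
         Heterochromatin     24
        BivalentPromoter     20
                Polycomb     20
 TranscriptionElongation     16
TranscriptionTermination     10
```

i.e. of the 200 synthetic query peaks, 40 fall in active promoters, 30 at
initiation windows, and so on; the remaining 40 peaks overlap no compartment
and are reported as `unassigned` in the exclusive-combination table.  On
this noise-free fixture every peak recovers exactly its planted compartment.

The same analyses are available from the shell:

```sh
glycochrom simulate --seed 1 --out fixture/
glycochrom compartments --marks-dir fixture/ --genes fixture/genes.tsv \
    --query fixture/query.bed --out comp/
glycochrom run-all --out run/ --seed 1     # full pipeline + report.json
```

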