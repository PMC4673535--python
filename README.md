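# mirtarnet

Inference of miRNA–mRNA inverse-expression regulatory networks from pooled
4-group microarray profiles of intestinal epithelial cells (IECs), as used
to contrast normal and colitis-inflamed small- and large-intestinal
epithelium in the mouse DSS (dextran sodium sulfate) colitis model.

## Who this is for

Groups profiling sorted epithelial cells on single pooled arrays per
condition — one miRNA chip (~1,900 probes) and one mRNA chip (~24,000
probes) for each of four groups (normal small-IEC, normal large-IEC,
inflamed small-IEC, inflamed large-IEC) — who want a reproducible,
scriptable version of the classic threshold-based integration analysis:

1. **Dual-threshold differential filter.** With no replicates, a probe is
   called differential when its fold change exceeds 2 (|log₂ FC| > 1) and
   the higher-expressed side exceeds 100 background-subtracted fluorescence
   units; a stricter "high tier" raises the intensity gate to 10,000 units.
2. **Presence calls and four-way Venn partition.** A probe is "expressed"
   in a group when its intensity strictly exceeds the pooled median of all
   four arrays of the channel; the four expressed sets are partitioned into
   the 15 Venn regions with tissue-exclusive and group-unique summaries.
3. **Target prediction.** Either ingest a precomputed miRNA→gene
   association table, or scan 3′UTRs for canonical seed sites (seed =
   mature miRNA nucleotides 2–8; site types ranked
   8mer > 7mer-m8 > 7mer-A1 > 6mer).
4. **Inverse-expression network.** A bipartite graph links each
   differential miRNA to associated target genes that moved in the
   *opposite* direction in the same cells (up-miRNA→down-gene, and the
   symmetric down-miRNA→up-gene network); edges are classified as
   single-to-single / single-to-multiple / multiple-to-single /
   multiple-to-multiple by endpoint degrees.
5. **Pathway enrichment.** One-sided hypergeometric tests against a
   configurable gene universe with Benjamini–Hochberg FDR control; a
   pathway is reported when q ≤ α and more than two query genes fall in it.

A synthetic-data generator reproduces the study design — log-normal
baseline intensities (median ≈ 500 units, log₂ SD 1.0) above a background
floor, planted group-specific differential expression, and planted
miRNA→target repression links — so the whole chain can be validated by
parameter recovery against known ground truth. Transcriptions of the
printed per-tissue intensity and fold-change tables are packaged as TSV
fixtures for desk-scale checks.

## Worked example

```python
from mirtarnet import (
    ArrayDesign, TruthConfig, generate_dataset,
    differential_table, apply_main_filter,
    build_inverse_network, classify_modes,
)

design = ArrayDesign()                 # 1,900 miRNA / 24,000 mRNA probes
truth_cfg = TruthConfig()              # 51 up / 15 down miRNAs, 166 up / 225 down mRNAs
mirna, mrna, truth = generate_dataset(design, truth_cfg, seed=3)

pair = ("normal_large", "inflamed_large")
mir_de = apply_main_filter(differential_table(mirna, *pair))
gene_de = apply_main_filter(differential_table(mrna, *pair))
print((mir_de.direction == "up").sum(), (mir_de.direction == "down").sum())

net = build_inverse_network(
    mir_de, gene_de, truth.repression_links | truth.decoy_associations
)
print(classify_modes(net).as_dict())
```

prints

```
51 16
{'n_mirnas': 27, 'n_genes': 82, 'n_edges': 164, 'mode_single-to-single': 0,
 'mode_single-to-multiple': 26, 'mode_multiple-to-single': 0,
 'mode_multiple-to-multiple': 138}
```

— all 51 planted up- and 15 planted down-regulated miRNAs pass the
dual-threshold filter (plus one noise-driven false positive in the down
list), and the inverse-expression network recovers the planted 27-miRNA
repression module (82 of its 83 target genes survive the mRNA filter at
this seed), dominated by multiple-to-multiple regulation.

The same pipeline is scriptable end to end:

```sh
mirtarnet run-all --seed 3 --outdir out/   # full report bundle + manifest.json
mirtarnet simulate --seed 3 --outdir sim/  # just the synthetic dataset
mirtarnet predict-targets --mirna-fasta mirnas.fa --utr-fasta utrs.fa --out sites.tsv
```

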