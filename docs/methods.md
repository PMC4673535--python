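# Methods

## The analysis model

The package implements a threshold-based integration of miRNA and mRNA
microarray profiles from a pooled experimental design: four sample groups
(normal small-IEC, normal large-IEC, inflamed small-IEC, inflamed
large-IEC), one array per group and channel, with background-subtracted
fluorescence intensities in arbitrary units. Pooling RNA from 8–10
animals per group removes biological replication, so no per-probe
hypothesis test is possible on the arrays themselves; differential calls
rest on dual thresholds, and the statistical machinery (t-test, ΔΔCt) is
reserved for replicated follow-up measurements such as qPCR.

### Differential filters

For a comparison of groups *a* (reference) and *b*, each probe gets
`log2_fc = log2(max(b, floor) / max(a, floor))` with a clamp floor
(default 1 unit) that keeps background-level spots from producing
infinite ratios. The **main filter** keeps probes with |log₂ FC| > 1 and
peak intensity > 100 units; the **high tier** raises the intensity gate
to 10,000 units. Three deliberate numerical choices:

* **All comparisons are strict** (`>`, not `≥`). The printed source
  tables are consistent with either reading at the 2-fold boundary, but
  their extreme retained entries (smallest retained |log₂ FC| 1.006,
  smallest retained intensity 112) sit strictly above the thresholds, so
  the strict form is used throughout, including the pooled-median
  presence rule.
* **The intensity gate applies to the higher-expressed side** of the
  comparison. A strongly down-regulated probe is gated on its reference
  intensity: what matters is that the *expressed* state was reliably
  above background.
* **High tier ⊂ main filter** by construction; the suite asserts this
  nesting and the monotonicity of both filters in their thresholds.

When the printed intensity tables are re-filtered, only the intensity
gate is re-applied (`fixture_high_tier`): membership in those tables
already certifies the fold criterion, and the reference-side intensities
were not printed.

### Presence calls and Venn partition

A single pooled median is computed over the valid intensities of **all
four arrays** of a channel; a probe is "expressed" in a group when its
spot is valid and its intensity strictly exceeds that median. This makes
presence calls invariant under any uniform rescaling of all arrays. The
four expressed sets are partitioned exactly into the 15 non-empty
membership signatures; tissue-exclusive and group-unique counts are
derived sums of regions, never recomputed independently.

### Target prediction

The seed is mature-miRNA nucleotides 2–8. On the UTR sense strand a site
is anchored by the 6-nt reverse complement of positions 2–7 (the core);
the base 5′ of the core may pair with miRNA position 8, and the base 3′
of the core may be the A across from position 1. Each core occurrence is
classified once, by the highest type its flanks support:
8mer (m8 match + A) > 7mer-m8 (m8 match) > 7mer-A1 (A only) > 6mer.
The A1 anchor requires a literal A in the UTR regardless of the miRNA's
first base, the standard canonical-site convention. Coordinates are
0-based half-open; DNA and RNA inputs are equivalent. No 3′-supplementary
pairing, context scoring or conservation filtering is attempted — the
scanner's role is to supply putative associations when no precomputed
association table is available, and both sources feed the network stage
through the same table schema.

### Network assembly and modes

An edge (m, g) exists when miRNA m passed the main filter in one
direction, gene g passed it in the opposite direction in the same
comparison, and (m, g) is in the association table. Every edge therefore
satisfies sign(log₂ FC_miRNA) × sign(log₂ FC_gene) = −1, asserted as an
invariant. Connectivity modes are classified **per edge** from endpoint
degrees (single-to-single, single-to-multiple = one miRNA with several
targets, multiple-to-single = several miRNAs onto one gene,
multiple-to-multiple); the source material names the four modes without
an operational definition, and the per-edge reading makes the counts sum
to the edge total. Genes measured by several probes are collapsed to the
probe with the largest |log₂ FC|, with the conflict logged.
Target-set uniqueness between two tissues is 100·|A∖B|/|A|, rounded
half-up to one decimal.

### Enrichment

One-sided hypergeometric upper-tail p-values (query of size N against a
pathway of size n in a universe of M genes), BH-adjusted across all
tested pathways. The universe defaults to all genes on the mRNA array
(~24,000) and is configurable. A pathway is *reported* when q ≤ α
(default 0.05) **and** more than two query genes overlap it (overlap ≥ 3).
The original analysis used a web service that names neither its test nor
its correction; the hypergeometric + BH combination is the standard,
exactly reproducible equivalent. Because the exact tail of a discrete
test is super-uniform, the null-calibration test checks uniformity on the
randomized p-value u = P(X>k) + U·P(X=k) and separately checks the raw
p-values are not anti-conservative.

## The synthetic-data generator

`generate_dataset` emulates the study conditions: per-probe baseline
log₂ intensities Normal(log₂ 500, 1.0) — matching the 100–43,000-unit
spread of the printed intensity lists — independent per-array measurement
noise (SD 0.2 log₂ units), intensities floored at the background level,
and one array per group. Differential expression is planted between one
group pair (default normal_large → inflamed_large) with effect ±3.0 log₂
units; default planted counts mirror that comparison's printed scale
(51 up / 15 down miRNAs, 166 up / 225 down mRNAs, and a 27-miRNA →
83-gene repression module in which each linked gene's downshift is its
strongest regulator's shift times a repression factor, default 1.0).
200 decoy association rows with no planted signal make network precision
a meaningful quantity. Identical seeds give bit-identical matrices.

What the generator does **not** model: hybridization chemistry, dye or
spot effects, probe-specific affinity, correlated noise across probes,
and partial (sub-proportional) repression. Passing recovery tests
therefore show that the inference chain is correct *given* the threshold
model's assumptions, not that the thresholds are optimal for real arrays.

`generate_sequences` plants seed sites verbatim into uniform-composition
random UTRs, forces the flanking bases so each planted site scans as
exactly its requested type, and regenerates a UTR (never silently
accepts it) if the background happens to contain an extra seed core of
any planted miRNA.

## Problem sizes in the tests and acceptance script

Oracle-equivalence tests run on instances up to ~10³ elements
(associations, probes, UTR windows), where brute-force enumeration is
exact and fast. Recovery benchmarks use the full 1,900-probe miRNA
design with a 6,000-probe mRNA channel over 20 seeds — the mRNA channel
is down-sampled from 24,000 because the planted mRNA signal (80 up / 120
down in the benchmark) and the recovery statistics are unaffected by
additional null probes, while generation time scales linearly in them.
The acceptance script's enrichment check uses the full 24,000-gene
universe with a 100-pathway collection.

## Known limitations

* The per-edge mode classification is one defensible reading of the
  four-mode vocabulary; a per-component alternative would label star
  components as wholes and give different counts.
* With a single array per group, the zero-signal configuration still
  yields occasional noise-driven filter survivors (|N(0, 0.2√2)| > 1 has
  probability ≈ 4·10⁻⁴ per probe); tests treat these as expected false
  positives, not failures.
* The packaged printed-table fixtures inherit the source tables'
  typography; underline styling did not survive into the transcription,
  so style-based category claims are reported from computed list
  membership instead.
* The enrichment universe matters: restricting it to expressed genes
  rather than the whole chip typically weakens apparent enrichment; the
  default (whole chip) is the more conservative choice for small query
  sets only when pathways are chip-wide, and is configurable for that
  reason.
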