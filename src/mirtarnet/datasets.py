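"""Synthetic microarray datasets with known ground truth, and packaged
transcriptions of the printed intensity / fold-change tables.

The real experiment pooled RNA from 8-10 mice per group onto a single
array per group, for four groups (normal small-IEC, normal large-IEC,
inflamed small-IEC, inflamed large-IEC), on ~1,900-probe miRNA and
~24,000-probe mRNA chips.  The raw arrays were never deposited, so two
kinds of data stand in for them here:

* a generator producing 4-group miRNA/mRNA intensity matrices with planted
  differential expression and planted miRNA->mRNA repression links, plus
  the ground truth needed for recovery tests;
* TSV fixtures transcribed from the printed tables: the per-tissue
  highly-expressed miRNA lists with fluorescence intensities (four
  sections) and the inflamed-vs-normal log2 fold-change lists (two
  tissues), each entry carrying the typographic style flag it was printed
  with.

Baseline intensities are log-normal with median ~500 arbitrary units and a
spread of 1.0 on the log2 scale, floored at the background level --
matching the 100-43,187-unit range of the printed intensity lists.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix
from .names import normalize_all

GROUPS = ("normal_small", "normal_large", "inflamed_small", "inflamed_large")

FIXTURE_IDS = (
    "table1_section1",  # increased in normal small-IECs (vs normal large)
    "table1_section2",  # increased in normal large-IECs (vs normal small)
    "table1_section3",  # increased in inflamed small-IECs (vs inflamed large)
    "table1_section4",  # increased in inflamed large-IECs (vs inflamed small)
    "table2_small",     # inflamed vs normal small-IECs, log2 fold change
    "table2_large",     # inflamed vs normal large-IECs, log2 fold change
)


@dataclass(frozen=True)
class ArrayDesign:
    """Chip layout of the pooled 4-group design."""

    group_names: tuple[str, ...] = GROUPS
    n_mirna_probes: int = 1900
    n_mrna_probes: int = 24000
    background_floor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.group_names) != 4:
            raise ValueError("the design has exactly four groups")
        if len(set(self.group_names)) != 4:
            raise ValueError("group names must be unique")
        if self.n_mirna_probes <= 0 or self.n_mrna_probes <= 0:
            raise ValueError("probe counts must be positive")
        if self.background_floor < 0:
            raise ValueError("background floor must be non-negative")


@dataclass(frozen=True)
class TruthConfig:
    """Parameters of the planted signal.

    Differential expression is planted between one reference/perturbed
    group pair; repression links tie a subset of the up-regulated miRNAs to
    a subset of the down-regulated mRNAs (the gene's downshift is the
    miRNA's shift scaled by ``repression_factor``).  Defaults mirror the
    inflamed-vs-normal large-IEC comparison: 51 up / 15 down miRNAs, 166 up
    / 225 down mRNAs, and a 27-miRNA -> 83-gene repression network.
    """

    pair: tuple[str, str] = ("normal_large", "inflamed_large")
    n_up_mirna: int = 51
    n_down_mirna: int = 15
    n_up_mrna: int = 166
    n_down_mrna: int = 225
    n_linked_mirna: int = 27
    n_linked_genes: int = 83
    n_decoy_associations: int = 200
    effect_size_log2: float = 3.0
    noise_sd_log2: float = 0.2
    repression_factor: float = 1.0
    baseline_median: float = 500.0
    baseline_sd_log2: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_size_log2 < 0:
            raise ValueError("effect size must be non-negative")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_linked_mirna > self.n_up_mirna:
            raise ValueError("linked miRNAs must come from the up-regulated set")
        if self.n_linked_genes > self.n_down_mrna:
            raise ValueError("linked genes must come from the down-regulated set")
        for n in (self.n_up_mirna, self.n_down_mirna, self.n_up_mrna, self.n_down_mrna):
            if n < 0:
                raise ValueError("planted counts must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset.

    ``de_up``/``de_down`` map a group pair to the probe ids planted up or
    down in the perturbed group (miRNA and mRNA probe ids share the maps;
    their namespaces are disjoint).  ``repression_links`` are the planted
    (mirna_id, gene_id) pairs; ``decoy_associations`` are additional
    association-table rows with no planted signal behind them.
    """

    de_up: dict[tuple[str, str], set[str]]
    de_down: dict[tuple[str, str], set[str]]
    repression_links: set[tuple[str, str]]
    decoy_associations: set[tuple[str, str]]
    effect_size_log2: float
    noise_sd_log2: float
    seed: int


def generate_dataset(
    design: ArrayDesign = ArrayDesign(),
    config: TruthConfig = TruthConfig(),
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Simulate one pooled 4-group miRNA/mRNA dataset with planted signal.

    Returns the two expression matrices and the :class:`SyntheticTruth`
    describing what was planted.  Identical seeds give bit-identical
    output.
    """
    ref, test = config.pair
    for g in config.pair:
        if g not in design.group_names:
            raise ValueError(f"unknown group {g!r} in pair")
    if config.n_up_mirna + config.n_down_mirna > design.n_mirna_probes:
        raise ValueError("more planted miRNA DE probes than miRNA probes")
    if config.n_up_mrna + config.n_down_mrna > design.n_mrna_probes:
        raise ValueError("more planted mRNA DE probes than mRNA probes")

    rng = np.random.default_rng(seed)
    mirna_ids = [f"mir-{i:04d}" for i in range(design.n_mirna_probes)]
    gene_ids = [f"gene-{i:05d}" for i in range(design.n_mrna_probes)]

    mir_perm = rng.permutation(design.n_mirna_probes)
    up_mir = [mirna_ids[i] for i in mir_perm[: config.n_up_mirna]]
    down_mir = [
        mirna_ids[i]
        for i in mir_perm[config.n_up_mirna : config.n_up_mirna + config.n_down_mirna]
    ]
    gene_perm = rng.permutation(design.n_mrna_probes)
    up_genes = [gene_ids[i] for i in gene_perm[: config.n_up_mrna]]
    down_genes = [
        gene_ids[i]
        for i in gene_perm[config.n_up_mrna : config.n_up_mrna + config.n_down_mrna]
    ]

    # Repression links: every linked miRNA regulates >=1 linked gene and
    # every linked gene is hit by >=1 linked miRNA.
    linked_mir = up_mir[: config.n_linked_mirna]
    linked_genes = down_genes[: config.n_linked_genes]
    links: set[tuple[str, str]] = set()
    if linked_mir and linked_genes:
        for j, g in enumerate(linked_genes):
            links.add((linked_mir[j % len(linked_mir)], g))
        extra = rng.integers(0, 3, size=len(linked_genes))
        for j, g in enumerate(linked_genes):
            k = min(int(extra[j]), len(linked_mir))
            for m in rng.choice(linked_mir, size=k, replace=False):
                links.add((str(m), g))

    # Decoy association rows referencing probes with no planted relation.
    decoys: set[tuple[str, str]] = set()
    if config.n_decoy_associations:
        dm = rng.choice(mirna_ids, size=config.n_decoy_associations)
        dg = rng.choice(gene_ids, size=config.n_decoy_associations)
        decoys = {(str(m), str(g)) for m, g in zip(dm, dg)} - links

    e = config.effect_size_log2
    mir_shift = np.zeros(design.n_mirna_probes)
    mir_pos = {p: i for i, p in enumerate(mirna_ids)}
    for p in up_mir:
        mir_shift[mir_pos[p]] = e
    for p in down_mir:
        mir_shift[mir_pos[p]] = -e

    gene_shift = np.zeros(design.n_mrna_probes)
    gene_pos = {p: i for i, p in enumerate(gene_ids)}
    for p in up_genes:
        gene_shift[gene_pos[p]] = e
    for p in down_genes:
        gene_shift[gene_pos[p]] = -e
    # Linked genes shift in proportion to their strongest regulator's shift.
    for m, g in links:
        gene_shift[gene_pos[g]] = min(
            gene_shift[gene_pos[g]], -config.repression_factor * mir_shift[mir_pos[m]]
        )

    def build(ids, shift, n, channel):
        log2_base = np.log2(config.baseline_median) + rng.normal(0.0, cfg_sd, size=n)
        cols = {}
        for g in design.group_names:
            x = log2_base + rng.normal(0.0, config.noise_sd_log2, size=n)
            if g == test:
                x = x + shift
            cols[g] = np.maximum(np.exp2(x), design.background_floor)
        return ExpressionMatrix(pd.DataFrame(cols, index=ids), channel=channel)

    cfg_sd = config.baseline_sd_log2
    mirna = build(mirna_ids, mir_shift, design.n_mirna_probes, "miRNA")
    mrna = build(gene_ids, gene_shift, design.n_mrna_probes, "mRNA")

    truth = SyntheticTruth(
        de_up={config.pair: set(up_mir) | set(up_genes)},
        de_down={config.pair: set(down_mir) | set(down_genes)},
        repression_links=links,
        decoy_associations=decoys,
        effect_size_log2=e,
        noise_sd_log2=config.noise_sd_log2,
        seed=seed,
    )
    return mirna, mrna, truth


# ---------------------------------------------------------------------------
# Packaged fixtures

@dataclass
class FixtureTable:
    """One transcribed printed table section."""

    table_id: str
    records: pd.DataFrame  # columns: mirna, value, style
    kind: str = field(init=False)  # "intensity" or "log2_fc"

    def __post_init__(self) -> None:
        self.kind = "intensity" if self.table_id.startswith("table1") else "log2_fc"

    @property
    def names(self) -> list[str]:
        return list(self.records["mirna"])

    @property
    def values(self) -> pd.Series:
        return self.records.set_index("mirna")["value"]


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("mirtarnet.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_fixture(table_id: str) -> FixtureTable:
    """Load one printed-table transcription by id.

    Valid ids: ``table1_section1`` .. ``table1_section4`` (per-tissue
    highly-expressed lists, fluorescence intensities) and ``table2_small``
    / ``table2_large`` (inflamed-vs-normal log2 fold changes).  Names are
    normalized; values in the intensity sections are positive.
    """
    if table_id not in FIXTURE_IDS:
        raise KeyError(f"unknown fixture {table_id!r}; valid ids: {FIXTURE_IDS}")
    df = _read_packaged_tsv(f"{table_id}.tsv")
    if list(df.columns) != ["mirna", "value", "style"]:
        raise ValueError(f"malformed fixture {table_id}")
    df = df.copy()
    df["mirna"] = normalize_all(df["mirna"])
    if df["mirna"].duplicated().any():
        raise ValueError(f"duplicate miRNA names in {table_id}")
    if table_id.startswith("table1") and (df["value"] <= 0).any():
        raise ValueError("intensity fixture with non-positive value")
    return FixtureTable(table_id=table_id, records=df)


def fixture_high_tier(table: FixtureTable, threshold: float = 10_000.0) -> list[str]:
    """Names in an intensity fixture passing the high-tier intensity gate.

    Entries of the printed intensity tables satisfy the fold criterion by
    construction (only probes with a >2-fold difference were listed), so the
    stricter tier re-applies just the fluorescence-intensity gate, strictly.
    """
    if table.kind != "intensity":
        raise ValueError("high tier applies to intensity tables")
    rec = table.records
    return list(rec.loc[rec["value"] > threshold, "mirna"])


def load_mir223_targets(tissue: str) -> pd.DataFrame:
    """Printed putative miR-223-3p target lists for inflamed IECs.

    ``large`` carries the 8 printed gene names plus one placeholder row
    flagged ``unresolved`` (the text counts 9 targets but prints 8 names).
    ``small`` is a synthetic stand-in: only the list size (13) and the one
    gene shared with the large-IEC list (SLC4A4) are printed; the other 12
    rows are placeholders flagged ``synthetic``.
    """
    if tissue not in ("small", "large"):
        raise KeyError(f"unknown tissue {tissue!r}")
    name = (
        "mir223_targets_large.tsv"
        if tissue == "large"
        else "mir223_targets_small_synthetic.tsv"
    )
    return _read_packaged_tsv(name)


def load_fig2_counts() -> pd.DataFrame:
    """Printed per-tissue up/down mRNA counts and chip size."""
    return _read_packaged_tsv("fig2_counts.tsv")


# ---------------------------------------------------------------------------
# Synthetic sequences with planted seed sites

_COMP = str.maketrans("ACGU", "UGCA")
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _revcomp(rna: str) -> str:
    return rna.translate(_COMP)[::-1]


def _site_pattern(mature: str, site_type: str) -> tuple[str, bool, bool]:
    """UTR-sense site string for a seed, plus which flanks it constrains.

    Returns (core-or-full site string written into the UTR, needs_m8,
    needs_a1).  The written string always includes whatever the type
    requires; flanks the type forbids are handled by the caller.
    """
    seed27 = mature[1:7]  # positions 2-7
    m8 = mature[7]  # position 8
    core = _revcomp(seed27)  # 6-nt core on the UTR sense strand
    comp_m8 = m8.translate(_COMP)
    if site_type == "8mer":
        return comp_m8 + core + "A", True, True
    if site_type == "7mer-m8":
        return comp_m8 + core, True, False
    if site_type == "7mer-A1":
        return core + "A", False, True
    if site_type == "6mer":
        return core, False, False
    raise ValueError(f"unknown site type {site_type!r}")


def _non(rng, forbidden: str) -> str:
    choices = [c for c in "ACGU" if c != forbidden]
    return str(rng.choice(choices))


def generate_sequences(
    n_mirna: int,
    n_utr: int,
    planted_sites,
    seed: int = 0,
    *,
    mirna_length: int = 22,
    utr_length: int = 300,
    max_attempts: int = 100,
):
    """Random mature miRNAs and 3'UTRs with seed sites planted verbatim.

    ``planted_sites`` is a list of ``(mirna_index, utr_index, site_type)``
    with ``site_type`` in ``{"8mer", "7mer-m8", "7mer-A1", "6mer"}``.  The
    background is uniform over A/C/G/U; each UTR is regenerated until it
    contains no accidental seed-core match for any planted miRNA besides
    the manifest sites, and the flanks of each planted site are forced so
    the site scans as exactly its requested type.  Returns
    ``(mirna_records, utr_records, manifest)`` with Biopython SeqRecords
    and a manifest DataFrame of 0-based half-open coordinates.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    matures = ["".join(rng.choice(alphabet, size=mirna_length)) for _ in range(n_mirna)]

    for mi, ui, st in planted_sites:
        if not (0 <= mi < n_mirna and 0 <= ui < n_utr):
            raise IndexError("planted site index out of range")
        if st not in SITE_TYPES:
            raise ValueError(f"unknown site type {st!r}")

    by_utr: dict[int, list[tuple[int, str]]] = {}
    for mi, ui, st in planted_sites:
        by_utr.setdefault(ui, []).append((mi, st))

    planted_mirnas = sorted({mi for mi, _, _ in planted_sites})
    cores = {mi: _revcomp(matures[mi][1:7]) for mi in planted_mirnas}

    utrs: list[str] = []
    manifest_rows = []
    for ui in range(n_utr):
        sites = by_utr.get(ui, [])
        for attempt in range(max_attempts):
            utr = list(rng.choice(alphabet, size=utr_length))
            placements = []
            ok = True
            taken: list[tuple[int, int]] = []
            for mi, st in sites:
                site, needs_m8, needs_a1 = _site_pattern(matures[mi], st)
                # reserve one spare base on each side for flank control
                lo, hi = 1, utr_length - len(site) - 1
                if hi <= lo:
                    raise ValueError("UTR too short for the requested site")
                for _ in range(max_attempts):
                    start = int(rng.integers(lo, hi))
                    span = (start - 1, start + len(site) + 1)
                    if all(span[1] <= a or span[0] >= b for a, b in taken):
                        break
                else:
                    ok = False
                    break
                taken.append(span)
                utr[start : start + len(site)] = list(site)
                comp_m8 = matures[mi][7].translate(_COMP)
                if not needs_m8:  # forbid an upgrade via the m8 flank
                    utr[start - 1] = _non(rng, comp_m8)
                if not needs_a1:  # forbid an upgrade via the A1 flank
                    utr[start + len(site)] = _non(rng, "A")
                core_start = start + (1 if needs_m8 else 0)
                site_start = start
                site_end = start + len(site)
                placements.append((mi, st, site_start, site_end, core_start))
            if not ok:
                continue
            text = "".join(utr)
            # reject accidental cores of any planted miRNA outside the manifest
            clean = True
            expected = {(mi, cs) for mi, _, _, _, cs in placements}
            for mi in planted_mirnas:
                core = cores[mi]
                pos = text.find(core)
                while pos != -1:
                    if (mi, pos) not in expected:
                        clean = False
                        break
                    pos = text.find(core, pos + 1)
                if not clean:
                    break
            if clean:
                break
        else:
            raise RuntimeError(f"could not place sites in UTR {ui} without collisions")
        utrs.append(text)
        for mi, st, s, e_, cs in placements:
            manifest_rows.append(
                {
                    "mirna_id": f"syn-miR-{mi}",
                    "utr_id": f"utr-{ui}",
                    "site_type": st,
                    "start": s,
                    "end": e_,
                }
            )

    mirna_records = [
        SeqRecord(Seq(m), id=f"syn-miR-{i}", description="synthetic mature miRNA")
        for i, m in enumerate(matures)
    ]
    utr_records = [
        SeqRecord(Seq(u), id=f"utr-{i}", description="synthetic 3'UTR")
        for i, u in enumerate(utrs)
    ]
    manifest = pd.DataFrame(
        manifest_rows, columns=["mirna_id", "utr_id", "site_type", "start", "end"]
    )
    return mirna_records, utr_records, manifest


def generate_geneset_collection(
    query: set[str],
    universe: set[str],
    *,
    n_enriched: int = 15,
    n_background: int = 85,
    enriched_overlap: int = 4,
    set_size: int = 40,
    n_categories_first: int = 3,
    category: str = "platelet",
    seed: int = 0,
):
    """Synthetic pathway collection with planted enrichment.

    ``n_enriched`` pathways each share ``enriched_overlap`` genes with the
    query; ``n_background`` pathways are drawn from outside the query.  The
    first ``n_categories_first`` enriched pathways are labelled with
    ``category`` and the rest ``other``, so a category-fraction computation
    over the enriched pathways is exercised end to end.  Returns
    ``(sets, categories)`` where ``sets`` maps pathway id -> gene set.
    """
    rng = np.random.default_rng(seed)
    query_l = sorted(query)
    rest = sorted(universe - query)
    if enriched_overlap > len(query_l):
        raise ValueError("overlap larger than the query")
    sets: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    for i in range(n_enriched):
        hit = rng.choice(query_l, size=enriched_overlap, replace=False)
        pad = rng.choice(rest, size=set_size - enriched_overlap, replace=False)
        pid = f"PW_ENRICHED_{i:02d}"
        sets[pid] = set(map(str, hit)) | set(map(str, pad))
        categories[pid] = category if i < n_categories_first else "other"
    for i in range(n_background):
        pid = f"PW_BG_{i:02d}"
        sets[pid] = set(map(str, rng.choice(rest, size=set_size, replace=False)))
        categories[pid] = "other"
    return sets, categories
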