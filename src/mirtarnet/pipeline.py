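"""End-to-end pipeline: simulate or load arrays, call differential
expression, partition presence calls, predict targets, assemble inverse
networks, run enrichment, and write a report bundle.

Every stage logs its in/out counts; a run manifest (thresholds, seed,
version) accompanies the machine-readable outputs, and identical
configurations with identical seeds produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datasets import (
    GROUPS,
    ArrayDesign,
    TruthConfig,
    generate_dataset,
    generate_geneset_collection,
)
from .enrichment import GeneSetCollection, enrich, read_gmt
from .expression import (
    ExpressionMatrix,
    apply_main_filter,
    differential_table,
    expressed_sets,
)
from .network import build_inverse_network, classify_modes, export_network
from .setops import venn_partition
from .targets import (
    build_association_table,
    ingest_association_table,
    read_fasta_seeds,
    read_fasta_utrs,
)

logger = logging.getLogger(__name__)

#: The four comparisons mirrored from the study: tissue contrasts within a
#: condition and condition contrasts within a tissue (reference first).
COMPARISONS = {
    "normal_small_vs_normal_large": ("normal_large", "normal_small"),
    "normal_large_vs_normal_small": ("normal_small", "normal_large"),
    "inflamed_small_vs_normal_small": ("normal_small", "inflamed_small"),
    "inflamed_large_vs_normal_large": ("normal_large", "inflamed_large"),
}


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Inputs are either ``synthetic`` (the generator is run with ``design``
    and ``truth`` parameters) or paths to probe x group intensity TSVs.
    Associations come from the synthetic truth, a precomputed table, or
    FASTA sequence scanning.
    """

    input_mode: str = "synthetic"  # "synthetic" | "files"
    mirna_tsv: str | None = None
    mrna_tsv: str | None = None
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    association_table: str | None = None
    geneset_gmt: str | None = None

    fold_threshold: float = 2.0
    intensity_threshold: float = 100.0
    high_tier_intensity: float = 10_000.0
    alpha: float = 0.05
    floor: float = 1.0

    seed: int = 0
    outdir: str = "mirtarnet_out"
    stages: tuple[str, ...] = ("differential", "venn", "network", "enrich")

    design: ArrayDesign = field(default_factory=ArrayDesign)
    truth: TruthConfig = field(default_factory=TruthConfig)

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold threshold must exceed 1")
        for t in (self.intensity_threshold, self.high_tier_intensity, self.alpha):
            if t <= 0:
                raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        design_raw = raw.pop("design", {})
        if "group_names" in design_raw:
            design_raw["group_names"] = tuple(design_raw["group_names"])
        design = ArrayDesign(**design_raw)
        truth = raw.pop("truth", {})
        if "pair" in truth:
            truth["pair"] = tuple(truth["pair"])
        truth = TruthConfig(**truth)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(design=design, truth=truth, **raw)


def _load_inputs(config: PipelineConfig):
    if config.input_mode == "synthetic":
        return generate_dataset(config.design, config.truth, seed=config.seed)
    if config.input_mode == "files":
        if not (config.mirna_tsv and config.mrna_tsv):
            raise ValueError("file mode needs mirna_tsv and mrna_tsv")
        mirna = ExpressionMatrix.from_tsv(config.mirna_tsv, channel="miRNA")
        mrna = ExpressionMatrix.from_tsv(config.mrna_tsv, channel="mRNA")
        return mirna, mrna, None
    raise ValueError(f"unknown input mode {config.input_mode!r}")


def _associations(config: PipelineConfig, truth):
    if config.association_table:
        return ingest_association_table(config.association_table)
    if config.mirna_fasta and config.utr_fasta:
        seeds = read_fasta_seeds(config.mirna_fasta)
        utrs = read_fasta_utrs(config.utr_fasta)
        return build_association_table(seeds, utrs)
    if truth is not None:
        pairs = sorted(truth.repression_links | truth.decoy_associations)
        return pd.DataFrame(
            {
                "mirna_name": [m for m, _ in pairs],
                "gene_id": [g for _, g in pairs],
                "site_type": "table",
                "utr_position": pd.NA,
            }
        )
    raise ValueError("no association source configured")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages and write the report bundle.

    Returns a dictionary of the summary quantities also written to
    ``<outdir>/manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    mirna, mrna, truth = _load_inputs(config)
    logger.info(
        "loaded matrices: %d miRNA probes, %d mRNA probes, groups %s",
        len(mirna.probe_ids), len(mrna.probe_ids), mirna.groups,
    )
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fold": config.fold_threshold,
            "intensity": config.intensity_threshold,
            "high_tier": config.high_tier_intensity,
            "alpha": config.alpha,
            "floor": config.floor,
        },
    }

    kw = dict(
        floor=config.floor,
        fold_threshold=config.fold_threshold,
        intensity_threshold=config.intensity_threshold,
        high_tier_intensity=config.high_tier_intensity,
    )
    diff: dict[str, dict[str, pd.DataFrame]] = {}
    if "differential" in config.stages:
        counts = {}
        for label, (ref, test) in COMPARISONS.items():
            for channel, matrix in (("miRNA", mirna), ("mRNA", mrna)):
                records = differential_table(matrix, ref, test, **kw)
                kept = apply_main_filter(
                    records,
                    fold_threshold=config.fold_threshold,
                    intensity_threshold=config.intensity_threshold,
                )
                diff.setdefault(label, {})[channel] = kept.assign(
                    passes_high_tier=records.loc[kept.index, "passes_high_tier"]
                )
                logger.info(
                    "differential %s [%s]: %d probes in, %d pass main filter",
                    label, channel, len(records), len(kept),
                )
                kept.sort_values("log2_fc", ascending=False).to_csv(
                    out / f"differential_{label}_{channel}.tsv", sep="\t", index=False
                )
                counts[f"{label}_{channel}"] = {
                    "up": int((kept["direction"] == "up").sum()),
                    "down": int((kept["direction"] == "down").sum()),
                    "high_tier": int(kept["passes_high_tier"].sum()),
                }
        summary["differential_counts"] = counts

    if "venn" in config.stages:
        sets = expressed_sets(mirna)
        part = venn_partition(sets)
        rows = [
            {"signature": "+".join(sig), "count": n}
            for sig, n in sorted(part.region_counts.items())
        ]
        pd.DataFrame(rows).to_csv(out / "venn_mirna.tsv", sep="\t", index=False)
        summary["venn"] = {
            "per_group_totals": part.per_group_totals(),
            "common_all": part.count(*GROUPS),
            "small_exclusive": part.exclusive_to(["normal_small", "inflamed_small"]),
            "large_exclusive": part.exclusive_to(["normal_large", "inflamed_large"]),
            "unique_per_group": {g: part.unique_to(g) for g in sets},
        }
        logger.info("venn: %s", summary["venn"]["per_group_totals"])

    networks = {}
    if "network" in config.stages and diff:
        associations = _associations(config, truth)
        label = "inflamed_large_vs_normal_large"
        for direction in ("up", "down"):
            g = build_inverse_network(
                diff[label]["miRNA"], diff[label]["mRNA"], associations,
                mirna_direction=direction,
            )
            networks[direction] = g
            ns = classify_modes(g)
            export_network(g, out / f"network_{direction}_mirna.graphml", "graphml")
            export_network(g, out / f"network_{direction}_mirna_edges.tsv", "edge-tsv")
            summary[f"network_{direction}_mirna"] = ns.as_dict()
            logger.info(
                "network (%s-miRNA): %d miRNAs, %d genes, %d edges",
                direction, ns.n_mirnas, ns.n_genes, ns.n_edges,
            )

    if "enrich" in config.stages and networks.get("up") is not None:
        from .network import gene_nodes

        query = gene_nodes(networks["up"])
        if query:
            universe = set(map(str, mrna.probe_ids))
            if config.geneset_gmt:
                collection = read_gmt(config.geneset_gmt, universe=universe)
            else:
                sets, cats = generate_geneset_collection(
                    query, universe, seed=config.seed
                )
                collection = GeneSetCollection(sets=sets, universe=universe)
                pd.DataFrame(
                    sorted(cats.items()), columns=["pathway_id", "category"]
                ).to_csv(out / "pathway_categories.tsv", sep="\t", index=False)
            results = enrich(query, collection, alpha=config.alpha)
            results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                "n_tested": int(len(results)),
                "n_reported": int(results["reported"].sum()),
            }
            logger.info(
                "enrichment: %d pathways tested, %d reported",
                len(results), int(results["reported"].sum()),
            )

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def write_config_template(path) -> None:
    """Write a YAML config with every default spelled out."""
    cfg = PipelineConfig()
    raw = dataclasses.asdict(cfg)
    raw["design"] = dataclasses.asdict(cfg.design)
    raw["truth"] = dataclasses.asdict(cfg.truth)
    raw["stages"] = list(cfg.stages)
    raw["truth"]["pair"] = list(cfg.truth.pair)
    raw["design"]["group_names"] = list(cfg.design.group_names)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
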