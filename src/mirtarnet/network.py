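"""Inverse-expression bipartite miRNA-gene network assembly and summaries.

An edge links a differentially expressed miRNA to a predicted target gene
whose expression moved in the opposite direction in the same cells: an
up-regulated miRNA to a down-regulated gene (repression gained) or a
down-regulated miRNA to an up-regulated gene (repression lost).  Edges
are classified into the four connectivity modes by endpoint degrees:
single-to-single, single-to-multiple (one miRNA, several targets),
multiple-to-single (several miRNAs onto one gene) and
multiple-to-multiple.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

UP_MIR_DOWN_GENE = "up_miRNA_down_gene"
DOWN_MIR_UP_GENE = "down_miRNA_up_gene"

MODES = (
    "single-to-single",
    "single-to-multiple",
    "multiple-to-single",
    "multiple-to-multiple",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (92.35 -> 92.4)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class NetworkSummary:
    n_mirnas: int
    n_genes: int
    n_edges: int
    mode_counts: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_mirnas": self.n_mirnas,
            "n_genes": self.n_genes,
            "n_edges": self.n_edges,
            **{f"mode_{k}": v for k, v in self.mode_counts.items()},
        }


def _collapse_records(records: pd.DataFrame, wanted_direction: str) -> pd.Series:
    """probe -> log2_fc for records with the wanted direction.

    A gene carried by several probes keeps the probe with the largest
    absolute fold change; conflicts are logged, never silently merged.
    """
    sub = records.loc[records["direction"] == wanted_direction]
    if sub["probe_id"].duplicated().any():
        n = int(sub["probe_id"].duplicated().sum())
        logger.warning("collapsing %d duplicate probe ids by max |log2_fc|", n)
        sub = sub.loc[
            sub.groupby("probe_id")["log2_fc"].transform(
                lambda s: s.abs() == s.abs().max()
            )
        ].drop_duplicates("probe_id")
    return sub.set_index("probe_id")["log2_fc"]


def build_inverse_network(
    mirna_records: pd.DataFrame,
    gene_records: pd.DataFrame,
    associations: pd.DataFrame | set,
    *,
    mirna_direction: str = "up",
) -> nx.Graph:
    """Bipartite network of inversely expressed miRNA-target pairs.

    ``mirna_records``/``gene_records`` are differential-record tables
    (after the main filter or with ``direction`` assigned);
    ``associations`` is an association table or a set of (mirna, gene)
    pairs.  With ``mirna_direction="up"`` the edges link up-regulated
    miRNAs to down-regulated genes; ``"down"`` gives the symmetric
    network.  Association rows referencing probes outside the two lists
    are skipped (counted in the graph attribute ``n_skipped``).
    """
    if mirna_direction not in ("up", "down"):
        raise ValueError("mirna_direction must be 'up' or 'down'")
    gene_direction = "down" if mirna_direction == "up" else "up"
    label = UP_MIR_DOWN_GENE if mirna_direction == "up" else DOWN_MIR_UP_GENE

    mir_fc = _collapse_records(mirna_records, mirna_direction)
    gene_fc = _collapse_records(gene_records, gene_direction)

    if isinstance(associations, pd.DataFrame):
        pairs = set(zip(associations["mirna_name"], associations["gene_id"]))
    else:
        pairs = set(associations)

    g = nx.Graph(direction_label=label, n_skipped=0)
    skipped = 0
    for m, t in sorted(pairs):
        if m in mir_fc.index and t in gene_fc.index:
            g.add_node(m, bipartite="miRNA", log2_fc=float(mir_fc[m]))
            g.add_node(t, bipartite="gene", log2_fc=float(gene_fc[t]))
            g.add_edge(m, t, direction_label=label)
        else:
            skipped += 1
    if skipped:
        logger.info("skipped %d associations referencing unlisted probes", skipped)
    g.graph["n_skipped"] = skipped
    return g


def mirna_nodes(g: nx.Graph) -> set[str]:
    return {n for n, d in g.nodes(data=True) if d.get("bipartite") == "miRNA"}


def gene_nodes(g: nx.Graph) -> set[str]:
    return {n for n, d in g.nodes(data=True) if d.get("bipartite") == "gene"}


def classify_modes(g: nx.Graph) -> NetworkSummary:
    """Per-edge connectivity-mode counts.

    For an edge (m, t): both endpoints degree 1 -> single-to-single;
    miRNA degree > 1, gene degree 1 -> single-to-multiple (one miRNA with
    several targets); miRNA degree 1, gene degree > 1 ->
    multiple-to-single; both > 1 -> multiple-to-multiple.
    """
    mirs = mirna_nodes(g)
    counts = dict.fromkeys(MODES, 0)
    for u, v in g.edges():
        m, t = (u, v) if u in mirs else (v, u)
        dm, dt = g.degree(m), g.degree(t)
        if dm == 1 and dt == 1:
            mode = "single-to-single"
        elif dm > 1 and dt == 1:
            mode = "single-to-multiple"
        elif dm == 1 and dt > 1:
            mode = "multiple-to-single"
        else:
            mode = "multiple-to-multiple"
        counts[mode] += 1
    return NetworkSummary(
        n_mirnas=len(mirs),
        n_genes=len(gene_nodes(g)),
        n_edges=g.number_of_edges(),
        mode_counts=counts,
    )


def target_uniqueness(targets_a: set, targets_b: set) -> tuple[float, float, set]:
    """Percent of each target set not shared with the other.

    Returns ``(pct_unique_a, pct_unique_b, shared)`` with percentages
    rounded half-up to one decimal.
    """
    a, b = set(targets_a), set(targets_b)
    if not a or not b:
        raise ValueError("target sets must be non-empty")
    shared = a & b
    pct_a = round_half_up(100.0 * len(a - b) / len(a))
    pct_b = round_half_up(100.0 * len(b - a) / len(b))
    return pct_a, pct_b, shared


def export_network(g: nx.Graph, path, fmt: str) -> None:
    """Write a network as GraphML, edge TSV or node-link JSON."""
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edge-tsv":
        mirs = mirna_nodes(g)
        rows = []
        for u, v, d in g.edges(data=True):
            m, t = (u, v) if u in mirs else (v, u)
            rows.append(
                {
                    "mirna_name": m,
                    "gene_id": t,
                    "direction_label": d.get("direction_label", ""),
                    "mirna_log2_fc": g.nodes[m].get("log2_fc"),
                    "gene_log2_fc": g.nodes[t].get("log2_fc"),
                }
            )
        cols = ["mirna_name", "gene_id", "direction_label", "mirna_log2_fc", "gene_log2_fc"]
        pd.DataFrame(rows, columns=cols).sort_values(cols[:2]).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "json":
        data = nx.node_link_data(g, edges="edges")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_network(path, fmt: str) -> nx.Graph:
    """Read back a network written by :func:`export_network`."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edge-tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_node(row.mirna_name, bipartite="miRNA", log2_fc=float(row.mirna_log2_fc))
            g.add_node(row.gene_id, bipartite="gene", log2_fc=float(row.gene_log2_fc))
            g.add_edge(row.mirna_name, row.gene_id, direction_label=row.direction_label)
        return g
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            return nx.node_link_graph(json.load(fh), edges="edges")
    raise ValueError(f"unknown format {fmt!r}")
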