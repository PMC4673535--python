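"""Gene-set (pathway) enrichment for target-gene lists.

Self-contained replacement for a web enrichment service: one-sided
hypergeometric tests against a configurable gene universe (default: all
genes on the mRNA array) with Benjamini-Hochberg FDR control across the
tested pathways.  A pathway is *reported* when its adjusted p-value is at
or below alpha and more than two query genes fall in it (overlap >= 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import round_half_up

logger = logging.getLogger(__name__)

MIN_REPORTED_OVERLAP = 3  # "more than two genes"


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe."""

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("empty collection")
        for pid, s in self.sets.items():
            if not s:
                raise ValueError(f"empty gene set {pid!r}")
            extra = set(s) - self.universe
            if extra:
                raise ValueError(f"gene set {pid!r} outside the universe: {sorted(extra)[:5]}")


def read_gmt(path, universe: set | None = None) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> gene...).

    Without an explicit universe, the union of all sets is used.
    """
    sets: dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    if universe is None:
        universe = set().union(*sets.values())
    else:
        sets = {pid: s & universe for pid, s in sets.items()}
        sets = {pid: s for pid, s in sets.items() if s}
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[pid]))
            fh.write(f"{pid}\tna\t{genes}\n")


def enrich(
    query: set,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    *,
    min_reported_overlap: int = MIN_REPORTED_OVERLAP,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene set against a collection.

    Query genes outside the universe are logged and dropped.  Returns one
    row per pathway sorted by p-value, with BH-adjusted ``q_value`` and a
    ``reported`` flag (q <= alpha and overlap >= ``min_reported_overlap``).
    """
    query = set(query)
    if not query:
        raise ValueError("empty query")
    outside = query - collection.universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query = query & collection.universe
    if not query:
        raise ValueError("query entirely outside the universe")

    M = len(collection.universe)
    N = len(query)
    rows = []
    for pid in sorted(collection.sets):
        s = collection.sets[pid]
        k = len(query & s)
        p = float(hypergeom.sf(k - 1, M, len(s), N))
        rows.append(
            {
                "pathway_id": pid,
                "overlap_count": k,
                "set_size": len(s),
                "query_size": N,
                "universe_size": M,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["q_value"] = q
    out["reported"] = (out["q_value"] <= alpha) & (
        out["overlap_count"] >= min_reported_overlap
    )
    return out.sort_values(["p_value", "pathway_id"], kind="stable").reset_index(
        drop=True
    )


def category_fraction(
    results: pd.DataFrame, category_map: dict[str, str]
) -> dict[str, float]:
    """Percentage of reported pathways per functional category.

    Unmapped reported pathways fall into ``"other"``.  Percentages are
    rounded half-up to one decimal.
    """
    reported = results.loc[results["reported"], "pathway_id"]
    if reported.empty:
        raise ValueError("no reported pathways")
    counts: dict[str, int] = {}
    for pid in reported:
        cat = category_map.get(pid, "other")
        counts[cat] = counts.get(cat, 0) + 1
    total = int(reported.size)
    return {cat: round_half_up(100.0 * n / total) for cat, n in sorted(counts.items())}
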