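"""Set operations over miRNA populations: four-way Venn partitioning,
list overlap, and cross-list category annotation.

The four-group presence comparison partitions the union of the per-group
expressed sets into the 15 non-empty membership signatures of a four-set
Venn diagram; derived summaries (tissue-exclusive and condition-unique
counts) follow directly from those regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .names import normalize_all


@dataclass
class VennPartition:
    """Exact partition of four named sets into membership regions.

    ``region_counts`` maps each non-empty membership signature -- a sorted
    tuple of group names -- to the number of elements belonging to exactly
    those groups.
    """

    group_sets: dict[str, set]
    region_counts: dict[tuple[str, ...], int]
    regions: dict[tuple[str, ...], set]

    @property
    def universe(self) -> set:
        out: set = set()
        for s in self.group_sets.values():
            out |= s
        return out

    def count(self, *groups: str) -> int:
        """Count of elements in exactly the given groups."""
        return self.region_counts.get(tuple(sorted(groups)), 0)

    def per_group_totals(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.group_sets.items()}

    def exclusive_to(self, groups) -> int:
        """Elements present in >=1 of ``groups`` and in no other group."""
        groups = set(groups)
        return sum(
            n for sig, n in self.region_counts.items() if set(sig) <= groups
        )

    def unique_to(self, group: str) -> int:
        """Elements present in exactly one group."""
        return self.count(group)


def venn_partition(sets: dict[str, set]) -> VennPartition:
    """Partition the union of four named sets into the 15 Venn regions."""
    if len(sets) != 4:
        raise ValueError("exactly four named sets are required")
    names = list(sets)
    regions: dict[tuple[str, ...], set] = {}
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, 5):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[g] for g in combo))
            for g in names:
                if g not in combo:
                    inside = inside - sets[g]
            sig = tuple(sorted(combo))
            regions[sig] = inside
            counts[sig] = len(inside)
    return VennPartition(group_sets={g: set(s) for g, s in sets.items()},
                         region_counts=counts, regions=regions)


def list_overlap(list_a, list_b) -> dict:
    """Exact overlap of two miRNA name lists after normalization.

    Duplicate names within either list are a fixture-integrity error.
    Returns the intersection set, the three counts and the Jaccard index.
    """
    a = normalize_all(list_a)
    b = normalize_all(list_b)
    if len(set(a)) != len(a):
        raise ValueError("duplicate names in list_a")
    if len(set(b)) != len(b):
        raise ValueError("duplicate names in list_b")
    sa, sb = set(a), set(b)
    inter = sa & sb
    union = sa | sb
    return {
        "intersection": inter,
        "n_a": len(sa),
        "n_b": len(sb),
        "n_intersection": len(inter),
        "jaccard": len(inter) / len(union) if union else 0.0,
    }


def annotate_categories(target_list, reference_lists: dict[str, list]) -> dict[str, set]:
    """Label each target name with the reference lists that contain it.

    A name found in none of the references is labelled ``{"novel"}``.
    """
    refs = {name: set(normalize_all(lst)) for name, lst in reference_lists.items()}
    out: dict[str, set] = {}
    for name in normalize_all(target_list):
        labels = {ref for ref, s in refs.items() if name in s}
        out[name] = labels if labels else {"novel"}
    return out


def category_counts(annotation: dict[str, set]) -> dict[str, int]:
    """Count names per exact label combination (sorted, '+'-joined)."""
    counts: dict[str, int] = {}
    for labels in annotation.values():
        key = "+".join(sorted(labels))
        counts[key] = counts.get(key, 0) + 1
    return counts
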