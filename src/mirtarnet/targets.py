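"""Canonical seed-site target prediction and association-table ingestion.

A mature miRNA's seed is nucleotides 2-8 (5'->3').  A canonical target
site in a 3'UTR is a Watson-Crick match to (part of) the seed, read on the
UTR sense strand as the reverse complement of the seed region, with four
site types ranked 8mer > 7mer-m8 > 7mer-A1 > 6mer:

* 8mer     -- match to positions 2-8 plus an A across from position 1;
* 7mer-m8  -- match to positions 2-8;
* 7mer-A1  -- match to positions 2-7 plus the A;
* 6mer     -- match to positions 2-7 only.

Each 6mer-core window is classified once, by the highest type its flanks
support; the A1 anchor is a literal A in the UTR regardless of the
miRNA's position-1 identity.  Coordinates are 0-based half-open on the
UTR sense strand.  No 3'-supplementary pairing, context scoring or
conservation weighting is attempted: the scanner provides putative
associations only, in the same spirit as a precomputed association table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .names import normalize_name

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMP = str.maketrans("ACGU", "UGCA")

ASSOCIATION_COLUMNS = ["mirna_name", "gene_id", "site_type", "utr_position", "multiplicity"]


def _as_rna(seq: str) -> str:
    s = str(seq).upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class SeedDefinition:
    """A mature miRNA and its seed (positions 2-8)."""

    mirna_name: str
    mature_sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_sequence", _as_rna(self.mature_sequence))
        if len(self.mature_sequence) < 8:
            raise ValueError("mature sequence must be at least 8 nt")

    @property
    def seed(self) -> str:
        """Positions 2-8 of the mature sequence (7 nt)."""
        return self.mature_sequence[1:8]

    @property
    def core_match(self) -> str:
        """UTR-sense reverse complement of seed positions 2-7 (6 nt)."""
        return self.mature_sequence[1:7].translate(_COMP)[::-1]

    @property
    def m8_match(self) -> str:
        """UTR base complementary to miRNA position 8."""
        return self.mature_sequence[7].translate(_COMP)


def scan_utr(seed_def: SeedDefinition, utr: str) -> pd.DataFrame:
    """All canonical seed sites of one miRNA in one UTR.

    Returns a DataFrame with one row per site (columns ``mirna_name``,
    ``gene_id`` empty, ``site_type``, ``utr_position``), ordered by
    position.  ``utr_position`` is the 0-based start of the full site
    (including the m8-match base for 8mer/7mer-m8 sites).  A UTR shorter
    than 6 nt yields an empty result; DNA (T) and RNA (U) inputs are
    equivalent.
    """
    u = _as_rna(utr)
    rows = []
    if len(u) >= 6:
        core = seed_def.core_match
        m8 = seed_def.m8_match
        pos = u.find(core)
        while pos != -1:
            has_m8 = pos >= 1 and u[pos - 1] == m8
            has_a1 = pos + 6 < len(u) and u[pos + 6] == "A"
            if has_m8 and has_a1:
                site_type, start = "8mer", pos - 1
            elif has_m8:
                site_type, start = "7mer-m8", pos - 1
            elif has_a1:
                site_type, start = "7mer-A1", pos
            else:
                site_type, start = "6mer", pos
            rows.append(
                {
                    "mirna_name": normalize_name(seed_def.mirna_name),
                    "gene_id": "",
                    "site_type": site_type,
                    "utr_position": start,
                }
            )
            pos = u.find(core, pos + 1)
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS[:4])


def build_association_table(seed_defs, utrs: dict[str, str]) -> pd.DataFrame:
    """Scan every miRNA against every UTR and collect associations.

    ``utrs`` maps unique gene ids to UTR sequences.  One row per
    (mirna, gene, site); rows are deduplicated and ordered by
    (mirna, gene, position).
    """
    gene_ids = list(utrs)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    frames = []
    for sd in seed_defs:
        for gene_id, utr in utrs.items():
            hits = scan_utr(sd, utr)
            if len(hits):
                hits = hits.assign(gene_id=gene_id)
                frames.append(hits)
    if not frames:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS[:4])
    out = pd.concat(frames, ignore_index=True).drop_duplicates()
    return out.sort_values(
        ["mirna_name", "gene_id", "utr_position"], kind="stable"
    ).reset_index(drop=True)


def read_fasta_seeds(path) -> list[SeedDefinition]:
    """Mature-miRNA FASTA -> seed definitions (record id = miRNA name)."""
    return [
        SeedDefinition(mirna_name=rec.id, mature_sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fasta_utrs(path) -> dict[str, str]:
    """3'UTR FASTA -> {gene_id: sequence}; duplicate ids are an error."""
    utrs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in utrs:
            raise ValueError(f"duplicate gene id {rec.id!r}")
        utrs[rec.id] = str(rec.seq)
    return utrs


def ingest_association_table(path, *, mirna_col: str = "mirna", gene_col: str = "gene") -> pd.DataFrame:
    """Load a precomputed miRNA->gene association table from delimited text.

    Rows are deduplicated with the duplicate count kept in a
    ``multiplicity`` column; ``site_type`` is set to ``"table"`` and
    positions are absent.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError("empty association table")
    missing = {mirna_col, gene_col} - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns {sorted(missing)}")
    df = df.rename(columns={mirna_col: "mirna_name", gene_col: "gene_id"})
    df["mirna_name"] = df["mirna_name"].map(normalize_name)
    grouped = (
        df.groupby(["mirna_name", "gene_id"], sort=True)
        .size()
        .rename("multiplicity")
        .reset_index()
    )
    grouped["site_type"] = "table"
    grouped["utr_position"] = pd.NA
    return grouped[ASSOCIATION_COLUMNS]


def association_pairs(associations: pd.DataFrame) -> set[tuple[str, str]]:
    """Distinct (mirna_name, gene_id) pairs of an association table."""
    return set(
        zip(associations["mirna_name"].astype(str), associations["gene_id"].astype(str))
    )
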