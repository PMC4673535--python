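import numpy as np
import pandas as pd
import pytest

from mirtarnet.datasets import (
    FIXTURE_IDS,
    ArrayDesign,
    TruthConfig,
    generate_dataset,
    generate_sequences,
    load_fixture,
    load_fig2_counts,
    load_mir223_targets,
)
from mirtarnet.expression import apply_main_filter, differential_table
from mirtarnet.targets import SeedDefinition, scan_utr


class TestGenerator:
    def test_same_seed_is_bit_identical(self):
        design = ArrayDesign(n_mirna_probes=100, n_mrna_probes=300)
        cfg = TruthConfig(n_up_mirna=5, n_down_mirna=5, n_up_mrna=10,
                          n_down_mrna=20, n_linked_mirna=3, n_linked_genes=8)
        a = generate_dataset(design, cfg, seed=42)
        b = generate_dataset(design, cfg, seed=42)
        assert a[0].intensity.equals(b[0].intensity)
        assert a[1].intensity.equals(b[1].intensity)
        assert a[2].repression_links == b[2].repression_links

    def test_truth_consistency(self, small_dataset):
        mirna, mrna, truth = small_dataset
        pair = ("normal_large", "inflamed_large")
        for probe in truth.de_up[pair]:
            mat = mirna if probe.startswith("mir-") else mrna
            assert (
                mat.intensity.loc[probe, "inflamed_large"]
                > mat.intensity.loc[probe, "normal_large"]
            )
        # every repression link references existing probes
        for m, g in truth.repression_links:
            assert m in mirna.probe_ids and g in mrna.probe_ids

    def test_zero_effect_gives_no_real_signal(self):
        design = ArrayDesign(n_mirna_probes=300, n_mrna_probes=300)
        cfg = TruthConfig(n_up_mirna=20, n_down_mirna=5, n_up_mrna=10,
                          n_down_mrna=20, n_linked_mirna=5, n_linked_genes=10,
                          effect_size_log2=0.0)
        mirna, _, truth = generate_dataset(design, cfg, seed=3)
        kept = apply_main_filter(
            differential_table(mirna, "normal_large", "inflamed_large")
        )
        planted = {p for p in truth.de_up[cfg.pair] if p.startswith("mir-")}
        # anything surviving is a noise-driven false positive, not the planted set
        assert not planted & set(kept["probe_id"]) or len(kept) < len(planted)

    def test_recovery_of_fifty_planted_mirnas(self):
        # 50 up-miRNAs at effect 3.0, noise 0.2: the main filter recovers >= 45
        design = ArrayDesign(n_mirna_probes=1900, n_mrna_probes=100)
        cfg = TruthConfig(n_up_mirna=50, n_down_mirna=0, n_up_mrna=0,
                          n_down_mrna=0, n_linked_mirna=0, n_linked_genes=0,
                          effect_size_log2=3.0, noise_sd_log2=0.2)
        recovered = []
        for seed in range(20):
            mirna, _, truth = generate_dataset(design, cfg, seed=seed)
            kept = apply_main_filter(
                differential_table(mirna, "normal_large", "inflamed_large")
            )
            up = set(kept.loc[kept["direction"] == "up", "probe_id"])
            recovered.append(len(up & truth.de_up[cfg.pair]))
        assert min(recovered) >= 45

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            TruthConfig(effect_size_log2=-1.0)
        with pytest.raises(ValueError):
            TruthConfig(noise_sd_log2=-0.1)
        with pytest.raises(ValueError):
            generate_dataset(
                ArrayDesign(n_mirna_probes=10, n_mrna_probes=10),
                TruthConfig(n_up_mirna=8, n_down_mirna=8),
                seed=0,
            )

    def test_design_invariants(self):
        with pytest.raises(ValueError):
            ArrayDesign(group_names=("a", "b", "c"))
        with pytest.raises(ValueError):
            ArrayDesign(background_floor=-1.0)


class TestFixtures:
    @pytest.mark.parametrize(
        ("table_id", "n", "n_up", "n_down"),
        [
            ("table1_section1", 86, 86, 0),
            ("table1_section2", 33, 33, 0),
            ("table1_section3", 13, 13, 0),
            ("table1_section4", 39, 39, 0),
            ("table2_small", 30, 1, 29),
            ("table2_large", 66, 51, 15),
        ],
    )
    def test_section_sizes(self, table_id, n, n_up, n_down):
        t = load_fixture(table_id)
        assert len(t.records) == n
        assert (t.records["value"] > 0).sum() == n_up
        assert (t.records["value"] < 0).sum() == n_down

    def test_printed_anchor_records(self):
        s1 = load_fixture("table1_section1")
        assert s1.records.iloc[0]["mirna"] == "miR-6243"
        assert s1.records.iloc[0]["value"] == 43187
        t2 = load_fixture("table2_small")
        assert t2.values["miR-223-3p"] == pytest.approx(1.327)
        # ordering as printed: by magnitude of value within each table
        assert s1.records["value"].is_monotonic_decreasing

    def test_odd_name_preserved_verbatim(self):
        t2 = load_fixture("table2_small")
        assert "miR-3102-5p.2-5p" in set(t2.names)

    def test_unknown_id(self):
        with pytest.raises(KeyError):
            load_fixture("table9")

    def test_all_fixture_names_unique(self):
        for tid in FIXTURE_IDS:
            names = load_fixture(tid).names
            assert len(names) == len(set(names))

    def test_mir223_target_lists(self):
        large = load_mir223_targets("large")
        small = load_mir223_targets("small")
        assert len(large) == 9  # printed count; one name unresolved
        assert (large["status"] == "unresolved").sum() == 1
        assert len(small) == 13
        assert "SLC4A4" in set(small["gene"]) and "SLC4A4" in set(large["gene"])

    def test_fig2_counts(self):
        c = load_fig2_counts().set_index("tissue")
        assert c.loc["small", "n_up"] == 24 and c.loc["small", "n_down"] == 326
        assert c.loc["large", "n_up"] == 166 and c.loc["large", "n_down"] == 225


class TestSequences:
    def test_planted_sites_scan_as_requested(self):
        plan = [(0, 0, "8mer"), (1, 1, "7mer-m8"), (2, 2, "7mer-A1"), (0, 3, "6mer")]
        mirnas, utrs, manifest = generate_sequences(3, 4, plan, seed=5)
        seeds = {r.id: SeedDefinition(r.id, str(r.seq)) for r in mirnas}
        utr_by_id = {r.id: str(r.seq) for r in utrs}
        assert len(manifest) == len(plan)
        for row in manifest.itertuples():
            hits = scan_utr(seeds[row.mirna_id], utr_by_id[row.utr_id])
            assert len(hits) == 1
            assert hits.iloc[0]["site_type"] == row.site_type
            assert hits.iloc[0]["utr_position"] == row.start

    def test_no_planted_sites_no_hits_for_planted_mirnas(self):
        mirnas, utrs, manifest = generate_sequences(2, 3, [(0, 0, "6mer")], seed=8)
        assert manifest.iloc[0]["site_type"] == "6mer"
        # miRNA 1 was never planted; by construction it may match by chance,
        # but miRNA 0 must match only at the manifest position
        sd = SeedDefinition(mirnas[0].id, str(mirnas[0].seq))
        for rec in utrs:
            hits = scan_utr(sd, str(rec.seq))
            expected = manifest.loc[manifest["utr_id"] == rec.id]
            assert len(hits) == len(expected)

    def test_same_seed_identical_fasta(self):
        a = generate_sequences(2, 2, [(0, 0, "8mer")], seed=9)
        b = generate_sequences(2, 2, [(0, 0, "8mer")], seed=9)
        assert [str(r.seq) for r in a[1]] == [str(r.seq) for r in b[1]]
        assert a[2].equals(b[2])

    def test_bad_requests(self):
        with pytest.raises(IndexError):
            generate_sequences(1, 1, [(2, 0, "8mer")], seed=0)
        with pytest.raises(ValueError):
            generate_sequences(1, 1, [(0, 0, "9mer")], seed=0)
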