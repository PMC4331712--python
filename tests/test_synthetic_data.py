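import hashlib

import numpy as np
import pandas as pd
import pytest

from miremap import de_calling
from miremap import synthetic_data as synth
from miremap.exceptions import ConfigError, SizingError
from miremap.smallrna_quant import QuantConfig, ReadRecord, match_and_count


class TestConfigValidation:
    def test_counts_invariant(self):
        with pytest.raises(ConfigError):
            synth.SyntheticConfig(n_mirnas=10, n_up_mirnas=8, n_down_mirnas=5)

    def test_cluster_within_up(self):
        with pytest.raises(ConfigError):
            synth.SyntheticConfig(n_up_mirnas=5,
                                  cluster_spec=("chr12", 1, 10_000_000, 6))

    def test_rho_bounds(self):
        with pytest.raises(ConfigError):
            synth.SyntheticConfig(cross_platform_rho=1.2)

    def test_hub_exceeding_genes(self):
        with pytest.raises(SizingError):
            synth.SyntheticConfig(n_genes=40, hub_spec=((0, 41),))


class TestAnnotation:
    def test_seeded_determinism_byte_identical(self, tmp_path, small_config):
        out1, out2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        synth.write_gff3(synth.generate_mirna_annotation(small_config), out1)
        synth.write_gff3(synth.generate_mirna_annotation(small_config), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_cluster_members_inside_interval(self):
        cfg = synth.SyntheticConfig(
            cluster_spec=("chr12", 109_500_000, 109_750_000, 41))
        loci = synth.generate_mirna_annotation(cfg)
        inside = [l for l in loci
                  if l.chrom == "chr12" and 109_500_000 <= l.start
                  and l.end <= 109_750_000]
        assert len(inside) == 41
        # non-members live on other chromosomes entirely
        assert sum(l.chrom == "chr12" for l in loci) == 41

    def test_empty_annotation(self):
        cfg = synth.SyntheticConfig(n_mirnas=0, n_up_mirnas=0, n_down_mirnas=0,
                                    cluster_spec=("chr12", 1, 2, 0))
        assert synth.generate_mirna_annotation(cfg) == []

    def test_cluster_interval_too_small(self):
        cfg = synth.SyntheticConfig(cluster_spec=("chr12", 1, 2_000, 41))
        with pytest.raises(SizingError):
            synth.generate_mirna_annotation(cfg)


class TestExpression:
    def test_all_unit_fold_changes_exact(self):
        """No planted DE, no noise: every recomputed FC is exactly 1.0."""
        cfg = synth.SyntheticConfig(
            n_mirnas=30, n_up_mirnas=0, n_down_mirnas=0,
            cluster_spec=("chr12", 109_500_000, 109_750_000, 0),
            noise_sd_log2=0.0, background_logfc_sd=0.0, seed=3)
        truth = synth.generate_truth(cfg)
        ct, counts = synth.generate_expression(cfg, truth)
        fc_a = de_calling.normalize_openarray(ct)
        fc_s = de_calling.seq_fold_changes(counts)
        assert np.all(fc_a["fc"].to_numpy() == 1.0)
        assert np.all(fc_s["fc"].to_numpy() == 1.0)

    def test_planted_four_fold_called_up_both_platforms(self):
        cfg = synth.SyntheticConfig(
            n_mirnas=50, n_up_mirnas=1, n_down_mirnas=0,
            cluster_spec=("chr12", 109_500_000, 109_750_000, 1),
            planted_fc_range=(4.0, 4.0), noise_sd_log2=0.1,
            seq_depth=1_000_000, seed=2)
        truth = synth.generate_truth(cfg)
        planted = cfg.mirna_names[0]
        ct, counts = synth.generate_expression(cfg, truth)
        fc_a = de_calling.normalize_openarray(ct).set_index("mirna")["fc"]
        fc_s = de_calling.seq_fold_changes(counts).set_index("mirna")["fc"]
        assert fc_a[planted] >= 1.5
        assert fc_s[planted] >= 1.5

    def test_rho_calibration_n500(self):
        """Measured cross-platform R of recomputed log2 FCs within 0.7 +/- 0.15."""
        cfg = synth.SyntheticConfig(n_mirnas=500, seed=1)
        truth = synth.generate_truth(cfg)
        ct, counts = synth.generate_expression(cfg, truth)
        arr = de_calling.normalize_openarray(ct).set_index("mirna")["fc"]
        seq = de_calling.seq_fold_changes(counts).set_index("mirna")["fc"]
        common = arr.index.intersection(seq.index).difference([cfg.knockout_name])
        r = np.corrcoef(np.log2(arr[common]), np.log2(seq[common]))[0, 1]
        assert abs(r - 0.7) <= 0.15

    def test_u6_present_with_duplicates(self, small_instance):
        cfg, loci, truth = small_instance
        ct, _ = synth.generate_expression(cfg, truth)
        u6 = ct[ct["mirna"] == "U6"]
        assert set(u6["sample"]) == {"WT", "KO"}
        assert len(u6) == 4  # two technical wells per sample
        per_mirna = ct[ct["mirna"] == cfg.mirna_names[0]]
        assert len(per_mirna) == 4

    def test_missing_control_flagged_downstream(self, small_instance):
        cfg, loci, truth = small_instance
        ct, _ = synth.generate_expression(cfg, truth)
        no_u6 = ct[ct["mirna"] != "U6"]
        with pytest.raises(ConfigError):
            de_calling.normalize_openarray(no_u6)


class TestReads:
    def small_cfg(self, **kw):
        return synth.SyntheticConfig(n_mirnas=3, n_up_mirnas=0, n_down_mirnas=0,
                                     cluster_spec=("chr12", 1, 2, 0), **kw)

    def test_exact_counts_and_prefix(self):
        cfg = self.small_cfg(error_rate=0.0)
        mature = {"mirX": "ACGTACGTACGTACGTACGTAC"}
        reads = synth.generate_reads({"mirX": 3}, mature, cfg)
        assert len(reads) == 3
        for _, seq, qual in reads:
            assert seq[: len(mature["mirX"])] == mature["mirX"]
            assert len(seq) == len(qual) == 50

    def test_adapter_follows_insert(self):
        cfg = self.small_cfg()
        insert = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        reads = synth.generate_reads({"m": 1}, {"m": insert}, cfg)
        _, seq, _ = reads[0]
        assert seq[22:43] == cfg.adapter  # bases 23..43 (1-based) = full adapter

    def test_short_mature_rejected(self):
        cfg = self.small_cfg()
        with pytest.raises(ConfigError):
            synth.generate_reads({"m": 1}, {"m": "ACGTACGTACGT"}, cfg)

    def test_round_trip_exact_counts(self):
        """Error-free FASTQ -> quantifier recovers the planted counts."""
        cfg = self.small_cfg(error_rate=0.0, seed=8)
        mature = synth.generate_mature_sequences(cfg)
        planted = {name: 5 + 3 * i for i, name in enumerate(mature)}
        reads = [ReadRecord(*r) for r in synth.generate_reads(planted, mature, cfg)]
        report = match_and_count(reads, mature, cfg=QuantConfig())
        assert {n: int(c) for n, c in report.counts.items()} == planted
        assert report.mirna_fraction() == 1.0


class TestInteractions:
    def test_hub_degree_planted_exactly(self, small_instance):
        cfg, loci, truth = small_instance
        hub = cfg.mirna_names[0]
        assert len(truth.de_targets[hub]) == 20
        assert truth.de_targets[hub] <= truth.curated_targets[hub]
        for g in truth.de_targets[hub]:
            assert truth.gene_direction[g] == "down"  # hub is up-regulated

    def test_cotarget_group_realized(self, small_instance):
        cfg, loci, truth = small_instance
        n_ref, n_cot = cfg.cotarget_spec
        assert len(truth.reference_targets) == n_ref
        assert len(truth.cotarget_mirnas) == n_cot
        union = set()
        for m in truth.cotarget_mirnas:
            shared = truth.curated_targets[m] & truth.reference_targets
            assert shared
            union |= shared
        assert union == truth.reference_targets
        for m in cfg.mirna_names:
            if m not in truth.cotarget_mirnas:
                assert not (truth.curated_targets[m] & truth.reference_targets)

    def test_cluster_tf_peaks_cover_members(self, small_instance):
        from miremap.interaction_db import infer_tf_mirna_from_peaks

        cfg, loci, truth = small_instance
        _, peaks, _ = synth.generate_interactions(cfg, truth, loci)
        edges = infer_tf_mirna_from_peaks(peaks, loci)
        covered = {e.target for e in edges if e.source == truth.cluster_tf}
        assert covered == set(truth.cluster_members)

    def test_empty_hub_spec_background_only(self):
        cfg = synth.SyntheticConfig(n_mirnas=20, n_up_mirnas=4, n_down_mirnas=2,
                                    cluster_spec=("chr12", 109_500_000, 109_750_000, 2),
                                    hub_spec=(), seed=5)
        truth = synth.generate_truth(cfg)
        de_sizes = {len(truth.de_targets[m]) for m in cfg.mirna_names
                    if truth.direction[m] != "none"}
        assert de_sizes == {cfg.baseline_de_targets}

    def test_mti_table_matches_truth(self, small_instance):
        cfg, loci, truth = small_instance
        _, _, mti = synth.generate_interactions(cfg, truth, loci)
        by_mirna = mti.groupby("mirna")["gene"].apply(set).to_dict()
        for m in cfg.mirna_names:
            assert by_mirna.get(m, set()) == truth.curated_targets[m]


class TestDirectionRecovery:
    def test_zero_noise_full_direction_recovery(self):
        """Deterministic mode: 100% of planted DE directions recovered by the
        two-platform intersection."""
        cfg = synth.SyntheticConfig(n_mirnas=80, n_up_mirnas=15, n_down_mirnas=6,
                                    cluster_spec=("chr12", 109_500_000, 109_750_000, 10),
                                    noise_sd_log2=0.0, seed=6)
        loci = synth.generate_mirna_annotation(cfg)
        truth = synth.generate_truth(cfg, loci)
        ct, counts = synth.generate_expression(cfg, truth)
        calls_a = de_calling.call_de(de_calling.normalize_openarray(ct),
                                     platform="openarray")
        calls_s = de_calling.call_de(de_calling.seq_fold_changes(counts),
                                     platform="seq")
        demirs, _ = de_calling.intersect_platforms(calls_s, calls_a)
        found = {d.mirna: d.direction for d in demirs}
        for m in cfg.mirna_names:
            if truth.direction[m] != "none":
                assert found.get(m) == truth.direction[m]


class TestPaperFixtures:
    def test_row_counts(self, paper_tables):
        table1, table2 = paper_tables
        assert len(table1) == 65
        assert len(table2) == 65

    def test_direction_split(self, paper_tables):
        table1, _ = paper_tables
        assert (table1["direction"] == "up").sum() == 48
        assert (table1["direction"] == "down").sum() == 17

    def test_mir127_row(self, paper_tables):
        table1, _ = paper_tables
        row = table1.set_index("mirna").loc["miR-127-3p"]
        assert (row["chrom"], int(row["locus_start"]), int(row["locus_end"]),
                row["strand"]) == ("chr12", 109592846, 109592915, "+")
        assert float(row["seq_fc_value"]) == 61.60
        assert row["array_fc"] == "1.59E+01"
        assert float(row["array_fc_value"]) == pytest.approx(15.9)

    def test_mir17_row(self, paper_tables):
        _, table2 = paper_tables
        row = table2.set_index("mirna").loc["miR-17-5p"]
        assert (int(row["n_curated"]), int(row["n_de_targets"])) == (992, 115)

    def test_de_target_sums_by_direction(self, paper_tables):
        _, table2 = paper_tables
        sums = table2.groupby("direction")["n_de_targets"].sum()
        assert sums["up"] == 536
        assert sums["down"] == 531

    def test_same_mirnas_in_both_tables(self, paper_tables):
        table1, table2 = paper_tables
        assert set(table1["mirna"]) == set(table2["mirna"])

    def test_integrity_check_fires(self, monkeypatch):
        from miremap.exceptions import FixtureIntegrityError

        monkeypatch.setitem(synth._FIXTURE_CHECKSUMS, "demir_table.tsv", "0" * 64)
        with pytest.raises(FixtureIntegrityError):
            synth.load_paper_fixtures()


class TestManifest:
    def test_manifest_round_trip(self, tmp_path, small_instance):
        import json

        cfg, loci, truth = small_instance
        path = tmp_path / "truth.json"
        truth.write_manifest(path)
        data = json.loads(path.read_text())
        assert data["hub_degrees"] == {cfg.mirna_names[0]: 20}
        assert sorted(data["cotarget_mirnas"]) == sorted(truth.cotarget_mirnas)
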