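"""The scenario generator: classifier round-trips, sampling algebra, determinism."""

import filecmp
import json
import warnings

import numpy as np
import pandas as pd
import pytest

from asnmd.annotation import GenomeSequence, annotate_exons, parse_annotation
from asnmd.peaks import filter_peaks, merge_replicates_and_pool, within_window
from asnmd.synthetic_data import (
    Scenario,
    ScenarioConfig,
    build_scenario,
    sample_inclusion_counts,
    simulate_junction_counts,
    simulate_peaks,
    simulate_psi_table,
    write_scenario,
)


def _classified(scenario: Scenario, tmp_path):
    out = tmp_path / "sc"
    write_scenario(scenario, out)
    genes = parse_annotation(out / "annotation.gtf", out / "genome.fa")
    genome = GenomeSequence.from_fasta(str(out / "genome.fa"))
    return annotate_exons(genes, genome)


class TestClassifierRoundTrip:
    def test_poison_gene_yields_exactly_one_poison_exon(self, tmp_path):
        cfg = ScenarioConfig(seed=3, n_genes=4, n_poison_loops=1,
                             n_essential_loops=0, n_null_rbps=0)
        scenario = build_scenario(cfg)
        table = _classified(scenario, tmp_path)
        poison = table.loc[table["poison"]]
        assert len(poison) == 1
        truth = scenario.truth.set_index("gene_id")
        assert poison["exon_id"].iloc[0] == truth.loc["G0001", "exon_id"]
        assert poison["cassette"].all()  # poison implies cassette

    def test_essential_gene_cassette_is_essential_and_frameshifting(self, tmp_path):
        cfg = ScenarioConfig(seed=4, n_genes=4, n_poison_loops=0,
                             n_essential_loops=1, n_null_rbps=0)
        scenario = build_scenario(cfg)
        table = _classified(scenario, tmp_path)
        truth = scenario.truth.set_index("gene_id")
        row = table.set_index("exon_id").loc[truth.loc["G0001", "exon_id"]]
        assert bool(row["essential"])
        assert row["frame_class"] == "3n+1"
        assert not row["poison"]

    def test_null_gene_cassette_is_neither(self, tmp_path):
        cfg = ScenarioConfig(seed=5, n_genes=3, n_poison_loops=0,
                             n_essential_loops=0, n_null_rbps=1)
        scenario = build_scenario(cfg)
        table = _classified(scenario, tmp_path)
        truth = scenario.truth.set_index("gene_id")
        row = table.set_index("exon_id").loc[truth.loc["G0001", "exon_id"]]
        assert bool(row["cassette"])
        assert not row["poison"] and not row["essential"]

    def test_gwn_matches_planted_nmd_isoforms(self, tmp_path):
        cfg = ScenarioConfig(seed=6, n_genes=8, n_poison_loops=2,
                             n_essential_loops=2, n_null_rbps=2)
        scenario = build_scenario(cfg)
        out = tmp_path / "sc"
        write_scenario(scenario, out)
        genes = parse_annotation(out / "annotation.gtf", out / "genome.fa")
        gwn = {g.gene_id for g in genes if g.gwn}
        expected = set(
            scenario.truth.loc[
                scenario.truth["gene_class"].isin({"poison_loop", "essential_loop"}),
                "gene_id",
            ]
        )
        assert gwn == expected

    def test_derived_50nt_rule_agrees_with_planted_tags(self, tmp_path):
        """Re-labelling via the rule (tags ignored) matches the annotation."""
        from asnmd.annotation import label_nmd

        cfg = ScenarioConfig(seed=12, n_genes=10, n_poison_loops=3,
                             n_essential_loops=3, n_null_rbps=0)
        scenario = build_scenario(cfg)
        out = tmp_path / "sc"
        write_scenario(scenario, out)
        genes = parse_annotation(out / "annotation.gtf", out / "genome.fa")
        genome = GenomeSequence.from_fasta(str(out / "genome.fa"))
        for g in genes:
            for t in g.transcripts:
                tagged = t.biotype == "nonsense_mediated_decay"
                t.biotype = "protein_coding"
                assert label_nmd(t, genome) is tagged


class TestCountSampling:
    def test_full_inclusion_has_no_exclusion_reads(self):
        rng = np.random.default_rng(0)
        inc1, inc2, exc = sample_inclusion_counts(1.0, 500, rng)
        assert exc == 0 and inc1 + inc2 == 500

    def test_expected_inc_exc_ratio_at_half(self):
        rng = np.random.default_rng(1)
        draws = [sample_inclusion_counts(0.5, 3000, rng) for _ in range(200)]
        inc = np.array([a + b for a, b, _ in draws])
        exc = np.array([c for _, _, c in draws])
        assert np.mean(inc) / np.mean(exc) == pytest.approx(2.0, rel=0.02)

    def test_psi_estimator_unbiased(self):
        rng = np.random.default_rng(2)
        for phi in (0.1, 0.5, 0.9):
            table = simulate_psi_table(300, 1e4, phi, 0.0, (0.0, 0.0), rng)
            assert table["psi_kd"].mean() == pytest.approx(phi, abs=0.01)

    def test_null_condition_centers_dpsi_on_zero(self):
        cfg = ScenarioConfig(seed=7, n_genes=40, n_poison_loops=0,
                             n_essential_loops=0, n_null_rbps=0, beta1=0.0)
        scenario = build_scenario(cfg)
        table = simulate_junction_counts(scenario, "upf1_xrn1")
        assert (table["count"] >= 0).all()
        rng = np.random.default_rng(3)
        sim = simulate_psi_table(2000, 200, 0.5, 0.0, (0.0, 0.0), rng)
        assert abs(sim["dpsi_raw"].mean()) < 0.005

    def test_planted_shift_moves_psi(self):
        scenario = build_scenario(
            ScenarioConfig(seed=8, n_genes=6, n_poison_loops=3,
                           n_essential_loops=0, n_null_rbps=0, beta1=0.0,
                           log10_fc_range=(0.0, 0.0), depth=2000.0)
        )
        ctrl = simulate_junction_counts(scenario, "control")
        kd = simulate_junction_counts(scenario, "upf1_xrn1")
        truth = scenario.truth.set_index("gene_id")
        junc = scenario.junctions
        for gene in ["G0001", "G0002", "G0003"]:
            sub = junc[junc.gene_id == gene]
            def psi(tbl):
                m = tbl.merge(sub, left_on=["chrom", "intron_start", "intron_end", "strand"],
                              right_on=["chrom", "start", "end", "strand"])
                inc = m.loc[m.kind.isin(["inc1", "inc2"]), "count"].sum()
                exc = m.loc[m.kind == "skip", "count"].sum()
                return inc / (inc + 2 * exc)
            assert psi(kd) - psi(ctrl) == pytest.approx(
                truth.loc[gene, "delta_nmd"], abs=0.06
            )


class TestPeakSimulation:
    def test_loop_gene_has_filtered_pooled_peak_within_window(self):
        cfg = ScenarioConfig(seed=9, n_genes=10, n_poison_loops=2,
                             n_essential_loops=2, n_null_rbps=0)
        scenario = build_scenario(cfg)
        raw = simulate_peaks(scenario)
        truth = scenario.truth.set_index("gene_id")
        for gene, rbp in scenario.rbp_by_gene.items():
            sub = raw[raw.rbp == rbp]
            frames = [
                filter_peaks(grp.assign(name=".", score=0))
                for _, grp in sub.groupby(["cell_line", "replicate"])
            ]
            merged = merge_replicates_and_pool(frames)
            info = truth.loc[gene]
            exon = (info["chrom"], int(info["exon_start"]), int(info["exon_end"]),
                    info["strand"])
            assert within_window(exon, merged, 5000)

    def test_subthreshold_background_removed_by_filter(self):
        cfg = ScenarioConfig(seed=10, n_genes=10, n_poison_loops=1,
                             n_essential_loops=0, n_null_rbps=3,
                             background_peak_rate=1e-4,
                             subthreshold_peak_fraction=1.0)
        scenario = build_scenario(cfg)
        raw = simulate_peaks(scenario)
        bg = raw[raw.kind == "background"].assign(name=".", score=0)
        assert len(bg) > 0
        assert filter_peaks(bg).empty


class TestDeterminism:
    CFG = dict(n_genes=12, n_poison_loops=2, n_essential_loops=2, n_null_rbps=2)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        for d in (a, b):
            write_scenario(build_scenario(ScenarioConfig(seed=42, **self.CFG)), d)
        for rel in ["annotation.gtf", "genome.fa", "truth.tsv",
                    "counts/control.tsv", "counts/upf1_xrn1.tsv",
                    "sample_sheet.tsv", "peaks_manifest.tsv", "manifest.json"]:
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel

    def test_different_seed_differs(self, tmp_path):
        s1 = build_scenario(ScenarioConfig(seed=1, **self.CFG))
        s2 = build_scenario(ScenarioConfig(seed=2, **self.CFG))
        assert s1.genome["chr1"] != s2.genome["chr1"]

    def test_manifest_records_seed_and_sample_count(self, tmp_path):
        out = tmp_path / "sc"
        write_scenario(build_scenario(ScenarioConfig(seed=42, **self.CFG)), out)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 42
        # control + 2 NMD conditions + one KD per RBP gene
        assert manifest["n_samples"] == 3 + 6

    def test_existing_directory_not_overwritten(self, tmp_path):
        out = tmp_path / "sc"
        scenario = build_scenario(ScenarioConfig(seed=42, **self.CFG))
        write_scenario(scenario, out)
        with pytest.raises(FileExistsError):
            write_scenario(scenario, out)
        write_scenario(scenario, out, force=True)


class TestConfigValidation:
    def test_too_many_special_genes(self):
        with pytest.raises(ValueError):
            ScenarioConfig(seed=1, n_genes=5, n_poison_loops=10)

    def test_depth_bound(self):
        with pytest.raises(ValueError):
            ScenarioConfig(seed=1, depth=0.1)
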