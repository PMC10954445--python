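import dataclasses

import numpy as np
import pandas as pd
import pytest

from nrskit import simulate as sim
from nrskit.demo import small_config


class TestConfigValidation:
    def test_af_out_of_range_rejected(self):
        spec = sim.EventSpec("unique_novel", 100, {"AFR": 1.2})
        with pytest.raises(ValueError, match="outside"):
            spec.validate(["AFR"])

    def test_short_event_rejected(self):
        spec = sim.EventSpec("unique_novel", 30, {"AFR": 0.5})
        with pytest.raises(ValueError, match="50"):
            spec.validate(["AFR"])

    def test_unknown_class_rejected(self):
        spec = sim.EventSpec("inversion", 100, {"AFR": 0.5})
        with pytest.raises(ValueError, match="class"):
            spec.validate(["AFR"])

    def test_tagged_snp_beyond_window_rejected(self):
        cfg = dataclasses.replace(
            small_config(),
            snp_panel=sim.SnpPanelConfig(
                n_snps=1, tagged=(sim.TaggedSnp(0, 1.0, offset=150_000),)))
        with pytest.raises(ValueError, match="100 kb"):
            cfg.validate()

    def test_chrom_too_small_for_annotations(self):
        cfg = dataclasses.replace(small_config(), chrom_length=10_000)
        with pytest.raises(ValueError, match="too small"):
            sim.build_reference(cfg)


class TestBuildReference:
    def test_deterministic(self, small_cfg, small_ref):
        again = sim.build_reference(small_cfg)
        assert again.sequences == small_ref.sequences
        assert again.satellites == small_ref.satellites

    def test_satellite_intervals_are_tandem_monomers(self, small_ref):
        from nrskit.seqcore.taxon import load_bundled_satellites
        monomers = load_bundled_satellites()
        for chrom, start, end, name in small_ref.satellites:
            segment = small_ref.sequences[chrom][start:end]
            monomer = monomers[name]
            expect = (monomer * (len(segment) // len(monomer) + 1))
            assert segment == expect[:len(segment)]

    def test_satellites_present_per_chromosome(self, small_cfg, small_ref):
        chroms = {s[0] for s in small_ref.satellites}
        assert chroms == set(small_ref.sequences)

    def test_no_satellites_configured(self, small_cfg):
        cfg = dataclasses.replace(small_cfg,
                                  n_satellite_arrays_per_chrom=0)
        ref = sim.build_reference(cfg)
        assert ref.satellites == []

    def test_genes_have_tss_inside_gene(self, small_ref):
        for gene in small_ref.genes:
            assert gene.start <= gene.tss < gene.end


class TestSimulatePopulation:
    def test_af_one_everywhere_homozygous(self, small_ref):
        cfg = dataclasses.replace(
            small_config(),
            events=(sim.EventSpec("unique_novel", 100,
                                  {"AFR": 1.0, "EAS": 1.0}),))
        truth = sim.simulate_population(small_ref, cfg)
        event = truth.events[0]
        assert all(event.presence[s.sample] == (True, True)
                   for s in truth.samples)

    def test_af_zero_absent_everywhere(self, small_ref):
        cfg = dataclasses.replace(
            small_config(),
            events=(sim.EventSpec("unique_novel", 100,
                                  {"AFR": 0.0, "EAS": 0.0}),))
        truth = sim.simulate_population(small_ref, cfg)
        assert not truth.events[0].carrier_samples()

    def test_empirical_af_binomial(self):
        # large panel: empirical AF within 3 standard errors of 0.3
        cfg = sim.SimConfig(
            n_chromosomes=1, chrom_length=400_000,
            n_samples_per_population={"POP": 5000},
            events=(sim.EventSpec("unique_novel", 100, {"POP": 0.3}),),
            n_genes_per_chrom=2, seed=5)
        ref = sim.build_reference(cfg)
        truth = sim.simulate_population(ref, cfg)
        event = truth.events[0]
        alleles = [int(h) for s in truth.samples
                   for h in event.presence[s.sample]]
        af = np.mean(alleles)
        se = np.sqrt(0.3 * 0.7 / len(alleles))
        assert abs(af - 0.3) < 3 * se

    def test_trio_children_mendelian_consistent(self, small_truth):
        assert small_truth.trio_pedigree
        for event in small_truth.events:
            for child, (father, mother) in small_truth.trio_pedigree.items():
                ch = event.presence[child]
                assert ch[0] in event.presence[father]
                assert ch[1] in event.presence[mother]

    def test_determinism(self, small_cfg, small_ref, small_truth):
        again = sim.simulate_population(small_ref, small_cfg)
        assert [e.sequence for e in again.events] == \
            [e.sequence for e in small_truth.events]
        assert [e.presence for e in again.events] == \
            [e.presence for e in small_truth.events]

    def test_event_ids_unique(self, small_truth):
        ids = [e.event_id for e in small_truth.events]
        assert len(set(ids)) == len(ids)


class TestEmitAssemblies:
    def test_heterozygous_event_fully_contained_with_flanks(
            self, small_cfg, small_ref, small_truth, small_assemblies):
        checked = 0
        for event in small_truth.events:
            for info in small_truth.samples:
                if not any(event.presence[info.sample]):
                    continue
                contigs = small_assemblies[info.sample].contigs
                found = any(
                    (i := seq.find(event.sequence)) >= 1000
                    and len(seq) - i - len(event.sequence) >= 1000
                    for seq in contigs.values())
                assert found, (event.event_id, info.sample)
                checked += 1
                break
        assert checked > 0

    def test_no_contaminants_by_default(self, small_assemblies):
        for assembly in small_assemblies.values():
            assert not any("contaminant" in name
                           for name in assembly.contigs)

    def test_contaminant_fraction(self, small_cfg, small_ref, small_truth):
        cfg = dataclasses.replace(small_cfg, contaminant_fraction=0.3)
        assembly = sim.emit_assembly(small_ref, small_truth, cfg,
                                     small_truth.samples[0].sample)
        n_cont = sum(1 for n in assembly.contigs if "contaminant" in n)
        n_host = len(assembly.contigs) - n_cont
        assert n_cont == round(0.3 * n_host / 0.7)

    def test_depth_bait_recorded_and_offset(self, small_cfg, small_ref,
                                            small_truth):
        sample = small_truth.samples[0].sample
        cfg = dataclasses.replace(
            small_cfg, depth_baits=(sim.DepthBait(sample, 3.5),))
        truth = sim.simulate_population(small_ref, cfg)
        assembly = sim.emit_assembly(small_ref, truth, cfg, sample)
        assert truth.depth_baits
        _, contig, start, end, depth = truth.depth_baits[0]
        assert depth == pytest.approx(3.5 * cfg.depth_mean)
        rows = [r for r in assembly.depth_track if r[0] == contig]
        assert any(r[3] == pytest.approx(3.5 * cfg.depth_mean)
                   for r in rows)

    def test_fragmentation_labels_unanchorable(self, small_cfg, small_ref):
        cfg = dataclasses.replace(small_cfg, fragmentation_rate=1 / 20_000)
        truth = sim.simulate_population(small_ref, cfg)
        for info in truth.samples:
            sim.emit_assembly(small_ref, truth, cfg, info.sample)
        # heavy fragmentation must label at least one occurrence
        assert truth.unanchorable

    def test_determinism(self, small_cfg, small_ref, small_truth,
                         small_assemblies):
        sample = small_truth.samples[0].sample
        again = sim.emit_assembly(small_ref, small_truth, small_cfg, sample)
        assert again.contigs == small_assemblies[sample].contigs
        assert again.depth_track == small_assemblies[sample].depth_track


class TestExpressionAndPhenotypes:
    def test_noise_free_dosage_steps(self, small_ref):
        cfg = dataclasses.replace(
            small_config(),
            events=(sim.EventSpec("unique_novel", 100,
                                  {"AFR": 0.5, "EAS": 0.5}),),
            eqtl_effects=((0, "chr1_g1", 1.0),))
        truth = sim.simulate_population(small_ref, cfg)
        expr = sim.simulate_expression(truth, cfg, small_ref, noise_sd=0.0)
        event = truth.events[0]
        row = expr.loc["chr1_g1"]
        baseline = min(row[s.sample] - event.dosage(s.sample)
                       for s in truth.samples)
        for info in truth.samples:
            assert row[info.sample] == pytest.approx(
                baseline + event.dosage(info.sample))

    def test_unknown_transcript_rejected(self, small_ref):
        cfg = dataclasses.replace(
            small_config(),
            events=(sim.EventSpec("unique_novel", 100,
                                  {"AFR": 0.5, "EAS": 0.5}),),
            eqtl_effects=((0, "nope", 1.0),))
        truth = sim.simulate_population(small_ref, cfg)
        with pytest.raises(ValueError, match="TSS"):
            sim.simulate_expression(truth, cfg, small_ref)

    def test_phenotype_covariates_present(self, small_truth, small_cfg):
        table = sim.simulate_phenotypes(small_truth, small_cfg)
        assert {"age", "sex", "BMI", "trait_q"} <= set(table.columns)
        assert len(table) == len(small_truth.samples)


class TestSnpPanel:
    def _cfg(self, r2, offset=50_000, n_snps=5):
        return dataclasses.replace(
            small_config(),
            events=(sim.EventSpec("unique_novel", 100,
                                  {"AFR": 0.5, "EAS": 0.5}),),
            snp_panel=sim.SnpPanelConfig(
                n_snps=n_snps, tagged=(sim.TaggedSnp(0, r2, offset),)))

    def test_r2_one_identical_dosage(self, small_ref):
        cfg = self._cfg(1.0)
        truth = sim.simulate_population(small_ref, cfg)
        genos, table = sim.simulate_snp_panel(truth, cfg, small_ref)
        event = truth.events[0]
        tagged = table.loc[table["tagged_event"] == event.event_id,
                           "snp"].iloc[0]
        for info in truth.samples:
            assert genos.at[tagged, info.sample] == event.dosage(info.sample)

    def test_r2_zero_uncorrelated(self):
        cfg = dataclasses.replace(
            self._cfg(0.0),
            n_samples_per_population={"AFR": 250, "EAS": 250})
        ref = sim.build_reference(cfg)
        truth = sim.simulate_population(ref, cfg)
        genos, table = sim.simulate_snp_panel(truth, cfg, ref)
        event = truth.events[0]
        tagged = table.loc[table["tagged_event"] == event.event_id,
                           "snp"].iloc[0]
        dosage = np.array([event.dosage(s.sample) for s in truth.samples])
        snp = genos.loc[tagged].to_numpy()
        r = np.corrcoef(dosage, snp)[0, 1]
        assert r * r < 0.1

    def test_untagged_count(self, small_ref):
        cfg = self._cfg(1.0, n_snps=5)
        truth = sim.simulate_population(small_ref, cfg)
        genos, table = sim.simulate_snp_panel(truth, cfg, small_ref)
        assert len(genos) == 5
        assert (table["tagged_event"] != "").sum() == 1
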