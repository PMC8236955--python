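"""Synthetic panel / evidence / cohort generator: determinism, calibration,
round-trips."""

import filecmp

import numpy as np
import pytest

from hnsomatic.msi import call_msi_sample
from hnsomatic.synthetic import (
    ANATOMIC_SITES, CohortConfig, FusionTruth, SampleTruth, SomaticVariant,
    expected_tumor_vaf, generate_panel, read_fixtures, simulate_cohort,
    simulate_sample_evidence, write_fixtures,
)


class TestGeneratePanel:
    def test_default_scale_panel(self):
        panel = generate_panel(383, 5, seed=1)
        assert len(panel.genes) == 383
        assert len(panel.ms_loci) == 100
        assert len(panel.bins) == 383 * 5
        assert 4000 <= len(panel.snp_loci) <= 6000  # ~5,000 SNP loci

    def test_named_landscape_genes_present(self):
        panel = generate_panel(12, 2, seed=0)
        for name in ("TP53", "CYLD", "BAP1", "PIK3CA", "CDKN2A", "CCND1",
                     "FGF3", "FGF4", "FGF19", "TEX10", "NTRK2"):
            assert panel.has_gene(name)
        assert any(d[0] == "tyrosine_kinase" for d in panel.gene("NTRK2").domains)

    def test_single_gene_panel_valid(self):
        panel = generate_panel(1, 1, seed=1)
        assert len(panel.genes) == 1
        gene = panel.genes[0]
        assert all(s < e for s, e in gene.exons)

    def test_deterministic_for_fixed_seed(self):
        assert generate_panel(15, 3, seed=9) == generate_panel(15, 3, seed=9)

    def test_different_seed_differs(self):
        assert generate_panel(15, 3, seed=9) != generate_panel(15, 3, seed=10)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            generate_panel(0, 5, seed=1)
        with pytest.raises(ValueError):
            generate_panel(5, 0, seed=1)

    def test_gc_fractions_in_range(self, small_panel):
        assert all(0.0 <= b.gc_fraction <= 1.0 for b in small_panel.bins)

    def test_exons_sorted_nonoverlapping(self, small_panel):
        for gene in small_panel.genes:
            for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
                assert e1 <= s2

    def test_11q13_block_contiguous(self, small_panel):
        block = [small_panel.gene(n) for n in ("CCND1", "FGF4", "FGF3", "FGF19")]
        assert len({g.chromosome for g in block}) == 1
        span = max(g.end for g in block) - min(g.start for g in block)
        assert span < 1_000_000


class TestSampleTruthValidation:
    def test_purity_below_20_percent_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            SampleTruth("S", "larynx", purity=0.1, ploidy=2.0)

    def test_msi_status_consistent_with_75_rule(self):
        with pytest.raises(ValueError, match="75"):
            SampleTruth("S", "larynx", 0.5, 2.0, msi_status="MSI-H",
                        unstable_locus_count=10)
        with pytest.raises(ValueError, match="75"):
            SampleTruth("S", "larynx", 0.5, 2.0, msi_status="MSS",
                        unstable_locus_count=80)


class TestSimulateSampleEvidence:
    def test_spiked_vaf_unbiased(self, tiny_panel):
        config = CohortConfig(seed=0, n_genes=len(tiny_panel.genes),
                              noise_sites=0, germline_sites=0)
        gene = tiny_panel.gene("TP53")
        variant = SomaticVariant("TP53", gene.chromosome, gene.exons[0][0] + 5,
                                 "C", "T", vaf=0.5, consequence="exonic",
                                 variant_class="missense")
        truth = SampleTruth("S", "larynx", purity=1.0, ploidy=2.0,
                            somatic_variants=(variant,))
        fractions = []
        for rep in range(100):
            ev = simulate_sample_evidence(truth, tiny_panel, config, seed=rep)
            site = ev.pileup_sites[0]
            fractions.append(site.tumor_alt / site.tumor_depth)
        v, depth = 0.5, 730
        tol = 3 * np.sqrt(v * (1 - v) / depth) / np.sqrt(100)
        assert np.mean(fractions) == pytest.approx(v, abs=3 * tol)

    def test_purity_scales_expected_vaf(self):
        assert expected_tumor_vaf(0.5, 1.0) == pytest.approx(0.5)
        assert expected_tumor_vaf(0.5, 0.4) == pytest.approx(0.2)

    def test_normal_carries_no_somatic_signal(self, tiny_panel):
        config = CohortConfig(seed=0, n_genes=len(tiny_panel.genes),
                              noise_sites=0, germline_sites=0)
        gene = tiny_panel.gene("TP53")
        variant = SomaticVariant("TP53", gene.chromosome, gene.exons[0][0] + 5,
                                 "C", "T", 0.5, "exonic", "missense")
        truth = SampleTruth("S", "larynx", 1.0, 2.0, (variant,))
        alt_fracs = []
        for rep in range(50):
            ev = simulate_sample_evidence(truth, tiny_panel, config, seed=rep)
            s = ev.pileup_sites[0]
            alt_fracs.append(s.normal_alt / s.normal_depth)
        assert np.mean(alt_fracs) < 5 * config.error_rate

    def test_fusion_emits_spanning_read_pairs(self, small_panel):
        config = CohortConfig(seed=1, n_genes=len(small_panel.genes))
        truth = SampleTruth("S", "larynx", 0.8, 2.0,
                            fusions=(FusionTruth("TEX10", 9, "NTRK2", 15),))
        ev = simulate_sample_evidence(truth, small_panel, config, seed=1)
        tex10 = small_panel.gene("TEX10")
        ntrk2 = small_panel.gene("NTRK2")
        spanning = [
            r for r in ev.discordant_reads
            if {r.end1.chrom, r.end2.chrom} == {tex10.chromosome, ntrk2.chromosome}
            and r.read_id.startswith("fus")
        ]
        assert len(spanning) >= config.fusion_read_pairs

    def test_mss_sample_no_shifted_loci(self, tiny_panel):
        config = CohortConfig(seed=2, n_genes=len(tiny_panel.genes))
        truth = SampleTruth("S", "larynx", 0.9, 2.0, msi_status="MSS",
                            unstable_locus_count=0)
        ev = simulate_sample_evidence(truth, tiny_panel, config, seed=2)
        result = call_msi_sample(ev.ms_histograms)
        assert result.unstable_count <= 15  # only alpha-level false positives

    def test_variant_outside_panel_names_gene_and_position(self, tiny_panel):
        variant = SomaticVariant("NOT_A_GENE", "chrX", 123, "C", "T", 0.5,
                                 "exonic", "missense")
        truth = SampleTruth("S", "larynx", 0.5, 2.0, (variant,))
        config = CohortConfig(seed=0, n_genes=len(tiny_panel.genes))
        with pytest.raises(ValueError, match="NOT_A_GENE.*123"):
            simulate_sample_evidence(truth, tiny_panel, config, seed=0)

    def test_pileup_sites_within_panel(self, tiny_panel):
        config = CohortConfig(seed=3, n_genes=len(tiny_panel.genes),
                              site_counts={"larynx": 1})
        truth, ev = simulate_cohort(config, tiny_panel)[0]
        for site in ev.pileup_sites:
            gene = tiny_panel.gene_at(site.chrom, site.pos)
            if gene is None:  # splice-region sites sit just past an exon end
                assert any(
                    g.chromosome == site.chrom
                    and g.start - 2 <= site.pos < g.end + 2
                    for g in tiny_panel.genes)

    def test_deterministic_for_fixed_seed(self, tiny_panel):
        config = CohortConfig(seed=4, n_genes=len(tiny_panel.genes))
        truth = SampleTruth("S", "larynx", 0.5, 2.0)
        ev1 = simulate_sample_evidence(truth, tiny_panel, config, seed=7)
        ev2 = simulate_sample_evidence(truth, tiny_panel, config, seed=7)
        assert ev1 == ev2


class TestSimulateCohort:
    def test_poisson_load_means_recovered(self, tiny_panel):
        config = CohortConfig(
            seed=5, n_genes=len(tiny_panel.genes),
            site_counts={"nasopharynx": 500, "larynx": 500},
            gene_mutation_freq={}, msi_h_rate=0.0, fusion_rate=0.0,
            amp11q13_rate=0.0, cdkn2a_loss_rate=0.0)
        cohort = simulate_cohort(config, tiny_panel)
        for site, mean in (("nasopharynx", 3.6), ("larynx", 8.3)):
            counts = [len(t.somatic_variants) for t, _ in cohort
                      if t.anatomic_site == site]
            se = np.sqrt(mean / len(counts))
            assert np.mean(counts) == pytest.approx(mean, abs=3 * se)

    def test_single_site_single_sample(self, tiny_panel):
        config = CohortConfig(seed=6, n_genes=len(tiny_panel.genes),
                              site_counts={"oral_cavity": 1})
        cohort = simulate_cohort(config, tiny_panel)
        assert len(cohort) == 1
        assert cohort[0][0].anatomic_site == "oral_cavity"

    def test_tp53_frequencies_recovered_at_study_sizes(self, tiny_panel):
        freqs = {("TP53", "hypopharynx"): 0.861, ("TP53", "larynx"): 0.900,
                 ("TP53", "nasopharynx"): 0.241, ("TP53", "oral_cavity"): 0.703}
        config = CohortConfig(
            seed=7, n_genes=len(tiny_panel.genes),
            site_counts={"hypopharynx": 36, "larynx": 60,
                         "nasopharynx": 83, "oral_cavity": 111},
            gene_mutation_freq=freqs, msi_h_rate=0.0, fusion_rate=0.0,
            amp11q13_rate=0.0, cdkn2a_loss_rate=0.0)
        cohort = simulate_cohort(config, tiny_panel)
        for (gene, site), f in freqs.items():
            group = [t for t, _ in cohort if t.anatomic_site == site]
            hits = sum(any(v.gene == gene for v in t.somatic_variants)
                       for t in group)
            n = len(group)
            se = np.sqrt(f * (1 - f) / n)
            assert hits / n == pytest.approx(f, abs=3.5 * se)

    def test_spectrum_matches_weights(self, tiny_panel):
        config = CohortConfig(seed=8, n_genes=len(tiny_panel.genes),
                              site_counts={"larynx": 200}, indel_fraction=0.0)
        cohort = simulate_cohort(config, tiny_panel)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        counts = dict.fromkeys(config.spectrum_weights, 0)
        total = 0
        for t, _ in cohort:
            for v in t.somatic_variants:
                ref, alt = v.ref, v.alt
                if ref in "AG":
                    ref, alt = comp[ref], comp[alt]
                counts[f"{ref}>{alt}"] += 1
                total += 1
        for cls, w in config.spectrum_weights.items():
            se = np.sqrt(w * (1 - w) / total)
            assert counts[cls] / total == pytest.approx(w, abs=4 * se)

    def test_invalid_frequency_rejected(self, tiny_panel):
        config = CohortConfig(seed=9, gene_mutation_freq={("TP53", "larynx"): 1.7})
        with pytest.raises(ValueError, match="outside"):
            simulate_cohort(config, tiny_panel)

    def test_invalid_spectrum_rejected(self):
        config = CohortConfig(spectrum_weights={"C>T": 1.5, "C>A": 0.5,
                                                "C>G": 0, "T>A": 0, "T>C": 0,
                                                "T>G": 0})
        with pytest.raises(ValueError, match="spectrum"):
            config.validate()


class TestFixtures:
    def _cohort(self, tiny_panel, n=2):
        config = CohortConfig(seed=10, n_genes=len(tiny_panel.genes),
                              site_counts={"larynx": n}, fusion_rate=1.0,
                              amp11q13_rate=1.0, msi_h_rate=0.5)
        return config, simulate_cohort(config, tiny_panel)

    def test_round_trip_equality(self, tiny_panel, tmp_path):
        _, cohort = self._cohort(tiny_panel)
        write_fixtures(cohort, tmp_path, tiny_panel)
        panel_back, cohort_back = read_fixtures(tmp_path)
        assert panel_back == tiny_panel
        assert cohort_back == cohort

    def test_empty_cohort_valid_files(self, tiny_panel, tmp_path):
        files = write_fixtures([], tmp_path, tiny_panel)
        for name in files:
            assert (tmp_path / name).exists()
        panel_back, cohort_back = read_fixtures(tmp_path)
        assert cohort_back == []
        assert panel_back == tiny_panel

    def test_identical_bytes_across_runs(self, tiny_panel, tmp_path):
        _, cohort = self._cohort(tiny_panel)
        dir1, dir2 = tmp_path / "a", tmp_path / "b"
        files = write_fixtures(cohort, dir1, tiny_panel)
        write_fixtures(cohort, dir2, tiny_panel)
        for name in files:
            assert filecmp.cmp(dir1 / name, dir2 / name, shallow=False), name
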