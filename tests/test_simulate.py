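"""The ground-truth generator: determinism, planted structure, recovery scoring."""

import dataclasses

import numpy as np
import pytest

import meripscan as ms
from meripscan.peakcalling import Peak
from meripscan.simulate import MOTIF, write_motifs


def small_params(**kw):
    defaults = dict(n_genes=20, sites_per_gene=1, site_enrichment=8.0,
                    coverage=20.0, seed=1)
    defaults.update(kw)
    return ms.SimulationParams(**defaults)


class TestGenerateTranscriptome:
    def test_counts(self):
        models, seqs = ms.generate_transcriptome(ms.SimulationParams(n_genes=50, seed=1))
        assert len(models) == 50 and len(seqs) == 50
        for g, m in models.items():
            assert len(seqs[g]) == m.length

    def test_seed_determinism(self):
        p = small_params()
        m1, s1 = ms.generate_transcriptome(p)
        m2, s2 = ms.generate_transcriptome(p)
        assert m1 == m2 and s1 == s2

    def test_multi_exon_length_is_exon_sum(self):
        models, _ = ms.generate_transcriptome(small_params(multi_exon=True))
        for m in models.values():
            span = m.exons[-1][1] - m.exons[0][0]
            assert m.length == sum(e - s for s, e in m.exons)
            if len(m.exons) > 1:
                assert m.length < span

    def test_coding_partition(self):
        models, _ = ms.generate_transcriptome(small_params())
        for m in models.values():
            assert 0 < m.cds_start < m.cds_end < m.length


class TestPlantSites:
    def test_one_site_per_gene(self):
        models, _ = ms.generate_transcriptome(small_params(n_genes=50))
        sites = ms.plant_sites(models, small_params(n_genes=50))
        assert len(sites) == 50
        assert {s.gene_id for s in sites} == set(models)

    def test_null_effect_when_knockdown_effect_one(self):
        p = small_params(knockdown_effect=1.0)
        models, _ = ms.generate_transcriptome(p)
        for s in ms.plant_sites(models, p):
            assert s.enrichment("control", p) == s.enrichment("knockdown", p)

    def test_responder_fraction_binomial(self):
        p = ms.SimulationParams(n_genes=200, sites_per_gene=1,
                                fto_target_fraction=0.5, seed=1)
        models, _ = ms.generate_transcriptome(p)
        sites = ms.plant_sites(models, p)
        n_resp = sum(s.responds_to_knockdown for s in sites)
        # binomial(200, 0.5): mean 100, sd ~7
        assert abs(n_resp - 100) < 30

    def test_sites_separated_and_in_bounds(self):
        p = small_params(sites_per_gene=3)
        models, _ = ms.generate_transcriptome(p)
        sites = ms.plant_sites(models, p)
        by_gene = {}
        for s in sites:
            by_gene.setdefault(s.gene_id, []).append(s.position)
            assert 0 <= s.position < models[s.gene_id].length
        for positions in by_gene.values():
            positions.sort()
            assert all(b - a >= 100 for a, b in zip(positions, positions[1:]))

    def test_motif_written_at_sites(self):
        p = small_params()
        models, seqs = ms.generate_transcriptome(p)
        sites = ms.plant_sites(models, p)
        seqs = write_motifs(seqs, sites)
        for s in sites:
            assert seqs[s.gene_id][s.position:s.position + len(MOTIF)] == MOTIF

    def test_motif_density_higher_at_sites(self):
        ds = ms.simulate_dataset(small_params(n_genes=50))
        site_hits = sum(
            ds.seqs[s.gene_id][s.position:s.position + 5] == MOTIF
            for s in ds.sites
        )
        site_rate = site_hits / len(ds.sites)  # per planted position
        bg_rate = (
            sum(seq.count(MOTIF) for seq in ds.seqs.values())
            / sum(len(seq) for seq in ds.seqs.values())
        )
        assert site_rate > bg_rate


class TestSimulateReads:
    def test_determinism(self):
        ds1 = ms.simulate_dataset(small_params())
        ds2 = ms.simulate_dataset(small_params())
        assert ds1.reads == ds2.reads
        assert ds1.sites == ds2.sites

    def test_coverage_scaling(self):
        p1 = small_params(site_enrichment=1.0, coverage=20)
        p2 = small_params(site_enrichment=1.0, coverage=40)
        n1 = len(ms.simulate_dataset(p1).reads["control"][1])
        n2 = len(ms.simulate_dataset(p2).reads["control"][1])
        assert n2 / n1 == pytest.approx(2.0, rel=0.1)

    def test_reads_have_read_length(self):
        ds = ms.simulate_dataset(small_params())
        for ip, inp in ds.reads.values():
            assert {r.length for r in ip} == {80}
            assert {r.sample for r in ip} == {"IP"}
            assert {r.sample for r in inp} == {"input"}

    def test_ip_covers_sites_more_than_input(self):
        ds = ms.simulate_dataset(small_params())
        params = ds.params
        F = params.fragment_length
        for s in ds.sites:
            model = ds.models[s.gene_id]
            ip, inp = ds.reads["control"]

            def frag_covers(r):
                iv = ms.genome_to_transcript(
                    ms.extend_read(r, F), model
                )
                return iv is not None and iv.start <= s.position < iv.end

            n_ip = sum(frag_covers(r) for r in ip if r.chrom == model.chrom)
            n_in = sum(frag_covers(r) for r in inp if r.chrom == model.chrom)
            assert n_ip > n_in  # 8-fold site at 20x: overwhelmingly likely


class TestRecovery:
    def site(self, gene="g", pos=500):
        return ms.PlantedSite(gene_id=gene, position=pos, region="cds",
                              base_enrichment=8.0, responds_to_knockdown=False)

    def peak(self, gene="g", start=450, end=560):
        return Peak(gene_id=gene, start=start, end=end, n_windows=1,
                    peak_es=4.0, summit=(start + end) // 2, min_q=1e-3)

    def test_perfect_calls(self):
        rep = ms.evaluate_recovery([self.peak()], [self.site()])
        assert rep.sensitivity == 1.0 and rep.precision == 1.0

    def test_zero_peaks(self):
        rep = ms.evaluate_recovery([], [self.site()])
        assert rep.sensitivity == 0.0

    def test_tolerance_window(self):
        # peak [0, 100), site at 149 -> recovered at tol 50, not at tol 49
        site = self.site(pos=149)
        peak = self.peak(start=0, end=100)
        assert ms.evaluate_recovery([peak], [site], tolerance=50).sensitivity == 1
        assert ms.evaluate_recovery([peak], [site], tolerance=49).sensitivity == 0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            ms.evaluate_recovery([self.peak()], [])

    def test_per_region_breakdown(self):
        sites = [self.site(pos=500),
                 ms.PlantedSite("g", 900, "utr3", 8.0, False)]
        rep = ms.evaluate_recovery([self.peak()], sites)
        assert rep.per_region_sensitivity == {"cds": 1.0, "utr3": 0.0}


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(n_genes=0), dict(fragment_length=50), dict(coverage=0),
         dict(fto_target_fraction=1.5), dict(knockdown_effect=0)],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            ms.SimulationParams(**kw).validate()

    def test_qpcr_noise_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            ms.simulate_qpcr({"X": 2.0}, noise_sd=-1)
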