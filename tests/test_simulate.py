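"""The synthetic study generator: structure, determinism, Mendelian audit."""

import json

import numpy as np
import pytest

from exomesieve import io as esio
from exomesieve.core import chromosome_class
from exomesieve.coverage import bin_exons, bin_proportions
from exomesieve.simulate import ConfigError, SimulationConfig, simulate

from conftest import small_config


class TestAnnotation:
    def test_gene_and_exon_counts(self):
        cfg = small_config(
            n_genes=10, exons_per_gene=3, single_exon_gene_fraction=0.0,
            n_variants=50, n_noncoding=30, n_sv_events=10,
        )
        ds = simulate(cfg)
        assert len(ds.genes) == 10
        assert len(ds.exons) == 30
        assert sum(1 for e in ds.exons if e.is_first_exon) == 10

    def test_single_exon_fraction_one(self):
        cfg = small_config(
            single_exon_gene_fraction=1.0, n_variants=50, n_noncoding=30,
            n_sv_events=10,
        )
        ds = simulate(cfg)
        assert all(len(g.exons) == 1 for g in ds.genes)

    def test_gene_loci_do_not_overlap(self, ds_small):
        by_chrom = {}
        for g in ds_small.genes:
            span = (g.exons[0].start, g.exons[-1].end)
            by_chrom.setdefault(g.chrom, []).append(span)
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestConfigValidation:
    def test_bad_rate_names_field(self):
        cfg = SimulationConfig(seed=1, common_fraction=1.4)
        with pytest.raises(ConfigError, match="common_fraction"):
            cfg.validate()

    def test_planting_needs_four_families(self):
        with pytest.raises(ConfigError, match="n_families"):
            SimulationConfig(seed=1, n_families=2).validate()

    def test_yaml_unknown_field_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 3\nbogus_field: 1\n")
        with pytest.raises(ConfigError, match="bogus_field"):
            SimulationConfig.from_yaml(p)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=9)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SimulationConfig.from_yaml(p) == cfg


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config(seed=21, n_variants=120, n_noncoding=60, n_sv_events=25)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate(cfg).write(d1)
        simulate(small_config(seed=21, n_variants=120, n_noncoding=60,
                              n_sv_events=25)).write(d2)
        files = sorted(f.name for f in d1.iterdir() if not f.name.endswith(".fai"))
        assert files == sorted(f.name for f in d2.iterdir() if not f.name.endswith(".fai"))
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seed_differs(self):
        a = simulate(small_config(seed=1, n_variants=100, n_noncoding=40, n_sv_events=20))
        b = simulate(small_config(seed=2, n_variants=100, n_noncoding=40, n_sv_events=20))
        assert a.reference["chr1"] != b.reference["chr1"]


class TestCohortGenetics:
    def test_mendelian_transmission_audit(self, ds_small):
        """Every child allele is traceable to a parent allele, except the
        planted de novo variants listed in the truth set."""
        planted_dn = {
            tuple(k)[:2]
            for specs in ds_small.truth.values()
            for spec in specs
            if spec["model"] == "de_novo_dominant"
            for k in spec["keys"]
        }
        by_id = {m.id: m for p in ds_small.pedigrees for m in p.members}
        for rec in ds_small.cohort_records:
            if (rec.chrom, rec.pos) in planted_dn:
                continue
            cls = chromosome_class(rec.chrom)
            for ped in ds_small.pedigrees:
                fa = next(m for m in ped.members if m.sex == "male" and m.is_founder)
                mo = next(m for m in ped.members if m.sex == "female" and m.is_founder)
                fg, mg = set(rec.genotypes[fa.id]), set(rec.genotypes[mo.id])
                for m in ped.members:
                    if m.is_founder:
                        continue
                    child = rec.genotypes[m.id]
                    if cls == "X" and m.sex == "male":
                        assert len(child) == 1 and child[0] in mg
                    elif cls == "X":
                        assert child[0] in fg and child[1] in mg
                    else:
                        assert child[0] in fg and child[1] in mg

    def test_founder_frequencies_match_spectrum(self):
        """Founder alt-allele fraction across common sites agrees with the
        configured spectrum mean within binomial error."""
        cfg = small_config(seed=5, n_families=10, n_variants=600,
                           multiallelic_fraction=0.0, plant_causal=False)
        ds = simulate(cfg)
        founders = [f.id for p in ds.pedigrees for f in p.founders]
        fractions = []
        for rec in ds.cohort_records:
            if rec.chrom != "chr1":
                continue
            alleles = [a for f in founders for a in rec.genotypes[f]]
            fractions.append(np.mean([a != 0 for a in alleles]))
        mean_expected = (
            cfg.common_fraction * (cfg.common_maf_low + cfg.common_maf_high) / 2
            + (1 - cfg.common_fraction) * cfg.rare_maf
        )
        assert np.mean(fractions) == pytest.approx(mean_expected, abs=0.02)

    def test_planted_models_present(self, ds_small):
        models = {s["model"] for specs in ds_small.truth.values() for s in specs}
        assert models == {
            "de_novo_dominant", "hom_recessive", "compound_het", "x_linked"
        }


class TestDepthModel:
    def test_dip_factor_zero_blanks_first_exons(self):
        cfg = small_config(seed=4, first_exon_dip=0.0, exon_dropout_rate=0.0,
                           systematic_low_exon_fraction=0.0,
                           n_variants=50, n_noncoding=30, n_sv_events=10)
        ds = simulate(cfg)
        sample = ds.probands[0]
        for rec in bin_exons(ds.depth[sample], ds.exons):
            if rec.exon.is_first_exon:
                assert rec.all_zero

    def test_clean_config_has_no_low_bins(self):
        cfg = small_config(seed=4, first_exon_dip=1.0, exon_dropout_rate=0.0,
                           systematic_low_exon_fraction=0.0,
                           base_dropout_rate=0.0, mean_depth=120.0,
                           n_variants=50, n_noncoding=30, n_sv_events=10)
        ds = simulate(cfg)
        for sample in ds.probands:
            props = bin_proportions(bin_exons(ds.depth[sample], ds.exons))
            assert props["min_lt_20"] == 0.0

    def test_systematic_exons_low_in_every_sample(self, ds_small):
        from exomesieve.coverage import cross_sample_consistency

        per = {s: bin_exons(t, ds_small.exons) for s, t in ds_small.depth.items()}
        res = cross_sample_consistency(per)
        # the generator plants shared capture-failure exons; with 6 samples
        # some survive the per-sample dropout noise
        assert len(res["consistently_low_exons"]) >= 1


class TestNoncodingAndSv:
    def test_benign_fraction_one_kills_not_benign_stage(self):
        from exomesieve.founders import cohort_founder_frequencies
        from exomesieve.noncoding import ExonDistanceIndex, NoncodingVariant, noncoding_funnel

        cfg = small_config(seed=6, benign_fraction=1.0,
                           n_variants=50, n_noncoding=120, n_sv_events=10)
        ds = simulate(cfg)
        nc = ds.noncoding_cohort()
        freqs = cohort_founder_frequencies(nc, ds.pedigrees, "F000")
        idx = ExonDistanceIndex(ds.exons)
        score = {
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): (r.raw, r.phred)
            for r in ds.scores.itertuples()
        }
        pid = ds.pedigrees[0].proband_id
        j = nc.sample_index(pid)
        vs = []
        for i, v in enumerate(nc.variants):
            if nc.alt_counts[i, j] <= 0:
                continue
            d, _ = idx.distance(v.chrom, v.pos)
            raw, phred = score[v.key]
            vs.append(NoncodingVariant(v.key, d, freqs[v.key], raw, phred))
        f = noncoding_funnel(vs)
        assert f.counts[2] == 0 and f.counts[5] == 0

    def test_sv_sizes_bounded_and_caller_redundancy_declines(self, ds_small):
        from exomesieve.indels import match_calls

        all_flags_small, all_flags_large = [], []
        for ped in ds_small.pedigrees:
            pid = ped.proband_id
            calls = ds_small.sv_calls[pid]
            assert all(1 <= abs(c.size) <= 16000 for c in calls)
            res = match_calls(calls, ds_small.caller_indels[pid],
                              reference=ds_small.reference)
            for c, f in zip(calls, res["flags"]):
                (all_flags_small if abs(c.size) <= 50 else all_flags_large).append(f)
        assert np.mean(all_flags_small) > np.mean(all_flags_large)


class TestRoundTrip:
    def test_written_files_reload_equal(self, ds_small, tmp_path):
        paths = ds_small.write(tmp_path)
        # VCF -> cohort matrix matches the in-memory build
        ref = esio.read_fasta(paths["reference.fa"])
        assert ref == ds_small.reference
        c_mem = ds_small.cohort()
        c_disk = esio.load_cohort(paths["cohort.vcf"], ref)
        assert sorted(v.key for v in c_mem.variants) == sorted(
            v.key for v in c_disk.variants
        )
        v0 = c_mem.variants[0]
        assert c_mem.calls_at(v0) == c_disk.calls_at(v0)
        # PED
        peds = esio.read_ped(paths["cohort.ped"])
        assert [p.family_id for p in peds] == [p.family_id for p in ds_small.pedigrees]
        assert peds[0].proband_id == ds_small.pedigrees[0].proband_id
        # BED with labels and first-exon flags
        exons = esio.read_bed(paths["exons.bed"])
        assert exons == ds_small.exons
        # depth tables
        track = esio.read_depth_table(paths[f"depth_{ds_small.probands[0]}.tsv"])
        from exomesieve.coverage import DepthTrack

        dt = DepthTrack.from_frames(track)
        e0 = ds_small.exons[0]
        mem = ds_small.depth[ds_small.probands[0]]
        assert dt.region_depths(e0).tolist() == mem.region_depths(e0).tolist()
        # SV table and truth
        svs = esio.read_sv_table(paths["sv_calls.tsv"])
        pid = ds_small.probands[0]
        assert svs[pid] == ds_small.sv_calls[pid]
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth) == set(ds_small.truth)
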