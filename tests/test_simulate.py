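"""Simulator: determinism, format validity, truth invariants, inbreeding."""

import filecmp

import numpy as np
import pytest

from autozygmap import intervals as iv
from autozygmap.errors import PedigreeError
from autozygmap.formats import (
    read_array_genotypes, read_depth_file, read_gene_models, read_pedigree, read_vcf,
)
from autozygmap.simulate import (
    SimConfig, first_cousin_config, first_cousin_pedigree, outbred_config,
    plant_de_novo, simulate_pedigree, simulate_truth, trio_config,
)

SMALL = dict(chromosomes=(("1", 8_000_000), ("2", 8_000_000)))


@pytest.fixture(scope="module")
def small_result():
    return simulate_pedigree(first_cousin_config(seed=5, array_for_affected=True, **SMALL))


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        config = trio_config(seed=9, **SMALL)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        simulate_pedigree(config).write(d1)
        simulate_pedigree(config).write(d2)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seed_differs(self, tmp_path):
        r1 = simulate_pedigree(trio_config(seed=1, **SMALL))
        r2 = simulate_pedigree(trio_config(seed=2, **SMALL))
        assert r1.truth.planted[0].pos != r2.truth.planted[0].pos or \
            len(r1.vcf_records["C01"]) != len(r2.vcf_records["C01"])


class TestEmittedFilesParse:
    def test_all_formats_round_trip_with_zero_flagged_records(self, tmp_path):
        # array parsing enforces the >10,000-genotype design floor, so this
        # round-trip needs a genome large enough to host that many markers
        config = first_cousin_config(
            seed=3, array_for_affected=True,
            chromosomes=(("1", 20_000_000), ("2", 20_000_000))).noiseless()
        result = simulate_pedigree(config)
        paths = result.write(tmp_path / "out")

        ped = read_pedigree(paths["pedigree"])
        assert {p.sample_id for p in ped} >= set(result.exome_samples)

        for sid in result.exome_samples:
            records, sample = read_vcf(paths[f"vcf:{sid}"])
            assert sample == sid
            assert len(records) == len(result.vcf_records[sid])
            assert not any(r.depth_missing for r in records)
            table = read_depth_file(paths[f"depth:{sid}"], sample_id=sid)
            assert table.depths == result.depth_tables[sid].depths

        array = read_array_genotypes(paths["array"], result.array_table.n_snps)
        assert array.sample_ids == result.array_table.sample_ids
        for sid in array.sample_ids:
            assert (array.calls[sid] == result.array_table.calls[sid]).all()

        genes, _ = read_gene_models(paths["genes"])
        assert len(genes) == len(result.genome.genes)
        assert all(g.valid for g in genes)

    def test_written_reference_matches_accessor(self, tmp_path):
        config = SimConfig(seed=4, pedigree=first_cousin_pedigree(),
                           chromosomes=(("1", 300_000),), pedigree_kind="first_cousin")
        result = simulate_pedigree(config)
        paths = result.write(tmp_path, write_reference=True)
        from pyfaidx import Fasta

        fa = Fasta(str(paths["reference"]))
        assert str(fa["1"][1000:1300]).upper() == result.genome.fetch("1", 1000, 1300)


class TestTruthInvariants:
    def test_recessive_causal_inside_shared_affected_segment(self, small_result):
        pv = small_result.truth.planted[0]
        assert pv.kind == "recessive_causal" and pv.rsid is None
        for sid in ("C01", "C02"):
            segs = small_result.truth.segments[sid].get(pv.chrom, [])
            assert iv.contains(segs, pv.pos)
            assert pv.expected_genotypes[sid] == "BB"
        assert pv.expected_genotypes["P1"] == "AB"
        assert pv.expected_genotypes["P2"] == "AB"

    def test_causal_variant_present_in_affected_vcfs(self, small_result):
        pv = small_result.truth.planted[0]
        for sid in ("C01", "C02"):
            hits = [r for r in small_result.vcf_records[sid]
                    if r.chrom == pv.chrom and r.pos == pv.pos]
            assert len(hits) == 1 and hits[0].alt == pv.alt

    def test_vcfs_contain_only_non_reference_sites(self, small_result):
        # AA genotypes never appear in a single-sample exome VCF
        for sid, recs in small_result.vcf_records.items():
            for r in recs:
                assert r.alt_depth > 0 or r.ref_depth + r.alt_depth == 0 or \
                    r.alt_depth / (r.ref_depth + r.alt_depth) > 0.05

    def test_depth_files_cover_all_marker_positions(self, small_result):
        for sid in small_result.exome_samples:
            table = small_result.depth_tables[sid]
            for chrom, em in small_result.genome.exome.items():
                for p in em.positions[:50]:
                    assert (chrom, int(p)) in table.depths

    def test_de_novo_parents_are_reference_in_truth(self):
        result = simulate_pedigree(trio_config(seed=11, **SMALL))
        pv = [p for p in result.truth.planted if p.kind == "de_novo"][0]
        assert pv.expected_genotypes == {"P1": "AA", "P2": "AA", "C01": "AB"}
        for sid in ("P1", "P2"):
            assert not any(r.pos == pv.pos and r.chrom == pv.chrom
                           for r in result.vcf_records[sid])

    def test_plant_de_novo_with_rs_gets_rs_id(self):
        result = simulate_pedigree(trio_config(seed=11, with_rs=True, **SMALL))
        pv = [p for p in result.truth.planted if p.kind == "de_novo"][0]
        assert pv.rsid and pv.rsid.startswith("rs")

    def test_plant_de_novo_rejects_founder_target(self):
        config = trio_config(seed=1, **SMALL)
        with pytest.raises(PedigreeError, match="founder"):
            plant_de_novo(config, "P1")

    def test_outbred_truth_has_no_autozygosity(self):
        result = simulate_pedigree(outbred_config(seed=6, **SMALL))
        for sid, by_chrom in result.truth.segments.items():
            assert by_chrom == {}, sid


class TestInbreedingCoefficient:
    def test_first_cousin_offspring_autozygous_fraction_near_one_sixteenth(self):
        """Unconditioned gene drops: offspring of first cousins should be
        autozygous over ~1/16 of the genome on average (F = 0.0625)."""
        genome_bp = 16_000_000
        config_base = dict(pedigree=first_cousin_pedigree(n_affected=2),
                           pedigree_kind="first_cousin",
                           chromosomes=(("1", 8_000_000), ("2", 8_000_000)))
        fracs = []
        for seed in range(200):
            truth = simulate_truth(SimConfig(seed=seed, **config_base))
            for sid in ("C01", "C02"):
                covered = sum(e - s + 1
                              for ivs in truth.segments.get(sid, {}).values()
                              for s, e in ivs)
                fracs.append(covered / genome_bp)
        mean_f = float(np.mean(fracs))
        assert 0.0625 * 0.7 <= mean_f <= 0.0625 * 1.3, mean_f


class TestExpectedGenotypesMatchEmission:
    def test_noiseless_vcf_genotypes_match_truth(self):
        config = first_cousin_config(seed=8, **SMALL).noiseless()
        result = simulate_pedigree(config)
        pv = result.truth.planted[0]
        for sid, expected in pv.expected_genotypes.items():
            recs = [r for r in result.vcf_records[sid]
                    if r.chrom == pv.chrom and r.pos == pv.pos]
            if expected == "AA":
                assert recs == []
            else:
                (r,) = recs
                total = r.ref_depth + r.alt_depth
                f = r.alt_depth / total
                assert (f > 0.8) == (expected == "BB")


class TestDeNovoNoiseBehaviour:
    def test_false_positives_bounded_at_default_noise(self):
        """With depth-based noise on, spurious de novo candidates arise from
        miscalled genotypes but stay rare (< 5 per trio)."""
        from autozygmap.dataset import build_unified_dataset
        from autozygmap.filters import run_cascade

        for seed in range(20):
            res = simulate_pedigree(trio_config(seed=seed, **SMALL))
            ds = build_unified_dataset(res.vcf_records, res.depth_tables, res.pedigree)
            result = run_cascade(ds, ["de_novo_het"])
            pv = res.truth.planted[0]
            hit = any(k[0] == pv.chrom and k[1] == pv.pos
                      for k in result.site_keys())
            assert result.n_retained - hit < 5


class TestPlotting:
    def test_region_plot_written(self, small_result, tmp_path):
        from autozygmap.autozygosity import find_regions_exome, to_marker_seq_exome
        from autozygmap.dataset import build_unified_dataset
        from autozygmap.plotting import plot_regions

        ds = build_unified_dataset(small_result.vcf_records,
                                   small_result.depth_tables, small_result.pedigree)
        regions = {sid: find_regions_exome(ds, sid) for sid in ds.sample_ids}
        seqs = {sid: to_marker_seq_exome(ds, sid) for sid in ds.sample_ids}
        out = tmp_path / "regions.png"
        plot_regions(regions, dict(small_result.config.chromosomes), out,
                     status_by_sample={s.sample_id: s.status for s in ds.samples},
                     marker_seqs=seqs)
        assert out.stat().st_size > 0


class TestDeletionHomPlant:
    def test_unexpected_hom_screen_recovers_planted_deletion_footprint(self):
        from dataclasses import replace

        from autozygmap.dataset import build_unified_dataset
        from autozygmap.filters import run_cascade
        from autozygmap.simulate import PlantSpec

        cfg = trio_config(seed=2, **SMALL).noiseless()
        cfg = replace(cfg, planted=(PlantSpec("deletion_hom", target="C01"),))
        res = simulate_pedigree(cfg)
        pv = res.truth.planted[0]
        # the child is homozygous-variant while one parent carries no copy
        assert pv.expected_genotypes["C01"] == "BB"
        assert "AA" in (pv.expected_genotypes["P1"], pv.expected_genotypes["P2"])
        ds = build_unified_dataset(res.vcf_records, res.depth_tables, res.pedigree)
        result = run_cascade(ds, ["unexpected_hom"])
        assert (pv.chrom, pv.pos, pv.ref, pv.alt) in result.site_keys()
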