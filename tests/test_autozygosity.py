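"""Run construction, interrupting-heterozygote reassignment, region calling,
array scaling, shared regions and concordance bins."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autozygmap.autozygosity import (
    M_HET, M_HOM, M_NOCALL, AutozygousRegion, MarkerSeq,
    array_min_run_variants, concordance_class, find_regions_array,
    find_runs, runs_to_regions, shared_autozygosity, to_marker_seq_exome,
)
from autozygmap.dataset import build_unified_dataset
from autozygmap.errors import DataFormatError
from autozygmap.formats import ArrayGenotypeTable, PedigreeRecord, VcfSiteRecord
from conftest import oracle_runs

H, E, N = M_HOM, M_HET, M_NOCALL


def runs_as_tuples(states, min_run=25, iters=4):
    return [tuple(r) for r in find_runs(np.array(states, dtype=np.int8), min_run, iters)]


class TestFindRuns:
    def test_single_isolated_het_merges_when_flanks_exceed_25(self):
        states = [H] * 30 + [E] + [H] * 30
        assert runs_as_tuples(states) == [(0, 60, 60)]

    def test_flank_of_20_is_not_enough(self):
        states = [H] * 20 + [E] + [H] * 30
        assert runs_as_tuples(states) == [(0, 19, 20), (21, 50, 30)]

    def test_exactly_26_qualifies_25_does_not(self):
        merged = [H] * 26 + [E] + [H] * 26
        assert runs_as_tuples(merged) == [(0, 52, 52)]
        split = [H] * 25 + [E] + [H] * 26
        assert len(runs_as_tuples(split)) == 2

    def test_chain_of_isolated_hets_resolves_within_four_iterations(self):
        # 5 runs of 26 separated by 4 single hets: each pass merges the
        # currently isolated hets simultaneously, reaching one run of 130.
        states = ([H] * 26 + [E]) * 4 + [H] * 26
        result = runs_as_tuples(states)
        assert result == [(0, len(states) - 1, 130)]
        assert result == [tuple(r) for r in oracle_runs(states)]

    def test_adjacent_het_pair_cannot_be_rescued(self):
        # two hets with a short run between them: neither is isolated
        states = [H] * 40 + [E] + [H] * 5 + [E] + [H] * 40
        assert len(runs_as_tuples(states)) == 3

    def test_nocall_is_transparent(self):
        states = [H] * 3 + [N] * 4 + [H] * 2
        assert runs_as_tuples(states) == [(0, 8, 5)]

    def test_nocall_does_not_count_toward_flanks(self):
        # 20 HOM + 10 NOCALL on one flank: still only 20 supporting markers
        states = [H] * 20 + [N] * 10 + [E] + [H] * 30
        assert len(runs_as_tuples(states)) == 2

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 200))
            states = rng.choice([H, E, N], size=n, p=[0.75, 0.15, 0.10])
            mr = int(rng.integers(1, 30))
            it = int(rng.integers(1, 6))
            assert runs_as_tuples(states, mr, it) == \
                [tuple(r) for r in oracle_runs(states.tolist(), mr, it)], \
                (states.tolist(), mr, it)

    @settings(derandomize=True, max_examples=150)
    @given(states=st.lists(st.sampled_from([H, E, N]), max_size=120),
           min_run=st.integers(min_value=1, max_value=12))
    def test_matches_oracle_property(self, states, min_run):
        assert runs_as_tuples(states, min_run, 4) == \
            [tuple(r) for r in oracle_runs(states, min_run, 4)]

    def test_monotone_in_min_run_variants(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            states = rng.choice([H, E, N], size=150, p=[0.8, 0.1, 0.1])
            n_prev = None
            for mr in (2, 5, 10, 20):
                n = len(runs_as_tuples(states, mr))
                if n_prev is not None:
                    assert n >= n_prev   # raising the bar never merges more
                n_prev = n

    def test_extra_pass_is_fixed_point_when_no_qualifying_het_remains(self):
        rng = np.random.default_rng(17)
        changed = 0
        for _ in range(200):
            states = rng.choice([H, E, N], size=200, p=[0.85, 0.08, 0.07])
            r4 = runs_as_tuples(states, 10, 4)
            r5 = runs_as_tuples(states, 10, 5)
            if r4 != r5:
                changed += 1
        # long chains needing a fifth pass are possible but must be rare
        assert changed <= 10


class TestRegions:
    def _seq(self, positions):
        return MarkerSeq(chrom="1", positions=np.array(positions),
                         states=np.full(len(positions), M_HOM, dtype=np.int8))

    @pytest.mark.parametrize("span,kept", [
        (499_999, False),     # below the >500 kb floor
        (500_000, False),     # exactly at the floor: strict comparison
        (500_001, True),
        (501_000, True),
    ])
    def test_region_length_floor(self, span, kept):
        seq = self._seq([1, span])   # two markers spanning `span` bp inclusive
        runs = find_runs(seq)
        regions = runs_to_regions(runs, seq, 500_000, "S", "exome")
        assert bool(regions) is kept
        if kept:
            assert regions[0].length == span and regions[0].n_variants == 2

    def test_empty_runs_give_empty_regions(self):
        seq = self._seq([1])
        assert runs_to_regions([], seq, 500_000, "S", "exome") == []


class TestMarkerSeqExome:
    def _dataset(self, records):
        ped = [PedigreeRecord("S1", status="affected")]
        return build_unified_dataset({"S1": records}, {}, ped)

    def test_depth_floors_gate_entry(self):
        records = [
            # BB rs-variant one read short of 15: excluded
            VcfSiteRecord("1", 100, "rs1", "A", "G", 0, 14),
            # AB no-rs variant at 149 reads: excluded (needs 150)
            VcfSiteRecord("1", 200, None, "A", "G", 75, 74),
            # AB rs-variant at exactly 30 reads: included as HET
            VcfSiteRecord("1", 300, "rs2", "A", "G", 15, 15),
            # BB rs-variant at 15 reads: included as HOM
            VcfSiteRecord("1", 400, "rs3", "A", "G", 0, 15),
        ]
        seqs = to_marker_seq_exome(self._dataset(records), "S1")
        seq = seqs["1"]
        assert seq.positions.tolist() == [300, 400]
        assert seq.states.tolist() == [M_HET, M_HOM]

    def test_x_chromosome_excluded_by_default(self):
        records = [VcfSiteRecord("X", 100, "rs1", "A", "G", 0, 30),
                   VcfSiteRecord("1", 100, "rs1", "A", "G", 0, 30)]
        ds = self._dataset(records)
        assert set(to_marker_seq_exome(ds, "S1")) == {"1"}
        assert set(to_marker_seq_exome(ds, "S1", include_x=True)) == {"1", "X"}

    def test_split_multiallelic_collapses_het_wins(self):
        records = [VcfSiteRecord("1", 100, "rs1", "A", "G", 0, 30),
                   VcfSiteRecord("1", 100, "rs1", "A", "T", 15, 15)]
        seq = to_marker_seq_exome(self._dataset(records), "S1")["1"]
        assert seq.positions.tolist() == [100]
        assert seq.states.tolist() == [M_HET]

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            to_marker_seq_exome(self._dataset([]), "nope")


def _array_table(positions, codes_by_sample, n_snps, chrom="1"):
    positions = np.asarray(positions, dtype=np.int64)
    return ArrayGenotypeTable(
        markers=[f"m{i}" for i in range(len(positions))],
        chroms=np.array([chrom] * len(positions), dtype=object),
        positions=positions,
        calls={sid: np.asarray(codes, dtype=np.int8)
               for sid, codes in codes_by_sample.items()},
        n_snps=n_snps,
    )


class TestArrayRegions:
    @pytest.mark.parametrize("n_snps,expected", [
        (1_000_000, 700),
        (906_600, 635),       # 634.62 rounded half-up
        (100_000, 70),
        (10_715, 8),          # 7.5005 -> 8
    ])
    def test_run_requirement_scales_with_design(self, n_snps, expected):
        assert array_min_run_variants(n_snps) == expected

    def test_small_design_rejected(self):
        table = _array_table([100], {"S1": [0]}, n_snps=10_000)
        with pytest.raises(DataFormatError, match="10,?000"):
            find_regions_array(table, "S1")

    def test_planted_homozygous_block_yields_one_region(self):
        rng = np.random.default_rng(21)
        positions = np.sort(rng.choice(20_000_000, size=6000, replace=False)) + 1
        codes = rng.choice([0, 1, 2], size=6000, p=[0.3, 0.4, 0.3]).astype(np.int8)
        block = (positions >= 5_000_000) & (positions <= 10_000_000)
        codes[block] = np.where(rng.random(block.sum()) < 0.5, 0, 2)  # 5 Mb hom block
        table = _array_table(positions, {"S1": codes}, n_snps=50_000)
        regions = find_regions_array(table, "S1")
        covering = [r for r in regions
                    if r.start <= 5_100_000 and r.end >= 9_900_000]
        assert len(covering) == 1
        assert all(r.length <= 5_200_000 for r in regions)


class TestSharedAutozygosity:
    def region(self, sid, start, end, chrom="1"):
        return AutozygousRegion(sid, chrom, start, end, 10, "exome")

    def test_intersection(self):
        regs = {"A": [self.region("A", 1_000_000, 10_000_000)],
                "B": [self.region("B", 5_000_000, 20_000_000)]}
        assert shared_autozygosity(regs, ["A", "B"]) == [("1", 5_000_000, 10_000_000)]

    def test_subtracting_unaffected(self):
        regs = {"A": [self.region("A", 1_000_000, 10_000_000)],
                "B": [self.region("B", 5_000_000, 20_000_000)],
                "U": [self.region("U", 5_000_000, 7_000_000)]}
        shared = shared_autozygosity(regs, ["A", "B"], unaffected_ids=["U"],
                                     subtract_unaffected=True)
        assert shared == [("1", 7_000_001, 10_000_000)]

    def test_disjoint_regions_share_nothing(self):
        regs = {"A": [self.region("A", 1, 10)], "B": [self.region("B", 20, 30)]}
        assert shared_autozygosity(regs, ["A", "B"]) == []

    def test_affected_sample_without_regions_blocks_chromosome(self):
        regs = {"A": [self.region("A", 1, 10)], "B": []}
        assert shared_autozygosity(regs, ["A", "B"]) == []

    def test_requires_affected(self):
        with pytest.raises(ValueError):
            shared_autozygosity({}, [])


class TestConcordance:
    @pytest.mark.parametrize("states,expected", [
        (["BB"] * 10, "black"),                   # all concordant homozygous
        (["AB"] * 5, "yellow"),                   # all heterozygous
        (["BB"] * 10 + ["AB"], "black"),          # 10/11 = 0.909 > 0.9
        (["BB"] * 9 + ["AB"], "orange"),          # exactly 0.9: inclusive in orange
        (["BB"] * 8 + ["AB", "AB"], "orange"),    # 0.8: inclusive lower edge
        (["BB"] * 6 + ["AB"] * 4, "yellow"),      # 0.6 < 0.8
        (["BB"] * 4 + ["AA"] * 4, "yellow"),      # split between the two hom states
        (["BB", "NC", "NC"], "black"),            # no-calls excluded from the fraction
        (["NC"] * 3, "uncalled"),
    ])
    def test_bins(self, states, expected):
        assert concordance_class(states) == expected
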