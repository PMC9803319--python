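"""Bin design, genome packing, variant placement, and sequence mutation."""

import itertools
from collections import Counter

import pytest

from svbench import (
    BinScheme,
    MockGenomeSpec,
    PlacementConfig,
    apply_variants,
    build_bin_scheme,
    evaluate_callset,
    pack_bins_into_genomes,
    place_variants,
    read_sv_vcf,
    write_truth,
)
from svbench.simulate import InfeasiblePackingError, PlacementError, random_reference
from svbench.variants import FilterConfig
from svbench.intervals import merged_span_length, overlap_length


class TestBuildBinScheme:
    def test_single_bin_covers_full_range(self):
        scheme = build_bin_scheme(100, 280_000, 1)
        assert scheme.edges == (100, 280_000)
        assert scheme.bin_index(100) == 0
        assert scheme.bin_index(280_000) == 0

    def test_log_spaced_edges(self):
        """Two bins over [100, 10000] split at the geometric midpoint 1000."""
        scheme = build_bin_scheme(100, 10_000, 2)
        assert scheme.edges == (100, 1000, 10_000)

    def test_bin_assignment_half_open_lower_closed_last(self):
        scheme = build_bin_scheme(100, 10_000, 2)
        assert scheme.bin_index(999) == 0
        assert scheme.bin_index(1000) == 1
        assert scheme.bin_index(10_000) == 1

    def test_every_size_maps_to_exactly_one_bin(self):
        scheme = build_bin_scheme(100, 5_000, 4)
        for size in range(100, 5_001, 7):
            idx = scheme.bin_index(size)
            lo, hi = scheme.edges[idx], scheme.edges[idx + 1]
            closed = idx == scheme.n_bins - 1
            assert lo <= size <= hi if closed else lo <= size < hi

    @pytest.mark.parametrize("args", [(0, 100, 1), (100, 100, 1), (100, 200, 0)])
    def test_invalid_bounds_rejected(self, args):
        with pytest.raises(ValueError):
            build_bin_scheme(*args)


class TestPackBins:
    def test_small_design_fits_one_genome(self):
        """3 types x 30 variants of ~100 bp fit well inside a 100 kbp budget."""
        scheme = BinScheme(edges=(100, 101), per_bin_count=30)
        specs = pack_bins_into_genomes(scheme, 10_000_000, PlacementConfig(seed=0))
        assert len(specs) == 1
        assert len(specs[0].planned) == 90

    def test_oversized_variant_raises_naming_the_bin(self):
        scheme = BinScheme(edges=(280_000, 280_001), per_bin_count=1)
        with pytest.raises(InfeasiblePackingError, match="bin 0"):
            pack_bins_into_genomes(scheme, 10_000_000, PlacementConfig(seed=0))

    def test_budget_respected_and_counts_exact(self):
        scheme = build_bin_scheme(100, 10_000, 3, per_bin_count=30)
        config = PlacementConfig(seed=4)
        ref_length = 2_000_000
        specs = pack_bins_into_genomes(scheme, ref_length, config)
        budget = int(config.max_fraction * ref_length)
        for spec in specs:
            assert spec.total_span <= budget
        counts = Counter(
            (sv_type, b) for spec in specs for sv_type, size, b in spec.planned
        )
        assert set(counts) == {
            (t, b) for t in ("DEL", "DUP", "INV") for b in range(3)
        }
        assert all(n == 30 for n in counts.values())
        # sizes actually belong to their bin
        for spec in specs:
            for sv_type, size, b in spec.planned:
                assert scheme.bin_index(size) == b

    def test_forced_multi_genome_split(self):
        """Total planned span three times the budget needs >= 3 genomes."""
        scheme = BinScheme(edges=(10_000, 10_001), per_bin_count=2)
        # 3 types x 2 x 10 kbp = 60 kbp of span; budget = 20 kbp
        specs = pack_bins_into_genomes(scheme, 2_000_000, PlacementConfig(seed=0))
        assert len(specs) >= 3
        assert all(s.total_span <= 20_000 for s in specs)

    def test_deterministic_given_seed(self):
        scheme = build_bin_scheme(100, 10_000, 3)
        a = pack_bins_into_genomes(scheme, 2_000_000, PlacementConfig(seed=9))
        b = pack_bins_into_genomes(scheme, 2_000_000, PlacementConfig(seed=9))
        assert [s.planned for s in a] == [s.planned for s in b]


class TestPlaceVariants:
    def test_empty_spec_gives_empty_truth(self):
        ref = random_reference({"I": 10_000}, seed=0)
        spec = MockGenomeSpec(genome_id="g0", planned=[])
        truth = place_variants(ref, spec, PlacementConfig(seed=0))
        assert len(truth.variants) == 0

    def test_deterministic_coordinates_under_seed(self):
        ref = random_reference({"I": 10_000}, seed=0)
        spec = MockGenomeSpec(genome_id="g0", planned=[("DEL", 1000, 0)])
        coords = {
            (v.chrom, v.interval.start, v.interval.end)
            for v in place_variants(ref, spec, PlacementConfig(seed=3)).variants
        }
        for _ in range(3):
            again = place_variants(ref, spec, PlacementConfig(seed=3))
            assert {
                (v.chrom, v.interval.start, v.interval.end) for v in again.variants
            } == coords

    def test_placement_respects_gaps_and_n_runs(self):
        ref = random_reference({"I": 500_000, "II": 500_000}, seed=1)
        ref["I"] = ref["I"][:100_000] + "N" * 5_000 + ref["I"][105_000:]
        spec = MockGenomeSpec(
            genome_id="g0",
            planned=[("DEL", 200, 0), ("DUP", 300, 0), ("INV", 150, 0)] * 33 +
                    [("DEL", 5_000, 0)],
        )
        config = PlacementConfig(seed=8, min_gap=500)
        truth = place_variants(ref, spec, config)
        assert len(truth.variants) == len(spec.planned)
        n_span = (100_000, 105_000)
        for a, b in itertools.combinations(truth.variants, 2):
            if a.chrom == b.chrom:
                gap = max(a.interval.start, b.interval.start) - min(
                    a.interval.end, b.interval.end
                )
                assert gap >= config.min_gap
        for v in truth.variants:
            if v.chrom == "I":
                assert v.interval.end <= n_span[0] or v.interval.start >= n_span[1]

    def test_impossible_density_raises(self):
        ref = random_reference({"I": 5_000}, seed=0)
        spec = MockGenomeSpec(
            genome_id="g0", planned=[("DEL", 2_000, 0)] * 5
        )
        with pytest.raises(PlacementError):
            place_variants(ref, spec, PlacementConfig(seed=0, max_retries=50))


class TestApplyVariants:
    def _one(self, seq, sv_type, start, end):
        from conftest import sv
        from svbench import TruthSet

        return apply_variants(
            {"c": seq},
            TruthSet(variants=[sv("c", start, end, sv_type)]),
        )["c"]

    def test_inversion_reverse_complements_span(self):
        assert self._one("AAAACGTCGGGGTTTT", "INV", 4, 8) == "AAAAGACGGGGGTTTT"

    def test_tandem_duplication_inserts_copy_after_span(self):
        assert self._one("AAAACGTCGGGGTTTT", "DUP", 4, 8) == "AAAACGTCCGTCGGGGTTTT"

    def test_deletion_removes_span(self):
        assert self._one("AAAACGTCGGGGTTTT", "DEL", 4, 8) == "AAAAGGGGTTTT"

    def test_length_conservation(self):
        ref = random_reference({"I": 50_000}, seed=5)
        spec = MockGenomeSpec(
            genome_id="g0",
            planned=[("DEL", 1000, 0), ("DUP", 2000, 0), ("INV", 1500, 0)],
        )
        truth = place_variants(ref, spec, PlacementConfig(seed=5))
        mutated = apply_variants(ref, truth)
        assert len(mutated["I"]) == 50_000 - 1000 + 2000

    def test_coordinates_stay_reference_coordinates(self):
        """Right-to-left application: earlier variants keep original sequence."""
        ref = {"c": "ACGT" * 2500}
        from conftest import sv
        from svbench import TruthSet

        truth = TruthSet(
            variants=[sv("c", 100, 200, "DEL"), sv("c", 5_000, 5_100, "DEL")]
        )
        mutated = apply_variants(ref, truth)["c"]
        assert mutated[:100] == ref["c"][:100]
        assert len(mutated) == 10_000 - 200

    def test_out_of_bounds_variant_rejected(self):
        from conftest import sv
        from svbench import TruthSet

        with pytest.raises(ValueError):
            apply_variants({"c": "ACGT"}, TruthSet(variants=[sv("c", 0, 10, "DEL")]))


class TestTruthProperties:
    def test_budget_audit_and_self_evaluation(self, tmp_path):
        ref = random_reference({"I": 1_000_000, "II": 1_000_000}, seed=2)
        ref_length = 2_000_000
        scheme = build_bin_scheme(100, 10_000, 3)
        config = PlacementConfig(seed=2)
        specs = pack_bins_into_genomes(scheme, ref_length, config)
        contig_lengths = {c: len(s) for c, s in ref.items()}
        for spec in specs[:3]:
            truth = place_variants(ref, spec, config)
            frac = merged_span_length(v.interval for v in truth.variants) / ref_length
            assert frac <= config.max_fraction
            results = evaluate_callset(truth, truth)
            for sv_type, r in results.items():
                if truth.of_type(sv_type):
                    assert (r.precision, r.recall, r.f1, r.jaccard) == (1, 1, 1, 1)

    def test_truth_vcf_byte_identical_across_runs(self, tmp_path):
        ref = random_reference({"I": 500_000}, seed=3)
        scheme = build_bin_scheme(100, 5_000, 2, per_bin_count=5)
        config = PlacementConfig(seed=10)
        spec = pack_bins_into_genomes(scheme, 500_000, config)[0]
        payloads = []
        for run in range(2):
            truth = place_variants(ref, spec, config)
            out = tmp_path / f"truth{run}.vcf"
            write_truth(truth, out, contig_lengths={"I": 500_000},
                        scheme=scheme, config=config)
            payloads.append(out.read_bytes())
        assert payloads[0] == payloads[1]

    def test_truth_round_trips_through_vcf(self, tmp_path):
        ref = random_reference({"I": 500_000}, seed=4)
        scheme = build_bin_scheme(100, 5_000, 2, per_bin_count=5)
        config = PlacementConfig(seed=11)
        spec = pack_bins_into_genomes(scheme, 500_000, config)[0]
        truth = place_variants(ref, spec, config)
        out = tmp_path / "truth.vcf"
        write_truth(truth, out, contig_lengths={"I": 500_000})
        back = read_sv_vcf(out, FilterConfig(min_size=1, require_pass=False))
        key = lambda v: (v.chrom, v.interval.start, v.interval.end, v.sv_type)
        assert sorted(map(key, back.variants)) == sorted(map(key, truth.variants))
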