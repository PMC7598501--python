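"""Synthetic repeatome generator: libraries, genomes, reads, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from censkim.cytometry import detect_domains, threshold_profile
from censkim.reads import reverse_complement
from censkim.simulate import (
    GenomeSpec,
    IntensityProfileSpec,
    OccupancyModel,
    RepeatFamilySpec,
    build_family_library,
    build_genome,
    default_genome_spec,
    expected_family_enrichment,
    pairwise_divergence,
    simulate_chip_input,
    simulate_profile,
    simulate_wgs_reads,
)


class TestFamilyLibrary:
    def test_five_subfamilies_within_divergence_bound(self):
        spec = RepeatFamilySpec("sat", 360, 0.17, 5, 0.30, "tandem", True)
        lib = build_family_library(spec, seed=1)
        assert len(lib) == 5
        assert all(len(s) == 360 for s in lib)
        divs = [pairwise_divergence(a, b) for i, a in enumerate(lib) for b in lib[i + 1 :]]
        assert all(d <= 0.30 for d in divs)
        assert max(divs) > 0.15  # family is genuinely heterogeneous

    def test_zero_divergence_gives_identical_consensuses(self):
        spec = RepeatFamilySpec("sat", 100, 0.1, 3, 0.0)
        lib = build_family_library(spec, seed=7)
        assert lib[0] == lib[1] == lib[2]

    def test_divergence_equals_positionwise_mismatch_count(self):
        spec = RepeatFamilySpec("sat", 360, 0.1, 2, 0.10)
        lib = build_family_library(spec, seed=5)
        mismatches = sum(1 for x, y in zip(lib[0], lib[1]) if x != y)
        assert pairwise_divergence(lib[0], lib[1]) == mismatches / 360

    def test_reproducible_from_seed(self):
        spec = RepeatFamilySpec("sat", 200, 0.1, 4, 0.2)
        assert build_family_library(spec, 3) == build_family_library(spec, 3)

    @pytest.mark.parametrize("bad", [dict(monomer_length=0), dict(n_subfamilies=0)])
    def test_invalid_spec_rejected(self, bad):
        kwargs = dict(name="x", monomer_length=10, genome_fraction=0.1, n_subfamilies=2)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            RepeatFamilySpec(**kwargs)


class TestGenomeBuild:
    def test_major_satellite_fraction_realized(self):
        fam = RepeatFamilySpec("sat", 360, 0.17, 5, 0.30, "tandem", True)
        g = build_genome(GenomeSpec(2_040_000, (fam,), seed=11))
        planted = sum(a.end - a.start for a in g.annotations)
        assert abs(planted - 346_800) <= 0.1 * 346_800

    def test_empty_family_list_gives_pure_background(self):
        g = build_genome(GenomeSpec(50_000, (), seed=1))
        assert g.annotations == []
        assert len(g.sequences["chr1"]) == 50_000

    def test_5s_like_monomers_all_192bp(self):
        fam = RepeatFamilySpec("rdna_5s", 192, 0.02, organization="tandem")
        g = build_genome(GenomeSpec(200_000, (fam,), seed=4))
        lengths = {a.end - a.start for a in g.annotations}
        assert lengths == {192}

    def test_infeasible_fractions_rejected(self):
        fams = (
            RepeatFamilySpec("a", 100, 0.6),
            RepeatFamilySpec("b", 100, 0.6),
        )
        with pytest.raises(ValueError, match="infeasible"):
            GenomeSpec(100_000, fams)

    def test_annotations_disjoint_and_in_bounds(self, small_genome):
        small_genome.validate()  # raises on violation

    def test_realized_fractions_within_ten_percent(self, small_genome):
        spec_fracs = {
            "major_sat": 0.17, "minor_sat180": 0.005, "rdna_5s": 0.002,
            "retroelement": 0.03,
        }
        for fam, frac in spec_fracs.items():
            realized = small_genome.family_base_fraction(fam)
            assert abs(realized - frac) <= 0.1 * frac, fam

    def test_centromeric_family_mostly_inside_centromere(self, small_genome):
        cen = {(c, s, e) for c, s, e in small_genome.centromeres}
        inside = outside = 0
        for a in small_genome.arrays:
            if a.family != "major_sat":
                continue
            if any(c == a.chrom and a.start >= s and a.end <= e for c, s, e in cen):
                inside += a.end - a.start
            else:
                outside += a.end - a.start
        assert inside > outside  # ~80/20 split with spill-over
        assert outside > 0

    def test_reproducible(self):
        spec = default_genome_spec(120_000, seed=9)
        assert build_genome(spec).sequences == build_genome(spec).sequences


class TestWgsReads:
    def test_read_count_formula_small_genome(self, small_genome, small_wgs):
        # ceil(0.2 * 500000 / 151) = 663 -> 664 (paired, rounded to even)
        assert len(small_wgs) == 664

    def test_zero_coverage_empty(self, small_genome):
        assert len(simulate_wgs_reads(small_genome, 0.0, 151, False, 1)) == 0

    def test_read_sequences_match_genome_truth(self, small_genome, small_wgs):
        for r in list(small_wgs)[:50]:
            sub = small_genome.sequences[r.source.chrom][r.source.start : r.source.end]
            expected = reverse_complement(sub) if r.source.strand == "-" else sub
            assert r.bases == expected

    def test_pairs_linked_symmetrically(self, small_wgs):
        small_wgs.validate_pairing()
        assert small_wgs.is_paired

    def test_negative_coverage_rejected(self, small_genome):
        with pytest.raises(ValueError):
            simulate_wgs_reads(small_genome, -0.1, 151, False, 1)


class TestChipInput:
    def test_uniform_model_origin_ratio_near_one(self, small_genome):
        model = OccupancyModel({"major_sat": 1.0}, 1.0, 1.0)
        chip, inp = simulate_chip_input(small_genome, model, 4000, 151, seed=5)
        chip_n = sum(1 for r in chip if r.source.family == "major_sat")
        inp_n = sum(1 for r in inp if r.source.family == "major_sat")
        assert inp_n > 0
        assert 0.8 < chip_n / inp_n < 1.25

    def test_weighted_model_matches_closed_form(self, small_genome):
        model = OccupancyModel({"major_sat": 4.0}, 1.0, 0.5)
        expected = expected_family_enrichment(small_genome, model, "major_sat")
        # occupancy is resampled per run: average origin ratios over draws
        ratios = []
        for seed in range(4):
            chip, inp = simulate_chip_input(small_genome, model, 8000, 151, seed=seed)
            chip_n = sum(1 for r in chip if r.source.family == "major_sat")
            inp_n = sum(1 for r in inp if r.source.family == "major_sat")
            ratios.append(chip_n / inp_n)
        assert expected == pytest.approx(np.mean(ratios), rel=0.25)
        assert np.mean(ratios) > 1.3  # clearly enriched over input

    def test_zero_reads_empty_sets(self, small_genome):
        model = OccupancyModel({"major_sat": 4.0}, 1.0, 0.5)
        chip, inp = simulate_chip_input(small_genome, model, 0, 151, seed=1)
        assert len(chip) == 0 and len(inp) == 0

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            OccupancyModel({"sat": 0.0}, 0.0, 0.5)


class TestProfiles:
    def test_chromosome_mode_outermost_span(self):
        spec = IntensityProfileSpec(1000, 0.435, 4, seed=1)
        p = simulate_profile(spec)
        present = np.flatnonzero(p.channels["cen"] > 0)
        span = present[-1] - present[0] + 1
        assert abs(span - 435) <= 1
        domains = detect_domains(p.channels["cen"] > 0, p.positions)
        assert len(domains) == 4

    def test_single_domain_dot_like(self):
        p = simulate_profile(IntensityProfileSpec(500, 0.3, 1, seed=1))
        domains = detect_domains(p.channels["cen"] > 0, p.positions)
        assert len(domains) == 1

    def test_fiber_zero_overlap_disjoint(self):
        p = simulate_profile(
            IntensityProfileSpec(1000, 0.4, 1, channel_overlap=0.0, mode="fiber")
        )
        assert not np.any((p.channels["a"] > 0) & (p.channels["b"] > 0))

    def test_noise_clipped_at_zero(self):
        p = simulate_profile(IntensityProfileSpec(1000, 0.4, 4, noise_sd=30.0, seed=2))
        for values in p.channels.values():
            assert values.min() >= 0

    def test_too_many_domains_rejected(self):
        with pytest.raises(ValueError):
            IntensityProfileSpec(30, 0.4, 4)


@settings(derandomize=True, max_examples=25)
@given(
    monomer=st.integers(20, 400),
    n_sub=st.integers(1, 6),
    div=st.floats(0.0, 0.4),
    seed=st.integers(0, 2**20),
)
def test_family_library_divergence_bound_property(monomer, n_sub, div, seed):
    """Pairwise consensus divergence never exceeds the spec bound."""
    spec = RepeatFamilySpec("f", monomer, 0.1, n_sub, div)
    lib = build_family_library(spec, seed)
    for i, a in enumerate(lib):
        for b in lib[i + 1 :]:
            assert pairwise_divergence(a, b) <= div + 1e-12
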