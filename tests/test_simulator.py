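"""Genome synthesis, shearing, SS damage, digestion and end repair."""
import numpy as np
import pytest

from ssduplex import (
    DamageParams,
    apply_ss_damage,
    apply_ss_damage_all,
    digest_nuclease,
    end_repair,
    get_model,
    make_genome,
    shear_fragments,
)
from ssduplex.fragments import Gap, Nick, SSLesion
from ssduplex.nuclease import NucleaseModel

from conftest import make_fragment, overhang


class TestMakeGenome:
    def test_gc_content_tracks_target(self):
        g = make_genome(10_000, 0.52, seed=7)
        assert abs(g.gc_content - 0.52) < 0.02
        g2 = make_genome(100_000, 0.25, seed=3)
        assert abs(g2.gc_content - 0.25) < 0.01

    def test_seed_determinism(self):
        assert make_genome(1000, 0.5, seed=1).sequence == make_genome(1000, 0.5, seed=1).sequence
        assert make_genome(1000, 0.5, seed=1).sequence != make_genome(1000, 0.5, seed=2).sequence

    @pytest.mark.parametrize("length,gc", [(10, 0.5), (1000, 0.0), (1000, 1.2)])
    def test_argument_errors(self, length, gc):
        with pytest.raises(ValueError):
            make_genome(length, gc, seed=0)

    def test_fasta_round_trip(self, genome, tmp_path):
        from ssduplex import read_fasta, write_fasta

        path = str(tmp_path / "g.fa")
        write_fasta(genome, path)
        back = read_fasta(path)
        assert back.name == genome.name and back.sequence == genome.sequence


class TestShear:
    def test_degenerate_config_is_blunt(self, genome):
        frags = shear_fragments(
            genome, 50, overhang_len_dist=("constant", 0), nick_rate=0, gap_rate=0, seed=1
        )
        assert all(f.is_blunt() for f in frags)
        assert all(not f.ss_regions(nick_window=5) for f in frags)

    def test_fragment_length_distribution(self, genome):
        frags = shear_fragments(genome, 10_000, size_mean=350, size_sd=50, seed=2)
        lengths = np.array([f.length for f in frags])
        se = 50 / np.sqrt(lengths.size)
        assert abs(lengths.mean() - 350) < 3 * se + 0.5  # rounding slack
        assert all(0 <= f.genome_start < f.genome_end <= genome.length for f in frags)
        assert len({f.molecule_id for f in frags}) == len(frags)

    def test_overhang_length_geometric_mean(self, genome):
        frags = shear_fragments(
            genome, 10_000, overhang_len_dist=("geometric", 8.0),
            end_kind_probs=(0.0, 0.5, 0.5), seed=3,
        )
        lens = [oh.length for f in frags for oh in (f.overhang_left, f.overhang_right)]
        lens = np.array(lens)
        # geometric(mean 8) has sd sqrt(1-p)/p ~ 7.48
        se = 7.5 / np.sqrt(lens.size)
        assert abs(lens.mean() - 8.0) < 3 * se + 0.1

    def test_nicks_and_gaps_inside_core(self, genome):
        frags = shear_fragments(genome, 500, nick_rate=5e-3, gap_rate=2e-3, seed=4)
        for f in frags:
            for nick in f.nicks:
                assert f.core_start < nick.position < f.core_end
            for gap in f.gaps:
                assert f.core_start < gap.start < gap.end < f.core_end


class TestSSRegions:
    def test_overhang_geometry_by_end_and_kind(self):
        f = make_fragment(
            100, 200,
            left=overhang("left", "five_prime", 6),
            right=overhang("right", "three_prime", 4),
        )
        # left 5' overhang protrudes on the plus strand; so does a right 3'
        regs = f.ss_regions()
        assert ("+", 100, 106, "overhang") in regs
        assert ("+", 196, 200, "overhang") in regs

    def test_gap_exposes_opposite_strand(self):
        f = make_fragment(0, 100, gaps=[Gap(strand="-", start=40, end=45)])
        assert ("+", 40, 45, "gap") in f.ss_regions()

    def test_nick_window_downstream_of_nick(self):
        f = make_fragment(0, 100, nicks=[Nick(strand="+", position=50), Nick(strand="-", position=70)])
        regs = f.ss_regions(nick_window=3)
        assert ("-", 50, 53, "nick_adjacent") in regs
        assert ("+", 67, 70, "nick_adjacent") in regs


class TestDamage:
    def test_blunt_fragment_gets_no_ss_lesions(self, genome):
        f = make_fragment(100, 400)
        params = DamageParams(p_oxog_ss=1.0, p_iz_ss=0.0, p_deamc_ss=1.0)
        out = apply_ss_damage(f, genome, params, seed=1)
        assert out.lesions == []

    def test_certainty_case_hits_every_exposed_g(self, genome):
        f = make_fragment(100, 400, left=overhang("left", "five_prime", 10))
        params = DamageParams(p_oxog_ss=1.0, p_iz_ss=0.0, p_deamc_ss=0.0)
        out = apply_ss_damage(f, genome, params, seed=1)
        n_g = genome.sequence[100:110].count("G")
        assert len(out.lesions) == n_g
        assert all(l.lesion == "oxoG" and l.original_base == "G" for l in out.lesions)

    def test_lesion_rate_matches_binomial_expectation(self, genome):
        frags = shear_fragments(
            genome, 5000, overhang_len_dist=("constant", 10),
            end_kind_probs=(0.0, 1.0, 0.0), nick_rate=0, gap_rate=0, seed=5,
        )
        params = DamageParams(p_oxog_ss=0.1, p_iz_ss=0.0, p_deamc_ss=0.0)
        damaged = apply_ss_damage_all(frags, genome, params, seed=6)
        n_g = sum(
            sum(genome.sequence[a:b].count("G") if s == "+" else genome.sequence[a:b].count("C")
                for s, a, b, _ in f.ss_regions())
            for f in frags
        )
        total = sum(len(f.lesions) for f in damaged)
        expect = 0.1 * n_g
        se = np.sqrt(n_g * 0.1 * 0.9)
        assert abs(total - expect) < 3 * se

    def test_lesions_confined_to_ss_regions(self, genome):
        frags = shear_fragments(genome, 300, nick_rate=2e-3, gap_rate=1e-3, seed=7)
        params = DamageParams(p_oxog_ss=0.5, p_iz_ss=0.3, p_deamc_ss=0.5, nick_window=2)
        for f in apply_ss_damage_all(frags, genome, params, seed=8):
            regions = f.ss_regions(nick_window=2)
            for l in f.lesions:
                assert any(l.strand == s and a <= l.position < b for s, a, b, _ in regions)

    def test_damage_determinism(self, genome):
        f = make_fragment(0, 300, left=overhang("left", "five_prime", 8))
        params = DamageParams(p_oxog_ss=0.3)
        a = apply_ss_damage(f, genome, params, seed=9)
        b = apply_ss_damage(f, genome, params, seed=9)
        assert a.lesions == b.lesions

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            DamageParams(p_oxog_ss=1.2)
        with pytest.raises(ValueError):
            DamageParams(p_oxog_ss=0.7, p_iz_ss=0.7)


def _lesioned_pool(genome, n=400, seed=11):
    frags = shear_fragments(genome, n, nick_rate=2e-3, gap_rate=1e-3, seed=seed)
    params = DamageParams(p_oxog_ss=0.5, p_iz_ss=0.2, p_deamc_ss=0.3)
    return apply_ss_damage_all(frags, genome, params, seed=seed + 1), params


class TestDigestion:
    def test_zero_units_identity(self, genome):
        pool, _ = _lesioned_pool(genome)
        s1 = get_model("s1")
        for f in pool[:50]:
            assert digest_nuclease(f, s1, 0.0, genome, seed=1) == [f]

    def test_complete_digestion_clears_all_ss_lesions(self, genome):
        pool, _ = _lesioned_pool(genome)
        full = NucleaseModel("s1", p_overhang_max=1.0, p_gap_max=1.0, p_nick_max=1.0)
        for f in pool:
            for prod in digest_nuclease(f, full, 1e6, genome, seed=2):
                assert prod.lesions == []

    def test_recjf_ignores_three_prime_overhangs(self, genome):
        recjf = get_model("recjf")
        for i in range(5):
            f = make_fragment(
                100 * i, 100 * i + 300, mol=str(i),
                left=overhang("left", "three_prime", 5),
                right=overhang("right", "three_prime", 7),
            )
            assert digest_nuclease(f, recjf, 1e6, genome, seed=3) == [f]

    def test_recjf_removes_five_prime_overhangs(self, genome):
        recjf = get_model("recjf")
        f = make_fragment(
            100, 400,
            left=overhang("left", "five_prime", 5),
            lesions=[SSLesion(102, "+", "G", "oxoG", "overhang")],
        )
        (out,) = digest_nuclease(f, recjf, 1e6, genome, seed=4)
        assert out.overhang_left.kind == "blunt"
        assert out.lesions == []
        assert out.genome_start == 105

    def test_gap_cleavage_splits_fragment(self, genome):
        f = make_fragment(0, 300, gaps=[Gap(strand="+", start=140, end=145)])
        full = NucleaseModel("x", p_gap_max=1.0)
        prods = digest_nuclease(f, full, 1e6, genome, seed=5)
        assert len(prods) == 2
        (a, b) = sorted(prods, key=lambda p: p.genome_start)
        assert a.genome_start == 0 and a.genome_end == 140
        assert b.genome_start == 145 and b.genome_end == 300
        assert {p.molecule_id for p in prods} == {"0.0", "0.1"}

    def test_short_products_are_dropped(self, genome):
        f = make_fragment(0, 120, gaps=[Gap(strand="+", start=30, end=31)])
        full = NucleaseModel("x", p_gap_max=1.0)
        prods = digest_nuclease(f, full, 1e6, genome, seed=6, min_length=50)
        assert [p.genome_start for p in prods] == [31]

    def test_survival_monotone_in_units(self, genome):
        pool, _ = _lesioned_pool(genome)
        s1 = get_model("s1")
        counts = []
        for units in (0.0, 1.0, 3.0, 10.0, 100.0):
            surv = sum(
                len(p.lesions)
                for f in pool
                for p in digest_nuclease(f, s1, units, genome, seed=7)
            )
            counts.append(surv)
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            get_model("exoVII")


class TestEndRepair:
    def test_five_prime_oxog_becomes_concordant_g_to_t(self, genome):
        # find a G on the plus strand inside a left 5' overhang
        pos = genome.sequence.index("G", 1000)
        start = pos - 2
        f = make_fragment(
            start, start + 300,
            left=overhang("left", "five_prime", 8),
            lesions=[SSLesion(pos, "+", "G", "oxoG", "overhang")],
        )
        out = end_repair(f, genome, DamageParams())
        assert out.repaired and out.is_blunt()
        (sub,) = out.concordant_subs
        assert (sub.position, sub.strand, sub.ref, sub.alt) == (pos, "+", "G", "T")

    def test_three_prime_overhang_is_chewed_back(self, genome):
        pos = genome.sequence.index("C", 1000)  # minus-strand G
        start = pos - 2
        f = make_fragment(
            start, start + 300,
            left=overhang("left", "three_prime", 8),
            lesions=[SSLesion(pos, "-", "G", "oxoG", "overhang")],
        )
        out = end_repair(f, genome, DamageParams())
        assert out.concordant_subs == []
        assert out.genome_start == start + 8

    def test_iz_on_gap_becomes_g_to_c(self, genome):
        pos = genome.sequence.index("G", 2000)
        f = make_fragment(
            pos - 100, pos + 100,
            gaps=[Gap(strand="-", start=pos - 2, end=pos + 3)],
            lesions=[SSLesion(pos, "+", "G", "iz", "gap")],
        )
        out = end_repair(f, genome, DamageParams())
        (sub,) = out.concordant_subs
        assert (sub.ref, sub.alt) == ("G", "C")
        assert out.nicks == [] and out.gaps == []

    def test_minus_strand_lesion_reference_frame_projection(self, genome):
        pos = genome.sequence.index("C", 3000)  # plus C = minus G
        f = make_fragment(
            pos - 100, pos + 100,
            gaps=[Gap(strand="+", start=pos - 1, end=pos + 1)],
            lesions=[SSLesion(pos, "-", "G", "oxoG", "gap")],
        )
        out = end_repair(f, genome, DamageParams(frame_rule="reference"))
        (sub,) = out.concordant_subs
        assert (sub.strand, sub.ref, sub.alt) == ("+", "C", "A")

    def test_discordant_damage_survives_repair(self, genome):
        from ssduplex.fragments import StrandDamage

        ref = genome.sequence[150]
        alt = "A" if ref != "A" else "C"
        f = make_fragment(0, 300, ds_damage=[StrandDamage(150, "+", ref, alt)])
        out = end_repair(f, genome, DamageParams())
        assert len(out.ds_damage) == 1
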