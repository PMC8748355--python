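"""Substitution counting, frames, clipping, masking and group statistics."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ssduplex as sx
from ssduplex.consensus import DuplexConsensusPair, FLAG_RESOLVED
from ssduplex.dna import seq_to_codes
from ssduplex.spectrum import (
    MUT6,
    MUT12,
    SpectrumTable,
    SubstitutionCounts,
    clip_ends,
    compare_groups,
    count_substitutions,
    frequencies,
    load_bed_mask,
    mask_positions,
)


def dcs_pair(chrom, start, seq):
    codes = seq_to_codes(seq)
    return DuplexConsensusPair(
        key=(chrom, start, start + len(seq)),
        bases=codes,
        flags=np.full(len(seq), FLAG_RESOLVED, dtype=np.uint8),
    )


def ref_pair(genome, start, end, edits=()):
    """dsDCS equal to the reference, with optional (pos, base) edits."""
    seq = list(genome.sequence[start:end])
    for pos, base in edits:
        seq[pos - start] = base
    return dcs_pair(genome.name, start, "".join(seq))


class TestClip:
    def test_zero_is_identity(self, genome):
        p = ref_pair(genome, 100, 160)
        assert clip_ends(p, 0) is p

    def test_full_masking_leaves_no_countable_positions(self, genome):
        p = ref_pair(genome, 100, 130)
        clipped = clip_ends(p, 20)
        assert (clipped.bases == ord("N")).all()
        counts = count_substitutions([clipped], genome)
        assert counts.total_denominator == 0

    def test_negative_clip_rejected(self, genome):
        with pytest.raises(ValueError):
            clip_ends(ref_pair(genome, 0, 50), -1)

    def test_denominator_conservation(self, genome):
        """countable + clipped + already-N = total aligned positions."""
        p = ref_pair(genome, 200, 300)
        p.bases[10] = ord("N")
        for k in (0, 5, 20):
            clipped = clip_ends(p, k)
            counts = count_substitutions([clipped], genome)
            n_masked = int((clipped.bases == ord("N")).sum())
            assert counts.total_denominator + n_masked == p.length


class TestMask:
    def test_empty_mask_changes_nothing(self, genome, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        mask = load_bed_mask(str(bed))
        p = ref_pair(genome, 0, 80)
        a = count_substitutions([p], genome, mask=mask)
        b = count_substitutions([p], genome)
        assert a.denominators == b.denominators

    def test_whole_genome_mask_zeroes_everything(self, genome, tmp_path):
        bed = tmp_path / "all.bed"
        bed.write_text(f"{genome.name}\t0\t{genome.length}\n")
        mask = load_bed_mask(str(bed))
        counts = count_substitutions([ref_pair(genome, 0, 80)], genome, mask=mask)
        assert counts.total_denominator == 0 and counts.total_count == 0

    def test_masking_planted_variants_removes_exactly_them(self, genome, tmp_path):
        start = 500
        g_positions = [start + i for i, b in enumerate(genome.sequence[start:start + 60]) if b == "G"][:3]
        p = ref_pair(genome, start, start + 60, edits=[(pos, "T") for pos in g_positions])
        before = count_substitutions([p], genome, frame="reference")
        assert before.counts["G>T"] == 3
        bed = tmp_path / "mask.bed"
        bed.write_text("".join(f"{genome.name}\t{pos}\t{pos + 1}\n" for pos in g_positions[:2]))
        after = count_substitutions([p], genome, frame="reference", mask=load_bed_mask(str(bed)))
        assert after.counts["G>T"] == 1
        assert before.total_denominator - after.total_denominator == 2

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t0\t10\nchr1\tfive\tten\n")
        with pytest.raises(ValueError, match="2"):
            load_bed_mask(str(bed))


class TestCountFrames:
    def test_reference_match_counts_only_denominators(self, genome):
        counts = count_substitutions([ref_pair(genome, 0, 100)], genome, frame="reference")
        assert counts.total_count == 0
        for b in "GCAT":
            assert counts.denominators[b] == genome.sequence[:100].count(b)

    def test_left_half_g_to_t_same_in_both_frames(self, genome):
        pos = genome.sequence.index("G", 1000)
        p = ref_pair(genome, pos - 5, pos + 95, edits=[(pos, "T")])  # left half
        for frame in ("reference", "fragment"):
            counts = count_substitutions([p], genome, frame=frame)
            assert counts.counts["G>T"] == 1 and counts.total_count == 1

    def test_right_half_event_is_complemented_in_fragment_frame(self, genome):
        pos = genome.sequence.index("G", 1000)
        p = ref_pair(genome, pos - 95, pos + 5, edits=[(pos, "T")])  # right half
        ref_counts = count_substitutions([p], genome, frame="reference")
        assert ref_counts.counts["G>T"] == 1
        frag_counts = count_substitutions([p], genome, frame="fragment")
        assert frag_counts.counts["C>A"] == 1 and frag_counts.counts["G>T"] == 0

    def test_six_type_pooling_is_frame_invariant(self, genome):
        rng = np.random.default_rng(0)
        pairs = []
        for _ in range(30):
            start = int(rng.integers(0, genome.length - 120))
            edits = []
            for _ in range(rng.integers(0, 3)):
                off = int(rng.integers(0, 120))
                cur = genome.sequence[start + off]
                edits.append((start + off, "ACGT"[(("ACGT".index(cur)) + 1) % 4]))
            pairs.append(ref_pair(genome, start, start + 120, edits=edits))
        f_ref = frequencies(count_substitutions(pairs, genome, frame="reference"))
        f_frag = frequencies(count_substitutions(pairs, genome, frame="fragment"))
        for m in MUT6:
            assert f_ref.freq6[m] == pytest.approx(f_frag.freq6[m], rel=1e-12)


class TestFrequencies:
    def test_basic_arithmetic(self):
        counts = SubstitutionCounts()
        counts.counts["G>T"] = 18
        counts.denominators = {"G": 10**8, "C": 10**8, "A": 1, "T": 1}
        tab = frequencies(counts)
        assert tab.freq12["G>T"] == pytest.approx(0.18)

    def test_pooled_six_type_matches_printed_worked_example(self):
        """Strand-resolved 0.18/0.021, 0.28/0.013, 0.062/0.096 per 1e6 bp
        pool to 0.10, 0.15, 0.08 (2 d.p.) over equal denominators."""
        den = 10**9
        counts = SubstitutionCounts()
        counts.denominators = {b: den for b in "GCAT"}
        for mut, freq in [("G>T", 0.18), ("C>A", 0.021), ("G>C", 0.28),
                          ("C>G", 0.013), ("G>A", 0.062), ("C>T", 0.096)]:
            counts.counts[mut] = int(round(freq * den / 1e6))
        tab = frequencies(counts)
        assert round(tab.freq6["G:C>T:A"], 2) == 0.10
        assert round(tab.freq6["G:C>C:G"], 2) == 0.15
        assert round(tab.freq6["G:C>A:T"], 2) == 0.08

    def test_zero_denominator_class_is_missing_not_zero(self):
        counts = SubstitutionCounts()
        counts.denominators = {"G": 100, "C": 100, "A": 0, "T": 0}
        tab = frequencies(counts)
        assert math.isnan(tab.freq12["A>T"])
        assert math.isnan(tab.freq6["A:T>T:A"])
        assert tab.freq12["G>T"] == 0.0

    def test_all_zero_denominators_error(self):
        with pytest.raises(ValueError):
            frequencies(SubstitutionCounts())

    def test_tsv_round_trip(self, tmp_path):
        from ssduplex.spectrum import read_spectrum_tsv

        counts = SubstitutionCounts()
        counts.counts["G>T"] = 5
        counts.denominators = {b: 10**6 for b in "GCAT"}
        tab = frequencies(counts, label="s1", replicate=2)
        path = str(tmp_path / "spec.tsv")
        tab.to_tsv(path)
        back = read_spectrum_tsv(path)
        assert back.label == "s1" and back.replicate == 2
        assert back.freq12["G>T"] == pytest.approx(tab.freq12["G>T"])


def _tables(rng, means, n):
    out = []
    for i in range(n):
        f6 = {m: max(0.0, rng.normal(mu, 0.1)) for m, mu in zip(MUT6, means)}
        out.append(SpectrumTable(freq12={}, freq6=f6, replicate=i))
    return out


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        tabs = [SpectrumTable(freq12={}, freq6={m: 1.0 for m in MUT6}, replicate=i) for i in range(3)]
        comp = compare_groups(tabs, tabs, test="ttest")
        assert (comp.table.log2_fold_change == 0).all()
        assert (comp.table.p_value == 1).all()

    def test_dunnett_single_group_equals_student_t(self):
        rng = np.random.default_rng(1)
        tr = _tables(rng, [1.5] * 6, 3)
        ct = _tables(rng, [1.0] * 6, 3)
        pd_ = compare_groups(tr, ct, test="dunnett").table.p_value.values
        pt = compare_groups(tr, ct, test="ttest").table.p_value.values
        assert np.abs(pd_ - pt).max() < 1e-3

    def test_pseudocount_keeps_fold_change_finite(self):
        zero = [SpectrumTable(freq12={}, freq6={m: 0.0 for m in MUT6}, replicate=i) for i in range(2)]
        some = _tables(np.random.default_rng(2), [1.0] * 6, 2)
        comp = compare_groups(some, zero, test="ttest")
        assert np.isfinite(comp.table.log2_fold_change).all()

    def test_replicate_requirements(self):
        one = [SpectrumTable(freq12={}, freq6={m: 1.0 for m in MUT6})]
        with pytest.raises(ValueError):
            compare_groups(one, one, test="ttest")

    def test_dunnett_unequal_group_sizes_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            compare_groups([_tables(rng, [1] * 6, 3), _tables(rng, [1] * 6, 4)],
                           _tables(rng, [1] * 6, 3), test="dunnett")

    def test_welch_flag_changes_test_name(self):
        rng = np.random.default_rng(4)
        comp = compare_groups(_tables(rng, [2] * 6, 3), _tables(rng, [1] * 6, 3), welch=True)
        assert comp.test_name == "welch_t"
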