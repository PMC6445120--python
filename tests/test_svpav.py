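"""Indel validation, PAV detection, sharing classification, repeat annotation."""

import numpy as np
import pytest

from pairgenome import svpav
from pairgenome.seqcore import Genome
from pairgenome.simpair import random_seq
from pairgenome.svpav import StructuralVariant


def _deletion_pair(seed=0, sv_len=500, pos=10_000, n=25_000):
    """Genome B carries a segment absent from genome A at ``pos``."""
    rng = np.random.default_rng(seed)
    a_seq = random_seq(rng, n)
    segment = random_seq(rng, sv_len)
    b_seq = a_seq[:pos] + segment + a_seq[pos:]
    return Genome([("c", a_seq)]), Genome([("c", b_seq)]), segment


class TestValidateIndel:
    def test_true_deletion_confirmed_with_exact_borders(self):
        a, b, _ = _deletion_pair(sv_len=500)
        cand = StructuralVariant("deletion", "c", 10_000, 10_500, 500)
        v = svpav.validate_indel(cand, b, a)
        assert v.validated
        assert abs(v.recalc_start - 10_000) <= 1 and abs(v.recalc_end - 10_500) <= 1
        assert abs(v.recalc_length - 500) <= 1

    def test_shuffled_decoy_rejected(self):
        a, b, _ = _deletion_pair(seed=1)
        decoy = StructuralVariant("deletion", "c", 18_000, 18_500, 500)
        assert not svpav.validate_indel(decoy, b, a).validated

    def test_length_100_rejected_before_alignment(self):
        a, b, _ = _deletion_pair(seed=2)
        cand = StructuralVariant("deletion", "c", 10_000, 10_100, 100)
        v = svpav.validate_indel(cand, b, a)
        assert not v.validated and "length" in v.note

    def test_insertion_mirror_case(self):
        """Swapping genome roles converts the deletion into a confirmed
        insertion with the same recalculated length."""
        a, b, _ = _deletion_pair(seed=3, sv_len=800)
        as_del = svpav.validate_indel(
            StructuralVariant("deletion", "c", 10_000, 10_800, 800), b, a
        )
        as_ins = svpav.validate_indel(
            StructuralVariant("insertion", "c", 10_000, 10_000, 800), a, b
        )
        assert as_del.validated and as_ins.validated
        assert as_del.recalc_length == as_ins.recalc_length

    def test_window_beyond_bounds_dropped_with_reason(self):
        a, b, _ = _deletion_pair(seed=4)
        cand = StructuralVariant("deletion", "c", 100, 600, 500)
        v = svpav.validate_indel(cand, b, a)
        assert not v.validated and v.note


class TestDetectPav:
    def test_identical_genomes_yield_nothing(self):
        g = Genome([("c", random_seq(np.random.default_rng(5), 40_000))])
        assert svpav.detect_pav(g, g) == []

    def test_implanted_segment_found_with_tight_borders(self):
        a, b, segment = _deletion_pair(seed=6, sv_len=1000, n=40_000)
        depth_a = {"c": np.full(40_000, 30.0)}
        depth_b = {"c": np.full(41_000, 30.0)}
        depth_b["c"][10_000:11_000] = 0.0  # no cross-genome reads over the novel segment
        pavs = svpav.detect_pav(a, b, depth_a=depth_a, depth_b=depth_b)
        assert len(pavs) == 1
        (v,) = pavs
        assert v.kind == "deletion"  # carried by B, absent from A
        assert abs(v.start - 10_000) <= 5 and abs(v.end - 11_000) <= 5

    def test_small_region_excluded_by_strict_min_len(self):
        a, b, _ = _deletion_pair(seed=7, sv_len=80, n=30_000)
        pavs = svpav.detect_pav(a, b)
        assert all(v.length > 100 for v in pavs)
        assert not any(abs(v.start - 10_000) < 300 for v in pavs)

    def test_normal_depth_region_filtered_out(self):
        a, b, _ = _deletion_pair(seed=8, sv_len=1000, n=40_000)
        depth_b = {"c": np.full(41_000, 30.0)}  # segment fully covered: not a PAV
        pavs = svpav.detect_pav(a, b, depth_a={"c": np.full(40_000, 30.0)}, depth_b=depth_b)
        assert pavs == []

    def test_missing_depth_flags_every_pav(self):
        a, b, _ = _deletion_pair(seed=9, sv_len=1000, n=40_000)
        pavs = svpav.detect_pav(a, b)
        assert pavs and all(not v.depth_checked for v in pavs)

    def test_no_pav_contains_n(self, small_pair, small_depths):
        _, a, b, _ = small_pair
        depth_a, depth_b = small_depths
        pavs = svpav.detect_pav(a, b, depth_a=depth_a, depth_b=depth_b)
        for v in pavs:
            genome = b if v.kind == "deletion" else a
            assert "N" not in genome[v.chrom][v.start : v.end]


class TestClassifyShared:
    def test_present_everywhere_absent_in_donor_is_shared(self):
        v = StructuralVariant("deletion", "c", 0, 500, 500)
        assert svpav.classify_shared(v, [True, True, True], False).shared

    def test_missing_from_one_parity_assembly_not_shared(self):
        v = StructuralVariant("deletion", "c", 0, 500, 500)
        assert not svpav.classify_shared(v, [True, False, True], False).shared

    def test_present_in_donor_not_shared(self):
        v = StructuralVariant("deletion", "c", 0, 500, 500)
        assert not svpav.classify_shared(v, [True, True, True], True).shared

    def test_presence_calls_from_synthetic_assembly_panel(self):
        """allele_present distinguishes assemblies carrying the B allele."""
        a, b, _ = _deletion_pair(seed=10, sv_len=600, n=30_000)
        v = StructuralVariant("deletion", "c", 10_000, 10_600, 600)
        assert svpav.allele_present(v, b, b)  # B itself carries the segment
        assert not svpav.allele_present(v, b, a)  # A lacks it


class TestAnnotateBreakpoints:
    REPEATS = {"c": [(100, 200, "SINE"), (150, 300, "LINE"), (5_000, 6_000, "LTR")]}

    def test_sv_inside_ltr(self):
        v = StructuralVariant("deletion", "c", 5_100, 5_200, 100)
        svpav.annotate_breakpoints([v], self.REPEATS)
        assert v.repeat_class == "LTR"

    def test_sv_overlapping_nothing_is_non(self):
        v = StructuralVariant("deletion", "c", 9_000, 9_100, 100)
        svpav.annotate_breakpoints([v], self.REPEATS)
        assert v.repeat_class == "Non"

    def test_precedence_sine_over_line(self):
        v = StructuralVariant("deletion", "c", 140, 260, 120)
        svpav.annotate_breakpoints([v], self.REPEATS)
        assert v.repeat_class == "SINE"

    def test_inversion_annotates_both_breakpoints(self):
        v = StructuralVariant("inversion", "c", 150, 5_500, 5_350)
        svpav.annotate_breakpoints([v], self.REPEATS)
        assert v.repeat_class == "SINE/LTR"
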