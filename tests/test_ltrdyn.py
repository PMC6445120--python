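"""LTR element detection, dating, cross-genome classes, CNS analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pairgenome import ltrdyn
from pairgenome.ltrdyn import CnsRateInputs, cns_rate, insertion_time
from pairgenome.seqcore import Genome
from pairgenome.simpair import SimConfig, random_seq, simulate_pair

TRUTH_TO_CLASS = {
    "SharedHigh": "shared",
    "SharedLow": "shared",
    "Insertion": "insertion_A",
    "Elimination": "elimination_B",
}


@pytest.fixture(scope="module")
def classified_pair():
    cfg = SimConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=600_000,
        snp_rate=0.0,
        n_shared=6,
        n_insertions_A=4,
        n_insertions_B=2,
        n_eliminations=3,
        min_event_spacing=22_000,
    )
    a, b, truth = simulate_pair(cfg)
    elements = ltrdyn.detect_intact_ltr(a)
    ltrdyn.date_elements(elements, a)
    ltrdyn.classify_elements(elements, a, b)
    return a, b, truth, elements


class TestDetectIntactLtr:
    def test_simulated_elements_recovered_with_exact_coordinates(self, classified_pair):
        a, _, truth, elements = classified_pair
        expected = truth.te_events[truth.te_events.start_A >= 0]
        found = {(e.chrom, e.start, e.end, e.ltr_len, e.tsd5) for e in elements}
        for r in expected.itertuples():
            assert (r.chrom, r.start_A, r.end_A, r.ltr_len, r.tsd) in found
        assert len(elements) == len(expected)

    def test_mutated_tsd_not_reported(self):
        """An element whose two TSD copies differ is by definition not intact."""
        rng = np.random.default_rng(3)
        ltr = "TG" + random_seq(rng, 496) + "CA"
        elem = ltr + random_seq(rng, 1000) + ltr
        flank5, flank3 = random_seq(rng, 20_000), random_seq(rng, 20_000)
        good = Genome([("c", flank5 + "CATAT" + elem + "CATAT" + flank3)])
        assert len(ltrdyn.detect_intact_ltr(good)) == 1
        bad = Genome([("c", flank5 + "CATAT" + elem + "CAGAT" + flank3)])
        assert ltrdyn.detect_intact_ltr(bad) == []

    def test_repeat_free_genome_empty(self):
        g = Genome([("c", random_seq(np.random.default_rng(4), 50_000))])
        assert ltrdyn.detect_intact_ltr(g) == []


class TestInsertionTime:
    def test_zero_divergence_zero_age(self):
        assert insertion_time(0.0) == 0.0

    def test_printed_rate_worked_examples(self):
        assert insertion_time(0.0026) == pytest.approx(100_000)
        assert insertion_time(0.0208) == pytest.approx(800_000)

    @given(st.floats(0, 0.7), st.floats(0, 0.7))
    def test_strictly_increasing_and_jc_dominates(self, k1, k2):
        if k1 < k2:
            assert insertion_time(k1) < insertion_time(k2)
        if k1 > 0:
            assert insertion_time(k1, jc_correct=True) >= insertion_time(k1)

    def test_jc_undefined_beyond_saturation(self):
        with pytest.raises(ValueError):
            insertion_time(0.76, jc_correct=True)


class TestClassification:
    def test_confusion_matrix_diagonal_on_noiseless_pair(self, classified_pair):
        _, _, truth, elements = classified_pair
        by_coord = {
            (r.chrom, r.start_A, r.end_A): r.cls
            for r in truth.te_events.itertuples()
            if r.start_A >= 0
        }
        for e in elements:
            assert TRUTH_TO_CLASS[e.cls] == by_coord[(e.chrom, e.start, e.end)]

    def test_partition_counts(self, classified_pair):
        _, _, _, elements = classified_pair
        summary = ltrdyn.class_summary(elements)
        total = sum(summary["counts"].values()) + sum(summary["discarded"].values())
        assert total == summary["n_total"] == len(elements)

    def test_shared_high_at_zero_divergence(self):
        """With divergence time 0 the B copy is identical: SharedHigh, identity 1."""
        cfg = SimConfig(seed=9, n_chromosomes=1, chrom_length=300_000, snp_rate=0.0,
                        n_shared=2, divergence_time_years=0.0,
                        ltr_age_range_years=(0.0, 0.0), min_event_spacing=22_000)
        a, b, _ = simulate_pair(cfg)
        els = ltrdyn.classify_elements(ltrdyn.detect_intact_ltr(a), a, b)
        assert [e.cls for e in els] == ["SharedHigh", "SharedHigh"]
        assert all(e.identity_cross == pytest.approx(1.0) for e in els)

    def test_age_zero_element_has_identical_ltrs(self, classified_pair):
        a, _, truth, _ = classified_pair
        young = truth.te_events[(truth.te_events.age_years < 50_000) & (truth.te_events.start_A >= 0)]
        for r in young.itertuples():
            el = [e for e in ltrdyn.detect_intact_ltr(a) if e.start == r.start_A]
            # raw divergence small for young insertions
            if el:
                assert ltrdyn.ltr_divergence(el[0], a) < 0.005


class TestCnsRate:
    def test_equal_frequencies_reduce_to_background_rate(self):
        s = 0.013
        x = CnsRateInputs(S_f=s, S_c=s, T_ltr=7e5, T_div=3e6)
        assert cns_rate(x) == pytest.approx(s / (2 * 3e6))

    def test_zero_control_reduces_to_flank_rate(self):
        x = CnsRateInputs(S_f=0.02, S_c=0.0, T_ltr=1e6, T_div=4e6)
        assert cns_rate(x) == pytest.approx(0.02 / 1e6)

    def test_worked_example(self):
        x = CnsRateInputs(S_f=0.02, S_c=0.01, T_ltr=1e6, T_div=4e6)
        assert cns_rate(x) == pytest.approx(1.125e-8)

    def test_negative_result_reported_as_is(self):
        x = CnsRateInputs(S_f=0.001, S_c=0.02, T_ltr=1e6, T_div=4e6)
        assert cns_rate(x) < 0

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            cns_rate(CnsRateInputs(0.01, 0.01, 0.0, 1e6))

    def test_exact_against_independent_arithmetic(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            sf, sc = rng.uniform(0, 0.2, 2)
            tl, td = rng.uniform(1e4, 1e7, 2)
            expected = (sf - sc) / tl + sc / (2.0 * td)
            assert cns_rate(CnsRateInputs(sf, sc, tl, td)) == pytest.approx(expected, rel=1e-12)


class TestCnsProfile:
    def test_mutation_free_pair_profiles_at_zero(self):
        cfg = SimConfig(seed=12, n_chromosomes=1, chrom_length=400_000, snp_rate=0.0,
                        n_shared=3, divergence_time_years=0.0,
                        ltr_age_range_years=(0.0, 0.0), min_event_spacing=22_000)
        a, b, _ = simulate_pair(cfg)
        els = ltrdyn.classify_elements(ltrdyn.detect_intact_ltr(a), a, b)
        prof, summary = ltrdyn.cns_profile(els, a, b, n_control=10)
        assert (prof.dropna().mean_freq == 0.0).all()
        assert summary["control_mean_freq"] == 0.0

    def test_uniform_snp_rate_gives_flat_profile_matching_control(self):
        cfg = SimConfig(seed=13, n_chromosomes=1, chrom_length=500_000, snp_rate=0.01,
                        n_shared=6, divergence_time_years=1e6, min_event_spacing=25_000)
        a, b, _ = simulate_pair(cfg)
        els = ltrdyn.classify_elements(ltrdyn.detect_intact_ltr(a), a, b)
        prof, summary = ltrdyn.cns_profile(els, a, b, n_control=25)
        flank = prof[prof.region == "flank"]
        assert flank.mean_freq.mean() == pytest.approx(0.01, abs=0.003)
        assert summary["control_mean_freq"] == pytest.approx(0.01, abs=0.003)

    def test_elevated_near_element_mutation_recovered(self):
        """A 1.6x mutation multiplier within 500 bp of elements shows up as a
        >=1.4x elevation adjacent to elements, decaying with distance."""
        cfg = SimConfig(seed=14, n_chromosomes=2, chrom_length=800_000, snp_rate=0.01,
                        te_proximal_snp_multiplier=1.6, n_shared=16,
                        divergence_time_years=1e6, min_event_spacing=25_000)
        a, b, _ = simulate_pair(cfg)
        els = ltrdyn.classify_elements(ltrdyn.detect_intact_ltr(a), a, b)
        prof, summary = ltrdyn.cns_profile(els, a, b, n_control=25)
        flank = prof[prof.region == "flank"].set_index("offset")
        near = flank.loc[0, "mean_freq"]  # window flush against the element
        far = flank.loc[flank.index >= 1000, "mean_freq"].mean()  # beyond the 500-bp zone
        assert near / far >= 1.4
        assert near / summary["control_mean_freq"] >= 1.4


class TestGeneDistance:
    def test_element_inside_gene_counts_as_distance_zero(self):
        g = Genome([("c", random_seq(np.random.default_rng(15), 50_000))])
        el = ltrdyn.LtrElement("c", 10_000, 11_000, 200, "ACGTA", "ACGTA")
        res = ltrdyn.gene_distance_distribution([el], {"c": [(9_000, 12_000)]}, g)
        assert res["distances"] == [0] and res["inside_fraction"] == 1.0

    def test_uniform_insertions_match_genic_fraction(self):
        rng = np.random.default_rng(16)
        g = Genome([("c", random_seq(rng, 200_000))])
        genes = {"c": [(s, s + 4_000) for s in range(0, 200_000, 20_000)]}  # 20% genic
        els = [
            ltrdyn.LtrElement("c", int(p), int(p) + 10, 5, "AC", "AC")
            for p in rng.integers(0, 199_000, 400)
        ]
        res = ltrdyn.gene_distance_distribution(els, genes, g)
        assert res["genic_fraction"] == pytest.approx(0.2, abs=0.01)
        assert res["inside_fraction"] == pytest.approx(0.2, abs=0.07)

    def test_avoidance_sampling_depletes_genic_insertions(self):
        cfg = SimConfig(seed=17, n_chromosomes=2, chrom_length=400_000, snp_rate=0.0,
                        n_insertions_A=15, gene_fraction=0.22, gene_avoidance=0.8,
                        min_event_spacing=20_000)
        a, _, truth = simulate_pair(cfg)
        genes = {
            c: [(r.start_A, r.end_A) for r in truth.genes.itertuples() if r.chrom == c]
            for c in a.ids()
        }
        els = ltrdyn.detect_intact_ltr(a)
        res = ltrdyn.gene_distance_distribution(els, genes, a)
        assert res["inside_fraction"] < 0.6 * res["genic_fraction"]


class TestCnsVsTime:
    def test_constant_clock_slope_recovers_twice_rate(self):
        """Flank divergence grows at 2r per year of element age; the regression
        against ledger ages recovers that slope within 20%."""
        r = 1.3e-8
        cfg = SimConfig(seed=5, n_chromosomes=2, chrom_length=500_000, snp_rate=0.0,
                        te_flank_divergence_rate=r, n_shared=20,
                        divergence_time_years=0.0, ltr_age_range_years=(2e5, 2e6),
                        min_event_spacing=25_000)
        a, b, truth = simulate_pair(cfg)
        els = ltrdyn.classify_elements(ltrdyn.date_elements(ltrdyn.detect_intact_ltr(a), a), a, b)
        curve, per = ltrdyn.cns_vs_time(els, a, b)
        ages = truth.te_events.set_index(["chrom", "start_A"]).age_years
        per["true_age"] = [ages.loc[(row.chrom, row.start)] for row in per.itertuples()]
        slope = np.polyfit(per.true_age, per.S_f, 1)[0]
        assert slope == pytest.approx(2 * r, rel=0.2)
        assert not curve.empty and curve.n.sum() >= len(per)

    def test_all_age_zero_collapses_to_single_window_at_origin(self):
        cfg = SimConfig(seed=18, n_chromosomes=1, chrom_length=300_000, snp_rate=0.0,
                        n_shared=3, divergence_time_years=0.0,
                        ltr_age_range_years=(0.0, 0.0), min_event_spacing=22_000)
        a, b, _ = simulate_pair(cfg)
        els = ltrdyn.classify_elements(ltrdyn.date_elements(ltrdyn.detect_intact_ltr(a), a), a, b)
        curve, _ = ltrdyn.cns_vs_time(els, a, b)
        assert len(curve) == 1 and curve.t_center.iloc[0] == 0.0

    def test_empty_input_signalled(self):
        g = Genome([("c", "ACGT" * 100)])
        with pytest.raises(ValueError):
            ltrdyn.cns_vs_time([], g, g)
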