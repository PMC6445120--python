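"""Simulator: determinism, event implantation semantics, round-trip, clocks."""

import numpy as np
import pytest

from pairgenome.seqcore import revcomp
from pairgenome.simpair import (
    SimConfig,
    SimConfigError,
    age_ltr,
    derive_pair,
    generate_ancestor,
    random_seq,
    reconstruct,
    simulate_depth,
    simulate_pair,
)


class TestGenerateAncestor:
    def test_length_alphabet_and_no_n(self):
        cfg = SimConfig(seed=1, n_chromosomes=1, chrom_length=100_000, gc_fraction=0.5)
        g = generate_ancestor(cfg)
        seq = g["chr01"]
        assert len(seq) == 100_000
        assert set(seq) <= set("ACGT")

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=1, n_chromosomes=2, chrom_length=50_000)
        assert generate_ancestor(cfg).records == generate_ancestor(cfg).records

    def test_gc_fraction_recovered(self):
        cfg = SimConfig(seed=2, n_chromosomes=1, chrom_length=1_000_000, gc_fraction=0.38)
        seq = generate_ancestor(cfg)["chr01"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.38, abs=0.01)

    @pytest.mark.parametrize("bad", [dict(gc_fraction=0.0), dict(gc_fraction=1.2), dict(chrom_length=-5)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(SimConfigError):
            generate_ancestor(SimConfig(**bad))


class TestDerivePair:
    def test_zero_events_yields_identical_descendants(self):
        cfg = SimConfig(seed=3, n_chromosomes=1, chrom_length=60_000, snp_rate=0.0,
                        telomere_copies_range=(50, 60))
        anc = generate_ancestor(cfg)
        a, b, truth = derive_pair(anc, cfg)
        assert a.records == b.records
        assert len(truth.snps) == len(truth.indels) == len(truth.te_events) == 0
        # descendants are the ancestor plus telomere arrays
        assert anc["chr01"] in a["chr01"]

    def test_insertion_carries_two_tsds_and_other_genome_one(self, small_pair):
        _, a, b, truth = small_pair
        r = truth.te_events.query("cls == 'insertion_A'").iloc[0]
        t = int(r.tsd_len)
        assert a[r.chrom][r.start_A - t : r.start_A] == r.tsd
        assert a[r.chrom][r.end_A : r.end_A + t] == r.tsd
        # single TSD copy, no intervening sequence, at the orthologous B point
        assert b[r.chrom][r.b_point : r.b_point + t] == r.tsd
        flank = a[r.chrom][r.start_A - t - 80 : r.start_A - t]
        after = a[r.chrom][r.end_A + t : r.end_A + t + 80]
        assert flank + r.tsd + after in b[r.chrom]

    def test_element_terminal_motif(self, small_pair):
        _, a, _, truth = small_pair
        for r in truth.te_events.itertuples():
            if r.start_A >= 0:
                assert a[r.chrom][r.start_A : r.start_A + 2] == "TG"
                assert a[r.chrom][r.end_A - 2 : r.end_A] == "CA"

    def test_requested_snp_count_and_exact_sites(self):
        cfg = SimConfig(seed=4, n_chromosomes=1, chrom_length=100_000, snp_rate=1e-4,
                        telomere_copies_range=(10, 12))
        anc = generate_ancestor(cfg)
        a, b, truth = derive_pair(anc, cfg)
        assert len(truth.snps) == 10
        # genomes differ exactly at the ledger sites (no other events configured)
        diffs = [i for i, (x, y) in enumerate(zip(a["chr01"], b["chr01"])) if x != y]
        assert diffs == sorted(truth.snps.pos_A.tolist())
        for r in truth.snps.itertuples():
            assert a[r.chrom][r.pos_A] == r.base_A
            assert b[r.chrom][r.pos_B] == r.base_B

    def test_round_trip_ledger_rebuilds_descendants(self, small_config, small_pair):
        """Applying the ledger's edit scripts to the ancestor reproduces both
        descendants byte-for-byte (independent string-surgery code path)."""
        anc, a, b, truth = small_pair
        ra = reconstruct(anc, truth, "A", small_config)
        rb = reconstruct(anc, truth, "B", small_config)
        assert ra.records == a.records
        assert rb.records == b.records

    def test_gaps_masked_in_b_with_recorded_truth(self, small_pair):
        _, a, b, truth = small_pair
        assert len(truth.gaps) > 0
        for r in truth.gaps.itertuples():
            assert set(b[r.chrom][r.start : r.end]) == {"N"}
            assert "N" not in r.truth_seq and len(r.truth_seq) == r.end - r.start

    def test_telomere_arrays_appended(self, small_pair):
        _, a, _, truth = small_pair
        for r in truth.telomeres.itertuples():
            if r.end == "3prime":
                assert a[r.chrom].endswith("TTTAGGG" * r.copies)
            else:
                assert a[r.chrom].startswith(revcomp("TTTAGGG") * r.copies)

    def test_determinism_full(self, small_config):
        a1, b1, t1 = simulate_pair(small_config)
        a2, b2, t2 = simulate_pair(small_config)
        assert a1.records == a2.records and b1.records == b2.records
        assert t1.te_events.equals(t2.te_events) and t1.snps.equals(t2.snps)

    def test_over_dense_configuration_signalled(self):
        cfg = SimConfig(seed=5, n_chromosomes=1, chrom_length=100_000, n_shared=50,
                        min_event_spacing=20_000)
        with pytest.raises(SimConfigError):
            simulate_pair(cfg)


class TestAgeLtr:
    def test_age_zero_keeps_ltrs_identical(self):
        rng = np.random.default_rng(0)
        elem = "TG" + random_seq(rng, 996) + "CA"
        elem = elem + random_seq(rng, 3000) + elem
        aged = age_ltr(elem, 1000, 0.0, rng=rng)
        assert aged == elem

    def test_expected_ltr_divergence_matches_clock(self):
        """1-kb LTRs, 1 My, r = 1.3e-8: mean pairwise differences ~ 2*r*t*L = 26."""
        rng = np.random.default_rng(1)
        ltr = "TG" + random_seq(rng, 996) + "CA"
        elem = ltr + random_seq(rng, 2000) + ltr
        diffs = []
        for _ in range(60):
            aged = age_ltr(elem, 1000, 1e6, 1.3e-8, rng)
            diffs.append(sum(x != y for x, y in zip(aged[:1000], aged[-1000:])))
        assert np.mean(diffs) == pytest.approx(26, rel=0.15)

    def test_terminal_motif_preserved(self):
        rng = np.random.default_rng(2)
        ltr = "TG" + random_seq(rng, 196) + "CA"
        elem = ltr + random_seq(rng, 500) + ltr
        aged = age_ltr(elem, 200, 5e6, 1.3e-8, rng)
        assert aged[:2] == "TG" and aged[198:200] == "CA"
        assert aged[-2:] == "CA" and aged[-200:-198] == "TG"

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            age_ltr("TGCA" * 100, 50, -1.0)


class TestDepthTracks:
    def test_depth_zero_over_genome_specific_segments(self, small_pair, small_depths):
        _, a, b, truth = small_pair
        depth_a, depth_b = small_depths
        for r in truth.te_events.itertuples():
            if r.cls == "insertion_A":
                assert depth_a[r.chrom][r.start_A : r.end_A].max() == 0.0
            if r.cls == "insertion_B":
                assert depth_b[r.chrom][r.start_B : r.end_B].max() == 0.0
        # baseline coverage elsewhere
        assert depth_a[a.ids()[0]][:500].min() == 30.0
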