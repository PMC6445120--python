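"""Gap merging, the four closure criteria, patching, truth recovery."""

import numpy as np
import pytest

from pairgenome import gapfill
from pairgenome.seqcore import Genome, find_n_runs
from pairgenome.simpair import random_seq, simulate_depth


def _rand(seed, n):
    return random_seq(np.random.default_rng(seed), n)


class TestExtractAndMergeGaps:
    def test_no_gaps(self):
        assert gapfill.extract_and_merge_gaps(Genome([("c", _rand(0, 5000))])) == []

    def test_runs_within_500_merge(self):
        seq = _rand(1, 100) + "N" * 100 + _rand(2, 450) + "N" * 50 + _rand(3, 1000)
        gaps = gapfill.extract_and_merge_gaps(Genome([("c", seq)]))
        assert gaps == [("c", 100, 700)]

    def test_runs_beyond_500_stay_separate(self):
        seq = _rand(4, 100) + "N" * 100 + _rand(5, 600) + "N" * 50 + _rand(6, 1000)
        gaps = gapfill.extract_and_merge_gaps(Genome([("c", seq)]))
        assert gaps == [("c", 100, 200), ("c", 800, 850)]


def _gap_pair(seed=0, gap_len=2000):
    """Recipient = donor with one N-masked segment; returns both plus truth."""
    rng = np.random.default_rng(seed)
    donor_seq = random_seq(rng, 30_000)
    s = 12_000
    truth_seg = donor_seq[s : s + gap_len]
    recipient_seq = donor_seq[:s] + "N" * gap_len + donor_seq[s + gap_len :]
    return Genome([("c", recipient_seq)]), Genome([("c", donor_seq)]), (s, s + gap_len, truth_seg)


class TestCloseGap:
    def test_masked_segment_recovered_exactly(self):
        recipient, donor, (s, e, truth_seg) = _gap_pair()
        cl = gapfill.close_gap(("c", s, e), recipient, donor)
        assert cl.status == "closed"
        assert cl.patched_sequence == truth_seg

    def test_criterion_ii_triggered_by_repetitive_flanks(self):
        """A flank present at six donor locations exceeds the <5 total-hits rule."""
        rng = np.random.default_rng(7)
        rep5 = random_seq(rng, 500)
        rep3 = random_seq(rng, 500)
        mid = random_seq(rng, 1000)
        donor_seq = "".join(
            random_seq(rng, 2000) + rep5 for _ in range(6)
        ) + mid + "".join(rep3 + random_seq(rng, 2000) for _ in range(6))
        recipient_seq = random_seq(rng, 5000) + rep5 + "N" * 1000 + rep3 + random_seq(rng, 5000)
        cl = gapfill.close_gap(
            ("c", 5500, 6500), Genome([("c", recipient_seq)]), Genome([("c", donor_seq)])
        )
        assert cl.status == "failed" and cl.failed_criterion == "ii"

    def test_criterion_iii_triggered_by_n_in_donor(self):
        recipient, donor, (s, e, _) = _gap_pair(seed=8)
        dseq = donor["c"]
        donor_n = Genome([("c", dseq[:13_000] + "N" + dseq[13_001:])])
        cl = gapfill.close_gap(("c", s, e), recipient, donor_n)
        assert cl.status == "failed" and cl.failed_criterion == "iii"

    def test_criterion_ordering_ii_before_iii(self):
        """A gap failing both ii and iii reports ii (criteria evaluated in order)."""
        rng = np.random.default_rng(9)
        rep5, rep3 = random_seq(rng, 500), random_seq(rng, 500)
        donor_seq = "".join(random_seq(rng, 2000) + rep5 for _ in range(6))
        donor_seq += "N" * 10 + random_seq(rng, 500)
        donor_seq += "".join(rep3 + random_seq(rng, 2000) for _ in range(6))
        recipient_seq = random_seq(rng, 4000) + rep5 + "N" * 800 + rep3 + random_seq(rng, 4000)
        cl = gapfill.close_gap(
            ("c", 4500, 5300), Genome([("c", recipient_seq)]), Genome([("c", donor_seq)])
        )
        assert cl.failed_criterion == "ii"

    def test_criterion_i_requires_same_orientation_within_span(self):
        rng = np.random.default_rng(10)
        f5 = random_seq(rng, 500)
        f3 = random_seq(rng, 500)
        recipient_seq = random_seq(rng, 2000) + f5 + "N" * 500 + f3 + random_seq(rng, 2000)
        # donor carries the flanks on opposite strands
        from pairgenome.seqcore import revcomp

        donor_seq = random_seq(rng, 3000) + f5 + random_seq(rng, 1000) + revcomp(f3) + random_seq(rng, 3000)
        cl = gapfill.close_gap(
            ("c", 2500, 3000), Genome([("c", recipient_seq)]), Genome([("c", donor_seq)])
        )
        assert cl.status == "failed" and cl.failed_criterion == "i"

    def test_gap_at_sequence_edge_reported_outside_criteria(self):
        recipient = Genome([("c", "N" * 300 + _rand(11, 5000))])
        donor = Genome([("c", _rand(11, 5000))])
        cl = gapfill.close_gap(("c", 0, 300), recipient, donor)
        assert cl.status == "failed" and cl.failed_criterion == "edge"

    def test_criterion_iv_depth_route(self):
        recipient, donor, (s, e, _) = _gap_pair(seed=12)
        low = {"c": np.zeros(30_000)}
        cl = gapfill.close_gap(("c", s, e), recipient, donor, donor_depth=low)
        assert cl.status == "failed" and cl.failed_criterion == "iv"
        high = {"c": np.full(30_000, 30.0)}
        cl = gapfill.close_gap(("c", s, e), recipient, donor, donor_depth=high)
        assert cl.status == "closed" and cl.route == "depth"

    def test_criterion_iv_parity_route(self):
        recipient, donor, (s, e, _) = _gap_pair(seed=13)
        cl = gapfill.close_gap(("c", s, e), recipient, donor, parity_assemblies=[donor])
        assert cl.status == "closed" and cl.route == "parity"
        unrelated = Genome([("c", _rand(99, 30_000))])
        cl = gapfill.close_gap(("c", s, e), recipient, donor, parity_assemblies=[unrelated])
        assert cl.status == "failed" and cl.failed_criterion == "iv"


class TestApplyClosures:
    def test_zero_closures_identity(self):
        g = Genome([("c", _rand(14, 4000))])
        patched, report = gapfill.apply_closures(g, [])
        assert patched.records == g.records and report["n_closed"] == 0

    def test_patch_length_shifts_coordinates(self):
        g = Genome([("c", _rand(15, 2000) + "N" * 1000 + _rand(16, 2000))])
        cl = gapfill.GapClosure("c", 2000, 3000, status="closed",
                                patched_sequence=_rand(17, 1234))
        patched, report = gapfill.apply_closures(g, [cl])
        assert len(patched["c"]) == len(g["c"]) + 234
        assert report["patched_intervals"] == [("c", 2000, 3234)]

    def test_full_synthetic_recovery(self, small_pair, small_depths):
        """Every closable masked gap is patched back to the pre-masking truth."""
        _, a, b, truth = small_pair
        depth_a, _ = small_depths
        patched, closures, report = gapfill.fill_gaps(b, a, donor_depth=depth_a)
        truth_by_gap = {(r.chrom, r.start, r.end): r.truth_seq for r in truth.gaps.itertuples()}
        assert report["n_closed"] == report["n_gaps"] == len(truth_by_gap) > 0
        for cl in closures:
            assert cl.patched_sequence == truth_by_gap[(cl.chrom, cl.gap_start, cl.gap_end)]
        # idempotence: nothing left to close on the patched genome
        assert gapfill.extract_and_merge_gaps(patched) == []
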