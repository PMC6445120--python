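"""Reciprocal gap closure by flank anchoring.

N-gap runs in a recipient assembly are merged (separation <= 500 bp),
the 500-bp fragments immediately up- and downstream of each merged gap
are anchored in a donor assembly, and a gap is closed only if four
criteria hold, evaluated in order:

  i.   both flanks place (coverage >= 80%) within 500 kb on the same
       sequence with the same orientation;
  ii.  the total number of placements of both flanks is < 5 (flanks
       inside repeats are thereby avoided);
  iii. the intervening donor sequence contains no ambiguous (N) bases;
  iv.  the intervening sequence is corroborated: it either anchors at
       coverage >= 80% in at least one independent parity assembly, or
       >90% of its positions have depth > 3 in a donor depth track.

Closed gaps are patched with the donor intervening sequence, oriented
to the recipient strand.  The first failing criterion is recorded, so
failure tallies are directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, median

import numpy as np
import pandas as pd

from .seqcore import AnchoredPlacement, Genome, anchor_fragment, find_n_runs, revcomp


@dataclass
class GapClosure:
    chrom: str
    gap_start: int
    gap_end: int
    status: str = "failed"  # 'closed' | 'failed'
    failed_criterion: str = "none"  # 'i'|'ii'|'iii'|'iv'|'none'|'edge'|'ambiguous'|'empty'
    flank5: AnchoredPlacement | None = None
    flank3: AnchoredPlacement | None = None
    donor_chrom: str = ""
    donor_start: int = -1
    donor_end: int = -1
    strand: str = ""
    route: str = ""  # criterion-iv evidence: 'parity' | 'depth' | 'unchecked'
    patched_sequence: str = field(default="", repr=False)

    @property
    def gap_length(self) -> int:
        return self.gap_end - self.gap_start

    @property
    def patch_length(self) -> int:
        return len(self.patched_sequence)


def extract_and_merge_gaps(
    genome: Genome, merge_distance: int = 500, min_gap_len: int = 1
) -> list[tuple[str, int, int]]:
    """N-runs merged when separated by <= ``merge_distance`` bases.

    A merged gap spans from the first run's start to the last run's end
    (any real bases between the runs are treated as part of the gap).
    """
    merged: list[list] = []
    for chrom, s, e in find_n_runs(genome, min_gap_len):
        if merged and merged[-1][0] == chrom and s - merged[-1][2] <= merge_distance:
            merged[-1][2] = e
        else:
            merged.append([chrom, s, e])
    return [(c, s, e) for c, s, e in merged]


def _pair_candidates(
    p5s: list[AnchoredPlacement], p3s: list[AnchoredPlacement], max_span: int
) -> list[tuple[AnchoredPlacement, AnchoredPlacement, int]]:
    """All (flank5, flank3) placement pairs satisfying criterion i geometry."""
    pairs = []
    for p5 in p5s:
        for p3 in p3s:
            if p5.chrom != p3.chrom or p5.strand != p3.strand:
                continue
            if p5.strand == "+":
                span = p3.start - p5.end
            else:
                span = p5.start - p3.end
            if 0 <= span <= max_span:
                pairs.append((p5, p3, span))
    return pairs


def close_gap(
    gap: tuple[str, int, int],
    recipient: Genome,
    donor: Genome,
    parity_assemblies: list[Genome] = (),
    donor_depth: dict[str, np.ndarray] | None = None,
    flank: int = 500,
    max_span: int = 500_000,
    max_total_hits: int = 5,
    min_coverage: float = 0.8,
    min_identity: float = 0.8,
    per_flank_hits: bool = False,
    depth_min: float = 3.0,
    depth_covered_frac: float = 0.9,
) -> GapClosure:
    """Evaluate one merged gap against the four closure criteria.

    ``per_flank_hits`` switches criterion ii from the sum reading
    (n_hits(flank5) + n_hits(flank3) < 5, the default) to requiring each
    flank individually to have < 5 placements.
    """
    chrom, gs, ge = gap
    closure = GapClosure(chrom, gs, ge)
    seq = recipient[chrom]
    if gs < flank or ge + flank > len(seq):
        closure.failed_criterion = "edge"
        return closure
    f5 = seq[gs - flank : gs]
    f3 = seq[ge : ge + flank]
    p5s = anchor_fragment(f5, donor, min_coverage, min_identity, query_id="flank5")
    p3s = anchor_fragment(f3, donor, min_coverage, min_identity, query_id="flank3")
    pairs = _pair_candidates(p5s, p3s, max_span)
    if not pairs:
        closure.failed_criterion = "i"
        return closure
    pairs.sort(key=lambda t: t[2])
    if len(pairs) > 1 and pairs[0][2] == pairs[1][2]:
        closure.failed_criterion = "ambiguous"
        return closure
    p5, p3, span = pairs[0]
    closure.flank5, closure.flank3 = p5, p3
    closure.donor_chrom, closure.strand = p5.chrom, p5.strand

    n5 = len(p5s)
    n3 = len(p3s)
    crit_ii = (n5 < max_total_hits and n3 < max_total_hits) if per_flank_hits else (n5 + n3 < max_total_hits)
    if not crit_ii:
        closure.failed_criterion = "ii"
        return closure

    if p5.strand == "+":
        d_lo, d_hi = p5.end, p3.start
        intervening = donor[p5.chrom][d_lo:d_hi]
    else:
        d_lo, d_hi = p3.end, p5.start
        intervening = revcomp(donor[p5.chrom][d_lo:d_hi])
    closure.donor_start, closure.donor_end = d_lo, d_hi
    if not intervening:
        closure.failed_criterion = "empty"
        return closure
    if "N" in intervening:
        closure.failed_criterion = "iii"
        return closure

    ok_iv, route = _criterion_iv(
        intervening, p5.chrom, d_lo, d_hi, parity_assemblies, donor_depth,
        min_coverage, min_identity, depth_min, depth_covered_frac,
    )
    if not ok_iv:
        closure.failed_criterion = "iv"
        return closure
    closure.route = route
    closure.status = "closed"
    closure.patched_sequence = intervening
    return closure


def _criterion_iv(
    intervening, donor_chrom, d_lo, d_hi, parity_assemblies, donor_depth,
    min_coverage, min_identity, depth_min, depth_covered_frac,
):
    checked = False
    if len(intervening) >= 50:
        for assembly in parity_assemblies:
            checked = True
            if anchor_fragment(intervening, assembly, min_coverage, min_identity):
                return True, "parity"
    if donor_depth is not None and donor_chrom in donor_depth:
        checked = True
        track = donor_depth[donor_chrom][d_lo:d_hi]
        if track.size and (track > depth_min).mean() > depth_covered_frac:
            return True, "depth"
    if not checked:
        # no corroborating evidence was supplied at all; pass but flag it
        return True, "unchecked"
    return False, ""


def apply_closures(recipient: Genome, closures: list[GapClosure]) -> tuple[Genome, dict]:
    """Patch every closed gap; coordinates downstream shift consistently.

    Raises on overlapping closures (an internal inconsistency).  The
    report carries closure counts, failure tallies by criterion, and
    patch-length statistics; patched intervals are reported in the new
    coordinate system.
    """
    by_chrom: dict[str, list[GapClosure]] = {}
    for cl in closures:
        if cl.status == "closed":
            by_chrom.setdefault(cl.chrom, []).append(cl)
    new_records = []
    patched_intervals = []
    for chrom, seq in recipient.records:
        todo = sorted(by_chrom.get(chrom, []), key=lambda c: c.gap_start)
        for a, b in zip(todo, todo[1:]):
            if b.gap_start < a.gap_end:
                raise ValueError(f"overlapping closures on {chrom}")
        parts = []
        cur = 0
        offset = 0
        for cl in todo:
            parts.append(seq[cur : cl.gap_start])
            patched_intervals.append(
                (chrom, cl.gap_start + offset, cl.gap_start + offset + cl.patch_length)
            )
            parts.append(cl.patched_sequence)
            offset += cl.patch_length - cl.gap_length
            cur = cl.gap_end
        parts.append(seq[cur:])
        new_records.append((chrom, "".join(parts)))
    closed = [c for c in closures if c.status == "closed"]
    fail_counts: dict[str, int] = {}
    for c in closures:
        if c.status != "closed":
            fail_counts[c.failed_criterion] = fail_counts.get(c.failed_criterion, 0) + 1
    report = {
        "n_gaps": len(closures),
        "n_closed": len(closed),
        "n_failed": len(closures) - len(closed),
        "failures_by_criterion": fail_counts,
        "mean_patch_length": float(mean(c.patch_length for c in closed)) if closed else 0.0,
        "median_patch_length": float(median(c.patch_length for c in closed)) if closed else 0.0,
        "patched_intervals": patched_intervals,
    }
    return Genome(new_records), report


def fill_gaps(
    recipient: Genome,
    donor: Genome,
    parity_assemblies: list[Genome] = (),
    donor_depth: dict[str, np.ndarray] | None = None,
    merge_distance: int = 500,
    **close_kwargs,
) -> tuple[Genome, list[GapClosure], dict]:
    """Full protocol: merge gaps, evaluate criteria, patch the recipient."""
    gaps = extract_and_merge_gaps(recipient, merge_distance)
    closures = [
        close_gap(g, recipient, donor, parity_assemblies, donor_depth, **close_kwargs)
        for g in gaps
    ]
    patched, report = apply_closures(recipient, closures)
    return patched, closures, report


def closures_table(closures: list[GapClosure]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=c.chrom,
                gap_start=c.gap_start,
                gap_end=c.gap_end,
                gap_length=c.gap_length,
                status=c.status,
                failed_criterion=c.failed_criterion,
                donor_chrom=c.donor_chrom,
                donor_start=c.donor_start,
                donor_end=c.donor_end,
                strand=c.strand,
                route=c.route,
                patch_length=c.patch_length,
            )
            for c in closures
        ]
    )
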