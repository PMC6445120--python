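"""Structural-variant validation, PAV detection, sharing classification,
and breakpoint repeat annotation.

Candidate indels (> 100 bp) called against genome B are re-validated by
realigning the 500-bp context around each candidate onto genome A: a
deletion (sequence present in B, absent from A) must show a
correspondingly sized B-only run in the alignment, an insertion the
mirror image; borders and lengths are recalculated from the alignment.

Presence/absence variations (PAVs) come from a whole-genome block
comparison: each genome is tiled, tiles are anchored in the other
genome, aligned blocks are merged (separation <= 50 bp) and the
remaining unaligned regions longer than 100 bp — N-split, refined by
flank realignment, and supported by a cross-genome depth below 10% of
the genome-wide mean — are reported.  PAVs on genome B are deletions,
PAVs on genome A insertions, following the convention that B plays the
reference assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .seqcore import (
    Genome,
    anchor_fragment,
    parse_cigar,
    revcomp,
)

#: repeat classes in overlap precedence order (first match wins)
REPEAT_PRECEDENCE = ("LTR", "DNA", "SINE", "LINE", "Other")


@dataclass
class StructuralVariant:
    kind: str  # 'deletion' | 'insertion' | 'inversion' | 'pav'
    chrom: str  # coordinates on genome B
    start: int
    end: int
    length: int
    validated: bool = False
    recalc_start: int = -1
    recalc_end: int = -1
    recalc_length: int = -1
    shared: bool | None = None
    repeat_class: str = ""
    depth_checked: bool = True
    note: str = ""
    counterpart: tuple[str, int, int] | None = None  # location on the other genome

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# Indel validation by flank realignment
# ---------------------------------------------------------------------------


def _longest_run(cigar: str, ops: str) -> tuple[int, int, int]:
    """(query offset, target offset, run length) of the longest run of ``ops``."""
    best = (0, 0, 0)
    q = t = 0
    for n, op in parse_cigar(cigar):
        if op in ops and n > best[2]:
            best = (q, t, n)
        if op in "=XM":
            q += n
            t += n
        elif op == "I":
            q += n
        elif op == "D":
            t += n
    return best


def _walk_match(a: str, ai: int, b: str, bi: int, step: int, max_streak: int = 4, min_run: int = 6):
    """Extend a matched pair of positions until sustained divergence.

    Walks forward (step=+1, comparing a[ai], b[bi], ...) or backward
    (step=-1, comparing a[ai-1], b[bi-1], ...); isolated substitutions
    are stepped over and the walk stops at ``max_streak`` consecutive
    mismatches.  The junction is placed after the last match run of at
    least ``min_run`` bases (the run entering the walk counts as solid,
    since the flank upstream has already been anchored), which keeps
    chance single-base matches beyond the true junction from inflating
    the extension.  Returns the (a, b) junction positions.
    """
    i = 0
    streak = 0
    run = min_run
    last_good = 0
    while True:
        if step > 0:
            pa, pb = ai + i, bi + i
            if pa >= len(a) or pb >= len(b):
                break
        else:
            pa, pb = ai - 1 - i, bi - 1 - i
            if pa < 0 or pb < 0:
                break
        ca, cb = a[pa], b[pb]
        if ca == cb and ca != "N":
            streak = 0
            run += 1
            if run >= min_run:
                last_good = i + 1
        else:
            run = 0
            streak += 1
            if streak >= max_streak:
                break
        i += 1
    return (ai + last_good, bi + last_good) if step > 0 else (ai - last_good, bi - last_good)


def _junctions(
    carrier_seq: str,
    s: int,
    e: int,
    other: Genome,
    flank: int = 500,
    expect_extra: int = 0,
    min_identity: float = 0.8,
):
    """Locate the exact divergence junctions around a candidate region.

    The flanks [s-flank, s) and [e, e+flank) of the carrier are anchored
    in the other genome (unique best pair, same sequence and
    orientation), then extended inward base-by-base to the points where
    the two genomes diverge.  Returns (ja, jb, other_gap, chrom, strand):
    [ja, jb) is the carrier-only run and ``other_gap`` the number of
    other-genome bases between the junctions (the mirror insertion).
    """
    if s - flank < 0 or e + flank > len(carrier_seq):
        return None
    f5 = carrier_seq[s - flank : s]
    f3 = carrier_seq[e : e + flank]
    try:
        p5s = anchor_fragment(f5, other, 0.8, min_identity)
        p3s = anchor_fragment(f3, other, 0.8, min_identity)
    except ValueError:
        return None
    pairs = []
    for p5 in p5s:
        for p3 in p3s:
            if p5.chrom != p3.chrom or p5.strand != p3.strand:
                continue
            span = (p3.start - p5.end) if p5.strand == "+" else (p5.start - p3.end)
            if -100 <= span <= expect_extra + 2_000:
                pairs.append((p5, p3, span))
    if not pairs:
        return None
    pairs.sort(key=lambda t: abs(t[2] - expect_extra))
    p5, p3, _ = pairs[0]
    chrom, strand = p5.chrom, p5.strand
    oseq = other[chrom]
    if strand == "-":
        n = len(oseq)
        oseq = revcomp(oseq)
        o5_end, o3_start = n - p5.start, n - p3.end
    else:
        o5_end, o3_start = p5.end, p3.start
    ja, oa = _walk_match(carrier_seq, s, oseq, o5_end, +1)
    jb, ob = _walk_match(carrier_seq, e, oseq, o3_start, -1)
    if jb < ja:
        jb = ja
    return ja, jb, max(ob - oa, 0), chrom, strand


def validate_indel(
    candidate: StructuralVariant,
    genome_b: Genome,
    genome_a: Genome,
    flank: int = 500,
    min_len: int = 100,
    tol_frac: float = 0.2,
    tol_bp: float = 50,
) -> StructuralVariant:
    """Confirm or reject a candidate indel by context realignment.

    Size compatibility requires the realigned event length to be within
    ±20% or ±50 bp (whichever is larger) of the candidate length; on
    confirmation the borders and length are recalculated from the
    alignment.
    """
    sv = candidate
    if sv.length <= min_len:
        sv.validated = False
        sv.note = f"length <= {min_len}"
        return sv
    seq_b = genome_b[sv.chrom]
    lo = sv.start - flank
    hi = sv.end + flank
    if lo < 0 or hi > len(seq_b):
        sv.validated = False
        sv.note = "window beyond sequence bounds"
        return sv
    expect_extra = sv.length if sv.kind == "insertion" else 0
    jn = _junctions(seq_b, sv.start, sv.end, genome_a, flank, expect_extra)
    if jn is None:
        sv.validated = False
        sv.note = "context not anchorable"
        return sv
    ja, jb, other_gap, chrom_a, strand = jn
    run = (jb - ja) if sv.kind == "deletion" else other_gap
    tol = max(tol_frac * sv.length, tol_bp)
    if abs(run - sv.length) > tol:
        sv.validated = False
        sv.note = f"no compatible {sv.kind} run (found {run})"
        return sv
    sv.validated = True
    sv.recalc_start = ja
    sv.recalc_end = jb if sv.kind == "deletion" else ja
    sv.recalc_length = run
    sv.counterpart = (chrom_a, -1, -1) if strand else None
    return sv


# ---------------------------------------------------------------------------
# Whole-genome block comparison and PAV detection
# ---------------------------------------------------------------------------


def alignment_blocks(
    carrier: Genome,
    other: Genome,
    tile: int = 250,
    min_coverage: float = 0.8,
    min_identity: float = 0.8,
    max_shift: int = 10_000,
    lookback: int = 400,
) -> dict[str, list[tuple[int, int]]]:
    """Syntenic aligned intervals on ``carrier`` against ``other``.

    The carrier is tiled and every tile anchored in the other genome;
    only placements on the best collinear chain per carrier chromosome
    count as aligned (the analogue of a filtered one-to-one whole-genome
    alignment).  Without the chaining restriction, a genome-specific
    repeat insertion whose family has copies elsewhere in the other
    genome would spuriously appear aligned and never surface as a PAV.
    ``max_shift`` bounds the diagonal offset between consecutive chain
    members, i.e. the largest indel the chain can step across.
    """
    blocks: dict[str, list[tuple[int, int]]] = {}
    for chrom, seq in carrier.records:
        cands: list[tuple[int, int, str, str, int]] = []
        for s in range(0, max(len(seq) - tile + 1, 1), tile):
            frag = seq[s : s + tile]
            if len(frag) < 50 or frag.count("N") > 0.5 * len(frag):
                continue
            try:
                hits = anchor_fragment(frag, other, min_coverage, min_identity)
            except ValueError:
                continue
            for h in hits[:8]:
                tkey = h.start if h.strand == "+" else -h.start
                cands.append((s, min(s + tile, len(seq)), h.chrom, h.strand, tkey))
        cands.sort(key=lambda t: (t[0], t[4]))
        n = len(cands)
        score = [1] * n
        parent = [-1] * n
        for i in range(n):
            ci = cands[i]
            for j in range(max(0, i - lookback), i):
                cj = cands[j]
                if cj[0] >= ci[0] or cj[2] != ci[2] or cj[3] != ci[3]:
                    continue
                dt = ci[4] - cj[4]
                if dt <= 0 or abs(dt - (ci[0] - cj[0])) > max_shift:
                    continue
                if score[j] + 1 > score[i]:
                    score[i] = score[j] + 1
                    parent[i] = j
        ivals: list[tuple[int, int]] = []
        if n:
            i = max(range(n), key=lambda x: score[x])
            while i != -1:
                ivals.append((cands[i][0], cands[i][1]))
                i = parent[i]
        blocks[chrom] = _merge_intervals(ivals, 0)
    return blocks


def _merge_intervals(ivals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _split_on_n(seq: str, s: int, e: int, min_len: int) -> list[tuple[int, int]]:
    """Split [s, e) at N bases; keep N-free pieces longer than ``min_len``."""
    out = []
    run_start = None
    for i in range(s, e):
        if seq[i] == "N":
            if run_start is not None and i - run_start > min_len:
                out.append((run_start, i))
            run_start = None
        elif run_start is None:
            run_start = i
    if run_start is not None and e - run_start > min_len:
        out.append((run_start, e))
    return out


def _refine_region(
    carrier: Genome, other: Genome, chrom: str, s: int, e: int, flank: int = 500, pad: int = 300
):
    """Tighten a coarse unaligned region to the exact carrier-only run.

    The coarse tile-quantised boundaries may sit slightly inside the
    novel segment, so the region is first padded outward to guarantee
    the flanks lie in shared sequence; the junction walk then recovers
    the exact boundaries.
    """
    seq = carrier[chrom]
    s, e = max(s - pad, 0), min(e + pad, len(seq))
    if s - flank < 0 or e + flank > len(seq):
        return None
    if "N" in seq[s - flank : s] or "N" in seq[e : e + flank]:
        return None
    jn = _junctions(seq, s, e, other, flank)
    if jn is None:
        return None
    ja, jb, _, _, _ = jn
    if jb <= ja:
        return None
    return ja, jb


def detect_pav(
    genome_a: Genome,
    genome_b: Genome,
    depth_a: dict[str, np.ndarray] | None = None,
    depth_b: dict[str, np.ndarray] | None = None,
    blocks_a: dict[str, list[tuple[int, int]]] | None = None,
    blocks_b: dict[str, list[tuple[int, int]]] | None = None,
    merge_distance: int = 50,
    min_len: int = 100,
    depth_fraction: float = 0.1,
    tile: int = 250,
    refine: bool = True,
) -> list[StructuralVariant]:
    """Presence/absence variations between the two genomes.

    ``depth_a``/``depth_b`` are per-base depth tracks of cross-genome
    reads on each assembly; a region only qualifies as a PAV when its
    average depth is below ``depth_fraction`` of the genome-wide mean.
    With no track supplied the filter is skipped and every emitted PAV
    carries ``depth_checked=False``.  Precomputed aligned blocks (e.g.
    imported from an external whole-genome aligner) can be passed in
    place of the internal tiling comparison.
    """
    out: list[StructuralVariant] = []
    for carrier, other, depth, kind in (
        (genome_b, genome_a, depth_b, "deletion"),
        (genome_a, genome_b, depth_a, "insertion"),
    ):
        blocks = blocks_b if kind == "deletion" else blocks_a
        if blocks is None:
            blocks = alignment_blocks(carrier, other, tile=tile)
        mean_depth = _genome_mean_depth(carrier, depth) if depth is not None else None
        for chrom, seq in carrier.records:
            aligned = _merge_intervals(blocks.get(chrom, []), merge_distance)
            unaligned = _complement(aligned, len(seq))
            for s, e in unaligned:
                if e - s <= min_len:
                    continue
                if refine:
                    refined = _refine_region(carrier, other, chrom, s, e)
                    if refined is not None:
                        s, e = refined
                        if e - s <= min_len:
                            continue
                for ps, pe in _split_on_n(seq, s, e, min_len):
                    sv = StructuralVariant(kind=kind, chrom=chrom, start=ps, end=pe, length=pe - ps)
                    if depth is not None and mean_depth:
                        region = depth[chrom][ps:pe]
                        if region.size and region.mean() >= depth_fraction * mean_depth:
                            continue
                    else:
                        sv.depth_checked = False
                        sv.note = "no depth track; depth filter skipped"
                    out.append(sv)
    return out


def _genome_mean_depth(genome: Genome, depth: dict[str, np.ndarray]) -> float:
    """Genome-wide mean depth over non-N positions."""
    tot = n = 0.0
    for chrom, seq in genome.records:
        arr = depth.get(chrom)
        if arr is None:
            continue
        mask = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) != ord("N")
        tot += float(arr[mask].sum())
        n += float(mask.sum())
    return tot / n if n else 0.0


def _complement(ivals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out = []
    cur = 0
    for s, e in ivals:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        out.append((cur, length))
    return out


# ---------------------------------------------------------------------------
# Sharing classification and breakpoint annotation
# ---------------------------------------------------------------------------


def classify_shared(
    variant: StructuralVariant, parity_calls: list[bool], donor_check: bool
) -> StructuralVariant:
    """Shared iff present in every parity assembly and absent from the donor set.

    This mirrors the definition of cultivar-shared variants: a variant
    counts as shared only when all independent assemblies of the
    reference cultivar carry it while the donor line does not.
    """
    variant.shared = bool(parity_calls) and all(parity_calls) and not donor_check
    return variant


def allele_present(
    variant: StructuralVariant,
    genome_b: Genome,
    assembly: Genome,
    flank: int = 500,
    min_coverage: float = 0.8,
    min_identity: float = 0.8,
    max_gap: int = 50,
) -> bool:
    """Does ``assembly`` carry the genome-B allele of ``variant``?

    For a deletion (segment present in B) the test is whether the
    segment-with-context anchors contiguously; for an insertion (absent
    from B) whether the B junction context anchors without a large gap.
    """
    seq = genome_b[variant.chrom]
    lo = max(variant.start - flank, 0)
    hi = min(variant.end + flank, len(seq))
    context = seq[lo:hi]
    if "N" in context:
        context = max(_split_on_n(seq, lo, hi, 50), key=lambda t: t[1] - t[0], default=None)
        if context is None:
            return False
        context = seq[context[0] : context[1]]
    hits = anchor_fragment(context, assembly, min_coverage, min_identity)
    if not hits:
        return False
    best = hits[0]
    # a contiguous placement must not hide a large target-only run
    _, _, drun = _longest_run(best.cigar, "D")
    return drun <= max_gap


def annotate_breakpoints(
    variants: list[StructuralVariant],
    repeat_annotation: dict[str, list[tuple[int, int, str]]],
) -> list[StructuralVariant]:
    """Assign a repeat class to each variant by overlap.

    A repeat element is associated with a variant if it overlaps it;
    overlapping classes resolve by the fixed precedence LTR > DNA > SINE
    > LINE > Other, and 'Non' means no repeat overlap.  For inversions
    both breakpoints are annotated (classes joined with '/').
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, ivals in repeat_annotation.items():
        trees[chrom] = IntervalTree()
        for s, e, cls in ivals:
            if e > s:
                trees[chrom].addi(s, e, cls)

    def best_class(chrom: str, s: int, e: int) -> str:
        tree = trees.get(chrom)
        if tree is None:
            return "Non"
        found = {iv.data for iv in tree.overlap(s, max(e, s + 1))}
        for cls in REPEAT_PRECEDENCE:
            if cls in found:
                return cls
        return "Other" if found else "Non"

    for sv in variants:
        if sv.kind == "inversion":
            left = best_class(sv.chrom, sv.start, sv.start + 1)
            right = best_class(sv.chrom, sv.end - 1, sv.end)
            sv.repeat_class = f"{left}/{right}"
        else:
            sv.repeat_class = best_class(sv.chrom, sv.start, sv.end)
    return variants


def summarize_by_chrom(variants: list[StructuralVariant]) -> "pd.DataFrame":
    import pandas as pd

    rows = {}
    for sv in variants:
        key = (sv.chrom, sv.kind)
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [dict(chrom=c, kind=k, count=n) for (c, k), n in sorted(rows.items())]
    )
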