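"""Assembly QC: telomere detection, heterochromatin window scan, summary statistics.

Telomeres in plants are tandem arrays of the 7-mer TTTAGGG at the 3' end
of each chromosome strand; on the 5' end the reverse complement
(CCCTAAA) is seen.  Pericentromeric heterochromatin is approximated by
1-Mb windows (250-kb step) whose repeat-element coverage exceeds 90%,
with adjacent qualifying windows merged into blocks.

The module also ships the published per-chromosome statistics table of
the two apple cultivar assemblies (HFTH1 / GDDH13) so that headline
tabulations — total telomere count, number of both-end chromosomes,
longest chromosome — can be recomputed from the printed numbers.
"""

from __future__ import annotations

import importlib.resources
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqcore import Genome, revcomp


@dataclass
class TelomereCall:
    chrom: str
    end: str  # '5prime' | '3prime'
    copies: int
    start: int
    stop: int


@dataclass
class ChromStats:
    chrom: str
    length: int
    n_gaps: int
    telomere_status: str  # 'Both' | 'Single' | 'None'


# ---------------------------------------------------------------------------
# Telomeres
# ---------------------------------------------------------------------------


def _tandem_arrays(region: str, unit: str, max_interrupt_frac: float, strict: bool):
    """Maximal tandem arrays of ``unit`` in ``region``.

    Returns (start, end, copies) triples.  In tolerant mode up to 10%
    interrupting bases are allowed inside an array (real telomere arrays
    are imperfect); strict mode requires exact back-to-back copies.
    """
    u = len(unit)
    starts = []
    i = region.find(unit)
    while i != -1:
        starts.append(i)
        i = region.find(unit, i + 1)
    # drop overlapping self-matches: keep greedy non-overlapping chain
    arrays = []
    cur = None  # [start, last_end, copies, interrupts]
    for s in starts:
        if cur and s < cur[1]:
            continue
        if cur is None:
            cur = [s, s + u, 1, 0]
            continue
        gap = s - cur[1]
        span = s + u - cur[0]
        if gap == 0 or (not strict and 0 < gap <= 3 * u and (cur[3] + gap) <= max_interrupt_frac * span):
            cur[1] = s + u
            cur[2] += 1
            cur[3] += gap
        else:
            arrays.append((cur[0], cur[1], cur[2]))
            cur = [s, s + u, 1, 0]
    if cur:
        arrays.append((cur[0], cur[1], cur[2]))
    return arrays


def detect_telomeres(
    genome: Genome,
    unit: str = "TTTAGGG",
    end_window: int = 50_000,
    min_copies: int = 100,
    max_interrupt_frac: float = 0.1,
    touch_slack: int = 1_000,
    strict: bool = False,
) -> list[TelomereCall]:
    """Telomere-unit tandem arrays at chromosome ends.

    For each chromosome the terminal ``end_window`` bases are scanned for
    the maximal tandem array of ``unit`` (5' end: reverse complement of
    the unit).  A call is reported when the array has at least
    ``min_copies`` copies and reaches to within ``touch_slack`` bases of
    the terminus.
    """
    if len(unit) < 4:
        raise ValueError("telomere unit must be at least 4 bases")
    calls = []
    for chrom, seq in genome.records:
        w = min(end_window, len(seq))
        for end, region, probe, offset in (
            ("5prime", seq[:w], revcomp(unit), 0),
            ("3prime", seq[-w:], unit, len(seq) - w),
        ):
            best = None
            for s, e, copies in _tandem_arrays(region, probe, max_interrupt_frac, strict):
                terminus_dist = s if end == "5prime" else w - e
                if copies >= min_copies and terminus_dist <= touch_slack:
                    if best is None or copies > best[2]:
                        best = (s, e, copies)
            if best:
                s, e, copies = best
                calls.append(TelomereCall(chrom, end, copies, offset + s, offset + e))
    return calls


def telomere_status(genome: Genome, calls: list[TelomereCall]) -> dict[str, str]:
    per = {c: set() for c in genome.ids()}
    for call in calls:
        per[call.chrom].add(call.end)
    return {
        c: "Both" if len(ends) == 2 else ("Single" if len(ends) == 1 else "None")
        for c, ends in per.items()
    }


# ---------------------------------------------------------------------------
# Heterochromatin scan
# ---------------------------------------------------------------------------


class _CoverageIndex:
    """Covered-bases prefix sums over merged intervals."""

    def __init__(self, intervals: list[tuple[int, int]]):
        merged = []
        for s, e in sorted(intervals):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self.starts = [s for s, _ in merged]
        self.ends = [e for _, e in merged]
        self.cum = np.concatenate([[0], np.cumsum([e - s for s, e in merged])]) if merged else np.array([0])

    def covered(self, lo: int, hi: int) -> int:
        def cov_upto(x: int) -> int:
            i = bisect_right(self.starts, x)
            if i == 0:
                return 0
            s, e = self.starts[i - 1], self.ends[i - 1]
            return int(self.cum[i - 1]) + min(max(x - s, 0), e - s)

        return cov_upto(hi) - cov_upto(lo)


def scan_heterochromatin(
    repeat_annotation: dict[str, list[tuple[int, int]]],
    chrom_lengths: dict[str, int],
    window: int = 1_000_000,
    step: int = 250_000,
    threshold: float = 0.9,
) -> list[tuple[str, int, int]]:
    """Merged blocks of windows whose repeat coverage strictly exceeds ``threshold``.

    Windows of ``window`` bases slide by ``step``; a window at exactly
    the threshold does not qualify (strict inequality).
    """
    blocks = []
    for chrom, length in chrom_lengths.items():
        idx = _CoverageIndex(repeat_annotation.get(chrom, []))
        qualifying = []
        s = 0
        while s + window <= length:
            frac = idx.covered(s, s + window) / window
            if frac > threshold:
                qualifying.append((s, s + window))
            s += step
        for qs, qe in qualifying:
            if blocks and blocks[-1][0] == chrom and qs <= blocks[-1][2]:
                blocks[-1][2] = max(blocks[-1][2], qe)
            else:
                blocks.append([chrom, qs, qe])
    return [(c, s, e) for c, s, e in blocks]


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------


def contig_n50(segment_lengths: list[int]) -> int:
    """N50 over gap-delimited segments: shortest length whose cumulative sum
    (over segments at least that long) reaches half the total."""
    if not segment_lengths:
        return 0
    lens = sorted(segment_lengths, reverse=True)
    half = sum(lens) / 2
    acc = 0
    for ln in lens:
        acc += ln
        if acc >= half:
            return ln
    return lens[-1]


def assembly_stats(
    genome: Genome,
    telomere_calls: list[TelomereCall],
    gap_runs: list[tuple[str, int, int]],
) -> tuple[list[ChromStats], dict]:
    """Per-chromosome statistics and a genome-level summary.

    Contigs are the segments between N-gap runs, so the N50 reflects gap
    structure; the telomere tabulation counts Both as two and Single as
    one captured telomere.
    """
    status = telomere_status(genome, telomere_calls)
    gaps_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.ids()}
    for c, s, e in gap_runs:
        gaps_by_chrom[c].append((s, e))
    rows = []
    seg_lens = []
    for chrom, seq in genome.records:
        gaps = sorted(gaps_by_chrom[chrom])
        rows.append(ChromStats(chrom, len(seq), len(gaps), status[chrom]))
        cur = 0
        for s, e in gaps:
            if s > cur:
                seg_lens.append(s - cur)
            cur = e
        if len(seq) > cur:
            seg_lens.append(len(seq) - cur)
    rows.sort(key=lambda r: r.chrom)
    counts = {k: sum(1 for r in rows if r.telomere_status == k) for k in ("Both", "Single", "None")}
    summary = {
        "total_length": genome.total_length(),
        "n_chromosomes": len(rows),
        "n_gaps": sum(r.n_gaps for r in rows),
        "contig_n50": contig_n50(seg_lens),
        "telomere_both": counts["Both"],
        "telomere_single": counts["Single"],
        "telomere_none": counts["None"],
        "telomere_total": 2 * counts["Both"] + counts["Single"],
    }
    return rows, summary


def stats_table(rows: list[ChromStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(chrom=r.chrom, length=r.length, n_gaps=r.n_gaps, telomere=r.telomere_status) for r in rows]
    )


# ---------------------------------------------------------------------------
# Published assembly table
# ---------------------------------------------------------------------------


def load_published_stats() -> pd.DataFrame:
    """Per-chromosome published statistics of the HFTH1 and GDDH13 assemblies."""
    ref = importlib.resources.files("pairgenome") / "data" / "published_assembly_stats.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def tabulate_published(df: pd.DataFrame, which: str = "hfth1") -> dict:
    """Headline tabulations recomputed from the published per-chromosome table.

    ``telomere_total`` counts two stretches for a Both chromosome and one
    for a Single; organelles (telomere 'NA') are excluded, as is the
    unanchored bin for the maximum-length lookup.
    """
    which = which.lower()
    telo = df[f"{which}_telomere"]
    both = int((telo == "Both").sum())
    single = int((telo == "Single").sum())
    nuclear = df[df.chrom.str.startswith("Chr")]
    max_row = nuclear.loc[nuclear[f"{which}_length"].idxmax()]
    return {
        "telomere_total": 2 * both + single,
        "both_end_chromosomes": both,
        "single_end_chromosomes": single,
        "max_chrom_length": int(max_row[f"{which}_length"]),
        "max_chrom": str(max_row["chrom"]),
        "total_gaps": int(nuclear[f"{which}_gaps"].sum()),
    }
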