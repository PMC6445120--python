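"""Cross-genome LTR retrotransposon dynamics.

An intact LTR retrotransposon (LTR-RT) is bounded by two near-identical
direct repeats (LTRs) that start with TG and end with CA, flanked by two
identical copies of a 4-6 bp target-site duplication (TSD).  Because the
two LTRs are identical at insertion, their divergence K is a molecular
clock: T = K / (2r) with r the neutral substitution rate (1.3e-8 per
site per year for apple).

Comparing the site of each element detected in genome A against genome
B classifies its history:

* Shared      — B carries an orthologous copy (>100 bp intervening
                sequence with a local hit to the A element); subdivided
                at 99% global identity into high/low similarity.
* Insertion   — B shows a single TSD copy with no intervening sequence:
                the element inserted in the A lineage after divergence.
* Elimination — the intervening B sequence has no hit to the element
                and carries two or zero TSDs: the element was lost from
                the B lineage.
* Unknown     — anything else.

Elements whose 500-bp flanks do not anchor uniquely (within 20 kb, same
orientation) in either genome are discarded and counted separately.

The module also provides the cumulative-nucleotide-substitution (CNS)
analyses around elements: flank/interior substitution profiles against
randomly placed control blocks, the per-element substitution rate
V = (S_f - S_c)/T_ltr + S_c/(2 T_div), insertion-site distance to genes,
and CNS as a function of element age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import (
    Genome,
    anchor_fragment,
    global_identity,
    revcomp,
    substitution_count,
)

DEFAULT_RATE = 1.3e-8

CLASSES = ("SharedHigh", "SharedLow", "Insertion", "Elimination", "Unknown")


@dataclass
class LtrElement:
    """An intact LTR retrotransposon in genome A.

    ``start``/``end`` delimit the element body (both LTRs included, TSD
    copies excluded); the TSD copies sit immediately outside.
    """

    chrom: str
    start: int
    end: int
    ltr_len: int
    tsd5: str
    tsd3: str
    terminal_motif_ok: bool = True
    identity_ltr: float = 0.0  # similarity of the two LTRs
    K: float = float("nan")  # raw LTR-LTR divergence (subs per site)
    T_ltr: float = float("nan")  # insertion time, years
    cls: str = ""  # one of CLASSES, or 'discarded'
    discard_reason: str = ""
    identity_cross: float = float("nan")  # A vs B intervening global identity
    # anchored site geometry (inner flank edges around TSD+element+TSD)
    a_iv: tuple[int, int] | None = field(default=None, repr=False)
    b_chrom: str = field(default="", repr=False)
    b_strand: str = field(default="", repr=False)
    b_iv: tuple[int, int] | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    def ltr5_seq(self, genome: Genome) -> str:
        return genome[self.chrom][self.start : self.start + self.ltr_len]

    def ltr3_seq(self, genome: Genome) -> str:
        return genome[self.chrom][self.end - self.ltr_len : self.end]

    def body_seq(self, genome: Genome) -> str:
        return genome[self.chrom][self.start : self.end]


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _seed_pairs(seq: str, k: int, min_d: int, max_d: int, max_occ: int):
    """(pos5, pos3) pairs of k-mers repeated within an element-scale distance."""
    from .seqcore import _rolling_codes, encode_bases  # reuse internals

    codes, valid = _rolling_codes(encode_bases(seq), k)
    idx = np.nonzero(valid)[0]
    codes = codes[idx]
    order = np.argsort(codes, kind="stable")
    codes, pos = codes[order], idx[order]
    pairs = []
    n = codes.size
    i = 0
    while i < n:
        j = i + 1
        while j < n and codes[j] == codes[i]:
            j += 1
        if 2 <= j - i <= max_occ:
            grp = np.sort(pos[i:j])
            for x in range(grp.size):
                for y in range(x + 1, grp.size):
                    d = grp[y] - grp[x]
                    if min_d <= d <= max_d:
                        pairs.append((int(grp[x]), int(d)))
        i = j
    return pairs


def _cluster_pairs(pairs, k: int, max_ltr: int, band: int = 24):
    """Group seed pairs into candidate (ltr5_start, ltr5_extent_end, distance)."""
    pairs.sort(key=lambda t: (t[1], t[0]))
    clusters = []
    cur: list[tuple[int, int]] = []
    for p, d in pairs:
        if cur and (d - cur[-1][1] > band or p - cur[-1][0] > max_ltr):
            clusters.append(cur)
            cur = []
        cur.append((p, d))
    if cur:
        clusters.append(cur)
    out = []
    for cl in clusters:
        ps = [p for p, _ in cl]
        ds = [d for _, d in cl]
        out.append((min(ps), max(ps) + k, int(np.median(ds))))
    return out


def _refine_candidate(
    seq: str,
    a0: int,
    ext_end: int,
    d: int,
    min_ltr: int,
    max_ltr: int,
    min_similarity: float,
    tsd_range: tuple[int, int],
    motif: str,
    slack: int = 176,
):
    """Pin exact LTR boundaries using the terminal motif and the TSD constraint."""
    m5, m3 = motif[:2], motif[2:]
    n = len(seq)

    def motif_starts(center: int) -> list[int]:
        lo, hi = max(center - slack, 0), min(center + 16, n - 2)
        return [i for i in range(lo, hi) if seq[i : i + 2] == m5]

    best = None
    for a in motif_starts(a0):
        for b in motif_starts(a0 + d):
            if b <= a:
                continue
            # candidate LTR lengths: both LTRs must end with the CA motif
            l_lo = max(min_ltr, ext_end - a - 16)
            l_hi = min(max_ltr, b - a, ext_end - a + slack)
            for L in range(l_lo, l_hi + 1):
                if seq[a + L - 2 : a + L] != m3 or seq[b + L - 2 : b + L] != m3:
                    continue
                tsd = None
                for t in range(tsd_range[1], tsd_range[0] - 1, -1):
                    cand5 = seq[a - t : a]
                    cand3 = seq[b + L : b + L + t]
                    if len(cand5) == t and cand5 == cand3 and "N" not in cand5:
                        tsd = cand5
                        break
                if tsd is None:
                    continue
                ident = global_identity(seq[a : a + L], seq[b : b + L])
                if ident < min_similarity:
                    continue
                # alignment-style score (match +1, mismatch/gap -2): trimming a
                # mismatch-dense LTR tail loses score, and so does extending
                # into flanking sequence, where even optimally gapped random
                # DNA matches only ~55% of columns
                score = ((3.0 * ident - 2.0) * L, ident)
                if best is None or score > best[0]:
                    best = (score, a, b, L, tsd, ident)
    if best is None:
        return None
    _, a, b, L, tsd, ident = best
    return LtrElement(
        chrom="",
        start=a,
        end=b + L,
        ltr_len=L,
        tsd5=tsd,
        tsd3=tsd,
        terminal_motif_ok=True,
        identity_ltr=ident,
    )


def detect_intact_ltr(
    genome: Genome,
    min_ltr: int = 100,
    max_ltr: int = 7000,
    min_similarity: float = 0.9,
    tsd_range: tuple[int, int] = (4, 6),
    motif: str = "TGCA",
    k: int = 21,
    max_element_span: int = 25_000,
    max_seed_occ: int = 100,
) -> list[LtrElement]:
    """Detect intact LTR elements: paired direct repeats with motif and TSDs.

    A simplified detector sufficient for simulator-grade genomes: seeds
    are exact k-mers repeated at element-scale distance, candidates are
    refined to exact boundaries using the TG...CA motif and the
    requirement of identical 4-6 bp TSD copies, and overlapping
    candidates resolve to the best-scoring one.  It is not a substitute
    for a full repeat-dense-genome annotator.
    """
    elements: list[LtrElement] = []
    for chrom, seq in genome.records:
        pairs = _seed_pairs(seq, k, min_ltr, max_element_span, max_seed_occ)
        cands = []
        for a0, ext_end, d in _cluster_pairs(pairs, k, max_ltr):
            el = _refine_candidate(
                seq, a0, ext_end, d, min_ltr, max_ltr, min_similarity, tsd_range, motif
            )
            if el is not None and el.length <= max_element_span:
                el.chrom = chrom
                cands.append(el)
        cands.sort(key=lambda e: (-(e.identity_ltr * e.length), e.start))
        taken: list[LtrElement] = []
        for el in cands:
            if all(el.end <= o.start or el.start >= o.end for o in taken):
                taken.append(el)
        elements.extend(sorted(taken, key=lambda e: e.start))
    return elements


# ---------------------------------------------------------------------------
# Dating
# ---------------------------------------------------------------------------


def ltr_divergence(element: LtrElement, genome: Genome) -> float:
    """Raw per-site divergence K between the element's two LTRs."""
    subs, sites = substitution_count(element.ltr5_seq(genome), element.ltr3_seq(genome))
    return subs / sites if sites else 0.0


def insertion_time(K: float, rate: float = DEFAULT_RATE, jc_correct: bool = False) -> float:
    """Insertion time T = d / (2 * rate), d raw or Jukes-Cantor corrected.

    The JC correction d = -(3/4) ln(1 - 4K/3) is undefined for K >= 0.75.
    Strictly increasing in K in both modes.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if jc_correct:
        if K >= 0.75:
            raise ValueError("Jukes-Cantor correction undefined for K >= 0.75")
        d = -0.75 * math.log1p(-4.0 * K / 3.0)
    else:
        d = K
    return d / (2.0 * rate)


def date_elements(
    elements: list[LtrElement],
    genome: Genome,
    rate: float = DEFAULT_RATE,
    jc_correct: bool = False,
) -> list[LtrElement]:
    for el in elements:
        el.K = ltr_divergence(el, genome)
        el.T_ltr = insertion_time(el.K, rate, jc_correct)
    return elements


# ---------------------------------------------------------------------------
# Cross-genome classification
# ---------------------------------------------------------------------------


def _has_local_hit(query: str, subject: str, k: int = 16, min_hits: int = 2) -> bool:
    """Local-similarity test: do the sequences share ``min_hits`` exact k-mers?

    Stands in for a low-stringency local aligner when asking whether an
    intervening sequence retains any trace of the element.  k and the
    hit count are chosen so that unrelated multi-kilobase sequences
    essentially never qualify, while homologous copies at any divergence
    the classifier must handle share hundreds of intact k-mers.
    """
    if len(query) < k or len(subject) < k:
        return False
    kmers = {subject[i : i + k] for i in range(len(subject) - k + 1)}
    hits = 0
    for q in (query, revcomp(query)):
        for i in range(len(q) - k + 1):
            if q[i : i + k] in kmers:
                hits += 1
                if hits >= min_hits:
                    return True
    return False


def _anchor_flank_pair(f5: str, f3: str, genome: Genome, window: int, min_identity: float):
    """Unique, same-orientation placements of the two flanks within ``window``."""
    p5s = anchor_fragment(f5, genome, 0.8, min_identity, query_id="flank5")
    p3s = anchor_fragment(f3, genome, 0.8, min_identity, query_id="flank3")
    if len(p5s) != 1 or len(p3s) != 1:
        return None
    p5, p3 = p5s[0], p3s[0]
    if p5.chrom != p3.chrom or p5.strand != p3.strand:
        return None
    span = (p3.start - p5.end) if p5.strand == "+" else (p5.start - p3.end)
    if not -10 <= span <= window:
        return None
    return p5, p3


def classify_cross_genome(
    element: LtrElement,
    genome_a: Genome,
    genome_b: Genome,
    flank: int = 500,
    window: int = 20_000,
    high_similarity: float = 0.99,
    min_flank_identity: float = 0.8,
    shared_min_len: int = 100,
    insertion_slack: int = 10,
) -> LtrElement:
    """Classify one genome-A element against genome B (see module docstring).

    Flanks are the 500-bp fragments immediately outside the TSD copies.
    Non-uniquely anchoring elements are discarded with a reason, first
    against genome A itself, then against genome B, mirroring a
    two-stage removal.  ``insertion_slack`` tolerates a few bases of
    alignment-edge jitter in the "no intervening sequence" condition.
    """
    seq_a = genome_a[element.chrom]
    t = len(element.tsd5)
    lo = element.start - t - flank
    hi = element.end + t + flank
    if lo < 0 or hi > len(seq_a):
        element.cls = "discarded"
        element.discard_reason = "flank_at_edge"
        return element
    f5 = seq_a[lo : element.start - t]
    f3 = seq_a[element.end + t : hi]

    pair_a = _anchor_flank_pair(f5, f3, genome_a, window, min_flank_identity)
    if pair_a is None:
        element.cls = "discarded"
        element.discard_reason = "nonunique_in_A"
        return element
    pa5, pa3 = pair_a
    element.a_iv = (pa5.end, pa3.start)

    pair_b = _anchor_flank_pair(f5, f3, genome_b, window, min_flank_identity)
    if pair_b is None:
        element.cls = "discarded"
        element.discard_reason = "nonunique_in_B"
        return element
    pb5, pb3 = pair_b
    element.b_chrom, element.b_strand = pb5.chrom, pb5.strand
    if pb5.strand == "+":
        element.b_iv = (pb5.end, pb3.start)
        iv_b = genome_b[pb5.chrom][pb5.end : pb3.start]
    else:
        element.b_iv = (pb3.end, pb5.start)
        iv_b = revcomp(genome_b[pb5.chrom][pb3.end : pb5.start])
    iv_a = seq_a[pa5.end : pa3.start]
    body = element.body_seq(genome_a)

    if len(iv_b) > shared_min_len and _has_local_hit(iv_b, body):
        element.identity_cross = global_identity(iv_a, iv_b)
        element.cls = "SharedHigh" if element.identity_cross >= high_similarity else "SharedLow"
    elif len(iv_b) <= t + insertion_slack and element.tsd5 in iv_b:
        element.cls = "Insertion"
    elif not _has_local_hit(iv_b, body) and _tsd_count(iv_b, element.tsd5, t) != 1:
        element.cls = "Elimination"
    else:
        element.cls = "Unknown"
    return element


def _tsd_count(iv: str, tsd: str, t: int) -> int:
    """0, 1 or 2 TSD copies at the edges of an intervening sequence."""
    if len(iv) < t:
        return 0
    n = int(iv[:t] == tsd) + int(iv[-t:] == tsd)
    if len(iv) == t and n == 2:
        return 1
    return n


def classify_elements(
    elements: list[LtrElement], genome_a: Genome, genome_b: Genome, **kwargs
) -> list[LtrElement]:
    return [classify_cross_genome(el, genome_a, genome_b, **kwargs) for el in elements]


def class_summary(elements: list[LtrElement]) -> dict:
    counts = {c: 0 for c in CLASSES}
    discarded: dict[str, int] = {}
    ages: dict[str, list[float]] = {c: [] for c in CLASSES}
    for el in elements:
        if el.cls == "discarded":
            discarded[el.discard_reason] = discarded.get(el.discard_reason, 0) + 1
        elif el.cls in counts:
            counts[el.cls] += 1
            if not math.isnan(el.T_ltr):
                ages[el.cls].append(el.T_ltr)
    return {
        "counts": counts,
        "discarded": discarded,
        "n_total": len(elements),
        "mean_age_years": {
            c: (float(np.mean(a)) if a else None) for c, a in ages.items()
        },
    }


def elements_table(elements: list[LtrElement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=e.chrom,
                start=e.start,
                end=e.end,
                ltr_len=e.ltr_len,
                tsd=e.tsd5,
                identity_ltr=round(e.identity_ltr, 5),
                K=e.K,
                T_ltr=e.T_ltr,
                cls=e.cls,
                discard_reason=e.discard_reason,
                identity_cross=e.identity_cross,
            )
            for e in elements
        ]
    )


# ---------------------------------------------------------------------------
# Cumulative nucleotide substitutions (CNS)
# ---------------------------------------------------------------------------


def _aligned_mismatch_positions(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    """(a-positions of compared columns, mismatch flags), N/gap columns excluded."""
    import edlib

    from .seqcore import _align_columns

    res = edlib.align(a, b, mode="NW", task="path")
    pos, mm = [], []
    ia = 0
    for x, y in _align_columns(a, b, res["cigar"]):
        if x != "-":
            if y != "-" and x != "N" and y != "N":
                pos.append(ia)
                mm.append(x != y)
            ia += 1
    return np.asarray(pos, dtype=np.int64), np.asarray(mm, dtype=bool)


def flank_substitution_frequency(
    element: LtrElement, genome_a: Genome, genome_b: Genome, flank: int = 500
) -> float:
    """Mean substitution frequency of the element's two 500-bp flanks (A vs B)."""
    if element.a_iv is None or element.b_iv is None:
        raise ValueError("element flanks are not anchored; classify it first")
    a = genome_a[element.chrom]
    b = genome_b[element.b_chrom]
    a_up = a[element.a_iv[0] - flank : element.a_iv[0]]
    a_dn = a[element.a_iv[1] : element.a_iv[1] + flank]
    if element.b_strand == "+":
        b_up = b[element.b_iv[0] - flank : element.b_iv[0]]
        b_dn = b[element.b_iv[1] : element.b_iv[1] + flank]
    else:
        b_up = revcomp(b[element.b_iv[1] : element.b_iv[1] + flank])
        b_dn = revcomp(b[element.b_iv[0] - flank : element.b_iv[0]])
    subs = sites = 0
    for x, y in ((a_up, b_up), (a_dn, b_dn)):
        if x and y:
            s, n = substitution_count(x, y)
            subs += s
            sites += n
    return subs / sites if sites else float("nan")


def control_substitution_frequency(
    element: LtrElement,
    genome_a: Genome,
    genome_b: Genome,
    offset: int = 9_000,
    length: int = 2_000,
    min_identity: float = 0.8,
) -> float:
    """Substitution frequency of a putatively neutral region 9 kb downstream.

    The control region is anchored in genome B; NaN when it cannot be
    placed uniquely.
    """
    a = genome_a[element.chrom]
    lo = element.a_iv[1] + offset if element.a_iv else element.end + offset
    seg = a[lo : lo + length]
    if len(seg) < length or "N" in seg:
        return float("nan")
    hits = anchor_fragment(seg, genome_b, 0.8, min_identity)
    if len(hits) != 1:
        return float("nan")
    h = hits[0]
    bseq = genome_b[h.chrom][h.start : h.end]
    if h.strand == "-":
        bseq = revcomp(bseq)
    s, n = substitution_count(seg, bseq)
    return s / n if n else float("nan")


def cns_profile(
    elements: list[LtrElement],
    genome_a: Genome,
    genome_b: Genome,
    flank_extent: int = 2_000,
    flank_window: int = 400,
    flank_step: int = 100,
    inner_bins: int = 10,
    n_control: int = 3_000,
    control_len: int = 20_000,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Substitution profile around and inside shared elements, with controls.

    Flank substitutions are measured in sliding windows of
    ``flank_window`` bases (step ``flank_step``) out to ``flank_extent``
    from the element edge, averaged over the up- and downstream flanks
    of every anchored Shared element; the element interior is split into
    ``inner_bins`` equal bins.  The control distribution comes from
    ``n_control`` random ``control_len`` blocks of genome A anchored in
    genome B.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    flank_rows: dict[int, list[float]] = {}
    bin_rows: dict[int, list[float]] = {i: [] for i in range(inner_bins)}
    skipped = 0
    for el in elements:
        if not el.cls.startswith("Shared"):
            continue
        if el.a_iv is None or el.b_iv is None:
            skipped += 1
            continue
        a = genome_a[el.chrom]
        b = genome_b[el.b_chrom]
        a_up = a[max(el.a_iv[0] - flank_extent, 0) : el.a_iv[0]]
        a_dn = a[el.a_iv[1] : el.a_iv[1] + flank_extent]
        if el.b_strand == "+":
            b_up = b[max(el.b_iv[0] - len(a_up), 0) : el.b_iv[0]]
            b_dn = b[el.b_iv[1] : el.b_iv[1] + len(a_dn)]
        else:
            b_up = revcomp(b[el.b_iv[1] : el.b_iv[1] + len(a_up)])
            b_dn = revcomp(b[max(el.b_iv[0] - len(a_dn), 0) : el.b_iv[0]])
        # upstream: distance measured leftwards from the element edge
        for aseq, bseq, reverse in ((a_up, b_up, True), (a_dn, b_dn, False)):
            if len(aseq) < flank_window or not bseq:
                continue
            pos, mm = _aligned_mismatch_positions(aseq, bseq)
            if reverse:
                pos = len(aseq) - 1 - pos
            for off in range(0, len(aseq) - flank_window + 1, flank_step):
                sel = (pos >= off) & (pos < off + flank_window)
                if sel.sum() >= 0.5 * flank_window:
                    flank_rows.setdefault(off, []).append(float(mm[sel].mean()))
        # interior bins
        iv_a = a[el.a_iv[0] : el.a_iv[1]]
        if el.b_strand == "+":
            iv_b = b[el.b_iv[0] : el.b_iv[1]]
        else:
            iv_b = revcomp(b[el.b_iv[0] : el.b_iv[1]])
        if iv_a and iv_b:
            pos, mm = _aligned_mismatch_positions(iv_a, iv_b)
            if pos.size:
                bins = np.minimum(pos * inner_bins // max(len(iv_a), 1), inner_bins - 1)
                for i in range(inner_bins):
                    sel = bins == i
                    if sel.any():
                        bin_rows[i].append(float(mm[sel].mean()))

    control_freqs = []
    chroms = genome_a.ids()
    lens = genome_a.lengths()
    weights = np.array([lens[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(n_control):
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        if lens[c] <= control_len:
            continue
        s = int(rng.integers(0, lens[c] - control_len))
        seg = genome_a[c][s : s + control_len]
        if "N" in seg:
            continue
        hits = anchor_fragment(seg, genome_b, 0.8, 0.8)
        if len(hits) != 1:
            continue
        h = hits[0]
        bseq = genome_b[h.chrom][h.start : h.end]
        if h.strand == "-":
            bseq = revcomp(bseq)
        subs, sites = substitution_count(seg, bseq)
        if sites:
            control_freqs.append(subs / sites)

    rows = []
    for off in sorted(flank_rows):
        vals = flank_rows[off]
        rows.append(dict(region="flank", offset=off, mean_freq=float(np.mean(vals)), n=len(vals)))
    for i in range(inner_bins):
        vals = bin_rows[i]
        rows.append(
            dict(
                region="inside",
                offset=i,
                mean_freq=float(np.mean(vals)) if vals else float("nan"),
                n=len(vals),
            )
        )
    summary = {
        "control_mean_freq": float(np.mean(control_freqs)) if control_freqs else float("nan"),
        "n_control_blocks": len(control_freqs),
        "n_elements_skipped": skipped,
    }
    return pd.DataFrame(rows), summary


@dataclass
class CnsRateInputs:
    """Inputs to the cumulative substitution rate of an element's flanks.

    S_f: substitution frequency of the 500-bp flanking sequence;
    S_c: substitution frequency of the control region 9 kb away;
    T_ltr: element insertion time (years);
    T_div: divergence time of the two genomes (years).
    """

    S_f: float
    S_c: float
    T_ltr: float
    T_div: float


def cns_rate(x: CnsRateInputs) -> float:
    """V = (S_f - S_c) / T_ltr + S_c / (2 * T_div).

    May be negative when the flank is less diverged than the control;
    reported as-is.
    """
    if x.T_ltr <= 0 or x.T_div <= 0:
        raise ValueError("T_ltr and T_div must be positive")
    return (x.S_f - x.S_c) / x.T_ltr + x.S_c / (2.0 * x.T_div)


# ---------------------------------------------------------------------------
# Insertion-site context analyses
# ---------------------------------------------------------------------------


def gene_distance_distribution(
    elements: list[LtrElement],
    gene_annotation: dict[str, list[tuple[int, int]]],
    genome: Genome,
    bin_size: int = 100,
    n_control: int | None = None,
    seed: int | None = 0,
) -> dict:
    """Distance of insertion sites to the nearest gene, in 100-bp bins.

    Also reports the genome fraction covered by genes, the fraction of
    insertions falling inside genes, and a control histogram from
    uniformly random positions.
    """
    rng = np.random.default_rng(seed)
    lens = genome.lengths()

    def nearest_distance(chrom: str, p: int) -> int:
        best = None
        for s, e in gene_annotation.get(chrom, []):
            if s <= p < e:
                return 0
            d = s - p if p < s else p - e + 1
            best = d if best is None else min(best, d)
        return best if best is not None else max(lens[chrom], 1)

    points = [(el.chrom, (el.start + el.end) // 2) for el in elements]
    dists = [nearest_distance(c, p) for c, p in points]
    if n_control is None:
        n_control = max(len(points) * 10, 1000)
    chroms = genome.ids()
    weights = np.array([lens[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    ctrl = []
    for _ in range(n_control):
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        ctrl.append(nearest_distance(c, int(rng.integers(0, lens[c]))))
    genic = sum(e - s for iv in gene_annotation.values() for s, e in iv)
    total = genome.total_length()

    def hist(values):
        out: dict[int, int] = {}
        for v in values:
            out[(v // bin_size) * bin_size] = out.get((v // bin_size) * bin_size, 0) + 1
        return out

    return {
        "distances": dists,
        "histogram": hist(dists),
        "control_histogram": hist(ctrl),
        "inside_fraction": (sum(1 for d in dists if d == 0) / len(dists)) if dists else float("nan"),
        "control_inside_fraction": (sum(1 for d in ctrl if d == 0) / len(ctrl)) if ctrl else float("nan"),
        "genic_fraction": genic / total if total else 0.0,
    }


def cns_vs_time(
    elements: list[LtrElement],
    genome_a: Genome,
    genome_b: Genome,
    window_years: float = 100_000.0,
    flank: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean flank substitution frequency in sliding windows of element age.

    Returns (curve, per_element): the curve has one row per window
    position (step = window/5), per_element carries S_f, T_ltr and the
    per-element rate S_f / T_ltr.
    """
    usable = [
        el
        for el in elements
        if el.a_iv is not None and el.b_iv is not None and not math.isnan(el.T_ltr)
    ]
    if len(usable) < 1:
        raise ValueError("no datable, anchored elements supplied")
    recs = []
    for el in usable:
        sf = flank_substitution_frequency(el, genome_a, genome_b, flank)
        recs.append(dict(chrom=el.chrom, start=el.start, T_ltr=el.T_ltr, S_f=sf, cls=el.cls))
    per_element = pd.DataFrame(recs)
    per_element["rate"] = per_element.S_f / per_element.T_ltr.where(per_element.T_ltr > 0)
    tmax = float(per_element.T_ltr.max())
    step = window_years / 5.0
    centers = np.arange(0.0, tmax + step, step)
    rows = []
    for c in centers:
        sel = (per_element.T_ltr >= c - window_years / 2) & (per_element.T_ltr < c + window_years / 2)
        if sel.any():
            rows.append(
                dict(t_center=c, mean_S_f=float(per_element.S_f[sel].mean()), n=int(sel.sum()))
            )
    return pd.DataFrame(rows), per_element
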