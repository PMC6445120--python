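"""Shared sequence infrastructure: genomes, N-run scanning, and the anchoring engine.

Every downstream stage (gap closure, SV validation, PAV detection, LTR
classification) reduces to the same primitive: take a fragment from one
assembly and find where it sits in the other one.  The engine here is a
k-mer seed index (numpy, 2-bit packed) plus edlib verification of each
seed cluster, which is fast enough for multi-megabase genomes on one CPU
and exact enough to report per-placement coverage and identity.

Coordinates are 0-based half-open throughout; BED is used on disk.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: bases outside this set are normalised to N on load
ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome container
# ---------------------------------------------------------------------------


class Genome:
    """Ordered collection of named chromosome/scaffold sequences.

    Sequences are plain upper-case strings over {A,C,G,T,N}.  Any other
    IUPAC code is normalised to N on load (the count is logged).  A lazy
    k-mer index over the whole genome is attached on first anchoring
    query and reused afterwards.
    """

    def __init__(self, records: list[tuple[str, str]]):
        ids = [r[0] for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        if any(len(r[1]) == 0 for r in records):
            raise ValueError("empty sequence")
        self.records: list[tuple[str, str]] = [(i, s.upper()) for i, s in records]
        self._index: dict[str, str] = dict(self.records)
        self._kmer_index: "KmerIndex | None" = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        records = []
        n_fixed = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if not set(seq) <= ALPHABET:
                cleaned = re.sub(r"[^ACGTN]", "N", seq)
                n_fixed += sum(1 for a, b in zip(seq, cleaned) if a != b)
                seq = cleaned
            records.append((rec.id, seq))
        if n_fixed:
            log.info("normalised %d non-ACGTN bases to N while loading %s", n_fixed, path)
        return cls(records)

    def to_fasta(self, path, width: int = 80) -> None:
        recs = [SeqRecord(Seq(s), id=i, description="") for i, s in self.records]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(recs)

    # -- access ------------------------------------------------------------

    def __getitem__(self, chrom: str) -> str:
        return self._index[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def lengths(self) -> dict[str, int]:
        return {i: len(s) for i, s in self.records}

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)

    def kmer_index(self, k: int = 15) -> "KmerIndex":
        if self._kmer_index is None or self._kmer_index.k != k:
            self._kmer_index = KmerIndex(self, k=k)
        return self._kmer_index


# ---------------------------------------------------------------------------
# N-run scanning
# ---------------------------------------------------------------------------


def find_n_runs(genome: Genome, min_len: int = 1) -> list[tuple[str, int, int]]:
    """Maximal runs of N of length >= ``min_len``, sorted by (chrom order, start)."""
    runs = []
    pattern = re.compile("N{%d,}" % max(1, min_len))
    for chrom, seq in genome.records:
        for m in pattern.finditer(seq):
            runs.append((chrom, m.start(), m.end()))
    return runs


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def encode_bases(seq: str) -> np.ndarray:
    """2-bit encode; non-ACGT positions get 255."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rolling_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-mer start; invalid where the window hits a non-base."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | (enc[j : j + n] & np.uint8(3)).astype(np.uint64)
    bad = (enc == 255).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


class KmerIndex:
    """Sorted k-mer position index over a whole genome.

    Chromosomes are virtually concatenated; a global position maps back to
    (chrom, local) via the offset table.  k must be <= 31.
    """

    def __init__(self, genome: Genome, k: int = 15):
        if not 1 <= k <= 31:
            raise ValueError("k must be in [1, 31]")
        self.k = k
        self.genome = genome
        self.offsets = []
        self.chrom_ids = []
        pos_parts, code_parts = [], []
        offset = 0
        for chrom, seq in genome.records:
            self.offsets.append(offset)
            self.chrom_ids.append(chrom)
            enc = encode_bases(seq)
            codes, valid = _rolling_codes(enc, k)
            idx = np.nonzero(valid)[0]
            pos_parts.append(idx + offset)
            code_parts.append(codes[idx])
            offset += len(seq)
        self.offsets = np.asarray(self.offsets + [offset], dtype=np.int64)
        codes = np.concatenate(code_parts) if code_parts else np.empty(0, np.uint64)
        pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def lookup(self, code: int) -> np.ndarray:
        """Global positions of a k-mer code (possibly empty)."""
        lo = np.searchsorted(self.codes, np.uint64(code), side="left")
        hi = np.searchsorted(self.codes, np.uint64(code), side="right")
        return self.pos[lo:hi]

    def to_local(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.chrom_ids[ci], int(gpos - self.offsets[ci])

    def chrom_span(self, gpos: int) -> tuple[int, int, int]:
        """(chrom index, chrom global start, chrom global end) containing gpos."""
        ci = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return ci, int(self.offsets[ci]), int(self.offsets[ci + 1])


# ---------------------------------------------------------------------------
# Placements and alignment accounting
# ---------------------------------------------------------------------------


@dataclass
class AnchoredPlacement:
    """A fragment placed on a target genome."""

    query_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    coverage: float  # aligned fraction of the query
    identity: float  # matches / alignment columns
    n_hits: int = 1
    cigar: str = field(default="", repr=False)

    def inner_edge(self, side: str) -> int:
        """Edge facing the mate flank: 'right' -> end, 'left' -> start."""
        return self.end if side == "right" else self.start


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(match columns, total columns, query bases in =/X columns)."""
    matches = cols = qaln = 0
    for n, op in parse_cigar(cigar):
        cols += n
        if op == "=":
            matches += n
            qaln += n
        elif op == "X":
            qaln += n
        elif op == "I":  # query-only
            pass
        # 'D': target-only
    return matches, cols, qaln


def _align_columns(a: str, b: str, cigar: str):
    """Yield per-column (base_a, base_b); '-' marks a gap."""
    i = j = 0
    for n, op in parse_cigar(cigar):
        for _ in range(n):
            if op in "=XM":
                yield a[i], b[j]
                i += 1
                j += 1
            elif op == "I":  # a-only
                yield a[i], "-"
                i += 1
            else:  # 'D', b-only
                yield "-", b[j]
                j += 1


def global_identity(a: str, b: str) -> float:
    """Global similarity: matching columns over the columns of a
    gap-minimal global alignment, i.e. (max(|a|,|b|) - d) / max(|a|,|b|)
    with d the Levenshtein distance.  Gap columns count against the
    identity.

    This form is deterministic (independent of which co-optimal
    alignment path the aligner happens to return), symmetric in its
    arguments and invariant under joint reverse complement.  It is the
    similarity measure used when comparing a retroelement with its
    counterpart in the other assembly.
    """
    if not a or not b:
        raise ValueError("global_identity requires non-empty sequences")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    n = max(len(a), len(b))
    return (n - d) / n


def substitution_count(a: str, b: str) -> tuple[int, int]:
    """(substitutions, compared sites) between two orthologous sequences.

    Sequences are globally aligned; gap columns and columns containing an
    N on either side are excluded from both counts.
    """
    if not a or not b:
        return 0, 0
    res = edlib.align(a, b, mode="NW", task="path")
    subs = compared = 0
    for x, y in _align_columns(a, b, res["cigar"]):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        compared += 1
        if x != y:
            subs += 1
    return subs, compared


# ---------------------------------------------------------------------------
# Anchoring engine
# ---------------------------------------------------------------------------

#: k-mers occurring more often than this are skipped as repetitive seeds
MAX_SEED_OCC = 400
_DIAG_BAND = 40


def _seed_clusters(q_enc: np.ndarray, index: KmerIndex, stride: int):
    """Cluster (diagonal, target pos) seed hits into candidate loci.

    Returns a list of (chrom_idx, window_gstart, window_gend) candidate
    regions in global coordinates.
    """
    k = index.k
    nq = q_enc.size
    codes, valid = _rolling_codes(q_enc, k)
    qpos_all = np.arange(codes.size)[valid]
    hits_d, hits_t, hits_q = [], [], []
    for qp in qpos_all[::stride]:
        tpos = index.lookup(int(codes[qp]))
        if tpos.size == 0 or tpos.size > MAX_SEED_OCC:
            continue
        hits_d.append(tpos - qp)
        hits_t.append(tpos)
        hits_q.append(np.full(tpos.size, qp))
    if not hits_d:
        return []
    diag = np.concatenate(hits_d)
    tpos = np.concatenate(hits_t)
    qpos = np.concatenate(hits_q)
    order = np.lexsort((tpos, diag))
    diag, tpos, qpos = diag[order], tpos[order], qpos[order]

    clusters = []
    start = 0
    for i in range(1, diag.size + 1):
        if (
            i == diag.size
            or diag[i] - diag[i - 1] > _DIAG_BAND
            or (diag[i] == diag[i - 1] and tpos[i] - tpos[i - 1] > nq + _DIAG_BAND)
        ):
            seg_t = tpos[start:i]
            seg_q = qpos[start:i]
            g_lo = int((seg_t - seg_q).min())
            g_hi = int((seg_t + (nq - seg_q)).max()) + k
            ci, c_lo, c_hi = index.chrom_span(max(g_lo, 0))
            clusters.append((ci, max(g_lo - _DIAG_BAND, c_lo), min(g_hi + _DIAG_BAND, c_hi)))
            start = i
    # merge duplicate/overlapping windows on the same chromosome
    clusters.sort()
    merged = []
    for ci, lo, hi in clusters:
        if merged and merged[-1][0] == ci and lo <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], hi)
        else:
            merged.append([ci, lo, hi])
    return merged


def _verify_window(query: str, window_seq: str, max_k: int):
    res = edlib.align(query, window_seq, mode="HW", task="path", k=max_k)
    if res["editDistance"] < 0:
        return None
    matches, cols, qaln = cigar_stats(res["cigar"])
    loc = res["locations"][0]
    return loc[0], loc[1] + 1, matches / cols, qaln / len(query), res["cigar"]


def anchor_fragment(
    fragment: str,
    target: Genome,
    min_coverage: float = 0.8,
    min_identity: float = 0.8,
    query_id: str = "query",
    k: int = 15,
    stride: int | None = None,
) -> list[AnchoredPlacement]:
    """Find every placement of ``fragment`` on ``target`` meeting both thresholds.

    Placements on either strand are reported, ranked by identity then
    coverage, ties broken by (chrom, start); ``n_hits`` on each placement
    is the total number of placements returned.  Raises ``ValueError``
    for fragments shorter than the seed size (unusable anchors).
    """
    fragment = fragment.upper()
    if len(fragment) < max(50, k):
        raise ValueError("fragment too short to anchor (need >= 50 bases)")
    index = target.kmer_index(k)
    if stride is None:
        stride = max(1, (len(fragment) - k) // 48)
    # edit-distance budget: substitutions from identity plus slack for indels
    max_k = int(len(fragment) * (1 - min_identity) * 2) + 16

    placements: list[AnchoredPlacement] = []
    for strand, q in (("+", fragment), ("-", revcomp(fragment))):
        q_enc = encode_bases(q)
        for ci, g_lo, g_hi in _seed_clusters(q_enc, index, stride):
            chrom = index.chrom_ids[ci]
            c_off = int(index.offsets[ci])
            wseq = target[chrom][g_lo - c_off : g_hi - c_off]
            hit = _verify_window(q, wseq, max_k)
            if hit is None:
                continue
            s, e, ident, cov, cigar = hit
            if ident >= min_identity and cov >= min_coverage:
                placements.append(
                    AnchoredPlacement(
                        query_id=query_id,
                        chrom=chrom,
                        start=g_lo - c_off + s,
                        end=g_lo - c_off + e,
                        strand=strand,
                        coverage=cov,
                        identity=ident,
                        cigar=cigar,
                    )
                )
    placements = _dedupe_placements(placements)
    placements.sort(key=lambda p: (-p.identity, -p.coverage, p.chrom, p.start))
    for p in placements:
        p.n_hits = len(placements)
    return placements


def _dedupe_placements(placements: list[AnchoredPlacement]) -> list[AnchoredPlacement]:
    """Collapse placements that overlap >50% on the target; keep the best."""
    placements = sorted(placements, key=lambda p: (-p.identity, -p.coverage))
    kept: list[AnchoredPlacement] = []
    for p in placements:
        redundant = False
        for q in kept:
            if p.chrom != q.chrom:
                continue
            ov = min(p.end, q.end) - max(p.start, q.start)
            if ov > 0 and ov > 0.5 * min(p.end - p.start, q.end - q.start):
                redundant = True
                break
        if not redundant:
            kept.append(p)
    return kept


def write_placements_tsv(placements: list[AnchoredPlacement], path) -> None:
    """BED-6 plus coverage/identity/n_hits extension columns."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tcoverage\tidentity\tn_hits\n")
        for p in placements:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.query_id}\t"
                f"{int(round(1000 * p.identity))}\t{p.strand}\t"
                f"{p.coverage:.4f}\t{p.identity:.4f}\t{p.n_hits}\n"
            )


def read_paf_like(path) -> list[AnchoredPlacement]:
    """Import externally produced placements from a PAF-like table.

    Columns: query, qlen, qstart, qend, strand, target, tstart, tend,
    matches, columns.  Provided for parity runs against an external
    mapper; coverage/identity are recomputed from the stated counts.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            qlen = int(f[1])
            matches, cols = int(f[8]), int(f[9])
            out.append(
                AnchoredPlacement(
                    query_id=f[0],
                    chrom=f[5],
                    start=int(f[6]),
                    end=int(f[7]),
                    strand=f[4],
                    coverage=(int(f[3]) - int(f[2])) / qlen,
                    identity=matches / cols if cols else 0.0,
                )
            )
    by_query: dict[str, int] = {}
    for p in out:
        by_query[p.query_id] = by_query.get(p.query_id, 0) + 1
    for p in out:
        p.n_hits = by_query[p.query_id]
    return out
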