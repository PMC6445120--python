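"""Presence/absence marker analysis for a transposon insertion allele.

Motivated by redTE, the gypsy-like LTR retrotransposon upstream of the
apple anthocyanin regulator *MdMYB1* whose presence perfectly
co-segregates with red fruit skin: a junction sequence spanning the
insertion boundary identifies carriers in sequence sets, an in-silico
PCR predicts the diagnostic amplicon, and a 2x2 tabulation of marker
state against phenotype quantifies co-segregation in accession panels
and crosses.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqcore import Genome, revcomp

PHENOTYPES = ("red", "non_red", "unknown")
MARKER_STATES = ("present", "absent", "failed")


# ---------------------------------------------------------------------------
# Junction search
# ---------------------------------------------------------------------------


def _mismatch_occurrences(text: str, pattern: str, max_mismatch: int) -> list[int]:
    """Start positions where ``pattern`` matches with <= max_mismatch substitutions.

    Pigeonhole seeding: split the pattern into max_mismatch+1 chunks, at
    least one of which must match exactly; candidates are then verified
    by direct comparison.  No indels are tolerated.
    """
    m = len(pattern)
    if m == 0 or m > len(text):
        return []
    if max_mismatch == 0:
        out = []
        i = text.find(pattern)
        while i != -1:
            out.append(i)
            i = text.find(pattern, i + 1)
        return out
    n_chunks = max_mismatch + 1
    bounds = [round(i * m / n_chunks) for i in range(n_chunks + 1)]
    candidates = set()
    for ci in range(n_chunks):
        lo, hi = bounds[ci], bounds[ci + 1]
        chunk = pattern[lo:hi]
        if not chunk:
            continue
        i = text.find(chunk)
        while i != -1:
            start = i - lo
            if 0 <= start <= len(text) - m:
                candidates.add(start)
            i = text.find(chunk, i + 1)
    out = []
    for s in sorted(candidates):
        mm = sum(1 for a, b in zip(text[s : s + m], pattern) if a != b)
        if mm <= max_mismatch:
            out.append(s)
    return out


def junction_search(
    sequences: dict[str, str] | Genome,
    junction: str,
    max_mismatch: int = 0,
) -> dict[str, list[tuple[str, int, str]]]:
    """Occurrences of a junction sequence (either strand) per sample sequence.

    The junction spans an insertion boundary, so only carriers of the
    insertion contain it contiguously; a sample holding the two halves
    separated by the element does not match.  Junctions shorter than 20
    bases are refused as unspecific.  Returns, per sequence id, a list
    of (sequence id, position, strand) occurrences.
    """
    junction = junction.upper()
    if len(junction) < 20:
        raise ValueError("junction must be at least 20 bases for specificity")
    records = sequences.records if isinstance(sequences, Genome) else sequences.items()
    result: dict[str, list[tuple[str, int, str]]] = {}
    rc = revcomp(junction)
    for sid, seq in records:
        occ = [(sid, p, "+") for p in _mismatch_occurrences(seq, junction, max_mismatch)]
        occ += [(sid, p, "-") for p in _mismatch_occurrences(seq, rc, max_mismatch)]
        result[sid] = sorted(occ, key=lambda t: t[1])
    return result


def junction_present(sequences, junction: str, max_mismatch: int = 0) -> bool:
    """Is the junction found anywhere in the sample's sequences?"""
    return any(v for v in junction_search(sequences, junction, max_mismatch).values())


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


def insilico_pcr(
    template: Genome,
    fwd: str,
    rev: str,
    max_product: int = 5_000,
    max_mismatch: int = 0,
    exact_3prime: int = 3,
) -> list[tuple[str, int, int]]:
    """Predicted PCR products: (chrom, product start, product length).

    The forward primer must match the plus strand and the reverse
    complement of the reverse primer must match downstream within
    ``max_product``; both orientations of the template are scanned.
    The product length is the outer span of the two primer sites.  The
    last ``exact_3prime`` bases of each primer must match exactly
    (polymerase extension requires a paired 3' end).
    """
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 18 or len(rev) < 18:
        raise ValueError("primers must be at least 18 bases")
    products = []
    for chrom, seq in template.records:
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            f_sites = [
                p
                for p in _mismatch_occurrences(s, fwd, max_mismatch)
                if s[p + len(fwd) - exact_3prime : p + len(fwd)] == fwd[-exact_3prime:]
            ]
            rc = revcomp(rev)
            r_sites = [
                p
                for p in _mismatch_occurrences(s, rc, max_mismatch)
                if s[p : p + exact_3prime] == rc[:exact_3prime]
            ]
            for fp in f_sites:
                for rp in r_sites:
                    end = rp + len(rc)
                    length = end - fp
                    if fp < end and length <= max_product:
                        start = fp if strand == "+" else len(s) - end
                        products.append((chrom, start, length))
    # the same amplicon found on both scanned orientations collapses to one
    return sorted(set(products))


# ---------------------------------------------------------------------------
# Co-segregation
# ---------------------------------------------------------------------------


@dataclass
class MarkerPanel:
    """Per-sample phenotype and marker state."""

    table: pd.DataFrame  # columns: sample, phenotype, marker

    def __post_init__(self):
        required = {"sample", "phenotype", "marker"}
        if not required <= set(self.table.columns):
            raise ValueError(f"panel requires columns {sorted(required)}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in panel")
        bad = set(self.table.phenotype) - set(PHENOTYPES)
        bad |= set(self.table.marker) - set(MARKER_STATES)
        if bad:
            raise ValueError(f"unrecognised panel values: {sorted(bad)}")

    @classmethod
    def from_counts(cls, **counts: int) -> "MarkerPanel":
        """Build a panel from composition counts, e.g.
        ``from_counts(red_present=112, non_red_absent=33)``."""
        rows = []
        i = 0
        for key, n in counts.items():
            pheno, marker = key.rsplit("_", 1)
            for _ in range(n):
                rows.append(dict(sample=f"s{i:04d}", phenotype=pheno, marker=marker))
                i += 1
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        return cls(pd.read_csv(path, sep="\t"))


def cosegregation(panel: MarkerPanel) -> dict:
    """2x2 tabulation of marker state against phenotype.

    Concordance counts red/present and non_red/absent samples over all
    samples with a known phenotype and a non-failed marker; the perfect
    flag requires concordance exactly 1.  Raises when no sample has a
    known phenotype.
    """
    df = panel.table
    known = df[(df.phenotype != "unknown") & (df.marker != "failed")]
    if known.empty:
        raise ValueError("panel has no samples with known phenotype and marker")
    tab = {
        (p, m): int(((known.phenotype == p) & (known.marker == m)).sum())
        for p in ("red", "non_red")
        for m in ("present", "absent")
    }
    concordant = tab[("red", "present")] + tab[("non_red", "absent")]
    concordance = concordant / len(known)
    return {
        "table": tab,
        "n_known": int(len(known)),
        "n_total": int(len(df)),
        "concordance": concordance,
        "perfect": concordance == 1.0,
    }


def gel_report(panel: MarkerPanel) -> str:
    """Text schematic of marker state per lane (one sample per lane)."""
    lines = ["lane sample           phenotype marker   band"]
    for i, r in enumerate(panel.table.itertuples(), start=1):
        band = "====" if r.marker == "present" else ("    " if r.marker == "absent" else " ?? ")
        lines.append(f"{i:>4} {r.sample:<16} {r.phenotype:<9} {r.marker:<8} [{band}]")
    return "\n".join(lines)
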