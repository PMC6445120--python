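"""Truth-tracked simulator of a diverged genome pair.

Generates an ancestral genome and derives two descendants, "A" and "B",
emulating a pair of homozygous cultivar assemblies that split from a
common ancestor: SNPs, small indels, LTR retrotransposon insertions with
4-6 bp target-site duplications and TG...CA-terminal LTR pairs, element
eliminations, N-gap masking, and terminal TTTAGGG telomere arrays.  Every
implanted event is recorded in a :class:`TruthSet` ledger with final
(post-editing) coordinates, which is the oracle for all recovery tests
downstream.

The mutation clock is a single uniform substitution process (no rate
heterogeneity), matching the constant-rate dating convention used for
LTR elements, so parameter-recovery checks stay closed-form.  Each event
category draws from its own RNG stream derived from the master seed:
changing the number of SNPs never reshuffles element placements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .seqcore import Genome, revcomp

DEFAULT_RATE = 1.3e-8  # substitutions per site per year


class SimConfigError(ValueError):
    pass


@dataclass
class TeFamily:
    """An LTR retrotransposon consensus: ltr + internal + ltr."""

    name: str
    ltr: str
    internal: str

    @property
    def element(self) -> str:
        return self.ltr + self.internal + self.ltr


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.38
    snp_rate: float = 0.001
    small_indel_rate: float = 0.0
    indel_max_len: int = 10
    te_library: list[TeFamily] | None = None
    n_te_families: int = 3
    te_ltr_length: int = 1000
    te_internal_length: int = 3000
    n_shared: int = 0
    n_insertions_A: int = 0
    n_insertions_B: int = 0
    n_eliminations: int = 0
    tsd_length_range: tuple[int, int] = (4, 6)
    ltr_terminal_motif: str = "TGCA"
    telomere_unit: str = "TTTAGGG"
    telomere_copies_range: tuple[int, int] = (100, 400)
    gap_spec: list[tuple[int, int]] = field(default_factory=list)  # (length, spacing) on B
    divergence_time_years: float = 1_000_000.0
    ltr_age_range_years: tuple[float, float] = (0.0, 2_000_000.0)
    substitution_rate: float = DEFAULT_RATE
    te_proximal_snp_multiplier: float = 1.0
    te_proximal_window: int = 500
    te_flank_divergence_rate: float = 0.0  # per site per year, over each element's age
    te_flank_window: int = 500
    gene_fraction: float = 0.0
    gene_mean_length: int = 3000
    gene_avoidance: float = 0.0
    elimination_remnant_prob: float = 0.66
    min_event_spacing: int = 20_000
    edge_exclusion: int = 10_000

    def validate(self) -> None:
        if not 0.0 < self.gc_fraction < 1.0:
            raise SimConfigError("gc_fraction must be in (0, 1)")
        if self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise SimConfigError("nonpositive genome dimensions")
        lo, hi = self.tsd_length_range
        if not (4 <= lo <= hi <= 6):
            raise SimConfigError("tsd_length_range must lie within [4, 6]")
        if self.substitution_rate <= 0:
            raise SimConfigError("substitution_rate must be positive")
        if self.snp_rate < 0 or self.small_indel_rate < 0:
            raise SimConfigError("negative mutation rate")
        longest = 2 * self.te_ltr_length + self.te_internal_length
        if self.te_library:
            longest = max(len(f.element) for f in self.te_library)
        if self.chrom_length < 10 * longest:
            raise SimConfigError("chrom_length must be >= 10x the longest TE consensus")

    # -- plain-text round trip ------------------------------------------------

    def to_file(self, path) -> None:
        d = dataclasses.asdict(self)
        d.pop("te_library")
        d["gap_spec"] = [list(g) for g in self.gap_spec]
        for k in ("tsd_length_range", "telomere_copies_range", "ltr_age_range_years"):
            d[k] = list(d[k])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
        for k in ("tsd_length_range", "telomere_copies_range", "ltr_age_range_years"):
            if k in d:
                d[k] = tuple(d[k])
        if "gap_spec" in d:
            d["gap_spec"] = [tuple(g) for g in d["gap_spec"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------


@dataclass
class TruthSet:
    """Ledger of every implanted event, in final-genome coordinates (0-based, half-open)."""

    snps: pd.DataFrame
    indels: pd.DataFrame
    te_events: pd.DataFrame
    gaps: pd.DataFrame
    telomeres: pd.DataFrame
    genes: pd.DataFrame
    # per-genome edit scripts in ancestor coordinates, kept for round-trip checks
    ops_A: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict, repr=False)
    ops_B: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict, repr=False)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("snps", "indels", "te_events", "gaps", "telomeres", "genes"):
            getattr(self, name).to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
        with open(outdir / "truth_te_events.bed", "w") as fh:
            for r in self.te_events.itertuples():
                if r.start_A >= 0:
                    fh.write(f"{r.chrom}\t{r.start_A}\t{r.end_A}\t{r.cls}:{r.event_id}\t0\t+\n")
        with open(outdir / "truth_gaps.bed", "w") as fh:
            for r in self.gaps.itertuples():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tgap\t0\t+\n")


# ---------------------------------------------------------------------------
# Random sequence and mutation primitives
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


def _mutate(seq: str, n_subs: int, rng: np.random.Generator, protect: int = 0) -> str:
    """Apply ``n_subs`` point substitutions at uniform positions.

    ``protect`` shields that many bases at each end (used to keep LTR
    terminal dinucleotides intact).  Repeated hits at one site are
    allowed, as in a true Poisson process; each hit moves to a different base.
    """
    if n_subs == 0 or len(seq) <= 2 * protect:
        return seq
    arr = bytearray(seq, "ascii")
    lo, hi = protect, len(seq) - protect
    sites = rng.integers(lo, hi, size=n_subs)
    for s in sites:
        cur = arr[s]
        choices = [b for b in b"ACGT" if b != cur]
        arr[s] = choices[rng.integers(0, 3)]
    return arr.decode("ascii")


def age_ltr(
    element: str,
    ltr_len: int,
    age_years: float,
    rate: float = DEFAULT_RATE,
    rng: np.random.Generator | int | None = None,
    protect_terminal: int = 2,
) -> str:
    """Evolve an intact element for ``age_years`` under a uniform clock.

    Each LTR accumulates substitutions as an independent Poisson process
    at ``rate`` per site per year, so the expected raw LTR-LTR divergence
    is ~ 2 * rate * age; the internal body mutates at the same rate.  The
    terminal dinucleotides of each LTR (the TG...CA motif) are shielded
    so that detectability is an age-independent property of the element.
    """
    if age_years < 0:
        raise ValueError("age must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ltr5, internal, ltr3 = (
        element[:ltr_len],
        element[ltr_len : len(element) - ltr_len],
        element[len(element) - ltr_len :],
    )
    lam_ltr = rate * age_years * ltr_len
    lam_int = rate * age_years * max(len(internal), 0)
    ltr5 = _mutate(ltr5, int(rng.poisson(lam_ltr)), rng, protect=protect_terminal)
    ltr3 = _mutate(ltr3, int(rng.poisson(lam_ltr)), rng, protect=protect_terminal)
    internal = _mutate(internal, int(rng.poisson(lam_int)), rng)
    return ltr5 + internal + ltr3


def default_te_library(config: SimConfig, rng: np.random.Generator) -> list[TeFamily]:
    motif = config.ltr_terminal_motif
    fams = []
    for i in range(config.n_te_families):
        ltr = motif[:2] + random_seq(rng, config.te_ltr_length - 4, 0.5) + motif[2:]
        internal = random_seq(rng, config.te_internal_length, 0.5)
        fams.append(TeFamily(name=f"fam{i}", ltr=ltr, internal=internal))
    return fams


# ---------------------------------------------------------------------------
# Ancestor
# ---------------------------------------------------------------------------


def generate_ancestor(config: SimConfig) -> Genome:
    """I.i.d. ancestral genome at the configured GC fraction (no N bases)."""
    config.validate()
    rng = _streams(config.seed)["ancestor"]
    records = []
    for c in range(config.n_chromosomes):
        records.append((f"chr{c + 1:02d}", random_seq(rng, config.chrom_length, config.gc_fraction)))
    return Genome(records)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "ancestor",
        "library",
        "placement",
        "elements",
        "snps",
        "indels",
        "gaps",
        "telomeres",
        "genes",
        "depth",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# Splicing with coordinate tracking
# ---------------------------------------------------------------------------


class PosMap:
    """Map ancestor coordinates to final coordinates after an edit script."""

    def __init__(self, anc_starts, fin_starts, seg_lens, final_len):
        self.anc_starts = np.asarray(anc_starts, dtype=np.int64)
        self.fin_starts = np.asarray(fin_starts, dtype=np.int64)
        self.seg_lens = np.asarray(seg_lens, dtype=np.int64)
        self.final_len = final_len

    def map(self, p: int) -> int:
        """Final position of ancestor base ``p`` (or of the insertion-free point)."""
        i = int(np.searchsorted(self.anc_starts, p, side="right")) - 1
        if i < 0:
            raise ValueError("position before first segment")
        off = p - self.anc_starts[i]
        if off > self.seg_lens[i]:
            raise ValueError(f"ancestor position {p} was replaced/deleted")
        return int(self.fin_starts[i] + off)


def splice(
    anc: str, ops: list[tuple[int, int, str]], prefix: str = "", suffix: str = ""
) -> tuple[str, PosMap, list[tuple[int, int]]]:
    """Apply an edit script to one chromosome.

    ``ops`` is a sorted list of (anc_start, anc_end, replacement); an
    insertion has anc_start == anc_end.  Returns the final sequence, a
    coordinate map for untouched ancestor positions, and the final-genome
    span of each op's replacement text (in op order).
    """
    parts = [prefix]
    fin = len(prefix)
    anc_starts, fin_starts, seg_lens = [], [], []
    op_spans = []
    cur = 0
    for s, e, repl in ops:
        if s < cur or e < s or e > len(anc):
            raise ValueError("overlapping or out-of-range ops")
        parts.append(anc[cur:s])
        anc_starts.append(cur)
        fin_starts.append(fin)
        seg_lens.append(s - cur)
        fin += s - cur
        parts.append(repl)
        op_spans.append((fin, fin + len(repl)))
        fin += len(repl)
        cur = e
    parts.append(anc[cur:])
    anc_starts.append(cur)
    fin_starts.append(fin)
    seg_lens.append(len(anc) - cur)
    fin += len(anc) - cur
    parts.append(suffix)
    pm = PosMap(anc_starts, fin_starts, seg_lens, fin + len(suffix))
    return "".join(parts), pm, op_spans


# ---------------------------------------------------------------------------
# Descendant derivation
# ---------------------------------------------------------------------------

_EVENT_CLASSES = ("shared", "insertion_A", "insertion_B", "elimination_B")


def derive_pair(ancestor: Genome, config: SimConfig) -> tuple[Genome, Genome, TruthSet]:
    """Derive descendants A and B from the ancestor with a complete truth ledger."""
    config.validate()
    streams = _streams(config.seed)
    rng_place, rng_elem = streams["placement"], streams["elements"]
    rng_snp, rng_indel = streams["snps"], streams["indels"]
    rng_gap, rng_telo, rng_gene = streams["gaps"], streams["telomeres"], streams["genes"]

    library = config.te_library or default_te_library(config, streams["library"])
    chroms = ancestor.ids()
    lengths = ancestor.lengths()
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    # -- gene annotation (ancestor coordinates) -----------------------------
    genes_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if config.gene_fraction > 0:
        for c in chroms:
            target = config.gene_fraction * lengths[c]
            covered, tries = 0, 0
            taken: list[tuple[int, int]] = []
            while covered < target and tries < 100_000:
                tries += 1
                glen = int(np.clip(rng_gene.exponential(config.gene_mean_length), 500, 10 * config.gene_mean_length))
                s = int(rng_gene.integers(0, max(lengths[c] - glen, 1)))
                if any(s < e0 and s + glen > s0 for s0, e0 in taken):
                    continue
                taken.append((s, s + glen))
                covered += glen
            genes_by_chrom[c] = sorted(taken)

    # -- TE event placement --------------------------------------------------
    classes = (
        ["shared"] * config.n_shared
        + ["insertion_A"] * config.n_insertions_A
        + ["insertion_B"] * config.n_insertions_B
        + ["elimination_B"] * config.n_eliminations
    )
    classes = [classes[i] for i in rng_place.permutation(len(classes))]
    placements: list[tuple[str, int, int]] = []  # (chrom, anc point, tsd_len)
    occupied: dict[str, list[int]] = {c: [] for c in chroms}
    tsd_lo, tsd_hi = config.tsd_length_range
    for _cls in classes:
        for attempt in range(10_000):
            c = chroms[int(rng_place.choice(len(chroms), p=weights))]
            lo = config.edge_exclusion
            hi = lengths[c] - config.edge_exclusion - tsd_hi
            if hi <= lo:
                continue
            p = int(rng_place.integers(lo, hi))
            if any(abs(p - q) < config.min_event_spacing for q in occupied[c]):
                continue
            if config.gene_avoidance > 0 and _in_intervals(p, genes_by_chrom[c]):
                if rng_place.random() < config.gene_avoidance:
                    continue
            t = int(rng_place.integers(tsd_lo, tsd_hi + 1))
            tsd = ancestor[c][p : p + t]
            # a TSD starting with CA or ending with TG makes the element
            # boundary ambiguous against the TG...CA terminal motif; pick
            # another site so implanted boundaries are identifiable
            if tsd.startswith(config.ltr_terminal_motif[2:]) or tsd.endswith(
                config.ltr_terminal_motif[:2]
            ):
                continue
            occupied[c].append(p)
            placements.append((c, p, t))
            break
        else:
            raise SimConfigError("could not place events: configuration too dense")

    # -- event instantiation -------------------------------------------------
    t_div = config.divergence_time_years
    age_lo, age_hi = config.ltr_age_range_years
    rate = config.substitution_rate
    te_rows = []
    ops_A: dict[str, list] = {c: [] for c in chroms}
    ops_B: dict[str, list] = {c: [] for c in chroms}
    op_refs_A: dict[str, list] = {c: [] for c in chroms}  # parallel: te event_id or None
    op_refs_B: dict[str, list] = {c: [] for c in chroms}

    for eid, (cls, (c, p, t)) in enumerate(zip(classes, placements)):
        fam = library[int(rng_elem.integers(0, len(library)))]
        tsd = ancestor[c][p : p + t]
        llen = len(fam.ltr)
        row = dict(
            event_id=eid,
            cls=cls,
            family=fam.name,
            chrom=c,
            anc_pos=p,
            tsd=tsd,
            tsd_len=t,
            ltr_len=llen,
            elim_mode="",
            seq_A="",
            seq_B="",
        )
        if cls in ("shared", "elimination_B"):
            age = float(rng_elem.uniform(max(t_div, age_lo), max(age_hi, t_div)))
            stem = age_ltr(fam.element, llen, age - t_div, rate, rng_elem)
            elem_A = age_ltr(stem, llen, t_div, rate, rng_elem)
            elem_B = age_ltr(stem, llen, t_div, rate, rng_elem)
        else:
            age = float(rng_elem.uniform(age_lo, min(age_hi, t_div) if t_div > 0 else age_hi))
            elem = age_ltr(fam.element, llen, age, rate, rng_elem)
            elem_A = elem_B = elem
        row["age_years"] = age

        if cls in ("shared", "insertion_A", "elimination_B"):
            ops_A[c].append((p + t, p + t, elem_A + tsd))
            op_refs_A[c].append(eid)
            row["seq_A"] = elem_A
        if cls == "shared":
            ops_B[c].append((p + t, p + t, elem_B + tsd))
            op_refs_B[c].append(eid)
            row["seq_B"] = elem_B
        elif cls == "insertion_B":
            ops_B[c].append((p + t, p + t, elem_B + tsd))
            op_refs_B[c].append(eid)
            row["seq_B"] = elem_B
        elif cls == "elimination_B":
            if rng_elem.random() < config.elimination_remnant_prob:
                # remnant mode: both TSD copies survive around a <100 bp scrap of
                # unrelated sequence (remains of other transposition events, not
                # of the eliminated element itself)
                row["elim_mode"] = "remnant"
                rl = int(rng_elem.integers(20, 100))
                remnant = random_seq(rng_elem, rl, config.gc_fraction)
                ops_B[c].append((p + t, p + t, remnant + tsd))
                op_refs_B[c].append(eid)
                row["seq_B"] = remnant
            else:
                # replacement mode: the whole site is overwritten by unrelated sequence
                row["elim_mode"] = "replacement"
                rl = int(rng_elem.integers(200, len(elem_B)))
                repl = random_seq(rng_elem, rl, config.gc_fraction)
                ops_B[c].append((p, p + t, repl))
                op_refs_B[c].append(eid)
                row["seq_B"] = repl
        te_rows.append(row)

    footprints: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for cls, (c, p, t) in zip(classes, placements):
        footprints[c].append((p, p + t))

    # -- age-proportional flank divergence around elements --------------------
    # Emulates the elevated local mutation load accrued near an element since
    # its insertion: expected A-B flank divergence 2 * rate * age per site.
    snp_rows = []
    snp_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    if config.te_flank_divergence_rate > 0:
        w = config.te_flank_window
        for row, (c, p, t) in zip(te_rows, placements):
            zones = [(max(p - w, 0), p), (p + t, min(p + t + w, lengths[c]))]
            zone_len = sum(e - s for s, e in zones)
            lam = 2.0 * config.te_flank_divergence_rate * row["age_years"] * zone_len
            taken = set(snp_by_chrom[c])
            for _ in range(int(rng_snp.poisson(lam))):
                for _try in range(200):
                    z = zones[int(rng_snp.integers(0, len(zones)))]
                    if z[1] <= z[0]:
                        continue
                    q = int(rng_snp.integers(z[0], z[1]))
                    if q in taken:
                        continue
                    taken.add(q)
                    anc_base = ancestor[c][q]
                    derived = "ACGT".replace(anc_base, "")[int(rng_snp.integers(0, 3))]
                    in_a = bool(rng_snp.random() < 0.5)
                    snp_rows.append(
                        dict(
                            chrom=c,
                            anc_pos=q,
                            anc_base=anc_base,
                            base_A=derived if in_a else anc_base,
                            base_B=anc_base if in_a else derived,
                            origin="te_flank",
                        )
                    )
                    snp_by_chrom[c].append(q)
                    (ops_A if in_a else ops_B)[c].append((q, q + 1, derived))
                    (op_refs_A if in_a else op_refs_B)[c].append(None)
                    break

    # -- SNPs ----------------------------------------------------------------
    if config.snp_rate > 0:
        for c in chroms:
            eligible = np.ones(lengths[c], dtype=bool)
            for s, e in footprints[c]:
                eligible[s:e] = False
            if snp_by_chrom[c]:
                eligible[np.asarray(snp_by_chrom[c])] = False
            prox = np.zeros(lengths[c], dtype=bool)
            if config.te_proximal_snp_multiplier != 1.0:
                w = config.te_proximal_window
                for s, e in footprints[c]:
                    prox[max(s - w, 0) : min(e + w, lengths[c])] = True
                prox &= eligible
            dist = eligible & ~prox
            n_dist = int(round(config.snp_rate * int(dist.sum())))
            n_prox = int(round(config.snp_rate * config.te_proximal_snp_multiplier * int(prox.sum())))
            pos = []
            if n_dist:
                pos.append(rng_snp.choice(np.flatnonzero(dist), size=n_dist, replace=False))
            if n_prox:
                pos.append(rng_snp.choice(np.flatnonzero(prox), size=n_prox, replace=False))
            if not pos:
                continue
            pos = np.sort(np.concatenate(pos))
            targets = rng_snp.random(pos.size) < 0.5  # True -> derived in A
            for p, in_a in zip(pos, targets):
                p = int(p)
                anc_base = ancestor[c][p]
                derived = "ACGT".replace(anc_base, "")[int(rng_snp.integers(0, 3))]
                snp_rows.append(
                    dict(
                        chrom=c,
                        anc_pos=p,
                        anc_base=anc_base,
                        base_A=derived if in_a else anc_base,
                        base_B=anc_base if in_a else derived,
                        origin="background",
                    )
                )
                snp_by_chrom[c].append(p)
                (ops_A if in_a else ops_B)[c].append((p, p + 1, derived))
                (op_refs_A if in_a else op_refs_B)[c].append(None)

    # -- small indels --------------------------------------------------------
    indel_rows = []
    if config.small_indel_rate > 0:
        n_indels = int(round(config.small_indel_rate * ancestor.total_length()))
        taken: dict[str, list[tuple[int, int]]] = {
            c: footprints[c] + [(p, p + 1) for p in snp_by_chrom[c]] for c in chroms
        }
        for _ in range(n_indels):
            for attempt in range(10_000):
                c = chroms[int(rng_indel.choice(len(chroms), p=weights))]
                ln = min(1 + int(rng_indel.geometric(0.5)), config.indel_max_len)
                p = int(rng_indel.integers(config.edge_exclusion, lengths[c] - config.edge_exclusion - ln))
                if any(p < e and p + ln > s for s, e in taken[c]):
                    continue
                taken[c].append((p, p + ln))
                in_a = bool(rng_indel.random() < 0.5)
                is_del = bool(rng_indel.random() < 0.5)
                if is_del:
                    op = (p, p + ln, "")
                    seq = ancestor[c][p : p + ln]
                else:
                    seq = random_seq(rng_indel, ln, config.gc_fraction)
                    op = (p, p, seq)
                (ops_A if in_a else ops_B)[c].append(op)
                (op_refs_A if in_a else op_refs_B)[c].append(None)
                indel_rows.append(
                    dict(
                        genome="A" if in_a else "B",
                        chrom=c,
                        anc_start=p,
                        anc_end=p + ln if is_del else p,
                        kind="deletion" if is_del else "insertion",
                        length=ln,
                        seq=seq,
                    )
                )
                break

    # -- build sequences -----------------------------------------------------
    telo_rows = []
    telos: dict[str, tuple[str, str]] = {}
    unit = config.telomere_unit
    for c in chroms:
        n5 = int(rng_telo.integers(*config.telomere_copies_range))
        n3 = int(rng_telo.integers(*config.telomere_copies_range))
        telos[c] = (revcomp(unit) * n5, unit * n3)
        telo_rows.append(dict(chrom=c, end="5prime", copies=n5))
        telo_rows.append(dict(chrom=c, end="3prime", copies=n3))

    seqs_A, seqs_B = {}, {}
    maps_A, maps_B = {}, {}
    spans_A, spans_B = {}, {}
    for c in chroms:
        for ops, refs in ((ops_A, op_refs_A), (ops_B, op_refs_B)):
            order = sorted(range(len(ops[c])), key=lambda i: (ops[c][i][0], ops[c][i][1]))
            ops[c] = [ops[c][i] for i in order]
            refs[c] = [refs[c][i] for i in order]
        telo5, telo3 = telos[c]
        seqs_A[c], maps_A[c], spans_A[c] = splice(ancestor[c], ops_A[c], telo5, telo3)
        seqs_B[c], maps_B[c], spans_B[c] = splice(ancestor[c], ops_B[c], telo5, telo3)

    # -- final coordinates in the ledger -------------------------------------
    span_by_eid_A = {
        e: (c, s)
        for c in chroms
        for e, s in zip(op_refs_A[c], spans_A[c])
        if e is not None
    }
    span_by_eid_B = {
        e: (c, s)
        for c in chroms
        for e, s in zip(op_refs_B[c], spans_B[c])
        if e is not None
    }
    for row in te_rows:
        eid, c, t = row["event_id"], row["chrom"], row["tsd_len"]
        if eid in span_by_eid_A:
            s, e = span_by_eid_A[eid][1]
            row["start_A"], row["end_A"] = s, e - t  # element body, TSD copies excluded
        else:
            row["start_A"], row["end_A"] = -1, -1
        if eid in span_by_eid_B:
            s, e = span_by_eid_B[eid][1]
            if row["elim_mode"] == "replacement":
                row["start_B"], row["end_B"] = s, e
            else:
                row["start_B"], row["end_B"] = s, e - t
        else:
            row["start_B"], row["end_B"] = -1, -1
        row["b_point"] = maps_B[c].map(row["anc_pos"]) if row["cls"] == "insertion_A" else -1

    for row in snp_rows:
        c = row["chrom"]
        row["pos_A"] = maps_A[c].map(row["anc_pos"])
        row["pos_B"] = maps_B[c].map(row["anc_pos"])
    for row in indel_rows:
        c = row["chrom"]
        m = maps_A[c] if row["genome"] == "A" else maps_B[c]
        row["start"] = m.map(row["anc_start"])
        row["end"] = row["start"] + (0 if row["kind"] == "deletion" else row["length"])

    gene_rows = [
        dict(chrom=c, start_A=maps_A[c].map(s), end_A=maps_A[c].map(e), anc_start=s, anc_end=e)
        for c in chroms
        for s, e in genes_by_chrom[c]
    ]

    # -- N-gap masking on B ---------------------------------------------------
    gap_rows = []
    if config.gap_spec:
        dirty: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        pad = 10
        for c in chroms:
            for (s, e, _r), (fs, fe) in zip(ops_A[c], spans_A[c]):
                # map the A-edit's ancestor footprint into B coordinates
                bs = maps_B[c].map(s)
                be = maps_B[c].map(e) if e <= lengths[c] else bs
                dirty[c].append((bs - pad, max(be, bs + 1) + pad))
            for (s, e, _r), (fs, fe) in zip(ops_B[c], spans_B[c]):
                dirty[c].append((fs - pad, max(fe, fs + 1) + pad))
            telo5, _ = telos[c]
            edge = len(telo5) + config.edge_exclusion
            dirty[c].append((0, edge))
            dirty[c].append((len(seqs_B[c]) - edge, len(seqs_B[c])))
            dirty[c].sort()
        for length, spacing in config.gap_spec:
            for c in chroms:
                x = spacing
                while x + length < len(seqs_B[c]):
                    placed = None
                    for shift in range(0, spacing // 2, 101):
                        cand = (x + shift, x + shift + length)
                        if cand[1] > len(seqs_B[c]):
                            break
                        if not _hits_intervals(cand, dirty[c]) and "N" not in seqs_B[c][cand[0] : cand[1]]:
                            placed = cand
                            break
                    if placed:
                        s, e = placed
                        gap_rows.append(
                            dict(genome="B", chrom=c, start=s, end=e, truth_seq=seqs_B[c][s:e])
                        )
                        seqs_B[c] = seqs_B[c][:s] + "N" * length + seqs_B[c][e:]
                        dirty[c].append((s - pad, e + pad))
                        dirty[c].sort()
                    x += spacing

    genome_A = Genome([(c, seqs_A[c]) for c in chroms])
    genome_B = Genome([(c, seqs_B[c]) for c in chroms])

    te_cols = [
        "event_id", "cls", "family", "chrom", "anc_pos", "tsd", "tsd_len", "ltr_len",
        "age_years", "start_A", "end_A", "start_B", "end_B", "b_point", "elim_mode",
        "seq_A", "seq_B",
    ]
    truth = TruthSet(
        snps=pd.DataFrame(snp_rows, columns=["chrom", "anc_pos", "anc_base", "base_A", "base_B", "origin", "pos_A", "pos_B"]),
        indels=pd.DataFrame(indel_rows, columns=["genome", "chrom", "anc_start", "anc_end", "kind", "length", "seq", "start", "end"]),
        te_events=pd.DataFrame(te_rows, columns=te_cols),
        gaps=pd.DataFrame(gap_rows, columns=["genome", "chrom", "start", "end", "truth_seq"]),
        telomeres=pd.DataFrame(telo_rows, columns=["chrom", "end", "copies"]),
        genes=pd.DataFrame(gene_rows, columns=["chrom", "start_A", "end_A", "anc_start", "anc_end"]),
        ops_A={c: list(ops_A[c]) for c in chroms},
        ops_B={c: list(ops_B[c]) for c in chroms},
    )
    return genome_A, genome_B, truth


def _in_intervals(p: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= p < e for s, e in intervals)


def _hits_intervals(cand: tuple[int, int], intervals: list[tuple[int, int]]) -> bool:
    s, e = cand
    return any(s < e0 and e > s0 for s0, e0 in intervals)


# ---------------------------------------------------------------------------
# Reconstruction (round-trip oracle support) and depth tracks
# ---------------------------------------------------------------------------


def reconstruct(ancestor: Genome, truth: TruthSet, which: str, config: SimConfig) -> Genome:
    """Rebuild a descendant from the ancestor using only the ledger.

    Applies the per-genome edit scripts back-to-front with plain string
    surgery (a code path independent of :func:`splice`), then telomeres
    and N-gap masks.  Used to check that the ledger is complete.
    """
    ops = truth.ops_A if which == "A" else truth.ops_B
    telo = {r.chrom: r for r in truth.telomeres.itertuples()}
    seqs = {}
    for c, anc in ancestor.records:
        s = anc
        for a, b, repl in sorted(ops.get(c, []), reverse=True):
            s = s[:a] + repl + s[b:]
        n5 = int(truth.telomeres.query("chrom == @c and end == '5prime'")["copies"].iloc[0])
        n3 = int(truth.telomeres.query("chrom == @c and end == '3prime'")["copies"].iloc[0])
        s = revcomp(config.telomere_unit) * n5 + s + config.telomere_unit * n3
        seqs[c] = s
    for r in truth.gaps.itertuples():
        if r.genome == which:
            seqs[r.chrom] = seqs[r.chrom][: r.start] + "N" * (r.end - r.start) + seqs[r.chrom][r.end :]
    return Genome([(c, seqs[c]) for c in ancestor.ids()])


def simulate_depth(
    genome: Genome, truth: TruthSet, which: str, coverage: float = 30.0
) -> dict[str, np.ndarray]:
    """Per-base depth of cross-genome reads mapped onto ``which``.

    Emulates mapping uniform reads from the *other* descendant: baseline
    ``coverage`` everywhere, zero over segments that have no counterpart
    in the other genome (genome-specific element bodies, elimination
    replacements, genome-specific indel insertions, N gaps).
    """
    depth = {c: np.full(len(s), float(coverage)) for c, s in genome.records}
    for r in truth.te_events.itertuples():
        if which == "A" and r.cls in ("insertion_A", "elimination_B") and r.start_A >= 0:
            depth[r.chrom][r.start_A : r.end_A] = 0.0
        if which == "B" and r.cls == "insertion_B" and r.start_B >= 0:
            depth[r.chrom][r.start_B : r.end_B] = 0.0
        if which == "B" and r.cls == "elimination_B" and r.start_B >= 0:
            depth[r.chrom][r.start_B : r.end_B] = 0.0
    for r in truth.indels.itertuples():
        if r.genome == which and r.kind == "insertion":
            depth[r.chrom][r.start : r.end] = 0.0
    for r in truth.gaps.itertuples():
        if r.genome == which:
            depth[r.chrom][r.start : r.end] = 0.0
    for c, s in genome.records:
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        depth[c][arr == ord("N")] = 0.0
    return depth


def write_bedgraph(depth: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for c, arr in depth.items():
            edges = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [arr.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{c}\t{s}\t{e}\t{arr[s]:g}\n")


def read_bedgraph(path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    depth = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, v = line.split("\t")
            if c in depth:
                depth[c][int(s) : int(e)] = float(v)
    return depth


def simulate_pair(config: SimConfig) -> tuple[Genome, Genome, TruthSet]:
    """Convenience wrapper: ancestor + derive in one call."""
    anc = generate_ancestor(config)
    a, b, truth = derive_pair(anc, config)
    return a, b, truth
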