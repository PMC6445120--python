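"""Pipeline orchestration and command-line interface.

One configuration drives simulate -> qc -> gapfill -> sv -> ltr ->
marker; every stage writes under its own subdirectory of the output
directory and a manifest records the seed, every threshold actually
used, and a checksum per output file, so that a rerun with the same
seed is byte-comparable.  Thresholds default to the values of the
protocol the pipeline reimplements (500-bp flanks, coverage >= 0.8,
< 5 total flank hits, 50-bp block merging, > 100-bp variants, 10%
depth fraction, 20-kb flank window, 0.99 shared-similarity split,
substitution rate 1.3e-8, 1-Mb/250-kb/0.9 heterochromatin scan,
400-bp flank windows, 10 interior bins, 100-bp gene bins, 100-ky age
windows).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import yaml

from . import asmqc, gapfill, ltrdyn, markerassoc, simpair, svpav
from .seqcore import Genome, find_n_runs

log = logging.getLogger("pairgenome")

DEFAULT_THRESHOLDS = dict(
    gap_merge_distance=500,
    flank_length=500,
    flank_min_coverage=0.8,
    flank_min_identity=0.8,
    gap_max_span=500_000,
    gap_max_total_hits=5,
    depth_min=3.0,
    depth_covered_frac=0.9,
    pav_merge_distance=50,
    sv_min_length=100,
    pav_depth_fraction=0.1,
    ltr_flank_window=20_000,
    shared_high_similarity=0.99,
    substitution_rate=1.3e-8,
    het_window=1_000_000,
    het_step=250_000,
    het_threshold=0.9,
    cns_flank_window=400,
    cns_inner_bins=10,
    cns_control_blocks=3_000,
    cns_control_length=20_000,
    gene_bin=100,
    cns_time_window=100_000,
    telomere_unit="TTTAGGG",
    telomere_min_copies=100,
    telomere_end_window=50_000,
)

STAGES = ("simulate", "qc", "gapfill", "sv", "ltr", "marker")


@dataclass
class RunConfig:
    sim: simpair.SimConfig = field(default_factory=simpair.SimConfig)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int | None = None  # overrides sim.seed when given
    outdir: str = "pairgenome_run"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = simpair.SimConfig(**_detuple(d.get("sim", {})))
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(d.get("thresholds", {}))
        return cls(
            sim=sim,
            thresholds=thresholds,
            stages=d.get("stages", list(STAGES)),
            seed=d.get("seed"),
            outdir=d.get("outdir", "pairgenome_run"),
        )


def _detuple(d: dict) -> dict:
    out = dict(d)
    for k in ("tsd_length_range", "telomere_copies_range", "ltr_age_range_years"):
        if k in out:
            out[k] = tuple(out[k])
    if "gap_spec" in out:
        out["gap_spec"] = [tuple(g) for g in out["gap_spec"]]
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.seed is not None:
        config.sim = dataclasses.replace(config.sim, seed=config.seed)
    th = config.thresholds
    manifest: dict = {
        "seed": config.sim.seed,
        "thresholds": th,
        "stages": list(config.stages),
        "outputs": {},
    }
    logging.basicConfig(
        level=logging.INFO,
        stream=sys.stderr,
        format="%(levelname)s %(name)s: %(message)s",
        force=False,
    )
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)

    def record(stage: str, path: Path):
        manifest["outputs"].setdefault(stage, {})[path.name] = _sha256(path)

    # ---- simulate ---------------------------------------------------------
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    log.info("simulating genome pair (seed=%d)", config.sim.seed)
    ancestor = simpair.generate_ancestor(config.sim)
    genome_a, genome_b, truth = simpair.derive_pair(ancestor, config.sim)
    if "simulate" in config.stages:
        genome_a.to_fasta(sim_dir / "genomeA.fasta")
        genome_b.to_fasta(sim_dir / "genomeB.fasta")
        ancestor.to_fasta(sim_dir / "ancestor.fasta")
        truth.write(sim_dir)
        config.sim.to_file(sim_dir / "sim_config.yaml")
        for p in sorted(sim_dir.iterdir()):
            record("simulate", p)

    depth_a = simpair.simulate_depth(genome_a, truth, "A")
    depth_b = simpair.simulate_depth(genome_b, truth, "B")

    # ---- qc ---------------------------------------------------------------
    if "qc" in config.stages:
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        for label, g in (("A", genome_a), ("B", genome_b)):
            calls = asmqc.detect_telomeres(
                g,
                unit=th["telomere_unit"],
                end_window=th["telomere_end_window"],
                min_copies=th["telomere_min_copies"],
            )
            gaps = find_n_runs(g)
            rows, summary = asmqc.assembly_stats(g, calls, gaps)
            asmqc.stats_table(rows).to_csv(qc_dir / f"stats_{label}.tsv", sep="\t", index=False)
            (qc_dir / f"summary_{label}.json").write_text(json.dumps(summary, indent=2))
        repeat_iv = {
            c: [
                (r.start_A, r.end_A)
                for r in truth.te_events.itertuples()
                if r.chrom == c and r.start_A >= 0
            ]
            for c in genome_a.ids()
        }
        blocks = asmqc.scan_heterochromatin(
            repeat_iv,
            genome_a.lengths(),
            window=th["het_window"],
            step=th["het_step"],
            threshold=th["het_threshold"],
        )
        with open(qc_dir / "heterochromatin_A.bed", "w") as bed:
            for c, s, e in blocks:
                bed.write(f"{c}\t{s}\t{e}\theterochromatin\t0\t+\n")
        for p in sorted(qc_dir.iterdir()):
            record("qc", p)

    # ---- gapfill ----------------------------------------------------------
    if "gapfill" in config.stages:
        gf_dir = out / "gapfill"
        gf_dir.mkdir(exist_ok=True)
        patched, closures, report = gapfill.fill_gaps(
            genome_b,
            genome_a,
            donor_depth=simpair.simulate_depth(genome_a, truth, "A"),
            merge_distance=th["gap_merge_distance"],
            flank=th["flank_length"],
            max_span=th["gap_max_span"],
            max_total_hits=th["gap_max_total_hits"],
            min_coverage=th["flank_min_coverage"],
            min_identity=th["flank_min_identity"],
            depth_min=th["depth_min"],
            depth_covered_frac=th["depth_covered_frac"],
        )
        patched.to_fasta(gf_dir / "genomeB.patched.fasta")
        gapfill.closures_table(closures).to_csv(gf_dir / "closures.tsv", sep="\t", index=False)
        report_out = {k: v for k, v in report.items() if k != "patched_intervals"}
        (gf_dir / "report.json").write_text(json.dumps(report_out, indent=2))
        with open(gf_dir / "patched.bed", "w") as bed:
            for c, s, e in report["patched_intervals"]:
                bed.write(f"{c}\t{s}\t{e}\tpatched\t0\t+\n")
        for p in sorted(gf_dir.iterdir()):
            record("gapfill", p)

    # ---- sv ---------------------------------------------------------------
    if "sv" in config.stages:
        sv_dir = out / "sv"
        sv_dir.mkdir(exist_ok=True)
        pavs = svpav.detect_pav(
            genome_a,
            genome_b,
            depth_a=depth_a,
            depth_b=depth_b,
            merge_distance=th["pav_merge_distance"],
            min_len=th["sv_min_length"],
            depth_fraction=th["pav_depth_fraction"],
        )
        repeat_ann = {
            c: [
                (r.start_B, r.end_B, "LTR")
                for r in truth.te_events.itertuples()
                if r.chrom == c and r.start_B >= 0
            ]
            for c in genome_b.ids()
        }
        svpav.annotate_breakpoints(pavs, repeat_ann)
        rows = [
            dict(
                kind=v.kind, chrom=v.chrom, start=v.start, end=v.end, length=v.length,
                repeat_class=v.repeat_class, depth_checked=v.depth_checked,
            )
            for v in pavs
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(sv_dir / "pav.tsv", sep="\t", index=False)
        svpav.summarize_by_chrom(pavs).to_csv(sv_dir / "pav_by_chrom.tsv", sep="\t", index=False)
        for p in sorted(sv_dir.iterdir()):
            record("sv", p)

    # ---- ltr --------------------------------------------------------------
    if "ltr" in config.stages:
        ltr_dir = out / "ltr"
        ltr_dir.mkdir(exist_ok=True)
        elements = ltrdyn.detect_intact_ltr(genome_a)
        ltrdyn.date_elements(elements, genome_a, rate=th["substitution_rate"])
        ltrdyn.classify_elements(
            elements,
            genome_a,
            genome_b,
            window=th["ltr_flank_window"],
            high_similarity=th["shared_high_similarity"],
        )
        ltrdyn.elements_table(elements).to_csv(ltr_dir / "elements.tsv", sep="\t", index=False)
        (ltr_dir / "summary.json").write_text(json.dumps(ltrdyn.class_summary(elements), indent=2))
        for p in sorted(ltr_dir.iterdir()):
            record("ltr", p)

    # ---- marker -----------------------------------------------------------
    if "marker" in config.stages:
        mk_dir = out / "marker"
        mk_dir.mkdir(exist_ok=True)
        ins = truth.te_events.query("cls == 'insertion_A'")
        if len(ins):
            r = ins.iloc[0]
            a = genome_a[r.chrom]
            junction = a[r.start_A - int(r.tsd_len) - 13 : r.start_A + 13]
            present = {
                label: markerassoc.junction_present({label: dict(g.records)[r.chrom]}, junction)
                for label, g in (("A", genome_a), ("B", genome_b))
            }
            import pandas as pd

            panel = markerassoc.MarkerPanel(
                pd.DataFrame(
                    [
                        dict(sample="A", phenotype="red", marker="present" if present["A"] else "absent"),
                        dict(sample="B", phenotype="non_red", marker="present" if present["B"] else "absent"),
                    ]
                )
            )
            summary = markerassoc.cosegregation(panel)
            summary["junction"] = junction
            summary["table"] = {f"{p}/{m}": n for (p, m), n in summary["table"].items()}
            (mk_dir / "cosegregation.json").write_text(json.dumps(summary, indent=2))
            (mk_dir / "gel.txt").write_text(markerassoc.gel_report(panel))
            for p in sorted(mk_dir.iterdir()):
                record("marker", p)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.removeHandler(fh)
    fh.close()
    return manifest


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def main():
    """Comparative analysis of a simulated pair of plant genome assemblies."""


def _load(config_path, outdir, seed, stages):
    cfg = RunConfig.from_file(config_path) if config_path else RunConfig()
    if outdir:
        cfg.outdir = outdir
    if seed is not None:
        cfg.seed = seed
    if stages:
        cfg.stages = list(stages)
    return cfg


def _stage_command(name: str, helptext: str):
    @main.command(name=name, help=helptext)
    @click.option("--config", "config_path", type=click.Path(exists=True), default=None)
    @click.option("--outdir", default=None)
    @click.option("--seed", type=int, default=None)
    def _cmd(config_path, outdir, seed, _name=name):
        stages = ["simulate"] if _name == "simulate" else ["simulate", _name]
        cfg = _load(config_path, outdir, seed, stages)
        run(cfg)

    return _cmd


for _name, _help in (
    ("simulate", "Generate the synthetic genome pair and truth ledger."),
    ("qc", "Telomere/heterochromatin scan and assembly statistics."),
    ("gapfill", "Reciprocal flank-anchored gap closure."),
    ("sv", "PAV detection and annotation."),
    ("ltr", "LTR element detection, dating and classification."),
    ("marker", "Junction-marker co-segregation demo."),
):
    _stage_command(_name, _help)


@main.command(name="all")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--outdir", default=None)
@click.option("--seed", type=int, default=None)
def run_all(config_path, outdir, seed):
    """Run every stage."""
    run(_load(config_path, outdir, seed, None))


@click.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--outdir", default="simpair_out")
def simulate_entry(config_path, seed, outdir):
    """Standalone simulator entry point (genomes + truth ledger only)."""
    sim = simpair.SimConfig.from_file(config_path) if config_path else simpair.SimConfig()
    if seed is not None:
        sim = dataclasses.replace(sim, seed=seed)
    run(RunConfig(sim=sim, stages=["simulate"], outdir=outdir))


if __name__ == "__main__":
    main()
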