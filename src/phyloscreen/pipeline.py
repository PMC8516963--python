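"""Pipeline orchestration: simulate -> search/screen -> compare -> QC.

Stages run in dependency order and only when their inputs are configured;
partial configs run partial pipelines.  Outputs are written atomically with
a manifest of content hashes; re-running with unchanged config and inputs
skips recomputation.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, io, losses, ploidy as ploidy_mod, simulate as sim
from .config import RunConfig
from .screen import ScreenConfig, screen_all_detailed
from .trees import SpeciesTree

log = logging.getLogger("phyloscreen")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ValidationFinding:
    stage: str
    name: str
    message: str


@dataclass
class ReportBundle:
    provenance: Dict
    matrix: Optional[losses.PresenceMatrix] = None
    loss_events: List[losses.LossEvent] = field(default_factory=list)
    complex_status: Optional[pd.DataFrame] = None
    completeness: Optional[pd.DataFrame] = None
    ploidy_report: Optional[ploidy_mod.PloidyReport] = None
    kmer_report: Optional[ploidy_mod.KmerCompleteness] = None
    outputs: Dict[str, str] = field(default_factory=dict)
    cached: bool = False


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dir_fastas(path: Optional[str]) -> Dict[str, Path]:
    if path is None:
        return {}
    d = Path(path)
    return {p.stem: p for p in sorted(d.glob("*.fasta")) + sorted(d.glob("*.fa"))}


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(config: RunConfig) -> List[ValidationFinding]:
    """Named findings; never raises past this boundary."""
    findings: List[ValidationFinding] = []

    def add(stage, name, msg):
        findings.append(ValidationFinding(stage, name, msg))

    for attr in ("tree", "complexes", "pileup", "kmer_assembly", "kmer_reads"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            add("paths", f"missing-{attr}", f"{attr} path {p} does not exist")
    tree = None
    if config.tree and Path(config.tree).exists():
        try:
            tree = SpeciesTree.from_newick(Path(config.tree).read_text())
        except Exception as exc:  # malformed newick
            add("tree", "bad-newick", str(exc))
    proteomes = _dir_fastas(config.proteomes)
    if tree is not None and proteomes:
        for taxon in tree.tip_labels:
            if taxon not in proteomes:
                add("screen", "taxon-missing-proteome",
                    f"taxon {taxon} in tree has no proteome FASTA")
    alignments = _dir_fastas(config.alignments)
    for fam, path in alignments.items():
        try:
            io.read_alignment(path)
        except ValueError as exc:
            add("search", "bad-alignment", str(exc))
    if config.complexes and Path(config.complexes).exists():
        try:
            cx = io.read_complexes(config.complexes)
            if alignments:
                for member in cx["member"]:
                    if member not in alignments:
                        add("compare", "complex-member-unknown",
                            f"complex member {member} has no seed alignment")
        except ValueError as exc:
            add("compare", "bad-complex-table", str(exc))
    for taxon, path in _dir_fastas(config.proteomes).items():
        seqs = io.read_fasta(path)
        for name, s in seqs.items():
            if set(s) - set("ACDEFGHIKLMNPQRSTVWYXBZJUO*"):
                add("screen", "bad-proteome-alphabet",
                    f"{taxon}:{name} has non-amino-acid characters")
                break
    return findings


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _write_synthetic_bundle(config: RunConfig, outdir: Path) -> RunConfig:
    """Generate the synthetic study inputs and return a config pointing at them."""
    sc = config.simulate
    assert sc is not None
    rng = np.random.default_rng(config.seed)
    tree = sim.simulate_tree(
        sc.n_taxa, int(rng.integers(2**31)), sc.long_clade_fraction, sc.long_multiplier
    )
    truths = []
    for k in range(sc.n_families):
        truths.append(
            sim.evolve_family(
                tree, sc.root_len, sc.sub_rate, sc.loss_rate,
                seed=int(rng.integers(2**31)), family_id=f"fam{k + 1:03d}",
            )
        )
    genomes, proteomes, registry = sim.emit_genome_and_proteome(
        truths, sc.intergenic_len, sc.hide_fraction, seed=int(rng.integers(2**31))
    )
    base = outdir / "synthetic"
    (base / "alignments").mkdir(parents=True, exist_ok=True)
    (base / "proteomes").mkdir(parents=True, exist_ok=True)
    (base / "genomes").mkdir(parents=True, exist_ok=True)
    with io.atomic_write(base / "tree.nwk") as fh:
        fh.write(tree.to_newick() + "\n")
    # seed alignments: ungapped rows perturbed around the family root sequence
    for truth in truths:
        seed_rows = {}
        for r in range(sc.n_seed_rows):
            seed_rows[f"{truth.family_id}_seed{r + 1}"] = sim.mutate_sequence(
                truth.root_seq, 0.95, rng
            )
        io.write_fasta(seed_rows, base / "alignments" / f"{truth.family_id}.fasta")
    for taxon in sorted(proteomes):
        io.write_fasta(proteomes[taxon], base / "proteomes" / f"{taxon}.fasta")
        io.write_fasta(genomes[taxon], base / "genomes" / f"{taxon}.fasta")
    io.write_tsv(registry, base / "truth_registry.tsv")
    pileup = sim.simulate_pileup(
        sc.pileup_ploidy, sc.pileup_sites, sc.pileup_cov, sc.pileup_error,
        sc.pileup_het_density, seed=int(rng.integers(2**31)),
    )
    io.write_tsv(pileup, base / "pileup.tsv")
    taxon0 = sorted(genomes)[0]
    assembly, reads = sim.sample_kmer_sets(
        genomes[taxon0], sc.kmer_k, sc.kmer_read_cov, sc.kmer_dropout,
        seed=int(rng.integers(2**31)),
    )
    io.write_kmer_table({km: 1 for km in sorted(assembly)}, base / "kmers_assembly.tsv")
    io.write_kmer_table(reads, base / "kmers_reads.tsv")

    cfg = RunConfig(
        outdir=str(outdir), seed=config.seed,
        tree=str(base / "tree.nwk"),
        alignments=str(base / "alignments"),
        proteomes=str(base / "proteomes"),
        genomes=str(base / "genomes"),
        complexes=config.complexes,
        pileup=str(base / "pileup.tsv"),
        kmer_assembly=str(base / "kmers_assembly.tsv"),
        kmer_reads=str(base / "kmers_reads.tsv"),
        thresholds=config.thresholds,
    )
    return cfg


def _screen_stage(config: RunConfig, outdir: Path, outputs: Dict[str, str]):
    alignments = _dir_fastas(config.alignments)
    proteome_files = _dir_fastas(config.proteomes)
    genome_files = _dir_fastas(config.genomes)
    families = {}
    domain_dir = _dir_fastas(config.domains)
    for fam, path in alignments.items():
        fam_spec = {"msa": io.read_alignment(path)}
        doms = [io.read_alignment(p) for name, p in domain_dir.items()
                if name.startswith(f"{fam}.dom")]
        if doms:
            fam_spec["domains"] = doms
        families[fam] = fam_spec
    taxa = {}
    for taxon, path in proteome_files.items():
        taxa[taxon] = {
            "proteome": io.read_fasta(path),
            "genome": io.read_fasta(genome_files[taxon]) if taxon in genome_files else None,
        }
    thr = config.thresholds
    sconf = ScreenConfig(
        inclusion_E=thr.inclusion_E, family_E=dict(thr.family_E), domain_E=thr.domain_E,
        gap_open=thr.gap_open, gap_extend=thr.gap_extend, alpha=thr.alpha,
        min_orf_len=thr.min_orf_len, n_decoys=thr.n_decoys, decoy_len=thr.decoy_len,
        max_iter=thr.max_iter, seed=config.seed,
    )
    log.info("screen: %d families x %d taxa", len(families), len(taxa))
    calls, models = screen_all_detailed(families, taxa, sconf)
    df = io.calls_to_frame(calls)
    io.write_tsv(df, outdir / "calls.tsv")
    outputs["calls"] = str(outdir / "calls.tsv")
    hit_rows = [
        {
            "family": h.family_id, "target": h.target_id,
            "start": h.start + 1, "end": h.end,
            "bitscore": round(h.bitscore, 3), "evalue": h.evalue,
            "iteration": h.iteration,
        }
        for m in models.values()
        for h in m.enrichment_hits
    ]
    io.write_tsv(pd.DataFrame(hit_rows), outdir / "hits.tsv")
    outputs["hits"] = str(outdir / "hits.tsv")
    profile_dir = outdir / "profiles"
    for fam, model in models.items():
        io.write_profile(model.profile, profile_dir / f"{fam}.tsv")
    outputs["profiles"] = str(profile_dir)
    return calls


def _compare_stage(config, calls, outdir: Path, outputs: Dict[str, str], bundle):
    tree = SpeciesTree.from_newick(Path(config.tree).read_text())
    matrix = losses.build_matrix(calls)
    io.write_tsv(matrix.states, outdir / "matrix.tsv", index=True)
    outputs["matrix"] = str(outdir / "matrix.tsv")
    events: List[losses.LossEvent] = []
    for fam in matrix.families:
        column = matrix.states.loc[fam].to_dict()
        rec = losses.dollo_reconstruct(tree, column, family_id=fam)
        events.extend(rec.events())
    ev_df = pd.DataFrame(
        [(e.family_id, e.branch, e.event) for e in events],
        columns=["family", "branch", "event"],
    )
    io.write_tsv(ev_df, outdir / "loss_events.tsv")
    outputs["loss_events"] = str(outdir / "loss_events.tsv")
    fam2cx = None
    if config.complexes:
        cx_df = io.read_complexes(config.complexes)
        defs = [
            losses.ComplexDefinition(cid, list(grp["member"]))
            for cid, grp in cx_df.groupby("complex", sort=True)
        ]
        status = losses.complex_status(matrix, defs)
        io.write_tsv(status, outdir / "complex_status.tsv", index=True)
        outputs["complex_status"] = str(outdir / "complex_status.tsv")
        bundle.complex_status = status
        fam2cx = dict(zip(cx_df["member"], cx_df["complex"]))
    summary = losses.branch_loss_summary(
        tree, [e for e in events if e.event == "loss"], fam2cx
    )
    io.write_tsv(summary, outdir / "branch_loss_summary.tsv", index=True)
    outputs["branch_loss_summary"] = str(outdir / "branch_loss_summary.tsv")
    present_counts = matrix.presence().sum(axis=0)
    comp = pd.DataFrame(
        {
            "taxon": matrix.taxa,
            "n_present": [int(present_counts[t]) for t in matrix.taxa],
            "n_families": len(matrix.families),
            "percent": [
                losses.busco_percentage(int(present_counts[t]), len(matrix.families))
                for t in matrix.taxa
            ],
        }
    )
    io.write_tsv(comp, outdir / "completeness.tsv")
    outputs["completeness"] = str(outdir / "completeness.tsv")
    bundle.matrix = matrix
    bundle.loss_events = [e for e in events if e.event == "loss"]
    bundle.completeness = comp


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all configured stages; returns the collected results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    findings = validate_inputs(config)
    if findings:
        msgs = "; ".join(f"{f.name}: {f.message}" for f in findings)
        raise PipelineError("validate", msgs)

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        import json

        old = json.loads(manifest_path.read_text())
        if old.get("provenance", {}).get("config_hash") == provenance["config_hash"]:
            ok = all(Path(p).exists() for p in old.get("outputs", {}).values())
            if ok:
                log.info("manifest unchanged; skipping recomputation")
                bundle = ReportBundle(provenance=old["provenance"], cached=True)
                bundle.outputs = old["outputs"]
                return bundle

    if config.simulate is not None:
        log.info("simulate: generating synthetic inputs")
        config = _write_synthetic_bundle(config, outdir)

    bundle = ReportBundle(provenance=provenance)
    outputs: Dict[str, str] = {}

    calls = None
    if config.alignments and config.proteomes:
        calls = _screen_stage(config, outdir, outputs)
    if calls is not None and config.tree:
        _compare_stage(config, calls, outdir, outputs, bundle)
    if config.pileup:
        thr = config.thresholds
        pileup = io.read_tsv(config.pileup)
        het = ploidy_mod.call_het_sites(pileup, thr.min_cov, thr.min_alt_reads)
        report = ploidy_mod.infer_ploidy(
            het, thr.het_frac_threshold, (thr.balance_low, thr.balance_high),
            thr.min_ploidy_sites, thr.balance_floor,
        )
        io.write_json(report.to_dict(), outdir / "ploidy.json")
        hist_df = pd.DataFrame(
            {
                "bin_low": report.bin_edges[:-1],
                "bin_high": report.bin_edges[1:],
                "n_het": report.histogram,
            }
        )
        io.write_tsv(hist_df, outdir / "balance_histogram.tsv")
        outputs["ploidy"] = str(outdir / "ploidy.json")
        outputs["balance_histogram"] = str(outdir / "balance_histogram.tsv")
        bundle.ploidy_report = report
    if config.kmer_assembly and config.kmer_reads:
        assembly = set(io.read_kmer_table(config.kmer_assembly))
        reads = io.read_kmer_table(config.kmer_reads)
        kc = ploidy_mod.kmer_completeness(assembly, reads, config.thresholds.solid_min)
        io.write_json(kc.to_dict(), outdir / "kmer_completeness.json")
        outputs["kmer_completeness"] = str(outdir / "kmer_completeness.json")
        bundle.kmer_report = kc

    bundle.outputs = outputs
    io.write_json({"provenance": provenance, "outputs": outputs}, manifest_path)
    return bundle
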