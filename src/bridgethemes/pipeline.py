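"""Pipeline orchestration: simulate -> detect -> structure -> binding -> network.

Stages communicate only via files, so any stage can be re-run alone; a run
is a pure function of (inputs, seed) and re-running is idempotent.  The
final JSON report carries per-stage counts, the configuration echo and the
package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as btio
from .binding import BindingAnnotation, annotate_domain, theme_enrichment
from .bridge import bridges_to_table, detect_bridges, parse_aligned_pairs
from .datamodel import DomainRecord
from .network import build_nested, build_overview, export_graph
from .structure import compute_metrics, fit_rmsd_mixture
from .synthetic import PlantConfig, generate_benchmark

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str, record_id: str | None = None):
        self.stage = stage
        self.record_id = record_id
        where = f" (record {record_id})" if record_id else ""
        super().__init__(f"stage {stage!r} failed{where}: {message}")


@dataclass
class RunConfig:
    """All paths, thresholds and alignment parameters of one run.

    Threshold defaults are the study's: E-value 1e-3 and coverage 0.85 for
    hit significance, 20 residues for the local-alignment length rule and
    the flank length rule, 25% identity for the flank context rule, 6
    Angstrom RMSD for structural similarity, contact maps at 9 and 11
    Angstrom, 4.5 Angstrom for ligand binding.
    """

    # inputs
    fasta: str | None = None
    pdb_dir: str | None = None
    classification: str | None = None
    hits: str | None = None
    biolip: str | None = None
    ss: str | None = None
    tm_scores: str | None = None
    # thresholds
    e_max: float = 1e-3
    cov_min: float = 0.85
    sw_min_aligned: int = 20
    flank_min_len: int = 20
    flank_max_id: float = 25.0
    rmsd_threshold: float = 6.0
    contact_thresholds: tuple[float, float] = (9.0, 11.0)
    binding_cutoff: float = 4.5
    # alignment
    matrix: str | None = None  # path to an NCBI-format matrix; None = BLOSUM62
    gap_open: float = 11.0
    gap_extend: float = 1.0
    n_pvalue_samples: int = 1000
    # mixture
    mixture_mode: str = "all"  # "all" | "local" | "global"
    # misc
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # PlantConfig overrides

    def __post_init__(self) -> None:
        for name in ("e_max", "cov_min", "flank_max_id", "rmsd_threshold",
                     "binding_cutoff", "gap_open", "gap_extend"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sw_min_aligned <= 0 or self.flank_min_len <= 0:
            raise ValueError("length thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "contact_thresholds" in data:
            data["contact_thresholds"] = tuple(data["contact_thresholds"])
        return cls(**data)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["contact_thresholds"] = list(self.contact_thresholds)
        return d


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(config: RunConfig, out_dir: str | Path) -> dict:
    """Generate the synthetic benchmark and point the config at it."""
    out_dir = Path(out_dir)
    plant = PlantConfig(**{"seed": config.seed, **config.simulate})
    paths = generate_benchmark(plant, out_dir / "benchmark")
    config.fasta = str(paths.fasta)
    config.pdb_dir = str(paths.pdb_dir)
    config.classification = str(paths.classification)
    config.hits = str(paths.hits)
    config.ss = str(paths.ss)
    config.biolip = str(paths.biolip)
    truth = btio.read_truth(paths.truth)
    return {
        "n_domains": plant.n_xgroups * plant.domains_per_group,
        "n_xgroups": plant.n_xgroups,
        "n_themes": plant.n_themes,
        "n_planted_occurrences": sum(1 for t in truth if t.planted),
        "n_decoy_hits": sum(1 for t in truth if not t.planted),
    }


def _load_domains(config: RunConfig) -> dict[str, DomainRecord]:
    for name in ("fasta", "classification", "hits"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise StageError("detect", f"missing input file for {name!r}: {p}")
    classification = btio.read_classification(config.classification)
    ss_table = btio.read_ss_table(config.ss) if config.ss else {}
    domains = {}
    for domain_id, seq in btio.read_fasta(config.fasta):
        label = classification.get(domain_id)
        if label is None:
            logger.warning("domain %s unclassified, skipped", domain_id)
            continue
        domains[domain_id] = DomainRecord(
            domain_id=domain_id, sequence=seq, classification=label,
            ss=ss_table.get(domain_id))
    return domains


def stage_detect(config: RunConfig, out_dir: str | Path) -> dict:
    """Hits + classification + sequences -> bridge table TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    domains = _load_domains(config)
    hits = btio.read_hits(config.hits)
    from .alignment import load_matrix
    matrix = load_matrix(config.matrix) if config.matrix else None
    try:
        reps, groups = detect_bridges(
            domains, hits, e_max=config.e_max, cov_min=config.cov_min,
            matrix=matrix, gap_open=config.gap_open, gap_extend=config.gap_extend,
            sw_min_aligned=config.sw_min_aligned,
            flank_min_len=config.flank_min_len, flank_max_id=config.flank_max_id,
            n_pvalue_samples=config.n_pvalue_samples, seed=config.seed)
    except ValueError as exc:
        raise StageError("detect", str(exc)) from exc
    table = bridges_to_table(reps)
    table.to_csv(out_dir / "bridges.tsv", sep="\t", index=False)
    kept = [h for h in hits if h.e_value <= config.e_max and h.coverage >= config.cov_min]
    return {
        "hits_in": len(hits),
        "hits_kept": len(kept),
        "candidate_groups": len(groups),
        "candidates_aligned": sum(len(g.candidates) for g in groups),
        "representatives": len(table),
        "nw_fallbacks": int((table["mode"] == "global").sum()),
        "flank_pass_both": int((table["flank_pass_before"]
                                & table["flank_pass_after"]).sum()),
    }


def _domain_from_pdb(config: RunConfig, domain_id: str, xgroup: str,
                     ss_table: dict[str, str]) -> DomainRecord:
    pdb = Path(config.pdb_dir) / f"{domain_id}.pdb"
    if not pdb.exists():
        raise StageError("structure", f"no PDB file {pdb}", domain_id)
    chain = btio.read_structure(pdb)
    return DomainRecord(
        domain_id=domain_id, sequence=chain.sequence,
        classification=f"0.{xgroup}", coords=chain.coords,
        ss=ss_table.get(domain_id), source_chain=None,
        author_numbers=chain.author_numbers)


def stage_structure(config: RunConfig, out_dir: str | Path) -> dict:
    """Bridge table + PDB files -> per-pair structural metrics + mixture fit."""
    out_dir = Path(out_dir)
    bridges = pd.read_csv(out_dir / "bridges.tsv", sep="\t")
    if config.pdb_dir is None:
        raise StageError("structure", "no pdb_dir configured")
    ss_table = btio.read_ss_table(config.ss) if config.ss else {}
    tm = {}
    if config.tm_scores:
        t = pd.read_csv(config.tm_scores, sep="\t")
        tm = {(r.domain_a, r.domain_b): float(r.tm_score) for r in t.itertuples()}

    cache: dict[str, DomainRecord] = {}
    rows = []
    for row in bridges.itertuples():
        for domain_id, xg in ((row.domain_a, row.xgroup_a), (row.domain_b, row.xgroup_b)):
            if domain_id not in cache:
                cache[domain_id] = _domain_from_pdb(config, domain_id, str(xg), ss_table)
        pairs = parse_aligned_pairs(row.aligned_pairs)
        try:
            m = compute_metrics(cache[row.domain_a], cache[row.domain_b], pairs,
                                rmsd_threshold=config.rmsd_threshold,
                                contact_thresholds=config.contact_thresholds)
        except ValueError as exc:
            raise StageError("structure", str(exc),
                             f"{row.domain_a}/{row.domain_b}") from exc
        rows.append({
            "theme_id": row.theme_id, "domain_a": row.domain_a,
            "domain_b": row.domain_b, "mode": row.mode,
            "rmsd_ca": round(m.rmsd_ca, 4), "drmsd": round(m.drmsd, 4),
            "cm_change_9": round(m.cm_change_9, 4),
            "cm_change_11": round(m.cm_change_11, 4),
            "ss_agreement": round(m.ss_agreement, 4) if m.ss_agreement is not None else "",
            "n_used": m.n_used, "similar": m.similar,
            "tm_score": tm.get((row.domain_a, row.domain_b), ""),
        })
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out_dir / "structure_metrics.tsv", sep="\t", index=False)

    report = {
        "pairs": len(metrics),
        "similar": int(metrics["similar"].sum()) if len(metrics) else 0,
        "dissimilar": int((~metrics["similar"]).sum()) if len(metrics) else 0,
    }
    sel = metrics
    if config.mixture_mode in ("local", "global") and len(metrics):
        sel = metrics[metrics["mode"] == config.mixture_mode]
    if len(sel) >= 10 and np.ptp(sel["rmsd_ca"].to_numpy()) > 0:
        fit = fit_rmsd_mixture(sel["rmsd_ca"].to_numpy(), seed=config.seed)
        mixture = {
            "weights": list(fit.weights), "means": list(fit.means),
            "sds": list(fit.sds), "loglik": fit.loglik,
            "n_iter": fit.n_iter, "converged": fit.converged,
            "n_values": int(len(sel)), "mode_filter": config.mixture_mode,
        }
        with open(out_dir / "rmsd_mixture.json", "w") as fh:
            json.dump(mixture, fh, indent=2)
        report["mixture"] = mixture
    else:
        report["mixture"] = None
    return report


def stage_binding(config: RunConfig, out_dir: str | Path) -> dict:
    """Bridge table + PDB files (+ optional BioLiP table) -> enrichment."""
    out_dir = Path(out_dir)
    bridges = pd.read_csv(out_dir / "bridges.tsv", sep="\t")
    if config.pdb_dir is None:
        raise StageError("binding", "no pdb_dir configured")

    themes: dict[str, list[tuple[int, int]]] = {}
    xg_of: dict[str, str] = {}
    for row in bridges.itertuples():
        themes.setdefault(row.domain_a, []).append((int(row.start_a), int(row.end_a)))
        themes.setdefault(row.domain_b, []).append((int(row.start_b), int(row.end_b)))
        xg_of[row.domain_a] = str(row.xgroup_a)
        xg_of[row.domain_b] = str(row.xgroup_b)

    lengths: dict[str, int] = {}
    distance_anns: list[BindingAnnotation] = []
    for domain_id in sorted(themes):
        pdb = Path(config.pdb_dir) / f"{domain_id}.pdb"
        if not pdb.exists():
            raise StageError("binding", f"no PDB file {pdb}", domain_id)
        chain = btio.read_structure(pdb)
        lengths[domain_id] = len(chain.sequence)
        record = DomainRecord(domain_id=domain_id, sequence=chain.sequence,
                              classification=f"0.{xg_of[domain_id]}",
                              coords=chain.coords)
        distance_anns.extend(annotate_domain(record, chain.ligands,
                                             cutoff=config.binding_cutoff))

    results = {}
    enr = theme_enrichment(lengths, themes, distance_anns)
    results["distance"] = enr
    if config.biolip:
        biolip_anns = [BindingAnnotation(d, code, res, "biolip")
                       for d, code, res in btio.read_biolip(config.biolip)
                       if d in themes]
        results["biolip"] = theme_enrichment(lengths, themes, biolip_anns)

    report = {}
    frames = []
    for method, enr in results.items():
        report[method] = {
            "theme_residue_fraction": enr.theme_residue_fraction,
            "binding_in_theme_fraction": enr.binding_in_theme_fraction,
            "n_domains": enr.n_domains,
            "total_binding_residues": enr.total_binding_residues,
            "binding_in_theme": enr.binding_in_theme,
        }
        df = enr.per_domain.copy()
        df.insert(0, "method", method)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        out_dir / "enrichment.tsv", sep="\t", index=False)
    with open(out_dir / "enrichment.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def stage_network(config: RunConfig, out_dir: str | Path,
                  nested_pair: tuple[str, str] | None = None) -> dict:
    """Bridge table + classification -> overview (and optional nested) graphs."""
    out_dir = Path(out_dir)
    bridges = pd.read_csv(out_dir / "bridges.tsv", sep="\t",
                          dtype={"xgroup_a": str, "xgroup_b": str})
    if bridges.empty:
        raise StageError("network", "bridge table is empty")
    classification = (btio.read_classification(config.classification)
                      if config.classification else {})
    overview = build_overview(bridges, classification)
    export_graph(overview, out_dir / "overview.graphml", "graphml")
    export_graph(overview, out_dir / "overview.sif", "sif")
    report = {
        "overview_nodes": overview.number_of_nodes(),
        "overview_edges": overview.number_of_edges(),
        "solid_edges": sum(1 for _, _, d in overview.edges(data=True)
                           if d["style"] == "solid"),
    }
    if nested_pair:
        nested = build_nested(bridges, nested_pair, classification)
        name = f"nested_{nested_pair[0]}_{nested_pair[1]}"
        export_graph(nested, out_dir / f"{name}.graphml", "graphml")
        report["nested_nodes"] = nested.number_of_nodes()
        report["nested_edges"] = nested.number_of_edges()
    return report


# ---------------------------------------------------------------------------
# Orchestration

def run_all(config: RunConfig, out_dir: str | Path,
            do_simulate: bool = False) -> dict:
    """Run every stage under one output directory and write report.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}
    if do_simulate:
        report["simulate"] = stage_simulate(config, out_dir)
    report["detect"] = stage_detect(config, out_dir)
    if config.pdb_dir:
        report["structure"] = stage_structure(config, out_dir)
        report["binding"] = stage_binding(config, out_dir)
    report["network"] = stage_network(config, out_dir)
    report["config"] = config.echo()
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
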