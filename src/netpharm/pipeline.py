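"""End-to-end orchestration: edges -> topology -> modules -> enrichment ->
prioritization, with a manifest recording the configuration of every run.

Each stage writes its table to the output directory, so stages can also be
rerun independently from cached upstream outputs via the CLI subcommands.
A ``fixtures`` run skips the network stages and executes the prioritization
cascade on the transcribed candidate table and functional groups.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .enrichment import TermGroup, enrich, group_terms
from .mcode import MCODEParams, find_modules
from .network_io import (AnnotationSet, read_gmt, read_string_tsv,
                         write_metrics_csv)
from .prioritize import PrioritizationResult, run_prioritization
from .synthetic_data import table1_fixture, table2_fixture
from .topology import compute_node_metrics, summarize

__all__ = ["PipelineConfig", "run_pipeline", "write_groups_tsv"]


@dataclass
class PipelineConfig:
    edges: str | None = None
    gmt: str | None = None
    use_paper_fixtures: bool = False
    score_threshold: int = 900
    seed_nodes: list[str] = field(default_factory=list)
    mcode: MCODEParams = field(default_factory=MCODEParams)
    alpha: float = 0.05
    kappa_threshold: float = 0.4
    k_levels: int = 10
    cc_threshold: float = 0.5
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "mcode" in d and isinstance(d["mcode"], dict):
            d["mcode"] = MCODEParams(**d["mcode"])
        return cls(**d)


def write_groups_tsv(groups: list[TermGroup], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("group_id\tmember_terms\tassociated_genes\n")
        for g in groups:
            fh.write(f"{g.group_id}\t{';'.join(g.member_terms)}\t"
                     f"{';'.join(g.associated_genes)}\n")


def read_groups_tsv(path: str | Path) -> list[TermGroup]:
    groups = []
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("group_id"):
            raise ValueError(f"{path}: not a groups TSV")
        for line in fh:
            gid, terms, genes = line.rstrip("\n").split("\t")
            groups.append(TermGroup(group_id=int(gid),
                                    member_terms=terms.split(";") if terms else [],
                                    associated_genes=genes.split(";") if genes else []))
    return groups


def _write_prioritization(res: PrioritizationResult, out_dir: Path) -> None:
    with (out_dir / "key_proteins.tsv").open("w") as fh:
        fh.write("protein\tpathway_coverage\n")
        for n in res.key_proteins:
            fh.write(f"{n}\t{res.coverage[n]}\n")
    with (out_dir / "prioritization.json").open("w") as fh:
        json.dump({"candidates": res.candidates,
                   "coverage": res.coverage,
                   "median_cutoff": res.median_cutoff,
                   "key_proteins": res.key_proteins}, fh, indent=2)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full analysis; returns a result bundle (also written to
    ``out_dir`` with a machine-readable manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    bundle: dict = {}

    if config.use_paper_fixtures:
        table = table1_fixture()
        groups = table2_fixture()
        result = run_prioritization(table, groups, k_levels=config.k_levels,
                                    cc_threshold=config.cc_threshold)
        _write_prioritization(result, out_dir)
        bundle.update(candidate_table=table, groups=groups,
                      prioritization=result)
        timings["prioritize"] = time.time() - t0
    else:
        if not config.edges:
            raise ValueError("config.edges is required unless "
                             "use_paper_fixtures is set")
        net = read_string_tsv(config.edges, config.score_threshold,
                              seed_nodes=config.seed_nodes)
        timings["read"] = time.time() - t0

        t = time.time()
        metrics = compute_node_metrics(net)
        write_metrics_csv(metrics, out_dir / "metrics.csv")
        summary = summarize(net) if net.n_edges else None
        if summary is not None:
            (out_dir / "summary.json").write_text(
                json.dumps(asdict(summary), indent=2))
        timings["topology"] = time.time() - t

        t = time.time()
        modules = find_modules(net, config.mcode)
        with (out_dir / "modules.tsv").open("w") as fh:
            fh.write("rank\tscore\tdensity\tsize\tmembers\n")
            for rank, mod in enumerate(modules, start=1):
                fh.write(f"{rank}\t{mod.score:.6g}\t{mod.density:.6g}\t"
                         f"{mod.size}\t{';'.join(sorted(mod.members))}\n")
        timings["modules"] = time.time() - t

        groups: list[TermGroup] = []
        if config.gmt:
            t = time.time()
            ann: AnnotationSet = read_gmt(config.gmt)
            query = set(net.nodes) & ann.universe
            records = enrich(query, ann, alpha=config.alpha)
            hits = {r.term_id: set(query) & ann.term_genes(r.term_id)
                    for r in records}
            groups = group_terms(records, hits, ann.universe,
                                 kappa_threshold=config.kappa_threshold)
            write_groups_tsv(groups, out_dir / "groups.tsv")
            timings["enrich"] = time.time() - t

        t = time.time()
        result = run_prioritization(metrics, groups, k_levels=config.k_levels,
                                    cc_threshold=config.cc_threshold)
        _write_prioritization(result, out_dir)
        timings["prioritize"] = time.time() - t
        bundle.update(network=net, metrics=metrics, summary=summary,
                      modules=modules, groups=groups, prioritization=result)

    cfg_json = config.to_json()
    manifest = {
        "netpharm_version": __version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "timings_s": timings,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
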