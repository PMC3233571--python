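"""End-to-end orchestration: read → mask → collapse → network → cores /
subgroups → diversity tables → centre ranking, with machine-readable
reporting.

Every stage writes its outputs into the configured directory and the final
``report.json`` bundles the headline numbers together with a provenance
block (configuration, package/library versions, SHA-256 checksums of the
inputs), so a run is reproducible and auditable. Stage failures are
re-raised as :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .alignment_io import (
    HaplotypeTable,
    collapse_haplotypes,
    crosstab_status,
    mask_columns,
    read_alignment,
    read_annotation,
    restrict_table,
    write_haplotype_table,
    write_haplotypes_fasta,
    write_sharing_summary,
)
from .gradient import (
    rank_centers,
    regional_table,
    sharing_table,
    write_ranking,
    write_table1,
    write_table2,
)
from .mj_network import (
    ConvergenceError,
    build_mj_network,
    write_dot,
    write_edge_list,
    write_gml,
)
from .simulate import SimulationParams, simulate, write_dataset
from .subgroups import (
    CoreSet,
    assign_subgroups,
    core_clusters,
    detect_cores,
    haplogroup_components,
    star_score,
    write_cores,
    write_subgroups,
)

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline"]

logger = logging.getLogger("hapnet")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for a full run. Exactly one of (``alignment`` +
    ``annotation``) or ``simulate`` must be given."""

    outdir: str | Path
    alignment: str | Path | None = None
    annotation: str | Path | None = None
    simulate: SimulationParams | None = None
    drop_ambiguous_columns: bool = True
    epsilon: float = 0.0
    weights: Sequence[float] | None = None
    cores: Sequence[str] | None = None      # explicit core ids; else detect
    min_freq: int = 10
    min_regions: int = 3
    cut: int = 5
    unique_scope: str = "region"
    ranking_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        real = self.alignment is not None and self.annotation is not None
        if real == (self.simulate is not None):
            raise ValueError(
                "exactly one of (alignment + annotation) or a simulate block "
                "must be configured"
            )
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.cut < 1:
            raise ValueError("cut must be a positive integer")
        if self.unique_scope not in ("region", "region-status"):
            raise ValueError("unique_scope must be 'region' or 'region-status'")
        if any(w < 0 for w in self.ranking_weights):
            raise ValueError("ranking weights must be nonnegative")


@dataclass
class ReportBundle:
    paths: dict[str, Path]
    report: dict
    table: HaplotypeTable = field(repr=False, default=None)
    graph: object = field(repr=False, default=None)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(outdir: Path) -> None:
    if not logger.handlers:
        logger.setLevel(logging.INFO)
        console = logging.StreamHandler()
        console.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(console)
    logfile = logging.FileHandler(outdir / "pipeline.log")
    logfile.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(logfile)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the whole analysis and write every output under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    paths: dict[str, Path] = {}

    # --- input stage
    stage = "input"
    try:
        if config.simulate is not None:
            logger.info("simulating dataset (seed=%d)", config.simulate.seed)
            dataset = simulate(config.simulate)
            written = write_dataset(dataset, outdir)
            paths.update(written)
            alignment_path, annotation_path = written["fasta"], written["tsv"]
        else:
            alignment_path = Path(config.alignment)
            annotation_path = Path(config.annotation)
        raw = read_alignment(alignment_path)
        annotations = read_annotation(annotation_path)
        checksums = {
            "alignment": _sha256(alignment_path),
            "annotation": _sha256(annotation_path),
        }
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- collapse stage
    stage = "collapse"
    try:
        matrix = mask_columns(raw, drop_ambiguous_columns=config.drop_ambiguous_columns)
        table = collapse_haplotypes(matrix, annotations)
        sharing = crosstab_status(table)
        logger.info(
            "collapsed %d samples into %d haplotypes over %d retained columns",
            len(matrix.sample_ids), len(table.haplotypes), matrix.columns,
        )
        paths["haplotypes_fasta"] = write_haplotypes_fasta(table, outdir / "haplotypes.fasta")
        paths["haplotype_table"] = write_haplotype_table(table, outdir / "haplotype_table.tsv")
        paths["sharing_summary"] = write_sharing_summary(sharing, outdir / "sharing_summary.tsv")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- network stage
    stage = "network"
    try:
        graph = build_mj_network(table, epsilon=config.epsilon, weights=config.weights)
        logger.info(
            "MJ network: %d observed + %d median nodes, %d edges",
            len(graph.observed_ids), len(graph.median_ids),
            graph.graph.number_of_edges(),
        )
        paths["network_gml"] = write_gml(graph, outdir / "network.gml", table)
        paths["network_dot"] = write_dot(graph, outdir / "network.dot")
        paths["edges"] = write_edge_list(graph, outdir / "edges.tsv")
    except ConvergenceError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- subgroup stage
    stage = "subgroups"
    try:
        if config.cores:
            cores = CoreSet(core_ids=frozenset(config.cores), provenance="user_specified")
        else:
            cores = detect_cores(graph, table, config.min_freq, config.min_regions)
        clusters = core_clusters(graph, cores) if cores.core_ids else []
        paths["cores"] = outdir / "cores.tsv"
        write_cores(cores, clusters, paths["cores"])
        components = haplogroup_components(graph, config.cut)
        subgroup_labels: dict[str, str] = {}
        star_scores: dict[str, float] = {}
        if clusters:
            # subgroup seeds: one per core cluster, labelled by descending
            # total individual count (S1 = the major subgroup)
            sized = sorted(
                clusters,
                key=lambda cl: (-sum(table.total_count(h) for h in cl), min(cl)),
            )
            seed_sets = {
                f"S{i + 1}": CoreSet(core_ids=cl, provenance=cores.provenance)
                for i, cl in enumerate(sized)
            }
            assignment = assign_subgroups(graph, seed_sets)
            subgroup_labels = assignment.assignment
            paths["subgroups"] = outdir / "subgroups.tsv"
            write_subgroups(assignment, graph, paths["subgroups"])
            for label, cs in seed_sets.items():
                star_scores[label] = star_score(
                    graph, cs.core_ids, members=assignment.members(label)
                )
    except (KeyError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- gradient stage
    stage = "gradient"
    try:
        rows = []
        ranking = None
        if clusters:
            # Table-2 view: the primary subgroup against its own core cluster
            primary_cores = seed_sets["S1"].core_ids
            primary_members = {
                h for h, lab in subgroup_labels.items() if lab == "S1"
            }
            sub_table = restrict_table(table, primary_members)
            rows = regional_table(
                sub_table, graph, primary_cores, unique_scope=config.unique_scope
            )
            paths["table2"] = outdir / "table2.tsv"
            write_table2(rows, paths["table2"])
            # centre ranking: all subgroup-assigned haplotypes, classified
            # against the global core set (union of all core clusters)
            all_cores = frozenset().union(*(cs.core_ids for cs in seed_sets.values()))
            assigned = {
                h for h, lab in subgroup_labels.items() if lab != "unassigned"
            }
            global_rows = regional_table(
                restrict_table(table, assigned), graph, all_cores,
                unique_scope=config.unique_scope,
            )
            ranking = rank_centers(global_rows, weights=config.ranking_weights)
            paths["ranking"] = outdir / "ranking.tsv"
            write_ranking(ranking, paths["ranking"])
        t1_rows = sharing_table(table, components)
        paths["table1"] = outdir / "table1.tsv"
        write_table1(t1_rows, paths["table1"])
    except (KeyError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- report
    import networkx, numpy, scipy  # versions for provenance

    report = {
        "n_samples": table.n_samples(),
        "n_haplotypes": len(table.haplotypes),
        "retained_columns": matrix.columns,
        "sharing": dataclasses.asdict(sharing),
        "network": {
            "n_observed": len(graph.observed_ids),
            "n_median": len(graph.median_ids),
            "n_edges": graph.graph.number_of_edges(),
        },
        "cores": sorted(cores.core_ids),
        "core_clusters": [sorted(c) for c in clusters],
        "subgroup_sizes": {
            lab: sum(1 for v in subgroup_labels.values() if v == lab)
            for lab in sorted(set(subgroup_labels.values()))
        },
        "star_scores": star_scores,
        "n_haplogroup_components": len(set(components.values())),
        "ranking": [list(kv) for kv in ranking.ranking] if ranking else [],
        "provenance": {
            "hapnet_version": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "networkx": networkx.__version__,
            "checksums": checksums,
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(config).items()
            },
        },
    }
    paths["report"] = outdir / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    logger.info("pipeline complete; report at %s", paths["report"])
    return ReportBundle(paths=paths, report=report, table=table, graph=graph)
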