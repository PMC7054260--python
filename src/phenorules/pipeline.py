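"""End-to-end orchestration: simulate/ingest -> call -> mine -> select ->
PPAP/pathway -> cluster -> enrich, with a run manifest.

All stage randomness fans out from the single config seed, so two runs of
the same config produce identical artifacts (modulo timings in the
manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .calls import make_grid, sweep_call_matrices
from .community import (
    build_membership_matrix,
    cluster_ppaps,
    cluster_systems,
    linkage_to_newick,
    measure_correlations,
    stage_type_rule_enrichment,
    system_pair_enrichment,
)
from .io import (
    export_graph,
    write_annotation,
    write_call_matrix,
    write_measurements,
    write_rules,
)
from .ppap import (
    TooComplexError,
    all_ppaps,
    build_phenome_pathway,
    build_rule_graph,
    convert_to_pathway,
    degree_deviation_table,
    MAX_PATHS_DEFAULT,
)
from .selection import (
    MAX_Q_DEFAULT,
    MIN_CO_DEFAULT,
    MIN_LIFT_DEFAULT,
    select_significant_rules,
)
from .synthetic import (
    PlantedPair,
    SimulationConfig,
    generate_catalog,
    generate_measurements,
)


@dataclass
class PipelineConfig:
    """Every tunable of a pipeline run, round-trippable through YAML."""

    out_dir: str = "phenorules_out"
    seed: int = 0
    # simulation (used when no measurement input is supplied)
    simulation: dict = field(default_factory=dict)
    # calling
    grid_start: float = 0.8
    grid_stop: float = 3.0
    grid_step: float = 0.1
    exact_test: str = "welch"
    # selection
    min_co: int = MIN_CO_DEFAULT
    min_lift: float = MIN_LIFT_DEFAULT
    max_q: float = MAX_Q_DEFAULT
    # pathways
    max_paths: int = MAX_PATHS_DEFAULT
    # clustering
    k_ppap: int = 7
    k_system: int = 4

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    version: str
    input_checksums: dict[str, str]
    stage_seconds: dict[str, float]
    counts: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage on a synthetic corpus and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    checksums: dict[str, str] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)

        return _Timer()

    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", config.seed)
    if "planted_pairs" in sim_kwargs:
        sim_kwargs["planted_pairs"] = [PlantedPair(*p) for p in sim_kwargs["planted_pairs"]]
    sim = SimulationConfig(**sim_kwargs)

    with stage("simulate"):
        catalog = generate_catalog(sim)
        measurements, truth = generate_measurements(sim, catalog)
        write_annotation(catalog, out / "annotation.tsv")
        write_measurements(measurements, out / "measurements.tsv")
        truth.to_json(out / "truth.json")
    counts["phenotypes_in"] = sim.n_phenotypes
    counts["strains"] = sim.n_strains
    counts["measurements"] = len(measurements)
    checksums["measurements.tsv"] = _checksum(out / "measurements.tsv")
    checksums["annotation.tsv"] = _checksum(out / "annotation.tsv")

    with stage("call"):
        grid = make_grid(config.grid_start, config.grid_stop, config.grid_step)
        sweep = sweep_call_matrices(
            measurements, catalog.parameter_to_phenotype(), grid, exact_test=config.exact_test
        )
        ref = sweep[min(sweep)]
        write_call_matrix(ref, out / "calls_lowest_threshold.tsv")
    counts["thresholds"] = len(sweep)

    with stage("select"):
        atlas = select_significant_rules(
            sweep, min_co=config.min_co, min_lift=config.min_lift, max_q=config.max_q
        )
        write_rules(atlas.rules, out / "atlas.csv")
    counts["rules_selected"] = atlas.n_rules
    counts["phenotypes_in_rules"] = len(atlas.phenotypes)

    graph = build_rule_graph(atlas)
    systems_of = catalog.systems_of()
    with stage("ppap"):
        ppaps = all_ppaps(graph, systems_of)
        if len(graph):
            degree_deviation_table(graph).to_csv(out / "degree_deviation.tsv", sep="\t", index=False)
    counts["ppaps"] = len(ppaps)

    with stage("pathway"):
        pathways = []
        excluded = 0
        for q in sorted(ppaps):
            try:
                pathways.append(convert_to_pathway(ppaps[q], max_paths=config.max_paths))
            except TooComplexError:
                excluded += 1
        phenome = build_phenome_pathway(pathways)
        export_graph(phenome.graph, "graphml", out / "phenome_pathway.graphml")
        export_graph(phenome.graph, "edgelist", out / "phenome_pathway.tsv")
    counts["ppaps_converted"] = len(pathways)
    counts["ppaps_excluded"] = excluded
    counts["pathway_nodes"] = phenome.graph.number_of_nodes()
    counts["pathway_edges"] = phenome.graph.number_of_edges()

    with stage("cluster"):
        if ppaps:
            build_membership_matrix(ppaps, ref).to_csv(
                out / "membership_matrix.tsv", sep="\t", index_label="ppap"
            )
        if len(ppaps) > max(config.k_ppap, 1):
            cl = cluster_ppaps(ppaps, k=config.k_ppap)
            _labels_to_tsv(cl.labels, out / "ppap_clusters.tsv")
            (out / "ppap_tree.nwk").write_text(linkage_to_newick(cl) + "\n")
            counts["ppap_clusters"] = cl.k
        systems_present = {s for p in ppaps.values() for ph in p.nodes for s in systems_of.get(ph, ())}
        if len(systems_present) > config.k_system:
            cs = cluster_systems(ppaps, systems_of, k=config.k_system)
            _labels_to_tsv(cs.labels, out / "system_clusters.tsv")
            counts["system_clusters"] = cs.k

    with stage("enrich"):
        if atlas.n_rules:
            stage_type_rule_enrichment(atlas, catalog.stage_type_of()).to_csv(
                out / "stage_type_enrichment.tsv", sep="\t", index=False
            )
            system_pair_enrichment(atlas, catalog.primary_system_of()).to_csv(
                out / "system_pair_enrichment.tsv", sep="\t", index=False
            )
            if atlas.n_rules >= 3:
                measure_correlations(atlas).to_csv(
                    out / "measure_correlations.tsv", sep="\t", index=False
                )

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        input_checksums=checksums,
        stage_seconds=timings,
        counts=counts,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _labels_to_tsv(labels: dict[str, int], path: Path) -> None:
    import pandas as pd

    pd.DataFrame({"item": list(labels), "cluster": list(labels.values())}).to_csv(
        path, sep="\t", index=False
    )
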