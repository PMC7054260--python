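"""Synthetic phenotyping corpora with planted association structure.

Emulates the statistical shape of a large knockout-mouse phenotyping
screen: a few hundred ontology-annotated phenotypes measured over a few
thousand mutant strains, a low (~4%) marginal abnormality frequency,
heavy not-tested missingness, and a handful of phenotype pairs whose
abnormalities co-occur more often than independence predicts (quantified
by a lift ratio).  Ground truth (latent abnormal statuses and the planted
pairs) is retained so downstream stages can be scored against it.

The generator draws, for every strain and phenotype, a latent abnormal
status; planted pairs are drawn jointly from an exact 2x2 joint law with
P(both abnormal) = lift * rate^2 (a shared-component coupling with a
closed-form joint probability).  Control measurements are N(0, 1); mutant
measurements are N(delta, 1) for latently abnormal strains and N(0, 1)
otherwise.  Not-tested masking is missing-completely-at-random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calls import ABNORMAL, NORMAL, NOT_TESTED, CallMatrix

STAGE_TYPES = ("adult_trait", "adult_gene", "embryo_trait", "embryo_gene")

#: default stage/type composition of the phenotype catalog
DEFAULT_STAGE_TYPE_MIX = {
    "adult_trait": 0.46,
    "adult_gene": 0.25,
    "embryo_trait": 0.17,
    "embryo_gene": 0.12,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedPair:
    """A phenotype pair whose abnormal statuses are positively coupled."""

    phenotype_i: int
    phenotype_j: int
    co_abnormality_lift: float


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic corpus.

    Defaults emulate the screen the pipeline targets: 500 phenotypes x
    3,000 strains, abnormality rate 0.04, abnormal shift delta = 3 sigma
    (so that calls at |ES| = 2 recover latent abnormals with high
    sensitivity), 7 mutant replicates per strain, a shared pool of 100
    controls per parameter, and 30% not-tested cells.
    """

    n_phenotypes: int = 500
    n_strains: int = 3000
    n_controls_per_parameter: int = 100
    n_mutants_per_strain: int = 7
    abnormality_rate: float = 0.04
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    effect_size_abnormal: float = 3.0
    missing_rate: float = 0.3
    stage_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_TYPE_MIX)
    )
    n_biological_systems: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_pairs = [
            p if isinstance(p, PlantedPair) else PlantedPair(*p) for p in self.planted_pairs
        ]
        for name in ("n_phenotypes", "n_strains", "n_controls_per_parameter",
                     "n_mutants_per_strain", "n_biological_systems"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("abnormality_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if set(self.stage_type_mix) - set(STAGE_TYPES):
            raise ConfigurationError(f"stage_type_mix keys must be in {STAGE_TYPES}")
        total = sum(self.stage_type_mix.values())
        if total <= 0:
            raise ConfigurationError("stage_type_mix must have positive mass")
        self.stage_type_mix = {k: v / total for k, v in self.stage_type_mix.items()}
        seen: set[int] = set()
        for p in self.planted_pairs:
            if not (0 <= p.phenotype_i < self.n_phenotypes) or not (
                0 <= p.phenotype_j < self.n_phenotypes
            ):
                raise ConfigurationError("planted pair references unknown phenotype")
            if p.phenotype_i == p.phenotype_j:
                raise ConfigurationError("planted pair must join two distinct phenotypes")
            if p.co_abnormality_lift < 1.0:
                raise ConfigurationError("co_abnormality_lift must be >= 1")
            if p.co_abnormality_lift * self.abnormality_rate > 1.0:
                raise ConfigurationError(
                    "infeasible coupling: lift * abnormality_rate > 1"
                )
            if p.phenotype_i in seen or p.phenotype_j in seen:
                raise ConfigurationError("each phenotype may join at most one planted pair")
            seen.update((p.phenotype_i, p.phenotype_j))


@dataclass
class AnnotationMap:
    """Parameter -> phenotype annotation with stage/type and biological systems.

    ``table`` columns: parameter_id, phenotype_id, stage_type,
    biological_systems (pipe-separated labels).
    """

    table: pd.DataFrame

    @property
    def phenotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["phenotype_id"]))

    def parameter_to_phenotype(self) -> dict[str, str]:
        return dict(zip(self.table["parameter_id"], self.table["phenotype_id"]))

    def stage_type_of(self) -> dict[str, str]:
        return dict(zip(self.table["phenotype_id"], self.table["stage_type"]))

    def systems_of(self) -> dict[str, tuple[str, ...]]:
        return {
            ph: tuple(sys.split("|"))
            for ph, sys in zip(self.table["phenotype_id"], self.table["biological_systems"])
        }

    def primary_system_of(self) -> dict[str, str]:
        return {ph: systems[0] for ph, systems in self.systems_of().items()}


@dataclass
class TruthSet:
    """Ground truth: latent abnormal statuses and the planted pairs."""

    latent_status: pd.DataFrame  # phenotypes x strains, bool
    planted_pairs: list[tuple[str, str, float]]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "phenotypes": list(self.latent_status.index),
            "strains": list(self.latent_status.columns),
            "abnormal": {
                ph: [int(i) for i in np.flatnonzero(row.to_numpy())]
                for ph, row in self.latent_status.iterrows()
            },
            "planted_pairs": [[a, b, lift] for a, b, lift in self.planted_pairs],
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        obj = json.loads(Path(path).read_text())
        mat = np.zeros((len(obj["phenotypes"]), len(obj["strains"])), dtype=bool)
        for r, ph in enumerate(obj["phenotypes"]):
            mat[r, obj["abnormal"][ph]] = True
        return cls(
            latent_status=pd.DataFrame(mat, index=obj["phenotypes"], columns=obj["strains"]),
            planted_pairs=[(a, b, float(l)) for a, b, l in obj["planted_pairs"]],
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # all stage randomness fans out from the single config seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def phenotype_ids(config: SimulationConfig, stages: Sequence[str]) -> list[str]:
    return [f"{stage}:phe{i:04d}" for i, stage in enumerate(stages)]


def generate_catalog(config: SimulationConfig) -> AnnotationMap:
    """Phenotype catalog: ids, stage/type categories, biological systems.

    One measured parameter per phenotype; ids follow the
    ``stage_type:ontology_name`` scheme.  Each phenotype receives 1-2
    biological-system labels.  Deterministic given the config seed.
    """
    rng = _rng(config, 0)
    cats = list(config.stage_type_mix)
    probs = np.array([config.stage_type_mix[c] for c in cats])
    stages = [cats[i] for i in rng.choice(len(cats), size=config.n_phenotypes, p=probs)]
    phenos = phenotype_ids(config, stages)
    n_sys = config.n_biological_systems
    rows = []
    for i, (ph, stage) in enumerate(zip(phenos, stages)):
        k = int(rng.integers(1, 3))  # 1 or 2 systems
        systems = rng.choice(n_sys, size=min(k, n_sys), replace=False)
        rows.append(
            {
                "parameter_id": f"par{i:04d}",
                "phenotype_id": ph,
                "stage_type": stage,
                "biological_systems": "|".join(f"system_{s:02d}" for s in sorted(systems)),
            }
        )
    return AnnotationMap(pd.DataFrame(rows))


def _draw_latent_status(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent abnormal statuses with planted-pair coupling.

    Planted pairs draw the two statuses jointly from the exact 2x2 law
    p11 = min(lift * rate^2, rate), p10 = p01 = rate - p11; marginals stay
    at the configured rate.
    """
    P, S = config.n_phenotypes, config.n_strains
    rate = config.abnormality_rate
    status = rng.random((P, S)) < rate
    for pair in config.planted_pairs:
        p11 = min(pair.co_abnormality_lift * rate * rate, rate)
        p10 = rate - p11
        p00 = 1.0 - 2.0 * rate + p11
        if p00 < 0:
            raise ConfigurationError("infeasible coupling: joint law has negative mass")
        u = rng.random(S)
        both = u < p11
        only_i = (u >= p11) & (u < p11 + p10)
        only_j = (u >= p11 + p10) & (u < p11 + 2 * p10)
        status[pair.phenotype_i] = both | only_i
        status[pair.phenotype_j] = both | only_j
    return status


def generate_measurements(
    config: SimulationConfig, catalog: AnnotationMap
) -> tuple[pd.DataFrame, TruthSet]:
    """Long-format measurement table plus the ground truth behind it.

    Controls: ``n_controls_per_parameter`` values N(0,1) per parameter
    (shared control pool).  Mutants: ``n_mutants_per_strain`` values per
    (parameter, strain), N(delta, 1) if the strain is latently abnormal
    for that phenotype, N(0,1) otherwise.  Cells masked not-tested with
    ``missing_rate`` contribute no mutant rows.
    """
    P, S = config.n_phenotypes, config.n_strains
    if len(catalog.table) != P:
        raise ConfigurationError("catalog size does not match config.n_phenotypes")
    status = _draw_latent_status(config, _rng(config, 1))
    rng_vals = _rng(config, 2)
    rng_mask = _rng(config, 3)

    params = catalog.table["parameter_id"].to_numpy()
    phenos = catalog.table["phenotype_id"].to_numpy()
    strains = np.array([f"g{j:04d}" for j in range(S)])

    nm = config.n_mutants_per_strain
    delta = config.effect_size_abnormal
    values = rng_vals.standard_normal((P, S, nm)) + delta * status[:, :, None]
    tested = rng_mask.random((P, S)) >= config.missing_rate

    p_idx, s_idx = np.nonzero(tested)
    mut = pd.DataFrame(
        {
            "parameter_id": np.repeat(params[p_idx], nm),
            "strain_id": np.repeat(strains[s_idx], nm),
            "cohort": "mutant",
            "value": values[p_idx, s_idx].ravel(),
        }
    )
    nc = config.n_controls_per_parameter
    ctl_values = rng_vals.standard_normal((P, nc))
    ctl = pd.DataFrame(
        {
            "parameter_id": np.repeat(params, nc),
            "strain_id": "control_pool",
            "cohort": "control",
            "value": ctl_values.ravel(),
        }
    )
    table = pd.concat([mut, ctl], ignore_index=True)
    truth = TruthSet(
        latent_status=pd.DataFrame(status, index=phenos, columns=strains),
        planted_pairs=[
            (phenos[p.phenotype_i], phenos[p.phenotype_j], p.co_abnormality_lift)
            for p in config.planted_pairs
        ],
    )
    return table, truth


def generate_call_matrix(config: SimulationConfig) -> tuple[CallMatrix, TruthSet]:
    """Shortcut: emit the three-valued call matrix directly from latent truth.

    Abnormal cells equal the latent statuses; not-tested masking is applied
    on top.  Uses the same random streams as ``generate_measurements`` so
    truth is identical for identical configs.
    """
    catalog = generate_catalog(config)
    status = _draw_latent_status(config, _rng(config, 1))
    tested = _rng(config, 3).random((config.n_phenotypes, config.n_strains)) >= config.missing_rate
    phenos = catalog.table["phenotype_id"].to_numpy()
    strains = np.array([f"g{j:04d}" for j in range(config.n_strains)])
    vals = np.where(~tested, NOT_TESTED, np.where(status, ABNORMAL, NORMAL))
    cm = CallMatrix(pd.DataFrame(vals, index=phenos, columns=strains))
    truth = TruthSet(
        latent_status=pd.DataFrame(status, index=phenos, columns=strains),
        planted_pairs=[
            (phenos[p.phenotype_i], phenos[p.phenotype_j], p.co_abnormality_lift)
            for p in config.planted_pairs
        ],
    )
    return cm, truth
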