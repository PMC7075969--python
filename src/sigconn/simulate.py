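"""Synthetic instance databases with planted, known ground truth.

The generator emulates the statistical shape of a drug-perturbation
reference database: each instance is one treated/control pair of
expression vectors on a log-like scale, reduced to the ranking of the
per-probe amplitude (treated − control).  Per probe ``g`` the baseline is
``b_g ~ N(baseline_mean, baseline_sd²)``; an instance of compound ``k``
observes

    control = b_g + ε,   treated = b_g + effect_{k,g} + ε',
    ε, ε' ~ N(0, σ²) i.i.d.

so the amplitude is ``effect_{k,g}`` plus noise of sd ``σ√2`` (the
baseline cancels by design — exactly what paired profiling achieves).
Planted compounds carry ``effect = +δ`` on a random up set and ``−δ`` on
a disjoint down set, each of size t/2; null compounds carry no effect.
The planted sets are the ground truth against which recovery, ranking and
calibration of the scoring engine are measured.

Reproducibility: one master seed; per-instance generator sub-streams are
derived deterministically from (seed, instance index), so regenerating a
database — in any order — is byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ModeError
from .instance_db import InstanceDatabase, ranks_from_amplitudes, write_rank_matrix
from .signatures import GeneSignature, write_signature

__all__ = [
    "SimulationConfig",
    "PlantedCompound",
    "SimulatedTruth",
    "simulate_database",
    "make_planted_query",
    "simulate_to_dir",
]

MODES = ("concordant", "oppositional", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic database.

    Defaults are the benchmark conditions used throughout the test suite:
    a 1000-probe universe, 50 compounds × 4 instances, 100-probe planted
    signatures (50 up + 50 down), effect size δ = 2 and noise σ = 1 on the
    log2-like expression scale, with one oppositional planted compound.
    """

    n_probes: int = 1000
    n_compounds: int = 50
    instances_per_compound: int = 4
    tag_set_size: int = 100
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    planted: tuple[tuple[int, str], ...] = ((0, "oppositional"),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tag_set_size % 2 != 0:
            raise ConfigError("tag_set_size must be even (t/2 up + t/2 down)")
        if self.n_probes < 2 * self.tag_set_size:
            raise ConfigError("need n_probes >= 2 * tag_set_size")
        if self.n_compounds < 1 or self.instances_per_compound < 1:
            raise ConfigError("need n_compounds >= 1 and instances_per_compound >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        for idx, mode in self.planted:
            if not (0 <= idx < self.n_compounds):
                raise ConfigError(f"planted compound index {idx} out of range")
            if mode not in MODES:
                raise ConfigError(f"unknown planted mode {mode!r}")
        indices = [idx for idx, _ in self.planted]
        if len(set(indices)) != len(indices):
            raise ConfigError("duplicate planted compound indices")


@dataclass(frozen=True)
class PlantedCompound:
    """Ground truth for one planted compound."""

    index: int
    mode: str
    up_probes: tuple[str, ...]
    down_probes: tuple[str, ...]

    @property
    def compound(self) -> str:
        return f"cpd_{self.index:03d}"


@dataclass
class SimulatedTruth:
    """Planted structure of a simulated database, keyed by compound index."""

    planted: dict[int, PlantedCompound] = field(default_factory=dict)
    seed: int = 0


def _probe_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"p{i:0{width}d}" for i in range(n)]


def simulate_database(config: SimulationConfig) -> tuple[InstanceDatabase, SimulatedTruth]:
    """Generate a rank database plus its planted ground truth."""
    G = config.n_probes
    probes = _probe_ids(G)
    probe_arr = np.array(probes)
    half = config.tag_set_size // 2

    truth = SimulatedTruth(seed=config.seed)
    effects: dict[int, np.ndarray] = {}
    for idx, mode in config.planted:
        rng_sets = np.random.default_rng([config.seed, 5, idx])
        chosen = rng_sets.choice(G, size=config.tag_set_size, replace=False)
        up_idx, down_idx = chosen[:half], chosen[half:]
        effect = np.zeros(G)
        if mode != "null":
            effect[up_idx] = config.effect_size
            effect[down_idx] = -config.effect_size
        effects[idx] = effect
        truth.planted[idx] = PlantedCompound(
            index=idx,
            mode=mode,
            up_probes=tuple(str(p) for p in probe_arr[np.sort(up_idx)]),
            down_probes=tuple(str(p) for p in probe_arr[np.sort(down_idx)]),
        )

    # Baseline cancels in treated - control but is generated anyway so the
    # expression matrices themselves are realistic if ever exposed.
    rng_base = np.random.default_rng([config.seed, 11])
    baseline = rng_base.normal(config.baseline_mean, config.baseline_sd, G)

    N = config.n_compounds * config.instances_per_compound
    matrix = np.empty((G, N), dtype=np.int64)
    ids, compounds = [], []
    col = 0
    for k in range(config.n_compounds):
        effect = effects.get(k, np.zeros(G))
        for i in range(config.instances_per_compound):
            rng = np.random.default_rng([config.seed, 1, col])
            control = baseline + rng.normal(0.0, config.noise_sd, G)
            treated = baseline + effect + rng.normal(0.0, config.noise_sd, G)
            matrix[:, col] = ranks_from_amplitudes(treated - control, probe_arr)
            ids.append(f"cpd_{k:03d}_i{i:02d}")
            compounds.append(f"cpd_{k:03d}")
            col += 1
    meta = pd.DataFrame(
        {"compound": compounds, "cell_line": ["SIM"] * N},
        index=pd.Index(ids, name="instance_id"),
    )
    db = InstanceDatabase(probe_ids=pd.Index(probes), matrix=matrix, meta=meta)
    return db, truth


def make_planted_query(truth: SimulatedTruth, compound_index: int) -> GeneSignature:
    """Build the query signature that targets a planted compound.

    ``concordant`` copies the compound's shifted sets directly (the
    compound should score positively, self-retrieval); ``oppositional``
    swaps them — query-up = compound's down-shifted set — so the compound
    scores negatively, the disease-vs-therapeutic configuration.
    """
    if compound_index not in truth.planted:
        raise ModeError(f"compound index {compound_index} was not planted")
    planted = truth.planted[compound_index]
    if planted.mode == "null":
        raise ModeError(f"compound {planted.compound} is a null plant; no query defined")
    if planted.mode == "concordant":
        up, down = planted.up_probes, planted.down_probes
    else:
        up, down = planted.down_probes, planted.up_probes
    return GeneSignature(
        up_tags=up,
        down_tags=down,
        namespace="probe",
        provenance={"builder": "planted", "mode": planted.mode, "compound": planted.compound},
    )


def simulate_to_dir(config: SimulationConfig, out_dir: str | os.PathLike) -> dict[str, str]:
    """Simulate and write rank_matrix.tsv, meta.tsv, truth.yaml and one
    GRP signature pair per planted non-null compound.  Returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    db, truth = simulate_database(config)
    paths = {
        "rank_matrix": os.path.join(out_dir, "rank_matrix.tsv"),
        "meta": os.path.join(out_dir, "meta.tsv"),
        "truth": os.path.join(out_dir, "truth.yaml"),
    }
    write_rank_matrix(db, paths["rank_matrix"], paths["meta"])
    truth_doc = {
        "seed": truth.seed,
        "config": asdict(config),
        "planted": {
            p.compound: {
                "mode": p.mode,
                "up_probes": list(p.up_probes),
                "down_probes": list(p.down_probes),
            }
            for p in truth.planted.values()
        },
    }
    # tuples -> lists for clean YAML
    truth_doc["config"]["planted"] = [list(x) for x in config.planted]
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)
    for idx, p in truth.planted.items():
        if p.mode == "null":
            continue
        query = make_planted_query(truth, idx)
        prefix = os.path.join(out_dir, f"query_{p.compound}")
        up_path, down_path = write_signature(query, prefix)
        paths[f"query_{p.compound}_up"] = up_path
        paths[f"query_{p.compound}_down"] = down_path
    return paths
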