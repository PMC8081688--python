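"""CSV readers/writers for the package's tabular artifacts and a small
deterministic pipeline driver.

All on-disk formats are plain CSV: marker matrices (rows = lines, columns =
markers, empty cell = missing, discrete calls in {-1, 0, 1}), 3-column
pedigrees, genetic maps and long-format phenotype records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinship import Pedigree, RelationshipMatrix
from .markers import GeneticMap, MarkerMatrix

__all__ = [
    "read_marker_csv",
    "write_marker_csv",
    "read_pedigree_csv",
    "read_map_csv",
    "write_map_csv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "write_relationship_csv",
    "read_relationship_csv",
    "RunConfig",
    "run_pipeline",
]


def write_marker_csv(matrix: MarkerMatrix, path) -> None:
    df = matrix.calls.copy()
    if matrix.mode == "discrete":
        df = df.astype("Int64")  # renders -1/0/1 without decimals, NaN empty
    df.to_csv(path, index_label="line_id")


def read_marker_csv(path, mode: str = "discrete") -> MarkerMatrix:
    df = pd.read_csv(path, index_col="line_id")
    values = df.to_numpy()
    numeric = pd.DataFrame(
        np.asarray(values, dtype=float), index=df.index, columns=df.columns
    )
    if mode == "discrete":
        v = numeric.to_numpy()
        bad = ~(np.isnan(v) | np.isin(v, (-1.0, 0.0, 1.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {df.iloc[i, j]!r} at line {df.index[i]!r}, "
                f"marker {df.columns[j]!r}"
            )
    return MarkerMatrix(numeric, mode=mode)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "id"})
    if "parent1" not in df.columns or "parent2" not in df.columns:
        df = df.rename(
            columns={df.columns[1]: "parent1", df.columns[2]: "parent2"}
        )
    ped = Pedigree(df[["id", "parent1", "parent2"]])
    ped.topological_ids()  # rejects cycles early, naming them
    return ped


def write_map_csv(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, index=False)


def read_map_csv(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path))


def write_phenotypes_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    key_cols = [c for c in ("line_id", "trial_id", "replicate", "trait") if c in df.columns]
    if key_cols and df.duplicated(subset=key_cols).any():
        dup = df[df.duplicated(subset=key_cols)].iloc[0]
        raise ValueError(f"duplicate phenotype key: {dict(dup[key_cols])}")
    return df


def write_relationship_csv(matrix: RelationshipMatrix, path) -> None:
    matrix.values.to_csv(path, index_label="id")


def read_relationship_csv(path, kind: str = "G") -> RelationshipMatrix:
    return RelationshipMatrix(pd.read_csv(path, index_col="id"), kind=kind)


@dataclass
class RunConfig:
    """Configuration of a small end-to-end simulation-and-validation run."""

    out_dir: str
    seed: int = 0
    n_families: int = 10
    progeny_per_family: int = 20
    n_pool: int = 120
    n_chromosomes: int = 5
    markers_per_chromosome: int = 60
    n_qtl: int = 40
    n_snp: int = 200
    n_training: int = 60
    lines_per_family: int = 4
    n_reps: int = 2
    h2_train: float = 0.5
    h2_validation: float = 0.3
    models: tuple = ("pblup", "gblup", "mblup", "fblup_gbs", "pheno")
    with_preexisting_info: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        if isinstance(cfg.models, list):
            cfg.models = tuple(cfg.models)
        return cfg


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Simulate a program, run a scheme-B validation with the configured
    models, and write tidy metrics plus a manifest to ``config.out_dir``.

    Deterministic: identical configs produce byte-identical outputs.
    """
    from .validation import (
        prediction_ability,
        run_models,
        simulate_breeding_program,
        simulation_scheme_B,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    program = simulate_breeding_program(
        n_families=config.n_families,
        progeny_per_family=config.progeny_per_family,
        n_pool=config.n_pool,
        n_chromosomes=config.n_chromosomes,
        markers_per_chromosome=config.markers_per_chromosome,
        n_qtl=config.n_qtl,
        n_snp=config.n_snp,
        seed=config.seed,
    )
    plans = simulation_scheme_B(
        program,
        lines_per_family=config.lines_per_family,
        h2_train=config.h2_train,
        h2_validation=config.h2_validation,
        n_training=config.n_training,
        n_reps=config.n_reps,
        seed=config.seed + 1000,
    )
    rows = []
    for plan in plans:
        result = run_models(
            plan, program, model_set=config.models,
            with_preexisting_info=config.with_preexisting_info,
        )
        for model, pred in result["gebv"].items():
            rows.append(
                (
                    plan.replicate,
                    model,
                    "accuracy",
                    prediction_ability(pred, result["tbv"]),
                )
            )
    metrics = pd.DataFrame(rows, columns=["replicate", "model", "metric", "value"])
    metrics.to_csv(out / "metrics.csv", index=False)
    write_marker_csv(program.markers, out / "markers.csv")
    manifest = {"config": {k: list(v) if isinstance(v, tuple) else v
                           for k, v in config.__dict__.items()}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return metrics
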