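"""Reading/writing point sets and model configurations; fixture generation.

Point sets are CSV/TSV with a header row of feature names; empty cells or
``NA`` mark missing entries.  Matrix orientation is rows = points/samples,
columns = features/genes everywhere; gene-by-sample expression files can be
transposed on read.  Model specifications round-trip through YAML with an
explicit variant tag and per-cluster blocks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .models import ClusterModel, ModelSpec
from .pointset import PointSet

__all__ = [
    "read_pointset",
    "write_pointset",
    "model_from_dict",
    "model_to_dict",
    "read_model",
    "write_model",
    "make_fixture",
]

_NA = ("", "NA", "NaN", "nan", "N/A", "null")


def read_pointset(path, transpose: bool = False) -> PointSet:
    """Read a CSV/TSV point table; NA/empty cells become missing entries."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, na_values=list(_NA), keep_default_na=False,
                     index_col=None)
    # non-numeric cells must fail loudly
    values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    if transpose:
        values = values.T
    return PointSet(values)


def write_pointset(S: PointSet, path, feature_names=None) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    names = feature_names or [f"f{j+1}" for j in range(S.d)]
    df = pd.DataFrame(S.values, columns=names)
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def model_to_dict(model: ModelSpec) -> dict:
    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    return {
        "variant": model.variant,
        "mc_draws": model.mc_draws,
        "clusters": [
            {
                k: (arr(getattr(c, k)) if k in ("mu", "Sigma", "m", "Psi")
                    else getattr(c, k))
                for k in ("mu", "Sigma", "m", "nu", "kappa", "Psi")
                if getattr(c, k) is not None
            }
            for c in model.clusters
        ],
    }


def model_from_dict(cfg: dict) -> ModelSpec:
    clusters = [ClusterModel(**block) for block in cfg["clusters"]]
    return ModelSpec(
        variant=cfg["variant"],
        clusters=clusters,
        mc_draws=int(cfg.get("mc_draws", 500)),
    )


def read_model(path) -> ModelSpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
    return model_from_dict(cfg)


def write_model(model: ModelSpec, path) -> None:
    cfg = model_to_dict(model)
    with open(path, "w") as fh:
        if str(path).endswith((".yaml", ".yml")):
            yaml.safe_dump(cfg, fh, sort_keys=False)
        else:
            json.dump(cfg, fh, indent=2)


def _rnaseq_like(seed: int, n_per_group: int = 20, n_genes: int = 120):
    """Synthetic stand-in for a two-condition expression matrix.

    Overdispersed log2-scale expression (as after a variance stabilizing
    transformation): per-gene baselines and dispersions vary widely, and a
    subset of genes carries a group effect, so variance-to-mean feature
    ranking and calibration are meaningful end to end.  Purely synthetic —
    no real cohort is involved.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    base = rng.uniform(3.0, 10.0, size=n_genes)
    scale = rng.gamma(shape=2.0, scale=0.25, size=n_genes) + 0.05
    n_signal = max(4, n_genes // 10)
    effect = np.zeros(n_genes)
    signal_idx = rng.choice(n_genes, size=n_signal, replace=False)
    effect[signal_idx] = rng.normal(0.0, 1.5, size=n_signal)
    groups = np.repeat([0, 1], n_per_group)
    X = (
        base
        + np.outer(groups, effect)
        + rng.standard_normal((2 * n_per_group, n_genes)) * scale
    )
    return X, groups + 1


def make_fixture(kind: str, seed: int, out_dir) -> dict:
    """Write a deterministic fixture tree for tests/docs; returns paths.

    ``simulated``: one masked draw from the known-variant two-cluster
    generator (points + truth labels + model config).  ``rnaseq_like``: a
    synthetic two-group expression matrix for the calibrate-then-cluster
    pipeline.
    """
    from .simulate import SimScenario, apply_mcar, draw_instance, table1_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if kind == "simulated":
        scen = SimScenario(
            model=table1_model("known"), n1=10, n2=10, missing_prob=0.2,
            base_seed=int(seed),
        )
        complete, truth, _ = draw_instance(scen, 0)
        S = apply_mcar(complete, scen.missing_prob,
                       np.random.SeedSequence([int(seed), 0, 1]))
        paths["points"] = out / "points.tsv"
        write_pointset(S, paths["points"])
        paths["truth"] = out / "truth.txt"
        Path(paths["truth"]).write_text(
            ",".join(map(str, truth.labels)) + "\n"
        )
        paths["model"] = out / "model.yaml"
        write_model(scen.model, paths["model"])
    elif kind == "rnaseq_like":
        X, groups = _rnaseq_like(seed)
        paths["expression"] = out / "expression.tsv"
        df = pd.DataFrame(X, columns=[f"g{j+1}" for j in range(X.shape[1])])
        df.to_csv(paths["expression"], sep="\t", index=False)
        paths["groups"] = out / "groups.txt"
        Path(paths["groups"]).write_text(",".join(map(str, groups)) + "\n")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    paths["provenance"] = out / "provenance.json"
    Path(paths["provenance"]).write_text(
        json.dumps({"kind": kind, "seed": int(seed)}, indent=2) + "\n"
    )
    return {k: str(v) for k, v in paths.items()}
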