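"""File formats, configuration, seed derivation, and the pipeline runner.

Single long-format trajectory CSV: columns ``cell_id, condition, dose,
replicate, time_min, p38_activity, nfkb_activity, units``; baseline frames
carry negative ``time_min``.  Feature tables and parameter tables are plain
CSV; configuration is YAML; analysis reports are JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trajectories import ActivityTrajectory

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ("cell_id", "condition", "dose", "replicate",
                      "time_min", "p38_activity", "nfkb_activity", "units")


def write_trajectories(trajs: list[ActivityTrajectory], path) -> None:
    frames = []
    for t in trajs:
        frames.append(pd.DataFrame({
            "cell_id": t.cell_id, "condition": t.stimulus, "dose": t.dose,
            "replicate": t.replicate, "time_min": t.time_min,
            "p38_activity": t.p38, "nfkb_activity": t.nfkb, "units": t.units,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[ActivityTrajectory]:
    """Read the long-format trajectory CSV back into trajectory objects.

    Missing required columns and non-uniform time grids are rejected;
    malformed rows are reported with their (1-based, header-inclusive) line
    numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    bad = df.index[df[["time_min"]].isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"malformed rows at line(s) {lines}")
    out = []
    for (cell, cond, dose, rep), g in df.groupby(
            ["cell_id", "condition", "dose", "replicate"], sort=False):
        g = g.sort_values("time_min")
        t = g["time_min"].to_numpy(dtype=float)
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise ValueError(f"cell {cell}: non-uniform time grid")
        units = g["units"].iloc[0]
        out.append(ActivityTrajectory(
            cell_id=str(cell), stimulus=str(cond), dose=float(dose),
            replicate=int(rep), time_min=t,
            p38=g["p38_activity"].to_numpy(dtype=float),
            nfkb=g["nfkb_activity"].to_numpy(dtype=float), units=str(units)))
    return out


def read_counts(path) -> tuple[np.ndarray, list, list]:
    """Gene x cell count matrix from CSV (genes as rows, first column names)
    or MatrixMarket ``.mtx`` (with optional ``<stem>_genes.txt`` /
    ``<stem>_cells.txt`` sidecar name files)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    if path.suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense")
                         else mmread(path), dtype=float)
        genes = _sidecar_names(path, "genes", mat.shape[0])
        cells = _sidecar_names(path, "cells", mat.shape[1])
    else:
        df = pd.read_csv(path, index_col=0)
        mat = df.to_numpy(dtype=float)
        genes, cells = list(df.index), list(df.columns)
    if (mat < 0).any():
        raise ValueError("negative counts encountered")
    return mat, genes, cells


def _sidecar_names(path: Path, kind: str, n: int) -> list:
    sidecar = path.with_name(path.stem + f"_{kind}.txt")
    if sidecar.exists():
        names = sidecar.read_text().split()
        if len(names) != n:
            raise ValueError(f"{sidecar}: expected {n} names, got {len(names)}")
        return names
    return [f"{kind[:-1]}_{i}" for i in range(n)]


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# configuration and pipeline
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the single global seed (documented,
    reproducible derivation: SHA-256 of ``"<global_seed>:<stage>"``,
    truncated below 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2 ** 31)


STAGE_ORDER = ("simulate", "features", "mi", "classify", "dose",
               "correlate", "express", "expr-stats")


def run_pipeline(config: dict, workdir=".") -> dict:
    """Execute the configured stages in declared order.

    Each stage's artifact record carries the config hash and derived seed.
    A stage failure aborts with the failing stage named.
    """
    from . import cli  # stage implementations live next to the CLI glue

    workdir = Path(workdir)
    seed = int(config.get("seed", 0))
    chash = config_hash(config)
    artifacts: dict = {"config_hash": chash, "seed": seed, "stages": {}}
    stages = config.get("stages", [])
    unknown = [s["stage"] for s in stages if s["stage"] not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stage name(s): {unknown}")
    for entry in stages:
        name = entry["stage"]
        stage_seed = derive_seed(seed, name)
        logger.info("running stage %s (seed %d)", name, stage_seed)
        try:
            result = cli.run_stage(name, dict(entry), stage_seed, workdir)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        artifacts["stages"][name] = {"seed": stage_seed, "config_hash": chash,
                                     **(result or {})}
    return artifacts
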