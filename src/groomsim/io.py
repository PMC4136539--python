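"""Readers, writers, config handling and run manifests.

File conventions: CSV is comma-separated UTF-8 with a mandatory header row;
ethograms use ``iteration,label`` with contiguous 1-based iterations; dust
images, masks and maps are PNG/TIFF rasters (maps are additionally written
as lossless CSV of fractions, since the 8-bit raster quantizes); configs
are YAML or JSON mirroring :class:`~groomsim.model.ModelConfig` field
names.  Every CLI run writes a JSON manifest sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dustmaps import DustImage, DustMap, RegionMask
from .ethogram import Ethogram, TransitionMatrix, marginal_probability
from .model import ModelConfig, SimulationResult

__all__ = [
    "read_ethogram_csv",
    "write_ethogram_csv",
    "write_trajectories",
    "load_config",
    "dump_config",
    "write_transition_matrix",
    "write_transition_graph",
    "read_dust_image",
    "read_region_mask",
    "write_binary_image",
    "write_dust_map",
    "RunManifest",
    "write_manifest",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# ethograms

def read_ethogram_csv(path: PathLike) -> Ethogram:
    """Read an ``iteration,label`` CSV into an :class:`Ethogram`.

    Iterations must be the contiguous run 1..n with no gaps or duplicates;
    an optional ``subject_id`` column (constant) is honored.
    """
    table = pd.read_csv(path)
    required = {"iteration", "label"}
    if not required <= set(table.columns):
        raise ValueError(f"ethogram CSV must have columns {sorted(required)}, got {list(table.columns)}")
    if len(table) == 0:
        raise ValueError("empty ethogram file")
    iters = table["iteration"].to_numpy()
    expected = np.arange(1, len(table) + 1)
    if not np.array_equal(iters, expected):
        raise ValueError("iterations must be contiguous and 1-based with no duplicates")
    subject = None
    if "subject_id" in table.columns:
        uniq = table["subject_id"].unique()
        if len(uniq) != 1:
            raise ValueError("a single-ethogram file must carry one subject_id")
        subject = str(uniq[0])
    return Ethogram(tuple(table["label"].astype(str)), subject_id=subject)


def write_ethogram_csv(ethogram: Ethogram, path: PathLike) -> Path:
    path = Path(path)
    table = pd.DataFrame(
        {"iteration": np.arange(1, len(ethogram) + 1), "label": list(ethogram.labels)}
    )
    if ethogram.subject_id is not None:
        table["subject_id"] = ethogram.subject_id
    table.to_csv(path, index=False)
    return path


def write_trajectories(result: SimulationResult, out_dir: PathLike) -> List[Path]:
    """Write a simulation's ethogram plus dust/activation/leg CSV matrices."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [write_ethogram_csv(result.ethogram, out_dir / "ethogram.csv")]
    for name, table in (
        ("dust.csv", result.dust_trajectory),
        ("activation.csv", result.activation_trajectory),
    ):
        table.to_csv(out_dir / name)
        paths.append(out_dir / name)
    if result.leg_trajectory is not None:
        result.leg_trajectory.to_csv(out_dir / "legs.csv")
        paths.append(out_dir / "legs.csv")
    return paths


# ---------------------------------------------------------------------------
# configs

def _config_to_dict(config: ModelConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["clamped_modules"] = sorted(config.clamped_modules)
    for key in ("sensory_weights", "initial_dust", "module_labels"):
        if raw[key] is not None:
            raw[key] = list(raw[key])
    return raw


def load_config(path: PathLike) -> ModelConfig:
    """Load a YAML or JSON simulator config mirroring ModelConfig fields."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "clamped_modules" in data and data["clamped_modules"] is not None:
        data["clamped_modules"] = frozenset(int(k) for k in data["clamped_modules"])
    return ModelConfig(**data)


def dump_config(config: ModelConfig, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(_config_to_dict(config), fh, indent=2)
        else:
            yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# transition matrices and graphs

def write_transition_matrix(tm: TransitionMatrix, out_dir: PathLike, prefix: str = "transition") -> List[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts_path = out_dir / f"{prefix}_counts.csv"
    probs_path = out_dir / f"{prefix}_probabilities.csv"
    tm.counts.rename_axis("from").to_csv(counts_path)
    tm.probabilities.rename_axis("from").to_csv(probs_path)
    return [counts_path, probs_path]


def write_transition_graph(
    tm: TransitionMatrix,
    path: PathLike,
    min_display: Optional[float] = None,
    node_weights: Optional[pd.Series] = None,
    nodes_path: Optional[PathLike] = None,
) -> Path:
    """Export a transition graph as an edge-list CSV (``from,to,probability``).

    Only edges with probability >= ``min_display`` (falling back to the
    matrix's own display threshold, else 0) are written; the matrix itself
    is never altered.  Node weights — marginal bout fractions — go to a
    companion ``label,weight`` CSV when given.
    """
    if min_display is None:
        min_display = tm.min_display if tm.min_display is not None else 0.0
    rows = []
    for a in tm.labels:
        for b in tm.labels:
            p = float(tm.probabilities.loc[a, b])
            if p > 0 and p >= min_display:
                rows.append({"from": a, "to": b, "probability": p})
    path = Path(path)
    pd.DataFrame(rows, columns=["from", "to", "probability"]).to_csv(path, index=False)
    if node_weights is not None:
        nodes_path = Path(nodes_path) if nodes_path else path.with_name(path.stem + "_nodes.csv")
        node_weights.rename("weight").rename_axis("label").to_csv(nodes_path)
    return path


# ---------------------------------------------------------------------------
# rasters

def read_dust_image(path: PathLike, body_part: str = "", subject_id: str = "", time_min: float = 0.0) -> DustImage:
    """Read a PNG/TIFF raster as a binary dust image (any nonzero = dust)."""
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:  # collapse color/alpha: any nonzero channel counts as dust
        raw = raw.max(axis=2)
    return DustImage((raw > 0).astype(np.uint8), body_part=body_part,
                     subject_id=subject_id or Path(path).stem, time_min=time_min)


def read_region_mask(path: PathLike, region_name: str = "") -> RegionMask:
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw.max(axis=2)
    return RegionMask((raw > 0).astype(np.uint8), region_name=region_name or Path(path).stem)


def write_binary_image(image: Union[DustImage, RegionMask], path: PathLike) -> Path:
    """Write a binary raster as an 8-bit 0/255 PNG or TIFF."""
    path = Path(path)
    iio.imwrite(path, (image.pixels * 255).astype(np.uint8))
    return path


def write_dust_map(dust_map: DustMap, path: PathLike) -> List[Path]:
    """Write a groomogram as an 8-bit raster plus a lossless CSV of fractions."""
    path = Path(path)
    iio.imwrite(path, np.round(dust_map.fractions * 255).astype(np.uint8))
    csv_path = path.with_suffix(".csv")
    pd.DataFrame(dust_map.fractions).to_csv(csv_path, index=False, header=False)
    return [path, csv_path]


# ---------------------------------------------------------------------------
# run manifests

@dataclass
class RunManifest:
    """Record of one CLI run: enough to reproduce it bit-for-bit."""

    subcommand: str
    config_echo: Dict
    seed: Optional[int]
    output_paths: List[str] = field(default_factory=list)
    package_version: str = __version__


def write_manifest(manifest: RunManifest, out_dir: PathLike) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)
    return path
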