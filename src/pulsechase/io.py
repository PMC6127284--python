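"""Readers and writers for the package's plain-text interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .synth import SimulationConfig
from .wave import DendriteTrace


def read_trace(path: str | Path) -> DendriteTrace:
    """Read a dendrite trace/ROI from JSON.

    Expected keys: ``points`` (list of [x, y] in μm), ``width_um`` (scalar
    or per-vertex list), ``roi_centre_um``, ``roi_halfwidth_um``.
    """
    d = json.loads(Path(path).read_text())
    return DendriteTrace(points=np.asarray(d["points"], dtype=float),
                         width=d["width_um"],
                         roi_centre=float(d["roi_centre_um"]),
                         roi_halfwidth=float(d["roi_halfwidth_um"]))


def write_trace(trace: DendriteTrace, path: str | Path) -> None:
    width = np.asarray(trace.width)
    Path(path).write_text(json.dumps({
        "points": trace.points.tolist(),
        "width_um": width.tolist() if width.ndim else float(width),
        "roi_centre_um": trace.roi_centre,
        "roi_halfwidth_um": trace.roi_halfwidth,
    }))


def read_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return SimulationConfig(**data)


def write_config(cfg: SimulationConfig, path: str | Path) -> None:
    data = {k: v for k, v in cfg.__dict__.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line (TSV-compatible: first column used)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.split("\t")[0])
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "") -> None:
    lines = ["\t".join([name, description, *genes])
             for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a 3D TIFF plus its voxel-size sidecar JSON (z, y, x μm)."""
    vol = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(Path(path).with_suffix(".tif.json").read_text())
    return vol, tuple(meta["voxel_size_um"])


def write_volume(volume: np.ndarray, voxel_size, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32),
                     photometric="minisblack")
    path.with_suffix(".tif.json").write_text(
        json.dumps({"voxel_size_um": list(voxel_size)}))
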