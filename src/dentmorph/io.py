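"""Plain-text and TIFF interchange for outlines, landmark tables and label volumes."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .outlines import LandmarkConfiguration, Outline2D
from .synthetic import LabeledVolume, SyntheticPopulation

__all__ = [
    "write_population_csv",
    "read_population_csv",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_labeled_volume",
    "read_labeled_volume",
    "read_cervical_csv",
]


def write_population_csv(population: SyntheticPopulation, path) -> None:
    """One row per outline vertex: specimen_id, label, vertex_index, x_mm, y_mm."""
    rows = []
    for i, (outline, label) in enumerate(zip(population.outlines, population.labels)):
        for j, (x, y) in enumerate(outline.vertices):
            rows.append({"specimen_id": f"s{i:04d}", "label": label,
                         "vertex_index": j, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_population_csv(path) -> tuple[list[Outline2D], list[str], list[str]]:
    """Returns (outlines, labels, specimen_ids) from a population CSV."""
    df = pd.read_csv(path)
    outlines, labels, ids = [], [], []
    for sid, grp in df.groupby("specimen_id", sort=True):
        grp = grp.sort_values("vertex_index")
        outlines.append(Outline2D(grp[["x_mm", "y_mm"]].to_numpy(dtype=float)))
        labels.append(str(grp["label"].iloc[0]))
        ids.append(str(sid))
    return outlines, labels, ids


def write_landmarks_csv(configs: dict[str, LandmarkConfiguration], path,
                        outline_kind: str = "crown",
                        labels: dict[str, str] | None = None) -> None:
    rows = []
    for sid, cfg in configs.items():
        for i, (x, y) in enumerate(cfg.points):
            rows.append({"specimen_id": sid, "outline_kind": outline_kind,
                         "label": (labels or {}).get(sid, ""),
                         "landmark_index": i, "x": x, "y": y,
                         "centroid_size": cfg.centroid_size,
                         "normalized": cfg.normalized})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path) -> tuple[dict[str, LandmarkConfiguration], dict[str, str]]:
    df = pd.read_csv(path)
    configs: dict[str, LandmarkConfiguration] = {}
    labels: dict[str, str] = {}
    for sid, grp in df.groupby("specimen_id", sort=True):
        grp = grp.sort_values("landmark_index")
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        normalized = bool(grp["normalized"].iloc[0])
        cs = float(grp["centroid_size"].iloc[0])
        configs[str(sid)] = LandmarkConfiguration(points=pts, centroid_size=cs,
                                                  normalized=normalized)
        if "label" in grp and not grp["label"].isna().all():
            labels[str(sid)] = str(grp["label"].iloc[0])
    return configs, labels


def write_labeled_volume(volume: LabeledVolume, path) -> None:
    """Multi-page TIFF (one page per z slice) plus a sidecar .txt header."""
    path = Path(path)
    # pages indexed by z; each page is (x, y)
    tifffile.imwrite(path, np.moveaxis(volume.labels, 2, 0))
    sidecar = path.with_suffix(path.suffix + ".txt")
    sidecar.write_text(
        "# labeled volume header\n"
        f"voxel_size_mm: {float(volume.voxel_size)!r}\n"
        f"origin_mm: {float(volume.origin[0])!r} {float(volume.origin[1])!r} "
        f"{float(volume.origin[2])!r}\n"
        "labels: 0=background 1=enamel 2=dentine+pulp\n")


def read_labeled_volume(path) -> LabeledVolume:
    path = Path(path)
    data = np.moveaxis(tifffile.imread(path), 0, 2)
    sidecar = path.with_suffix(path.suffix + ".txt")
    voxel_size = 1.0
    origin = np.zeros(3)
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if line.startswith("voxel_size_mm:"):
                voxel_size = float(line.split(":")[1])
            elif line.startswith("origin_mm:"):
                origin = np.array([float(v) for v in line.split(":")[1].split()])
    return LabeledVolume(labels=data, voxel_size=voxel_size, origin=origin)


def read_cervical_csv(path) -> np.ndarray:
    """Cervical line CSV (point_index, x_mm, y_mm, z_mm) -> (n, 3) array."""
    df = pd.read_csv(path).sort_values("point_index")
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
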