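"""Gridded GPC prediction and class-map production.

A fitted model (PLS or baseline) is applied cell-wise to congruent
vegetation-index grids under a wheat mask; predictions are then binned
into GPC classes for map rendering. Default bin edges (11.3, 11.8,
12.5 % GPC) partition the range into four classes with half-open
[low, high) intervals.

Maps are written as plain-text matrices (one layer per file) or
single-page TIFF, with a JSON legend recording bin edges, class labels
and per-class cell counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GridError

DEFAULT_BIN_EDGES = (11.3, 11.8, 12.5)

_NODATA = -9999.0
_CLASS_NODATA = 255


def class_labels(bin_edges) -> list[str]:
    """Human-readable class labels for a set of increasing bin edges."""
    edges = list(bin_edges)
    labels = [f"<{edges[0]}"]
    labels += [f"{lo}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">{edges[-1]}")
    return labels


@dataclass
class GPCGrid:
    """Predicted GPC raster with validity mask and class layer."""

    predicted: np.ndarray  # float, NaN on invalid cells
    mask: np.ndarray  # bool, True = valid wheat cell
    class_raster: np.ndarray | None = None  # uint8, _CLASS_NODATA on invalid
    bin_edges: tuple | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.predicted.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def class_counts(self) -> dict[str, int]:
        if self.class_raster is None or self.bin_edges is None:
            raise GridError("grid has not been classified")
        labels = class_labels(self.bin_edges)
        valid = self.class_raster[self.mask]
        return {lab: int(np.sum(valid == i)) for i, lab in enumerate(labels)}


def predict_grid(model, index_grids: dict[str, np.ndarray], mask: np.ndarray) -> GPCGrid:
    """Apply a fitted model's linear form cell-wise under a wheat mask.

    ``model`` is any object with ``predictor_names``, ``coefficients``
    and ``intercept`` (PLSModel or LinearModel). ``index_grids`` maps
    variable name to a 2-D array; every model predictor must be
    present and congruent with the mask.
    """
    missing = [p for p in model.predictor_names if p not in index_grids]
    if missing:
        raise GridError(f"missing predictor grid(s): {missing}")
    mask = np.asarray(mask, dtype=bool)
    layers = []
    for name in model.predictor_names:
        g = np.ma.filled(np.asanyarray(index_grids[name], dtype=float), np.nan)
        if g.shape != mask.shape:
            raise GridError(f"grid {name!r} shape {g.shape} != mask shape {mask.shape}")
        layers.append(g)
    stack = np.stack(layers, axis=-1)
    finite = np.all(np.isfinite(stack), axis=-1)
    valid = mask & finite
    predicted = np.full(mask.shape, np.nan)
    if valid.any():
        predicted[valid] = model.intercept + stack[valid] @ np.asarray(model.coefficients)
    return GPCGrid(predicted=predicted, mask=valid)


def classify_gpc(grid: GPCGrid, bin_edges=DEFAULT_BIN_EDGES) -> GPCGrid:
    """Bin predictions into GPC classes with half-open [low, high) bins.

    With k edges there are k+1 classes; a value equal to an edge falls
    in the class whose low bound it is. Invalid cells stay invalid.
    Returns the grid with ``class_raster`` and ``bin_edges`` set.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 1 or np.any(np.diff(edges) <= 0):
        raise GridError(f"bin edges must be strictly increasing, got {tuple(bin_edges)}")
    classes = np.full(grid.shape, _CLASS_NODATA, dtype=np.uint8)
    valid = grid.mask
    classes[valid] = np.digitize(grid.predicted[valid], edges, right=False)
    grid.class_raster = classes
    grid.bin_edges = tuple(float(e) for e in edges)
    return grid


def export_map(grid: GPCGrid, out_dir: str | Path, fmt: str = "text") -> dict[str, Path]:
    """Write prediction, class and mask layers plus a JSON legend.

    ``fmt="text"`` writes whitespace-delimited matrices (values to 6
    decimals, nodata -9999); ``fmt="tiff"`` writes single-page float32
    / uint8 TIFFs (requires tifffile). Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if grid.class_raster is None:
        raise GridError("classify the grid before exporting")
    pred = np.where(grid.mask, grid.predicted, _NODATA)
    paths = {}
    if fmt == "text":
        paths["predicted"] = out_dir / "gpc_predicted.txt"
        paths["classes"] = out_dir / "gpc_classes.txt"
        paths["mask"] = out_dir / "mask.txt"
        np.savetxt(paths["predicted"], pred, fmt="%.6f")
        np.savetxt(paths["classes"], grid.class_raster, fmt="%d")
        np.savetxt(paths["mask"], grid.mask.astype(np.uint8), fmt="%d")
    elif fmt == "tiff":
        import tifffile

        paths["predicted"] = out_dir / "gpc_predicted.tif"
        paths["classes"] = out_dir / "gpc_classes.tif"
        paths["mask"] = out_dir / "mask.tif"
        tifffile.imwrite(paths["predicted"], pred.astype(np.float32))
        tifffile.imwrite(paths["classes"], grid.class_raster)
        tifffile.imwrite(paths["mask"], grid.mask.astype(np.uint8))
    else:
        raise GridError(f"unknown export format {fmt!r}")
    legend = {
        "bin_edges": list(grid.bin_edges),
        "class_labels": class_labels(grid.bin_edges),
        "class_cells": grid.class_counts(),
        "valid_cells": grid.n_valid,
        "nodata": {"predicted": _NODATA, "classes": _CLASS_NODATA},
        "shape": list(grid.shape),
    }
    paths["legend"] = out_dir / "legend.json"
    paths["legend"].write_text(json.dumps(legend, indent=2, sort_keys=True))
    return paths


def read_map(out_dir: str | Path, fmt: str = "text") -> GPCGrid:
    """Read back an exported map (inverse of :func:`export_map`)."""
    out_dir = Path(out_dir)
    legend = json.loads((out_dir / "legend.json").read_text())
    if fmt == "text":
        pred = np.loadtxt(out_dir / "gpc_predicted.txt", ndmin=2)
        classes = np.loadtxt(out_dir / "gpc_classes.txt", dtype=np.uint8, ndmin=2)
        mask = np.loadtxt(out_dir / "mask.txt", dtype=np.uint8, ndmin=2).astype(bool)
    elif fmt == "tiff":
        import tifffile

        pred = tifffile.imread(out_dir / "gpc_predicted.tif").astype(float)
        classes = tifffile.imread(out_dir / "gpc_classes.tif")
        mask = tifffile.imread(out_dir / "mask.tif").astype(bool)
    else:
        raise GridError(f"unknown export format {fmt!r}")
    pred = np.where(mask, pred, np.nan)
    return GPCGrid(
        predicted=pred,
        mask=mask,
        class_raster=classes,
        bin_edges=tuple(legend["bin_edges"]),
    )
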