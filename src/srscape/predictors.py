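"""Gridded covariates, point extraction, blocked PCA, and design-matrix assembly.

Covariate rasters are grouped into thematic blocks (climate, soil,
geology, aerosol, terrain, distance).  Each block is reduced
independently with a standardized PCA, keeping the smallest number of
components that explains a configurable fraction of the block's
variance; selected variables (distance-to-coast, basement age) pass
through unreduced because they are interpreted individually in
variable-importance reporting.  The design matrix appends one-hot
indicators for the sample-type covariate.

Rasters are read and written as single-band ESRI ASCII grids (plain
text) with an optional JSON sidecar carrying the CRS id and block label.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .geo import GridSpec

logger = logging.getLogger(__name__)

VALID_BLOCKS = frozenset(
    {"climate", "soil", "geology", "aerosol", "terrain", "distance", "other"}
)
#: Blocks never PCA-reduced.
DEFAULT_PASSTHROUGH_BLOCKS = frozenset({"distance"})

NODATA = -9999.0


@dataclass
class Band:
    name: str
    block: str
    values: np.ndarray  # 2D float, NaN = missing

    def __post_init__(self) -> None:
        if self.block not in VALID_BLOCKS:
            raise ValueError(f"band {self.name!r}: unknown block {self.block!r}")
        self.values = np.asarray(self.values, dtype=float)


class PredictorStack:
    """Aligned gridded covariates sharing one :class:`GridSpec`."""

    def __init__(self, grid: GridSpec, bands: Iterable[Band] = ()):
        self.grid = grid
        self.bands: list[Band] = []
        self._index: dict[str, Band] = {}
        for b in bands:
            self.add(b)

    def add(self, band: Band) -> None:
        if band.values.shape != self.grid.shape:
            raise ValueError(
                f"band {band.name!r} shape {band.values.shape} != grid {self.grid.shape}"
            )
        if band.name in self._index:
            raise ValueError(f"duplicate band name {band.name!r}")
        self.bands.append(band)
        self._index[band.name] = band

    def __getitem__(self, name: str) -> Band:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def block_map(self) -> dict[str, str]:
        return {b.name: b.block for b in self.bands}

    def mask(self) -> np.ndarray:
        """Union of the per-band missing masks (True = missing anywhere)."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for b in self.bands:
            m |= ~np.isfinite(b.values)
        return m


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_ascii_grid(path, grid: GridSpec, values: np.ndarray,
                     sidecar: Mapping | None = None) -> None:
    """Write one band as an ESRI ASCII grid (+ optional JSON sidecar)."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    path = Path(path)
    out = np.where(np.isfinite(values), values, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.origin_lat - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")
    if sidecar is not None:
        with open(Path(str(path) + ".json"), "w", encoding="utf-8") as fh:
            json.dump(dict(sidecar), fh, indent=1)


def read_ascii_grid(path, crs_id: str = "EPSG:4326") -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    cell = header["cellsize"]
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        crs_id = meta.get("crs_id", crs_id)
    grid = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        cell_size=cell, n_rows=n_rows, n_cols=n_cols, crs_id=crs_id,
    )
    nodata = header.get("nodata_value", NODATA)
    values = np.where(np.isclose(values, nodata), np.nan, values)
    return grid, values


def load_stack(paths: Sequence, block_map: Mapping[str, str]) -> PredictorStack:
    """Load aligned single-band ASCII-grid rasters into a stack.

    Band names are the file stems; every raster must share the grid and
    CRS of the first.
    """
    stack: PredictorStack | None = None
    for p in paths:
        p = Path(p)
        name = p.stem
        grid, values = read_ascii_grid(p)
        if name not in block_map:
            raise KeyError(f"no block assigned for raster {name!r}")
        if stack is None:
            stack = PredictorStack(grid)
        else:
            ref = stack.grid
            if (grid.n_rows, grid.n_cols) != (ref.n_rows, ref.n_cols) or \
               not np.isclose(grid.cell_size, ref.cell_size) or \
               not np.isclose(grid.origin_lon, ref.origin_lon) or \
               not np.isclose(grid.origin_lat, ref.origin_lat):
                raise ValueError(f"raster {name!r} grid does not match the stack grid")
            if grid.crs_id != ref.crs_id:
                raise ValueError(f"raster {name!r} CRS {grid.crs_id} != {ref.crs_id}")
        stack.add(Band(name, block_map[name], values))
    if stack is None:
        raise ValueError("no rasters given")
    return stack


def extract_covariates(stack: PredictorStack, lons, lats) -> pd.DataFrame:
    """Nearest-cell covariate lookup for a list of points.

    Points outside the grid extent, or falling on a cell masked in any
    band, get NaN in every column; callers drop them downstream (with a
    warning from :func:`assemble_design` helpers).
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if not (np.all(np.isfinite(lons)) and np.all(np.isfinite(lats))):
        raise ValueError("point coordinates must be finite")
    inside = stack.grid.contains(lons, lats)
    row, col = stack.grid.cell_index(lons, lats)
    row_c = np.clip(row, 0, stack.grid.n_rows - 1)
    col_c = np.clip(col, 0, stack.grid.n_cols - 1)
    masked = stack.mask()[row_c, col_c] | ~inside
    data = {}
    for b in stack.bands:
        vals = b.values[row_c, col_c].astype(float)
        vals[masked] = np.nan
        data[b.name] = vals
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Blocked PCA

@dataclass
class BlockPca:
    """Fitted standardized PCA for one covariate block."""

    variables: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray      # (n_components, n_variables), orthonormal rows
    eigenvalues: np.ndarray   # non-increasing
    n_retained: int

    def scores(self, rows: pd.DataFrame) -> np.ndarray:
        z = (rows[self.variables].to_numpy(dtype=float) - self.means) / self.scales
        return z @ self.loadings[: self.n_retained].T


@dataclass
class BlockedPcaModel:
    """Per-block PCA reductions plus the passthrough variable list."""

    blocks: dict[str, BlockPca]
    passthrough: list[str]
    var_threshold: float

    @property
    def score_names(self) -> list[str]:
        names = []
        for block in sorted(self.blocks):
            names += [f"{block}_pc{i + 1}" for i in range(self.blocks[block].n_retained)]
        return names

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        """PC scores (per block, fitted means/scales) plus passthrough columns."""
        if rows.isna().any().any():
            raise ValueError("covariate rows contain missing values")
        parts = {}
        for block in sorted(self.blocks):
            s = self.blocks[block].scores(rows)
            for i in range(s.shape[1]):
                parts[f"{block}_pc{i + 1}"] = s[:, i]
        for v in self.passthrough:
            parts[v] = rows[v].to_numpy(dtype=float)
        return pd.DataFrame(parts, index=rows.index)


def fit_blocked_pca(
    rows: pd.DataFrame,
    blocks: Mapping[str, str],
    var_threshold: float = 0.80,
    passthrough_blocks: Iterable[str] = DEFAULT_PASSTHROUGH_BLOCKS,
    passthrough_vars: Iterable[str] = (),
) -> BlockedPcaModel:
    """Fit per-block standardized PCAs on complete covariate rows.

    Variables are centred and scaled to unit variance within each block
    before eigendecomposition; per block the smallest component count
    whose cumulative explained variance reaches ``var_threshold`` is
    retained.  Blocks in ``passthrough_blocks``, blocks left with fewer
    than 2 usable variables, and variables named in ``passthrough_vars``
    skip the reduction and enter the design unchanged.  Constant
    variables are dropped with a warning.
    """
    if not 0.0 < var_threshold <= 1.0:
        raise ValueError("var_threshold must lie in (0, 1]")
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to fit a PCA")
    if rows.isna().any().any():
        raise ValueError("covariate rows contain missing values; drop them first")
    passthrough_blocks = set(passthrough_blocks)
    passthrough: list[str] = list(passthrough_vars)

    by_block: dict[str, list[str]] = {}
    for var in rows.columns:
        if var in passthrough:
            continue
        block = blocks.get(var, "other")
        if block in passthrough_blocks:
            passthrough.append(var)
        else:
            by_block.setdefault(block, []).append(var)

    fitted: dict[str, BlockPca] = {}
    for block, variables in by_block.items():
        X = rows[variables].to_numpy(dtype=float)
        scales = X.std(axis=0, ddof=1)
        keep = scales > 0
        if not keep.all():
            dropped = [v for v, k in zip(variables, keep) if not k]
            warnings.warn(f"block {block!r}: dropping constant variable(s) {dropped}")
            variables = [v for v, k in zip(variables, keep) if k]
            X = rows[variables].to_numpy(dtype=float)
        if len(variables) < 2:
            passthrough.extend(variables)
            continue
        means = X.mean(axis=0)
        scales = X.std(axis=0, ddof=1)
        Z = (X - means) / scales
        pca = PCA(n_components=len(variables), svd_solver="full")
        pca.fit(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_ret = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
        n_ret = min(n_ret, len(variables))
        fitted[block] = BlockPca(
            variables=variables, means=means, scales=scales,
            loadings=pca.components_, eigenvalues=pca.explained_variance_,
            n_retained=n_ret,
        )
    return BlockedPcaModel(blocks=fitted, passthrough=passthrough,
                           var_threshold=var_threshold)


def pca_to_dict(model: BlockedPcaModel) -> dict:
    """JSON-serializable representation of a fitted blocked PCA."""
    return {
        "var_threshold": model.var_threshold,
        "passthrough": list(model.passthrough),
        "blocks": {
            name: {
                "variables": b.variables,
                "means": b.means.tolist(),
                "scales": b.scales.tolist(),
                "loadings": b.loadings.tolist(),
                "eigenvalues": b.eigenvalues.tolist(),
                "n_retained": b.n_retained,
            }
            for name, b in model.blocks.items()
        },
    }


def pca_from_dict(d: Mapping) -> BlockedPcaModel:
    return BlockedPcaModel(
        blocks={
            name: BlockPca(
                variables=list(bd["variables"]),
                means=np.array(bd["means"]),
                scales=np.array(bd["scales"]),
                loadings=np.array(bd["loadings"]),
                eigenvalues=np.array(bd["eigenvalues"]),
                n_retained=int(bd["n_retained"]),
            )
            for name, bd in d["blocks"].items()
        },
        passthrough=list(d["passthrough"]),
        var_threshold=float(d["var_threshold"]),
    )


# ---------------------------------------------------------------------------
# Design matrix

@dataclass(frozen=True)
class ColumnInfo:
    name: str
    kind: str   # "pc" | "passthrough" | "type"
    block: str


@dataclass
class DesignMatrix:
    """Numeric model matrix with column metadata and sample-type levels."""

    X: np.ndarray
    columns: list[ColumnInfo]
    type_levels: tuple[str, ...]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.column_names)


def assemble_design(
    rows: pd.DataFrame,
    pca: BlockedPcaModel,
    sample_types: Sequence[str],
    type_levels: Sequence[str] | None = None,
) -> DesignMatrix:
    """Build the model matrix: block PC scores + passthrough + one-hot sample type.

    ``type_levels`` fixes the indicator columns; pass the training
    matrix's levels at prediction time.  An unseen type at prediction is
    an error.  Rows must be complete (no missing covariates).
    """
    if len(sample_types) != len(rows):
        raise ValueError("sample_types length must match rows")
    scores = pca.transform(rows)  # raises on missing values
    if type_levels is None:
        levels = tuple(sorted(set(sample_types)))
    else:
        levels = tuple(type_levels)
        unseen = set(sample_types) - set(levels)
        if unseen:
            raise ValueError(f"sample type(s) {sorted(unseen)} not seen in training")

    cols: list[ColumnInfo] = []
    mats: list[np.ndarray] = []
    for block in sorted(pca.blocks):
        for i in range(pca.blocks[block].n_retained):
            cols.append(ColumnInfo(f"{block}_pc{i + 1}", "pc", block))
    for v in pca.passthrough:
        cols.append(ColumnInfo(v, "passthrough", "passthrough"))
    mats.append(scores[[c.name for c in cols]].to_numpy(dtype=float))

    onehot = np.zeros((len(rows), len(levels)))
    for j, lvl in enumerate(levels):
        onehot[:, j] = [1.0 if t == lvl else 0.0 for t in sample_types]
    mats.append(onehot)
    cols += [ColumnInfo(f"type_{lvl}", "type", "sample_type") for lvl in levels]

    X = np.hstack(mats)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains missing values")
    return DesignMatrix(X=X, columns=cols, type_levels=levels)


def drop_missing_rows(rows: pd.DataFrame, sample_types: Sequence[str] | None = None):
    """Drop rows with any missing covariate, warning with the dropped indices."""
    bad = rows.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} point(s) outside the grid or on masked cells"
        )
    kept = rows[~bad]
    if sample_types is None:
        return kept
    types = [t for t, b in zip(sample_types, bad) if not b]
    return kept, types
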