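"""Gridded isoscape prediction: posterior summaries in ratio units, cellwise.

Back-transformation is applied per posterior draw and the summaries
(median, IQR, central 95% interval, sd) are computed on the
ratio-scale draws — not by transforming logit-scale summaries — so
quantiles are exact under the monotone transform and the sd is
descriptive of the ratio-scale predictive spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bart import BartPosterior, predict_draws
from .geo import GridSpec
from .predictors import (
    BlockedPcaModel,
    DesignMatrix,
    PredictorStack,
    assemble_design,
    extract_covariates,
    write_ascii_grid,
    read_ascii_grid,
)

LAYER_NAMES = ("median", "q25", "q75", "ci2_5", "ci97_5", "sd")


@dataclass
class IsoscapeRaster:
    """Gridded posterior summaries of predicted 87Sr/86Sr."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    mask: np.ndarray                    # True = missing
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in LAYER_NAMES:
            if name not in self.layers:
                raise ValueError(f"missing layer {name!r}")
            if self.layers[name].shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape mismatch")


def predict_isoscape(
    post: BartPosterior,
    stack: PredictorStack,
    pca: BlockedPcaModel,
    sample_type: str = "plant",
    include_noise: bool | None = None,
    noise_seed: int = 0,
) -> IsoscapeRaster:
    """Apply a fitted posterior across a predictor grid.

    Per unmasked cell: assemble the design row for ``sample_type``,
    draw the posterior (predictive) distribution, back-transform each
    draw to ratio units, and summarize.  ``include_noise`` defaults to
    the fitted configuration's setting; the noiseless sum of trees is
    the mean-surface alternative.
    """
    if post.type_levels and sample_type not in post.type_levels:
        raise ValueError(f"sample type {sample_type!r} not seen in training")
    if include_noise is None:
        include_noise = post.config.include_noise

    grid = stack.grid
    mask = stack.mask()
    lon, lat = grid.cell_centers()
    ok = ~mask.ravel()
    rows = extract_covariates(stack, lon.ravel()[ok], lat.ravel()[ok])
    needed = {v for b in pca.blocks.values() for v in b.variables} | set(pca.passthrough)
    missing_bands = needed - set(rows.columns)
    if missing_bands:
        raise ValueError(f"stack lacks band(s) required by the model: {sorted(missing_bands)}")

    design = assemble_design(rows, pca, [sample_type] * len(rows),
                             type_levels=post.type_levels or None)
    draws_logit = predict_draws(post, design, include_noise=include_noise,
                                rng=noise_seed)
    draws_ratio = post.transform.from_logit(draws_logit)

    def full(vec: np.ndarray) -> np.ndarray:
        out = np.full(grid.n_rows * grid.n_cols, np.nan)
        out[ok] = vec
        return out.reshape(grid.shape)

    q = np.quantile(draws_ratio, [0.025, 0.25, 0.5, 0.75, 0.975], axis=1)
    layers = {
        "ci2_5": full(q[0]), "q25": full(q[1]), "median": full(q[2]),
        "q75": full(q[3]), "ci97_5": full(q[4]),
        "sd": full(draws_ratio.std(axis=1, ddof=1)),
    }
    provenance = {
        "sample_type": sample_type,
        "include_noise": bool(include_noise),
        "n_draws": post.n_draws,
        "transform": {"lower": post.transform.lower, "upper": post.transform.upper,
                      "epsilon": post.transform.epsilon},
    }
    return IsoscapeRaster(grid=grid, layers=layers, mask=mask, provenance=provenance)


def export_isoscape(iso: IsoscapeRaster, directory, prefix: str = "isoscape") -> list[Path]:
    """Write one ASCII grid per layer plus a JSON sidecar; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in LAYER_NAMES:
        p = directory / f"{prefix}_{name}.asc"
        write_ascii_grid(p, iso.grid, np.asarray(iso.layers[name], dtype=np.float32))
        paths.append(p)
    sidecar = directory / f"{prefix}_metadata.json"
    sidecar.write_text(json.dumps(
        {"layers": list(LAYER_NAMES), "crs_id": iso.grid.crs_id, **iso.provenance},
        indent=1))
    paths.append(sidecar)
    return paths


def import_isoscape(directory, prefix: str = "isoscape") -> IsoscapeRaster:
    """Read back an exported isoscape (float32 precision)."""
    directory = Path(directory)
    meta = json.loads((directory / f"{prefix}_metadata.json").read_text())
    layers = {}
    grid = None
    for name in LAYER_NAMES:
        grid, vals = read_ascii_grid(directory / f"{prefix}_{name}.asc",
                                     crs_id=meta.get("crs_id", "EPSG:4326"))
        layers[name] = vals
    mask = ~np.isfinite(layers["median"])
    return IsoscapeRaster(grid=grid, layers=layers, mask=mask, provenance=meta)
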