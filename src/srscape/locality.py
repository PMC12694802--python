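"""Posterior-predictive local range at a site and tissue locality assessment.

The "local range" at a site is the interquartile range of the model's
posterior predictive distribution for the site's grid cell.  A tissue
value is placed on a continuous spectrum of locality via its two-sided
tail probability under the empirical predictive distribution, and
categorized: ``local`` inside the IQR, ``marginal`` between the IQR and
the central 95% interval, ``nonlocal`` outside it.  Measurement error,
when supplied, is handled by interval overlap at +/- 2 SE, reporting
the most local class consistent with any point of that interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bart import BartPosterior, predict_draws
from .predictors import BlockedPcaModel, PredictorStack, assemble_design, extract_covariates


@dataclass(frozen=True)
class LocalRange:
    site: str
    lon: float
    lat: float
    median: float
    q25: float
    q75: float
    ci2_5: float
    ci97_5: float
    n_draws: int


@dataclass(frozen=True)
class TissueAssessment:
    tissue_id: str
    value: float
    se: float | None
    locality_p: float
    category: str            # local | marginal | nonlocal
    overlap_note: str = ""


def local_range_at(
    post: BartPosterior,
    stack: PredictorStack,
    pca: BlockedPcaModel,
    lon: float,
    lat: float,
    sample_type: str = "plant",
    site: str = "",
    include_noise: bool | None = None,
    noise_seed: int = 0,
    return_draws: bool = False,
):
    """Posterior predictive local range at the grid cell containing (lon, lat)."""
    if not stack.grid.contains(lon, lat):
        raise ValueError(f"point ({lon}, {lat}) outside the predictor grid extent")
    row, col = stack.grid.cell_index(lon, lat)
    if stack.mask()[int(row), int(col)]:
        raise ValueError(f"cell ({int(row)}, {int(col)}) is masked in the predictor stack")
    if include_noise is None:
        include_noise = post.config.include_noise

    rows = extract_covariates(stack, [lon], [lat])
    design = assemble_design(rows, pca, [sample_type],
                             type_levels=post.type_levels or None)
    draws_logit = predict_draws(post, design, include_noise=include_noise, rng=noise_seed)
    draws = post.transform.from_logit(draws_logit[0])

    q = np.quantile(draws, [0.025, 0.25, 0.5, 0.75, 0.975])
    lr = LocalRange(site=site, lon=lon, lat=lat, median=float(q[2]),
                    q25=float(q[1]), q75=float(q[3]),
                    ci2_5=float(q[0]), ci97_5=float(q[4]), n_draws=draws.size)
    return (lr, draws) if return_draws else lr


def _ecdf(draws: np.ndarray, value: float) -> float:
    """Hazen (midpoint-rank) empirical CDF, clipped away from 0 and 1.

    The clip to [0.5/n, 1 - 0.5/n] keeps the two-sided tail probability
    strictly positive at finite draw counts.
    """
    n = draws.size
    below = np.count_nonzero(draws < value)
    equal = np.count_nonzero(draws == value)
    f = (below + 0.5 * equal) / n
    return float(np.clip(f, 0.5 / n, 1.0 - 0.5 / n))


def _category(value: float, lr: LocalRange) -> str:
    if lr.q25 <= value <= lr.q75:
        return "local"
    if lr.ci2_5 <= value <= lr.ci97_5:
        return "marginal"
    return "nonlocal"


_CATEGORY_ORDER = {"local": 0, "marginal": 1, "nonlocal": 2}


def assess_tissue(value: float, lr: LocalRange, draws: np.ndarray,
                  se: float | None = None, tissue_id: str = "") -> TissueAssessment:
    """Place one tissue 87Sr/86Sr value on the continuous locality spectrum.

    ``locality_p = 2 * min(F(value), 1 - F(value))`` with F the Hazen
    empirical CDF of the predictive draws: ~1 at the predictive median,
    ~0 far outside the predictive distribution.  With a positive SE the
    category is the most local class consistent with any point of
    ``value +/- 2*se``, noted in ``overlap_note``.
    """
    if draws is None or len(draws) == 0:
        raise ValueError("no predictive draws available")
    if not (0.5 < value < 1.0):
        raise ValueError(f"ratio {value} outside the physical sanity window (0.5, 1.0)")
    draws = np.asarray(draws, dtype=float)

    F = _ecdf(draws, value)
    locality_p = float(np.clip(2.0 * min(F, 1.0 - F), 0.0, 1.0))

    cat_point = _category(value, lr)
    category, note = cat_point, ""
    if se is not None and se > 0:
        lo, hi = value - 2.0 * se, value + 2.0 * se
        candidates = {cat_point}
        # most local class consistent with any point of the +/-2 SE interval
        if not (hi < lr.q25 or lo > lr.q75):
            candidates.add("local")
        if not (hi < lr.ci2_5 or lo > lr.ci97_5):
            candidates.add("marginal")
        category = min(candidates, key=_CATEGORY_ORDER.get)
        if category != cat_point:
            note = (f"point value is {cat_point} but its +/-2SE interval "
                    f"[{lo:.6f}, {hi:.6f}] overlaps the {category} band")
    return TissueAssessment(tissue_id=tissue_id, value=float(value), se=se,
                            locality_p=locality_p, category=category,
                            overlap_note=note)


def assess_tissue_table(table: pd.DataFrame, lr: LocalRange,
                        draws: np.ndarray) -> pd.DataFrame:
    """Assess a tissue CSV (tissue_id, ratio, optional se2); appends results."""
    out = table.copy()
    ps, cats, notes = [], [], []
    for _, row in table.iterrows():
        se2 = row.get("se2")
        se = float(se2) / 2.0 if pd.notna(se2) else None
        a = assess_tissue(float(row["ratio"]), lr, draws, se=se,
                          tissue_id=str(row.get("tissue_id", "")))
        ps.append(a.locality_p)
        cats.append(a.category)
        notes.append(a.overlap_note)
    out["locality_p"] = ps
    out["category"] = cats
    out["note"] = notes
    return out
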