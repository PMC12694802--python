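"""Region-holdout experiment design and RMSE / R-squared metrics.

Model skill is reported in both the logit space the model is fitted in
and the raw ratio units archaeologists interpret.  The holdout design
mirrors iterative regional calibration: train on a continental pool
with a region excluded, test on that region, then fold the region into
training and re-test on a nested subregion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .samples import BoundedLogitTransform, DEFAULT_TRANSFORM, SampleSet

#: Country tags conventionally grouped as Mesoamerica in regional holdouts.
MESOAMERICAN_COUNTRIES = ("MX", "BZ", "GT", "HN", "SV", "NI", "CR")


@dataclass(frozen=True)
class MetricsReport:
    n: int
    rmse_logit: float
    r2_logit: float
    rmse_raw: float
    r2_raw: float
    label: str = ""

    def to_row(self) -> dict:
        return {"label": self.label, "n": self.n,
                "rmse_logit": self.rmse_logit, "r2_logit": self.r2_logit,
                "rmse_raw": self.rmse_raw, "r2_raw": self.r2_raw}


def split_by_region(sset: SampleSet, test_regions: Iterable[str]) -> tuple[SampleSet, SampleSet]:
    """Partition a sample set into train/test by region tag.

    Test = samples whose ``region_tag`` is in ``test_regions``; train is
    the complement.  Errors if either side is empty.
    """
    test_regions = set(test_regions)
    if not test_regions:
        raise ValueError("empty test-region list")
    in_test = [s.region_tag in test_regions for s in sset]
    test = sset.subset(in_test, metadata=f"test regions {sorted(test_regions)}")
    train = sset.subset([not t for t in in_test], metadata="train complement")
    if len(test) == 0:
        raise ValueError(f"no samples match test regions {sorted(test_regions)}")
    if len(train) == 0:
        raise ValueError(f"all samples match test regions {sorted(test_regions)}; train empty")
    return train, test


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("zero-variance observations: R^2 undefined")
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def compute_metrics(obs, pred_draws: np.ndarray,
                    transform: BoundedLogitTransform = DEFAULT_TRANSFORM,
                    label: str = "") -> MetricsReport:
    """RMSE and R^2 in logit and raw units from posterior draws.

    The logit-space point prediction is the mean over draws; the
    raw-space point prediction is the mean of back-transformed draws
    (back-transform first, then average).  Out-of-sample R^2 uses the
    test-set mean in the denominator.
    """
    obs = np.asarray(obs, dtype=float)
    pred_draws = np.asarray(pred_draws, dtype=float)
    if pred_draws.shape[0] != obs.shape[0]:
        raise ValueError("obs and prediction rows must align")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    z_obs = transform.to_logit(obs)
    z_hat = pred_draws.mean(axis=1)
    r_hat = transform.from_logit(pred_draws).mean(axis=1)
    return MetricsReport(
        n=int(obs.size),
        rmse_logit=_rmse(z_obs, z_hat), r2_logit=_r2(z_obs, z_hat),
        rmse_raw=_rmse(obs, r_hat), r2_raw=_r2(obs, r_hat),
        label=label,
    )


def evaluate_baseline(obs, baseline_pred,
                      transform: BoundedLogitTransform = DEFAULT_TRANSFORM,
                      label: str = "baseline") -> MetricsReport:
    """Score an externally supplied point prediction (e.g. a bedrock model).

    Baseline values outside the transform bounds are clamped with a
    warning before the logit-space metrics.
    """
    obs = np.asarray(obs, dtype=float)
    baseline = np.asarray(baseline_pred, dtype=float)
    if baseline.shape != obs.shape:
        raise ValueError("obs and baseline must align")
    lo, hi = transform.lower, transform.upper
    if np.any(baseline < lo) or np.any(baseline > hi):
        warnings.warn("baseline predictions outside transform bounds; clamping")
        baseline = np.clip(baseline, lo, hi)
    z_obs = transform.to_logit(obs)
    z_hat = transform.to_logit(baseline)
    return MetricsReport(
        n=int(obs.size),
        rmse_logit=_rmse(z_obs, z_hat), r2_logit=_r2(z_obs, z_hat),
        rmse_raw=_rmse(obs, baseline), r2_raw=_r2(obs, baseline),
        label=label,
    )


def reports_to_csv(reports: Sequence[MetricsReport], path) -> None:
    """Write one row per stage (the regional-holdout table shape)."""
    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, index=False)
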