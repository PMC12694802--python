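"""Sample data model, I/O, QC filters, and the bounded-logit response transform.

The unit of all training and evaluation data is a georeferenced
87Sr/86Sr measurement (:class:`SrSample`).  Ratios are modelled on a
bounded-logit scale: raw ratios are confined to an interval [L, U]
relevant for the study region, mapped to the real line with a logistic
transform, regressed there, and mapped back for reporting.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .geo import utm_to_geographic

logger = logging.getLogger(__name__)

#: QC / provenance flags a sample may carry.
VALID_FLAGS = frozenset(
    {"fertilizer_contaminated", "nonlocal_human", "out_of_range", "site_outlier"}
)
VALID_SAMPLE_TYPES = frozenset({"plant", "water", "human", "fauna", "soil", "rock", "other"})
VALID_ROOTING_DEPTHS = frozenset({"shallow", "deep", "unknown"})

#: Sentinel site name for pooled summaries.
ALL_SITES = "ALL"


@dataclass
class SrSample:
    """One georeferenced 87Sr/86Sr measurement."""

    sample_id: str
    site: str
    lon: float
    lat: float
    ratio: float
    sample_type: str = "plant"
    se2: float | None = None
    elevation: float | None = None
    species: str | None = None
    rooting_depth: str = "unknown"
    flags: set[str] = field(default_factory=set)
    region_tag: str = ""
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError(f"{self.sample_id}: ratio must be positive, got {self.ratio}")
        if self.se2 is not None and self.se2 < 0:
            raise ValueError(f"{self.sample_id}: se2 must be non-negative")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"{self.sample_id}: latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"{self.sample_id}: longitude {self.lon} outside [-180, 180]")
        if self.sample_type not in VALID_SAMPLE_TYPES:
            raise ValueError(f"{self.sample_id}: unknown sample_type {self.sample_type!r}")
        if self.rooting_depth not in VALID_ROOTING_DEPTHS:
            raise ValueError(f"{self.sample_id}: unknown rooting_depth {self.rooting_depth!r}")
        self.flags = set(self.flags)
        unknown = self.flags - VALID_FLAGS
        if unknown:
            raise ValueError(f"{self.sample_id}: unknown flags {sorted(unknown)}")


class SampleSet:
    """An ordered collection of :class:`SrSample` with unique ids."""

    def __init__(self, samples: Iterable[SrSample], metadata: str = ""):
        self.samples: list[SrSample] = list(samples)
        self.metadata = metadata
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValueError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SrSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> SrSample:
        return self.samples[i]

    @property
    def ratios(self) -> np.ndarray:
        return np.array([s.ratio for s in self.samples], dtype=float)

    @property
    def sites(self) -> list[str]:
        return sorted({s.site for s in self.samples})

    def subset(self, keep: Sequence[bool], metadata: str | None = None) -> "SampleSet":
        kept = [s for s, k in zip(self.samples, keep) if k]
        return SampleSet(kept, metadata if metadata is not None else self.metadata)


@dataclass(frozen=True)
class BoundedLogitTransform:
    """Logistic map between a bounded ratio interval [L, U] and the real line.

    ``to_logit`` sends r in [L, U] to z = log(s / (1 - s)) with
    s = clamp((r - L) / (U - L), eps, 1 - eps); ``from_logit`` inverts it.
    The epsilon clamp keeps boundary values finite.
    """

    lower: float = 0.703
    upper: float = 0.780
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 1/2) of the unit interval")

    def to_logit(self, r):
        r_arr = np.asarray(r, dtype=float)
        if np.any(r_arr < self.lower) or np.any(r_arr > self.upper):
            raise ValueError(
                f"ratio outside transform bounds [{self.lower}, {self.upper}]"
            )
        s = (r_arr - self.lower) / (self.upper - self.lower)
        s = np.clip(s, self.epsilon, 1.0 - self.epsilon)
        z = np.log(s / (1.0 - s))
        return float(z) if np.isscalar(r) else z

    def from_logit(self, z):
        z_arr = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z_arr)):
            raise ValueError("non-finite logit value")
        r = self.lower + (self.upper - self.lower) / (1.0 + np.exp(-z_arr))
        return float(r) if np.isscalar(z) else r


DEFAULT_TRANSFORM = BoundedLogitTransform()


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample sd (n-1 denominator), min, max of a set of ratios."""

    n: int
    mean: float
    sd: float
    min: float
    max: float


# ---------------------------------------------------------------------------
# I/O

_REQUIRED_COLUMNS = ("sample_id", "site", "ratio")
_OPTIONAL_COLUMNS = (
    "se2", "elevation", "species", "rooting_depth", "sample_type",
    "flags", "region_tag", "source_tag",
)


def read_samples(path, schema: Mapping[str, str] | None = None) -> SampleSet:
    """Read a sample table (CSV/TSV with header) into a :class:`SampleSet`.

    Coordinates come either from ``lon``/``lat`` columns (WGS84 decimal
    degrees) or from ``utm_e``/``utm_n``/``utm_zone``, converted on
    ingest.  ``schema`` optionally maps canonical column names to the
    file's column names.  Rows whose ratio does not parse are rejected
    and reported by row index.
    """
    schema = dict(schema or {})

    def col(name: str) -> str:
        return schema.get(name, name)

    path = str(path)
    delimiter = "\t" if path.endswith((".tsv", ".tab")) else ","
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: no records (empty file)")
        header = set(reader.fieldnames)
        missing = [c for c in _REQUIRED_COLUMNS if col(c) not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        has_lonlat = col("lon") in header and col("lat") in header
        has_utm = all(col(c) in header for c in ("utm_e", "utm_n", "utm_zone"))
        if not (has_lonlat or has_utm):
            raise ValueError(
                f"{path}: need either lon/lat or utm_e/utm_n/utm_zone columns"
            )
        rows = list(reader)

    if not rows:
        raise ValueError(f"{path}: no records")

    samples: list[SrSample] = []
    bad_rows: list[int] = []
    for i, row in enumerate(rows):
        try:
            ratio = float(row[col("ratio")])
        except (TypeError, ValueError):
            bad_rows.append(i)
            continue
        if has_lonlat:
            lon, lat = float(row[col("lon")]), float(row[col("lat")])
        else:
            lon, lat = utm_to_geographic(
                float(row[col("utm_e")]), float(row[col("utm_n")]), row[col("utm_zone")]
            )

        def opt(name, cast=str):
            v = row.get(col(name), "")
            return cast(v) if v not in ("", None) else None

        flags_raw = row.get(col("flags"), "") or ""
        flags = {f.strip() for f in flags_raw.split(";") if f.strip()}
        samples.append(
            SrSample(
                sample_id=row[col("sample_id")],
                site=row[col("site")],
                lon=lon,
                lat=lat,
                ratio=ratio,
                se2=opt("se2", float),
                elevation=opt("elevation", float),
                species=opt("species"),
                rooting_depth=opt("rooting_depth") or "unknown",
                sample_type=opt("sample_type") or "plant",
                flags=flags,
                region_tag=opt("region_tag") or "",
                source_tag=opt("source_tag") or "",
            )
        )
    if bad_rows:
        logger.warning("%s: rejected %d row(s) with unparseable ratio: %s",
                       path, len(bad_rows), bad_rows)
    if not samples:
        raise ValueError(f"{path}: no records with a parseable ratio")
    return SampleSet(samples, metadata=f"read from {path}")


def write_samples(sset: SampleSet, path) -> None:
    """Write a :class:`SampleSet` as UTF-8 CSV in the same dialect read_samples accepts."""
    fieldnames = [
        "sample_id", "site", "lon", "lat", "elevation", "species", "rooting_depth",
        "sample_type", "ratio", "se2", "flags", "region_tag", "source_tag",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for s in sset:
            writer.writerow({
                "sample_id": s.sample_id, "site": s.site,
                "lon": repr(s.lon), "lat": repr(s.lat),
                "elevation": "" if s.elevation is None else s.elevation,
                "species": s.species or "", "rooting_depth": s.rooting_depth,
                "sample_type": s.sample_type, "ratio": f"{s.ratio:.6f}",
                "se2": "" if s.se2 is None else f"{s.se2:.6f}",
                "flags": ";".join(sorted(s.flags)),
                "region_tag": s.region_tag, "source_tag": s.source_tag,
            })


def load_oaxaca_plants() -> SampleSet:
    """Load the packaged Valley of Oaxaca modern-plant baseline table (95 samples).

    Samples judged fertilizer-contaminated carry the
    ``fertilizer_contaminated`` flag and are conventionally excluded
    from model training via :func:`apply_exclusions`.
    """
    with resources.as_file(
        resources.files("srscape.data").joinpath("oaxaca_plants.csv")
    ) as p:
        return read_samples(p)


# ---------------------------------------------------------------------------
# QC filters

def filter_ratio_range(
    sset: SampleSet, transform: BoundedLogitTransform = DEFAULT_TRANSFORM
) -> SampleSet:
    """Drop samples whose ratio falls outside [L, U] (bounds inclusive).

    Removed samples are flagged ``out_of_range``; the removal count is
    logged. Keeps model training inside the ratio window relevant for
    the study region.
    """
    keep = []
    n_removed = 0
    for s in sset:
        if transform.lower <= s.ratio <= transform.upper:
            keep.append(True)
        else:
            s.flags.add("out_of_range")
            keep.append(False)
            n_removed += 1
    if n_removed:
        logger.info("filter_ratio_range: removed %d of %d samples", n_removed, len(sset))
    return sset.subset(keep)


def apply_exclusions(sset: SampleSet, excluded_flags: Iterable[str]) -> SampleSet:
    """Remove samples carrying any of the given flags, preserving order."""
    excluded = set(excluded_flags)
    unknown = excluded - VALID_FLAGS
    if unknown:
        raise ValueError(f"unknown flag name(s): {sorted(unknown)}")
    return sset.subset([not (s.flags & excluded) for s in sset])


def screen_site_outliers(sset: SampleSet, threshold: float = 3.0,
                         mad_floor: float = 1e-7,
                         min_effect: float = 0.0015) -> SampleSet:
    """Flag within-site outliers by robust z-score; removes nothing.

    A sample is flagged ``site_outlier`` when both
    ``|ratio - site median| / (1.4826 * site MAD)`` exceeds
    ``threshold`` *and* the absolute deviation exceeds ``min_effect``.
    The effect-size guard keeps the screen aimed at analytically
    meaningful offsets (fertilizer contamination shifts ratios by
    thousandths) rather than statistical flukes: at the 3-9 samples per
    site typical of baseline surveys, the MAD is noisy enough that the
    bare z-rule alone would flag a few percent of clean samples.
    Sites with fewer than 3 samples are skipped with a warning.  The
    MAD is floored at ``mad_floor`` so constant sites never divide by
    zero (and never flag).
    """
    out = SampleSet([replace(s, flags=set(s.flags)) for s in sset], sset.metadata)
    by_site: dict[str, list[SrSample]] = {}
    for s in out:
        by_site.setdefault(s.site, []).append(s)
    for site, members in by_site.items():
        if len(members) < 3:
            warnings.warn(f"site {site!r} has <3 samples; outlier screen skipped")
            continue
        vals = np.array([s.ratio for s in members])
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        scale = max(mad * 1.4826, mad_floor)
        if mad == 0.0:
            continue  # identical values: nothing can be an outlier
        for s, v in zip(members, vals):
            if abs(v - med) / scale > threshold and abs(v - med) > min_effect:
                s.flags.add("site_outlier")
    return out


def site_summary(sset: SampleSet, site: str = ALL_SITES) -> SummaryStats:
    """Summary statistics (n, mean, 1-sigma sample sd, min, max) for one site or ALL."""
    if site == ALL_SITES:
        vals = sset.ratios
    else:
        vals = np.array([s.ratio for s in sset if s.site == site])
        if vals.size == 0:
            raise KeyError(f"unknown site {site!r}")
    if vals.size == 1:
        warnings.warn(f"site {site!r} has a single sample; sd reported as 0")
        sd = 0.0
    else:
        sd = float(np.std(vals, ddof=1))
    return SummaryStats(
        n=int(vals.size), mean=float(np.mean(vals)), sd=sd,
        min=float(np.min(vals)), max=float(np.max(vals)),
    )
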