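# Methods

## Response transform

⁸⁷Sr/⁸⁶Sr ratios relevant to Mesoamerican provenance work span roughly
0.703–0.780, and their landscape distribution is bounded and skewed.
The package regresses on a bounded-logit scale: with L = 0.703,
U = 0.780, z = log(s/(1−s)) where s = clamp((r−L)/(U−L), ε, 1−ε),
ε = 1e−6. The same interval doubles as the QC filter: samples outside
[L, U] (bounds inclusive) are flagged and dropped before training.
The clamp keeps boundary values finite; `from_logit` is the exact
inverse on the interior, and round-trips hold to 1e−12. The interval
is configurable; these defaults are the only bounds the application
domain names.

## Sample QC

Three filters operate on sample sets, in the order a user would apply
them:

1. **Range filter** — removes ratios outside [L, U], flagging them
   `out_of_range`.
2. **Exclusions** — removes samples carrying named flags
   (`fertilizer_contaminated`, `nonlocal_human`). The packaged Oaxaca
   plant table carries contamination flags on the 12 San Martín
   Tilcajete rows whose ratios are implausibly radiogenic for the
   local geology; excluding them leaves 83 training samples out of 95.
3. **Site outlier screen** — a Hampel-style within-site rule: flag a
   sample when |ratio − site median| / (1.4826 · site MAD) exceeds a
   threshold (default 3) *and* the absolute deviation exceeds a
   minimum effect size (default 0.0015 ratio units). The effect-size
   guard exists because at realistic site sizes (3–9 samples) the MAD
   is noisy enough that the bare z-rule alone false-flags several
   percent of clean samples; contamination offsets of interest are an
   order of magnitude larger than analytical and within-site noise, so
   the double filter loses essentially no power (≥90% detection of a
   +0.003 offset at a 10% contamination rate in simulation) while
   keeping the false-flag rate well under 1%. Sites with fewer than 3
   samples are skipped with a warning; a MAD floor of 1e−7 makes
   constant sites inert. The screen only flags — nothing is removed —
   and it is a generic robust screen, not a reconstruction of any
   specific forensic contamination test.

Summary statistics report the sample standard deviation (n−1
denominator) as "1σ"; single-sample sites report sd 0 with a warning
rather than erroring, so pooled pipelines keep running.

Coordinates are stored as WGS84 lon/lat. UTM input is converted on
ingest with an in-package transverse Mercator implementation
(Krüger series, 4th order in the third flattening; the inverse
recovers latitude by Newton iteration on the conformal-latitude
relation). Round-trips are accurate to ~1e−7 m, far inside the 0.01 m
contract; no external projection library is required.

## Predictors

Covariates are single-band, grid-aligned rasters grouped into blocks:
climate, soil, geology, aerosol, terrain, distance. I/O uses the ESRI
ASCII grid format (plain text, nodata honored) with a JSON sidecar for
the CRS id and block label. Point extraction is nearest-cell under a
half-open, row-major, north-up convention (row = ⌊(origin_lat −
lat)/cell⌋); nearest-cell rather than bilinear because several bands
are categorical (geology) and the products emulated are ~1 km
granules. Points outside the grid or on cells masked in any band are
marked missing and dropped with a warning before design assembly.

Each block is reduced by its own PCA on standardized (z-scored)
variables — standardization is necessary because blocks mix units —
keeping the smallest component count whose cumulative explained
variance reaches a threshold (default 0.80, exposed in config since
the appropriate final dimensionality is data-dependent).
Distance-to-coast and basement age pass through unreduced: they are
the covariates practitioners interpret individually in importance
rankings. Blocks left with fewer than two usable variables pass
through as well; constant variables are dropped with a warning. The
design matrix appends one-hot sample-type indicators; the type levels
are fixed at training time and an unseen type at prediction is an
error, not a silent zero row.

## The tree-ensemble sampler

The regression engine is a from-scratch implementation of the
sum-of-trees Bayesian model with regularizing priors:

* **Tree-shape prior** — a node at depth d splits with probability
  α(1+d)^(−β); defaults α = 0.95, β = 2 keep individual trees shallow.
  Split variables are uniform over variables with at least one
  admissible cutpoint at the node; cutpoints are uniform over the
  admissible values of a per-variable grid (up to 100 interior
  quantiles of the training values; one-hot columns split at 0.5).
  Admissibility requires both children nonempty.
* **Leaf prior** — N(0, σ_μ²), σ_μ = (max z − min z)/(2k√m) after
  centring the response; defaults k = 2, m = 200 trees.
* **Noise prior** — σ² ~ νλ/χ²_ν with ν = 3; λ is calibrated so the
  prior puts mass q = 0.9 below a residual-sd estimate from a
  saturated linear least-squares fit when p < n (otherwise the
  response sd).
* **Chain** — 1,000 burn-in plus 1,000 retained sweeps by default,
  thinning 1. Move mix: grow 0.25, prune 0.25, change 0.40, swap
  0.10. Change proposals act on internal nodes with two leaf children
  (symmetric, so the acceptance ratio is the marginal-likelihood ratio
  alone); swap exchanges the rules of an internal parent–child pair
  and recomputes the full subtree prior, rejecting any proposal that
  empties a leaf.

All of these defaults are the method literature's canonical settings,
exposed in `BartConfig`. Acceptance uses the closed-form
leaf-marginalized likelihood; leaf values and σ are redrawn from exact
conjugate full conditionals each sweep. The entire chain runs off one
seeded generator, so runs are bit-reproducible, lengthening the chain
never changes earlier retained draws, and grow/prune proposals satisfy
the reversibility identity exactly (checked to 1e−10 over seeded
traces; acceptance ratios are verified against brute-force enumeration
of prior × marginal likelihood on small fixtures, and the conjugate
pieces against adaptive quadrature).

Variable importance is split frequency: the share of all splits, over
retained draws, that use each design column.

Posterior containers serialize to a versioned gzip-JSON file
(byte-identical across runs of the same fit, round-trip lossless).

## Prediction and uncertainty

Isoscape prediction assembles a design row per unmasked cell for one
sample type (default `plant` — the bioavailable baseline convention —
because a published isoscape should represent what plants, hence
diets, record), draws the posterior predictive distribution, and
back-transforms **per draw** before summarizing into median, IQR,
central 95% interval, and sd layers. Summary-then-transform would bias
every statistic except the median; the per-draw order makes quantiles
exact and the sd a genuine ratio-scale descriptive.

Two uncertainty flavours are exposed: posterior-predictive draws
(adding N(0, σ_draw²) observation noise; the default, and the one
whose intervals calibrate against new observations) and noiseless
mean-function draws (for mean-surface maps). The published-map
convention is ambiguous between median and mean surfaces; the median
is the default here.

Locality assessment: the local range at a site is the IQR of the
predictive distribution at the containing cell. A tissue value v gets
`locality_p = 2·min(F̂(v), 1−F̂(v))` with F̂ the Hazen (midpoint-rank)
empirical CDF of the draws, clipped to [0.5/n, 1−0.5/n] so finite draw
counts never produce exact 0/1. Categories: `local` inside the IQR,
`marginal` between IQR and the 95% band, `nonlocal` outside —
"marginal" is this package's term for the zone the tradition leaves
unnamed; thresholds are configurable. When a measurement SE is
supplied, the category reported is the most local class consistent
with any point of v ± 2·SE, with the overlap noted. By construction,
a truly local sample lands in the IQR about half the time; the
categories quantify confidence, they do not sharpen it.

## Evaluation

Region-holdout splitting is tag-based (samples carry a `region_tag`;
geometry stays out of the evaluation module), with the canonical
Mesoamerican country list provided as a constant. Metrics are RMSE
and R² in both logit and raw ratio units; the raw-space point
prediction is the mean of back-transformed draws, and out-of-sample R²
uses the test-set mean in its denominator. External baseline
predictions (e.g. a bedrock-model raster) are scored with the same
formulas, clamped into [L, U] with a warning if needed.

## The synthetic landscape

The generator emulates the statistical structure the analysis assumes,
with full ground truth retained:

* **Geology** — a nearest-centre partition of 12 random unit centres
  on a 60×60 grid (1 km cells); unit ages uniform on 20–1000 Ma;
  bedrock ratio 0.7040 + 0.0080·(age/age_max), so older units are
  strictly more radiogenic.
* **Mixing** — bioavailable ratio = weighted mean of bedrock,
  sea-spray (0.709182, the modern-seawater value) and dust (0.7100, a
  generic loess-like value) endmembers with weights 1,
  exp(−d_coast/20 km), and 0.3·dust respectively; the coast is the
  western grid edge.
* **Covariates** — smooth random fields (precipitation, dust index,
  elevation, seasonality), temperature via a lapse rate off elevation,
  slope from the elevation gradient, distance-to-coast, per-cell unit
  age, and one pure-noise covariate for importance testing.
* **Sampling** — type-dependent noise sd (plant 0.0003, water 0.0008,
  human 0.0005, soil 0.0010 — water noisiest because it integrates
  across watersheds, plants tightest because they average local
  bioavailable Sr); water samples blend in a random other cell's value
  at weight 0.3 (the transport confound); an optional contamination
  process shifts a configurable fraction of plant samples by +0.003
  (the scale of observed fertilizer artifacts), with labels recorded
  in the truth table only — a field analyst would not know them.
  Observed ratios are confined to the modelling bounds, so every
  generated sample survives the range filter. Region tags are grid
  quadrants. Components draw from independent substreams, so adding a
  covariate never perturbs the sample draw.

The generator reproduces realistic *scales* (valley-wide plant sd on
the order of 1e−3) and the qualitative structure (age signal, coastal
gradient, type heteroscedasticity), not any real terrane's geology.
Tests passing on it show the estimator and its uncertainty are
correct under the assumed data-generating process; they cannot show
that real covariates capture real Sr cycling.

## Problem sizes used in the checks

The calibration check trains on 800 plant samples and scores 2,000
held-out cells with the default sampler configuration (m = 200,
1,000 + 1,000 sweeps), comparing posterior-predictive intervals
against fresh observations (true field + plant noise) — the quantity
those intervals are calibrated for. The regional-calibration contrast
averages 10 replicates at 400 samples with a reduced configuration
(m = 25, 200 + 200); the importance-ranking check averages 20
replicates at 500 samples (m = 25, 500 + 500), sizes chosen so the
split tallies resolve the weaker coastal signal. The reproduction
script (`scripts/acceptance.py`) re-runs all of these from scratch off
a single seed.

## Known limitations

* Homoscedastic noise: one σ serves all sample types; the type enters
  the mean only. Mixed-type training therefore overcovers quiet types
  (plants) and undercovers noisy ones (soil, water).
* On landscapes with sharp geology boundaries, residual lack-of-fit
  inflates the σ posterior slightly; predictive IQRs then overcover
  (55–60% rather than 50%) even when the 95% band stays calibrated.
* The bounded-logit transform hard-fails on ratios outside [L, U] by
  design; data beyond the window need wider bounds, not the defaults.
* Split-frequency importance is a usage measure, not an effect size;
  correlated covariates share splits and dilute each other.
* The Monte Albán local range published for the real study area
  (0.7069–0.7086, median 0.7077) depends on a 7,271-record continental
  compilation and global raster stacks that are not redistributable
  here; the package reproduces the printed plant-table statistics
  exactly and validates the model machinery on synthetic ground truth
  instead.
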