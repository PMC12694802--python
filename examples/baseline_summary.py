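"""Summarize the packaged Valley of Oaxaca plant baseline.

Loads the 95-sample modern plant table, applies the standard QC steps
(ratio-range filter, contamination exclusion), and prints the pooled
and Monte Albán summary statistics used as the observational baseline.
"""

from srscape import (
    apply_exclusions,
    filter_ratio_range,
    load_oaxaca_plants,
    site_summary,
)
from srscape.samples import ALL_SITES, DEFAULT_TRANSFORM

plants = load_oaxaca_plants()
print(f"loaded {len(plants)} plant samples from {len(plants.sites)} sites")

pooled = site_summary(plants, ALL_SITES)
print(f"valley-wide  87Sr/86Sr: {pooled.mean:.6f} +/- {pooled.sd:.6f} (1 sigma, "
      f"n = {pooled.n}), range {pooled.min:.6f} - {pooled.max:.6f}")

ma = site_summary(plants, "Monte Albán")
print(f"Monte Albán  87Sr/86Sr: {ma.mean:.6f} +/- {ma.sd:.6f} (1 sigma, "
      f"n = {ma.n}), range {ma.min:.6f} - {ma.max:.6f}")

in_range = filter_ratio_range(plants, DEFAULT_TRANSFORM)
training = apply_exclusions(in_range, {"fertilizer_contaminated"})
print(f"after the [0.703, 0.780] range filter: {len(in_range)} samples")
print(f"after excluding fertilizer-contaminated rows: {len(training)} "
      "training samples")
# The excluded rows are the San Martín Tilcajete samples whose ratios are
# implausibly radiogenic for their geology — a fertilizer artifact, not a
# bedrock signal.
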