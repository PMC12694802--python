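import numpy as np
import pytest

from srscape import (
    BartConfig,
    SimConfig,
    assemble_design,
    draw_samples,
    extract_covariates,
    fit_bart,
    fit_blocked_pca,
    load_oaxaca_plants,
    make_landscape,
)
from srscape.samples import DEFAULT_TRANSFORM


@pytest.fixture(scope="session")
def oaxaca():
    """The packaged Valley of Oaxaca plant baseline (95 samples, 17 sites)."""
    return load_oaxaca_plants()


@pytest.fixture(scope="session")
def landscape_bundle():
    """A small fitted end-to-end bundle shared by isoscape/locality tests.

    Plant-only sampling keeps the noise model homoscedastic; the short
    chain is enough for structural (non-calibration) checks.
    """
    cfg = SimConfig(type_mix={"plant": 1.0})
    ls = make_landscape(cfg, seed=42)
    sset, truth = draw_samples(ls, 300, seed=43, cfg=cfg)
    stack = ls.stack()
    rows = extract_covariates(stack, [s.lon for s in sset], [s.lat for s in sset])
    pca = fit_blocked_pca(rows, ls.block_map, passthrough_vars=["dist_coast", "age"])
    design = assemble_design(rows, pca, [s.sample_type for s in sset])
    post = fit_bart(
        design,
        DEFAULT_TRANSFORM.to_logit(sset.ratios),
        BartConfig(m=20, n_burn=200, n_draw=200, seed=44),
        transform=DEFAULT_TRANSFORM,
    )
    return {
        "cfg": cfg, "landscape": ls, "samples": sset, "truth": truth,
        "stack": stack, "pca": pca, "design": design, "posterior": post,
    }
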