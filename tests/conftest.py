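"""Shared fixtures: zero-noise synthetic transect and closed-form OLS oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

import guildflux as gf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def ols_oracle(t, y):
    """Closed-form two-parameter OLS, independent of the fitting path.

    Returns (slope, intercept, se_slope, r_squared).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    tbar, ybar = t.mean(), y.mean()
    sxx = ((t - tbar) ** 2).sum()
    sxy = ((t - tbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    sse = (resid**2).sum()
    sst = ((y - ybar) ** 2).sum()
    r2 = 1.0 - sse / sst
    se = math.sqrt(sse / (n - 2) / sxx) if n > 2 else 0.0
    return slope, intercept, se, r2


@pytest.fixture(scope="session")
def zero_noise_run(tmp_path_factory):
    """Full pipeline run on a noiseless, perfect-inhibitor transect.

    8 sites x 2 assays x 6 treatments (incl. simvastatin) x 4 replicates;
    every recovered quantity should equal ground truth to float precision.
    """
    outroot = tmp_path_factory.mktemp("zero_noise")
    config = gf.SyntheticConfig(
        n_sites=8,
        n_replicates=4,
        noise_sd=0.0,
        include_archaeal_inhibitor=True,
        seed=42,
    )
    paths = gf.generate_dataset(config, outroot / "data")
    run_config = gf.RunConfig(
        measurements=str(paths["measurements"]),
        genes=str(paths["genes"]),
        environment=str(paths["environment"]),
        outdir=str(outroot / "out"),
        n_boot=25,
        seed=42,
    )
    manifest = gf.run_pipeline(run_config)
    return {
        "config": config,
        "truth": gf.draw_truth(config),
        "paths": paths,
        "run_config": run_config,
        "manifest": manifest,
        "outdir": outroot / "out",
    }
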