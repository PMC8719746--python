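"""Shared fixtures: small synthetic studies generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tidal_issa import issa, tracks
from tidal_issa.pipeline import RunConfig, prepare_bird_strata
from tidal_issa.synthetic import (
    SITE_LAT,
    SITE_LON,
    SyntheticTruth,
    make_landscape,
    make_tide,
    simulate_track,
)


@pytest.fixture(scope="session")
def landscape():
    return make_landscape(seed=11)


@pytest.fixture(scope="session")
def tide():
    return make_tide(duration_days=45)


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth(seed=11)


@pytest.fixture(scope="session")
def one_bird_strata(landscape, tide, truth):
    """One simulated bird run through the step-preparation pipeline.

    Returns (observed steps, strata with covariates, tentative kernel,
    full-model fit) at 2000 steps.
    """
    habitat, elev = landscape
    rng = np.random.default_rng(42)
    track = simulate_track(habitat, elev, tide, truth, n_steps=2000,
                           bird_id="b0", rng=rng)
    fixes, _ = tracks.filter_fixes(track, SITE_LAT, SITE_LON)
    observed = tracks.steps_from_fixes(fixes)
    config = RunConfig()
    strata, kernel = prepare_bird_strata(
        observed, habitat, elev, tide, config, np.random.default_rng(43))
    full = issa.fit_clogit(strata, issa.candidate_set()[-1])
    return observed, strata, kernel, full


@pytest.fixture()
def toy_strata():
    """3 strata x 3 members with small-integer covariates (closed toy)."""
    rows = []
    data = [
        # stratum, case, wetland code, depth
        (0, "observed", 1, 1.0), (0, "available", 0, 0.0), (0, "available", 1, -1.0),
        (1, "observed", 0, 0.0), (1, "available", 1, 1.0), (1, "available", 0, 1.0),
        (2, "observed", 1, -1.0), (2, "available", 0, 1.0), (2, "available", 0, 0.0),
    ]
    for s, case, w, d in data:
        rows.append((s, case, w, d))
    df = pd.DataFrame(rows, columns=["stratum_id", "case", "code", "depth_end"])
    df["wetland_end"] = pd.Categorical.from_codes(
        df["code"].to_numpy(dtype=np.int8),
        categories=["other_tidal", "eelgrass", "shellfish", "tidal_marsh"])
    return df
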