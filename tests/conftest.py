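"""Shared fixtures: simulated panels at the standard study profiles.

Session-scoped fixtures hold the expensive simulations (the 20-population /
20,000-variant profiles) so calibration, power and acceptance tests share
one generation per profile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from altiscan import selection, sim, stats
from altiscan.model import AltitudeSelectionScan


@pytest.fixture(scope="session")
def null_profile():
    """Null study profile: 20 populations, 20,000 variants, no selected loci."""
    cfg = sim.SimConfig(fraction_selected=0.0, seed=11)
    panel, truth = sim.simulate_balding_nichols(cfg)
    return panel, truth


@pytest.fixture(scope="session")
def null_lmm(null_profile):
    """Kinship, REML null fit, and LMM + naive OLS scans on the null profile."""
    panel, truth = null_profile
    pops = truth.populations
    scan_pops = [c for c in pops.codes if not c.startswith("EX")]
    idx = np.concatenate([panel.population_indices(c) for c in scan_pops])
    sub = panel.subset(sample_idx=idx)
    kin = stats.kinship_grm(sub)
    y = pops.sample_altitudes(sub)
    null_fit = selection.lmm_fit_null(y, kin)
    lmm = selection.lmm_assoc_scan(sub, null_fit)
    ols = selection.ols_altitude_scan(sub, y)
    return {
        "panel": panel,
        "pops": pops,
        "sub": sub,
        "kinship": kin,
        "altitude": y,
        "null_fit": null_fit,
        "p_lmm": lmm["p_lmm"].to_numpy(),
        "p_ols": ols["p_ols"].to_numpy(),
    }


def _fit_replicates(seeds, **cfg_overrides):
    out = []
    for seed in seeds:
        cfg = sim.SimConfig(seed=seed, **cfg_overrides)
        panel, truth = sim.simulate_balding_nichols(cfg)
        model = AltitudeSelectionScan(
            panel, truth.populations, ref_c="EXC", ref_o="EXO"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        out.append((res, truth))
    return out


@pytest.fixture(scope="session")
def power_replicates():
    """Fitted scans over replicate panels with 10 sparse planted loci (slope 0.15/km).

    Sparse planting (0.05% of loci) keeps the planted count below the
    0.1%-of-variants budget the PBS top-rank property refers to.
    """
    return _fit_replicates((42, 43, 44, 45, 46), fraction_selected=0.0005)


@pytest.fixture(scope="session")
def default_profile_scans():
    """Fitted scans over replicates of the full default profile (0.5% selected)."""
    return _fit_replicates((42, 43, 44, 45, 46))


@pytest.fixture(scope="session")
def small_structured():
    """Small two-population panel with strong drift, for kinship/FST structure tests."""
    cfg = sim.SimConfig(
        n_populations=2,
        n_samples=30,
        drift_f=[0.15, 0.15],
        altitude_m=[200.0, 3800.0],
        n_variants=5_000,
        fraction_selected=0.0,
        external_references=False,
        seed=7,
    )
    return sim.simulate_balding_nichols(cfg)
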