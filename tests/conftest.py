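"""Shared fixtures: small simulated trios and the packaged cohort table.

Expensive cohort-scale simulations are session-scoped so the whole suite
pays for them once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import dnmsuite as d
from dnmsuite import simkit
from dnmsuite.pipeline import PipelineConfig, run_pipeline


def small_config(**overrides) -> d.SimulationConfig:
    """A two-window 10-Mb genome: fast, but large enough that DNM placement
    and 20-kb clusters behave normally within a window."""
    kwargs = dict(
        n_trios=1,
        genome_windows=[("chr1", 5_000_000), ("chr2", 5_000_000)],
        base_error_rate=0.0,
    )
    kwargs.update(overrides)
    return d.SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return d.load_cohort()


@pytest.fixture(scope="session")
def trio_error_free():
    """One trio with error-free depths plus its child read fragments."""
    cfg = small_config()
    model = d.RateModel()
    rng = np.random.default_rng(11)
    trio = d.generate_trio(cfg, model, rng, "T001")
    margin = int(cfg.insert_size_mean + 4 * cfg.insert_size_sd)
    frags = d.simulate_reads(trio, cfg, np.random.default_rng(12), "child",
                             regions=simkit.dnm_regions(trio, 5000, margin))
    return cfg, model, trio, frags


@pytest.fixture(scope="session")
def oracle_cohort():
    """20 error-free high-depth trios for exact caller-vs-truth checks."""
    cfg = small_config(n_trios=20, coverage=60.0)
    return cfg, d.generate_cohort(cfg, d.RateModel(), seed=13)


@pytest.fixture(scope="session")
def cohort_run():
    """Full 50-trio pipeline run at the calibrated defaults with
    error-free reads (seed 1): the cohort-recovery reference for phasing,
    clustering and regression checks."""
    cfg = PipelineConfig(seed=1)
    cfg.simulation = dataclasses.replace(cfg.simulation, n_trios=50,
                                         base_error_rate=0.0)
    summary = run_pipeline(cfg)
    return cfg, summary
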