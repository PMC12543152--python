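"""Shared fixtures: deterministic parameter variants and forcing builders."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from silvatau.config import ExperimentConfig, ScenarioConfig
from silvatau.params import DEFAULT_PARAMS, FireParams, ModelParams


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def quiet_params() -> ModelParams:
    """All stochastic death channels and fire disabled: pure growth."""
    pfts = {k: dataclasses.replace(v, mort_background=0.0, longevity=1e12,
                                   ge_threshold=-1.0)
            for k, v in DEFAULT_PARAMS.pfts.items()}
    return DEFAULT_PARAMS.replace(
        pfts=pfts, fire=FireParams(base_rate=0.0),
        disturbance_interval=math.inf)


def constant_forcing(years: int, temp: float = 15.0, precip: float = 800.0,
                     rad: float = 0.75, co2: float = 400.0) -> dict:
    return {
        "temp": np.full(years, temp),
        "precip": np.full(years, precip),
        "rad": np.full(years, rad),
        "co2": np.full(years, co2),
        "ndep": np.full(years, 0.8),
    }


@pytest.fixture
def make_forcing():
    return constant_forcing


@pytest.fixture
def unmanaged_scen() -> ScenarioConfig:
    return ScenarioConfig(option="unmanaged", management_start=0)


@pytest.fixture
def base_scen() -> ScenarioConfig:
    return ScenarioConfig(option="base", management_start=0)


@pytest.fixture(scope="session")
def small_experiment() -> ExperimentConfig:
    return ExperimentConfig(n_cells=4, spinup_years=120)
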