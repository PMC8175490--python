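"""Shared fixtures: reference parameter sets, noiseless study profiles and
the (expensive, session-scoped) parameter-recovery fit."""

import pytest

import packinetics as pk


@pytest.fixture(scope="session")
def opt_params() -> pk.KineticParameters:
    return pk.REFERENCE_OPTIMIZED


@pytest.fixture(scope="session")
def init_params() -> pk.KineticParameters:
    return pk.REFERENCE_INITIAL


@pytest.fixture(scope="session")
def noiseless_profiles(opt_params) -> dict:
    """Ground-truth sampled profiles for the three canonical substrate pairs."""
    return {label: pk.generate_noiseless_profile(
                opt_params, pk.study_conditions(label), label=label)
            for label in ("30/36", "50/60", "100/120")}


@pytest.fixture(scope="session")
def fast_config() -> pk.SearchConfig:
    """Reduced search budget for workflow-level tests where a rough fit
    (RSS_T well below the start, R^2 ~ 1 on noiseless data) suffices."""
    return pk.SearchConfig(max_sweeps=40, refine=False, max_cycles=1)


@pytest.fixture(scope="session")
def recovery_fit(noiseless_profiles, init_params) -> pk.FitResult:
    """Full-depth grid search on noiseless 30/36 + 100/120 truth data,
    started from the literature initial values (the parameter-recovery
    experiment; shared because it is the most expensive computation)."""
    profiles = [noiseless_profiles["30/36"], noiseless_profiles["100/120"]]
    return pk.grid_search_fit(profiles, init_params)
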