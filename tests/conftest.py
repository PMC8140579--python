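import warnings

import pytest

from cryoleak import (
    LeakageSeries,
    SimConfig,
    fit_loglogistic,
    simulate_leakage_experiment,
    simulate_visual_damage,
    standardize_dataset,
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Library warnings (skipped genotypes, caps) are asserted explicitly where
    they matter; elsewhere they are noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def noisefree_cfg() -> SimConfig:
    return SimConfig(n_species=2, noise_sd=0.0, seed=5)


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=17)


@pytest.fixture(scope="session")
def noisefree_experiment(noisefree_cfg):
    return simulate_leakage_experiment(noisefree_cfg)


@pytest.fixture(scope="session")
def default_experiment(default_cfg):
    return simulate_leakage_experiment(default_cfg)


def vd_series(records) -> list[LeakageSeries]:
    groups: dict[tuple[str, str], list] = {}
    for r in records:
        groups.setdefault((r.species, r.genotype), []).append(r)
    return [
        LeakageSeries(
            sp, g, "VD", [r.temperature_C for r in rs], [r.damage_pct for r in rs]
        )
        for (sp, g), rs in groups.items()
    ]


@pytest.fixture(scope="session")
def lim_fits(default_experiment):
    records, _ = default_experiment
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        series = standardize_dataset(records, "I_adj")
        return {
            s.genotype: fit_loglogistic(s, "lim_c0_d100")
            for s in series
            if s.fit_eligible()
        }


@pytest.fixture(scope="session")
def vd_fits(default_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        records = simulate_visual_damage(default_cfg)
        return {
            s.genotype: fit_loglogistic(s, "vd_c0_d100")
            for s in vd_series(records)
            if s.fit_eligible()
        }
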