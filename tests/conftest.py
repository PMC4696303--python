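import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import saltmod as sm
from saltmod import requirements as req

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("default")


def small_config(seed: int = 11, **overrides) -> sm.GeneratorConfig:
    """A reduced simulation (6 stores x 30 weeks) for fast unit tests."""
    kwargs = dict(
        n_stores=6, n_weeks=30, seed=seed,
        outliers=(sm.OutlierSpec("S02", 10, 4.0),
                  sm.OutlierSpec("S02", 11, 4.0)))
    kwargs.update(overrides)
    return sm.GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cfg() -> sm.GeneratorConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_catalogue(small_cfg):
    return sm.generate_catalogue(small_cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_catalogue):
    sales, truth = sm.generate_sales(small_cfg, small_catalogue)
    return sales, truth


@pytest.fixture(scope="session")
def small_linked(small_dataset, small_catalogue) -> pd.DataFrame:
    sales, _ = small_dataset
    return sm.link_sales(sales, small_catalogue)


@pytest.fixture(scope="session")
def nrv_table() -> pd.DataFrame:
    return req.load_nrv()


@pytest.fixture(scope="session")
def weighted_nrv(nrv_table) -> sm.PopulationWeightedNRV:
    demo = sm.generate_demography(sm.GeneratorConfig())
    return sm.weight_nrv(nrv_table, demo,
                         births_per_year=demo.attrs["births_per_year"])


@pytest.fixture(scope="session")
def study():
    """The full default study: generate, link, screen, exclude, weight.

    This is the calibrated 20-store x 104-week dataset the package's
    headline numbers are computed from.
    """
    cfg = sm.GeneratorConfig()
    catalogue = sm.generate_catalogue(cfg)
    sales, truth = sm.generate_sales(cfg, catalogue)
    demo = sm.generate_demography(cfg)
    weighted = sm.weight_nrv(req.load_nrv(), demo,
                             births_per_year=demo.attrs["births_per_year"])
    linked = sm.link_sales(sales, catalogue)
    flagged = sm.screen_outlier_weeks(sm.weekly_energy(linked))
    clean = sm.exclude_weeks(linked, flagged)
    return {
        "config": cfg, "catalogue": catalogue, "sales": sales,
        "truth": truth, "demography": demo, "nrv": weighted,
        "linked": linked, "flagged": flagged, "clean": clean,
    }


@pytest.fixture()
def tiny_table() -> sm.CompositionTable:
    """Three hand-built products for arithmetic-level tests."""
    entries = (
        sm.CompositionEntry("A1", "Canned stew",
                            sm.CategoryCode("18", "182", "1821"),
                            energy_kj_per_100g=500.0,
                            sodium_mg_per_100g=400.0,
                            iodine_ug_per_100g=5.0),
        sm.CompositionEntry("A2", "Iodised salt",
                            sm.CategoryCode("25", "251", "2511"),
                            energy_kj_per_100g=0.0,
                            sodium_mg_per_100g=38000.0,
                            iodine_ug_per_100g=4400.0,
                            is_discretionary_salt=True, is_iodised=True),
        sm.CompositionEntry("A3", "Plain salt",
                            sm.CategoryCode("25", "251", "2512"),
                            energy_kj_per_100g=0.0,
                            sodium_mg_per_100g=38000.0,
                            iodine_ug_per_100g=0.0,
                            is_discretionary_salt=True, is_iodised=False),
    )
    return sm.CompositionTable(entries)


def sales_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["store_id", "week_start",
                                       "product_id", "quantity",
                                       "total_weight_g"])
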