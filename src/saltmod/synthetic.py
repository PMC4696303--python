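"""Calibrated synthetic store-sales, catalogue and demography generator.

Emulates two years of weekly sales from a set of remote community stores
that are the near-exclusive food source for their populations. The
generator is calibration-first: category purchase weights are solved so
that the pooled data reproduce a target sodium/iodine density (mg/MJ,
μg/MJ) and target category shares of each nutrient, while store-level
category multipliers and bounded week-to-week demand variation provide
realistic between-store and between-week spread. Rare "event weeks" can
be injected as multiplicative surges in a store's quantities.

Weekly product quantities are drawn as negative-binomial counts around
the calibrated store-week means. After drawing, each product's effective
unit weight is rescaled once so that pooled totals over non-event weeks
hit the calibration targets exactly — the proportional-fitting step that
makes parameter recovery by the analysis pipeline testable to tight
tolerance. Every emitted quantity is bookkept in a :class:`GroundTruth`
computed from the emitted records themselves.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import CompositionTable

# ---------------------------------------------------------------------------
# default calibration targets
# ---------------------------------------------------------------------------

#: Category shares of total sodium (percent). The residual share is
#: carried by the 'fresh_staples' category.
DEFAULT_NA_SHARES: dict[str, float] = {
    "salt": 19.1,
    "bread": 18.4,
    "pasta_noodles": 3.0,
    "processed_meat": 9.0,
    "dried_fruit": 4.5,
    "cereal_dishes": 4.1,
    "pastries": 4.0,
    "sauces": 3.5,
    "milk": 3.4,
    "soft_drinks": 2.2,
    "eggs": 1.2,
    "other_processed": 18.75,
}

#: Category shares of total iodine (percent); residual to fresh_staples.
DEFAULT_IODINE_SHARES: dict[str, float] = {
    "salt": 21.52,
    "bread": 34.4,
    "pasta_noodles": 0.1,
    "processed_meat": 0.8,
    "dried_fruit": 0.02,
    "cereal_dishes": 1.9,
    "pastries": 0.7,
    "sauces": 0.1,
    "milk": 18.6,
    "soft_drinks": 3.4,
    "eggs": 6.0,
    "other_processed": 6.5,
}

RESIDUAL_CATEGORY = "fresh_staples"

# product spec: id, name, minor code, sodium mg/100g, base iodine μg/100g,
# energy kJ/100g (None = solved to close the energy budget), unit g,
# within-category sodium fraction, discretionary-salt flag, iodised flag
_P = ("product_id", "name", "minor", "na", "iodine", "energy", "unit_g",
      "na_frac", "salt", "iodised")
_PRODUCT_SPECS: dict[str, list[tuple]] = {
    "salt": [  # within-category split computed from the iodised weight share
        ("P001", "Salt, table, iodised", "2511", 38168.0, 4400.0, 0.0,
         500, None, True, True),
        ("P002", "Salt, table, non-iodised", "2512", 38178.0, 20.0, 0.0,
         500, None, True, False),
        ("P003", "Salt, cooking, non-iodised", "2513", 38100.0, 15.0, 0.0,
         1000, None, True, False),
    ],
    "bread": [
        ("P101", "Bread, white", "1221", 459.0, 56.0, 1010.0, 650,
         0.049, False, False),
        ("P102", "Bread, wholemeal", "1222", 443.0, 62.0, 960.0, 650,
         0.848, False, False),
        ("P103", "Bread, mixed grain", "1223", 459.0, 70.0, 1050.0, 650,
         0.103, False, False),
    ],
    "pasta_noodles": [
        ("P104", "Instant noodles, wheat based", "1241", 676.0, 1.0,
         1900.0, 85, 1.0, False, False),
    ],
    "processed_meat": [
        ("P201", "Canned corned meat", "1821", 643.0, 6.0, 950.0, 340,
         0.622, False, False),
        ("P202", "Bacon", "1822", 1289.0, 1.0, 1100.0, 250,
         0.133, False, False),
        ("P203", "Ham", "1823", 1257.0, 8.0, 450.0, 200,
         0.111, False, False),
        ("P204", "Sausages & other processed meat", "1824", 1000.0, 4.0,
         1000.0, 500, 0.134, False, False),
    ],
    "dried_fruit": [
        ("P301", "Plum, salted, preserved", "1631", 8400.0, 4.0, 1200.0,
         150, 1.0, False, False),
    ],
    "cereal_dishes": [
        ("P401", "Savoury pasta/noodle & sauce dish", "1311", 582.0, 42.0,
         650.0, 300, 0.293, False, False),
        ("P402", "Sandwiches & filled rolls", "1312", 342.0, 3.0, 950.0,
         200, 0.341, False, False),
        ("P403", "Other cereal-based dishes", "1313", 450.0, 16.0, 700.0,
         400, 0.366, False, False),
    ],
    "pastries": [
        ("P411", "Savoury pies & sausage rolls", "1321", 490.0, 6.0,
         1100.0, 175, 0.875, False, False),
        ("P412", "Other pastries", "1322", 510.0, 5.0, 1400.0, 150,
         0.125, False, False),
    ],
    "sauces": [
        ("P501", "Savoury sauce, not tomato based", "2411", 3159.0, 5.0,
         800.0, 300, 0.457, False, False),
        ("P502", "Savoury sauce, tomato based", "2412", 756.0, 4.0, 450.0,
         500, 0.286, False, False),
        ("P503", "Gravy powder", "2413", 2000.0, 3.0, 1500.0, 120,
         0.257, False, False),
    ],
    "milk": [
        ("P601", "Milk, powder, cow, dry", "1911", 311.0, 121.0, 2080.0,
         1000, 0.882, False, False),
        ("P602", "Milk, cow, fluid", "1912", 37.0, 22.0, 270.0, 1000,
         0.118, False, False),
    ],
    "soft_drinks": [
        ("P701", "Cola soft drink", "1111", 15.0, 2.0, 170.0, 375,
         1.0, False, False),
    ],
    "eggs": [
        ("P801", "Eggs, chicken", "1711", 150.0, 57.0, 550.0, 700,
         1.0, False, False),
    ],
    "other_processed": [
        ("P901", "Processed foods, aggregate (synthetic stand-in)", "3011",
         400.0, 10.0, 1200.0, 500, 1.0, False, False),
    ],
    RESIDUAL_CATEGORY: [
        ("P902", "Staple foods & fresh produce, aggregate (synthetic "
         "stand-in)", "3111", 50.0, 2.5, None, 1000, 1.0, False, False),
    ],
}

# Demographic cell fractions calibrated (dev-time optimisation, see
# docs/methods.md) so the bundled 2006 NRV table yields the study's
# population-weighted reference values; the age pyramid is a calibration
# artefact emulating a young population, not a census extract.
_DEMOGRAPHY_FRACTIONS: dict[tuple[str, str], float] = {
    ("0-0.5", "F"): 0.000001, ("0-0.5", "M"): 0.000001,
    ("0.5-1", "F"): 0.003192, ("0.5-1", "M"): 0.003215,
    ("1-3", "F"): 0.023509, ("1-3", "M"): 0.029127,
    ("4-8", "F"): 0.085708, ("4-8", "M"): 0.084937,
    ("9-13", "F"): 0.003635, ("9-13", "M"): 0.005137,
    ("14-18", "F"): 0.121650, ("14-18", "M"): 0.081102,
    ("19-30", "F"): 0.080517, ("19-30", "M"): 0.078153,
    ("31-50", "F"): 0.084919, ("31-50", "M"): 0.116829,
    ("51-70", "F"): 0.087895, ("51-70", "M"): 0.083548,
    ("71+", "F"): 0.013453, ("71+", "M"): 0.013472,
}
_DEFAULT_BIRTH_RATE = 0.033999  # births per person per year (calibrated)


class GeneratorError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class OutlierSpec:
    """One injected event week: a store-week whose quantities are scaled."""

    store_id: str
    week_index: int
    magnitude: float = 4.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults emulate 20 community stores serving ~8300 people over 104
    weeks, pooled sodium density 311.0 mg/MJ and iodine density
    23.1 μg/MJ, category nutrient shares matching the source-attribution
    targets, 71.7% of discretionary salt iodised by weight, and two
    injected event weeks in one store.
    """

    n_stores: int = 20
    n_weeks: int = 104
    persons_per_store: float = 415.0
    mean_eer_mj: float = 8.9
    sodium_density_target: float = 311.0   # mg/MJ
    iodine_density_target: float = 23.1    # μg/MJ
    na_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NA_SHARES))
    iodine_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IODINE_SHARES))
    iodised_salt_weight_share: float = 71.7  # percent of salt weight
    between_store_cv: float = 0.15
    salt_store_cv_multiplier: float = 3.0
    week_demand_halfwidth: float = 0.20   # bounded weekly demand swing
    nb_dispersion: float = 300.0          # negative-binomial size k
    store_size_sigma: float = 0.25        # lognormal spread of store sizes
    outliers: tuple[OutlierSpec, ...] = (OutlierSpec("S04", 52, 4.0),
                                         OutlierSpec("S04", 53, 4.0))
    birth_rate_per_person: float = _DEFAULT_BIRTH_RATE
    start_date: date = date(2012, 7, 2)   # a Monday
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stores < 1 or self.n_weeks < 1:
            raise GeneratorError("n_stores and n_weeks must be >= 1")
        for name, shares in (("sodium", self.na_shares),
                             ("iodine", self.iodine_shares)):
            total = sum(shares.values())
            if total > 100.0 + 1e-9:
                raise GeneratorError(
                    f"{name} category shares sum to {total:.2f}% > 100%")
            unknown = set(shares) - set(_PRODUCT_SPECS)
            if unknown:
                raise GeneratorError(
                    f"unknown {name}-share categories: {sorted(unknown)}")
        if not 0.0 <= self.iodised_salt_weight_share <= 100.0:
            raise GeneratorError("iodised_salt_weight_share must be in "
                                 "[0, 100]")
        if not 0.0 <= self.week_demand_halfwidth < 1.0:
            raise GeneratorError("week_demand_halfwidth must be in [0, 1)")
        store_ids = set(self.store_ids)
        for o in self.outliers:
            if o.store_id not in store_ids:
                raise GeneratorError(f"outlier store {o.store_id!r} not "
                                     "among generated stores")
            if not 0 <= o.week_index < self.n_weeks:
                raise GeneratorError(
                    f"outlier week_index {o.week_index} outside "
                    f"[0, {self.n_weeks})")
            if o.magnitude <= 0:
                raise GeneratorError("outlier magnitude must be positive")

    @property
    def store_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_stores))

    @property
    def total_energy_mj(self) -> float:
        """Pooled purchased energy implied by population x EER x duration."""
        return (self.n_stores * self.persons_per_store * self.mean_eer_mj
                * 7.0 * self.n_weeks)

    @property
    def week_starts(self) -> tuple[date, ...]:
        return tuple(self.start_date + timedelta(weeks=w)
                     for w in range(self.n_weeks))


@dataclass(frozen=True)
class GroundTruth:
    """Exact bookkeeping of what the generator emitted.

    All totals/shares are over non-event weeks (the analysis target);
    ``with_outliers`` carries the raw totals including event weeks.
    """

    energy_mj: float
    sodium_mg: float
    iodine_ug: float
    sodium_density: float
    iodine_density: float
    category_sodium_shares: dict[str, float]
    category_iodine_shares: dict[str, float]
    iodised_salt_weight_share: float
    outliers: tuple[OutlierSpec, ...]
    with_outliers: dict[str, float]
    n_records: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["outliers"] = [dataclasses.asdict(o) for o in self.outliers]
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _salt_na_fractions(config: GeneratorConfig) -> dict[str, float]:
    """Within-category sodium fractions of the three salt products from
    the iodised-by-weight share (non-iodised weight split 78/22 between
    table and cooking salt)."""
    w_iod = config.iodised_salt_weight_share / 100.0
    weights = {"P001": w_iod, "P002": (1 - w_iod) * 0.78,
               "P003": (1 - w_iod) * 0.22}
    na = {p[0]: p[3] for p in _PRODUCT_SPECS["salt"]}
    raw = {k: v * na[k] for k, v in weights.items()}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def _category_shares(config: GeneratorConfig, which: str) -> dict[str, float]:
    shares = dict(config.na_shares if which == "na"
                  else config.iodine_shares)
    shares[RESIDUAL_CATEGORY] = 100.0 - sum(shares.values())
    return shares


def calibrate_products(config: GeneratorConfig) -> pd.DataFrame:
    """Solve the per-product purchase weights (g per MJ of pooled energy)
    and calibrated nutrient contents that reproduce the target densities
    and category shares.

    Product sodium targets follow from the category sodium shares and
    within-category splits; purchase weight is then sodium over sodium
    content. The residual category's energy density closes the energy
    budget, and each category's iodine contents are scaled so pooled
    iodine shares and density hit their targets.
    """
    na_shares = _category_shares(config, "na")
    i_shares = _category_shares(config, "iodine")
    salt_fracs = _salt_na_fractions(config)

    rows = []
    for cat, prods in _PRODUCT_SPECS.items():
        for spec in prods:
            d = dict(zip(_P, spec))
            d["category"] = cat
            if cat == "salt":
                d["na_frac"] = salt_fracs[d["product_id"]]
            rows.append(d)
    df = pd.DataFrame(rows)

    na_density = config.sodium_density_target      # mg per MJ
    i_density = config.iodine_density_target       # μg per MJ
    df["na_share_pct"] = df["category"].map(na_shares) * df["na_frac"]
    # grams purchased per MJ of pooled energy
    df["w_g_per_mj"] = df["na_share_pct"] / 100.0 * na_density / (
        df["na"] / 100.0)

    # close the energy budget with the residual category's energy density
    known = df["energy"].notna()
    kj_known = float((df.loc[known, "w_g_per_mj"]
                      * df.loc[known, "energy"] / 100.0).sum())
    w_resid = float(df.loc[~known, "w_g_per_mj"].sum())
    if w_resid <= 0:
        raise GeneratorError("residual category has no purchase weight; "
                             "cannot close the energy budget")
    e_resid = (1000.0 - kj_known) / (w_resid / 100.0)
    if not 100.0 <= e_resid <= 3000.0:
        raise GeneratorError(
            f"implied residual energy density {e_resid:.0f} kJ/100g is "
            "implausible; adjust shares or energy contents")
    df.loc[~known, "energy"] = e_resid

    # scale each category's iodine contents to its target iodine share
    for cat, grp in df.groupby("category"):
        target_ug = i_shares[cat] / 100.0 * i_density
        base_ug = float((grp["w_g_per_mj"] * grp["iodine"] / 100.0).sum())
        if base_ug <= 0:
            if target_ug > 1e-12:
                raise GeneratorError(
                    f"category {cat} has zero base iodine but a positive "
                    "iodine-share target")
            continue
        df.loc[grp.index, "iodine"] *= target_ug / base_ug

    return df


def generate_catalogue(config: GeneratorConfig | None = None
                       ) -> CompositionTable:
    """Build the calibrated composition table for the synthetic study."""
    config = config or GeneratorConfig()
    df = calibrate_products(config)
    out = pd.DataFrame({
        "product_id": df["product_id"],
        "name": df["name"],
        "major_code": df["minor"].str[:2],
        "sub_major_code": df["minor"].str[:3],
        "minor_code": df["minor"],
        "energy_kj_100g": df["energy"].astype(float),
        "sodium_mg_100g": df["na"].astype(float),
        "iodine_ug_100g": df["iodine"].astype(float),
        "is_discretionary_salt": df["salt"],
        "is_iodised": df["iodised"],
    })
    return CompositionTable.from_dataframe(out)


# ---------------------------------------------------------------------------
# sales generation
# ---------------------------------------------------------------------------

def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       k: float) -> np.ndarray:
    """NB counts with mean ``mean`` and dispersion ``k`` (var = m + m^2/k)."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    p = k / (k + mean[pos])
    out[pos] = rng.negative_binomial(k, p)
    return out


def generate_sales(config: GeneratorConfig | None = None,
                   catalogue: CompositionTable | None = None
                   ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw weekly store-sales records and their exact bookkeeping.

    Returns a long DataFrame (store_id, week_start, product_id, quantity,
    total_weight_g) and the :class:`GroundTruth` recomputed from the
    emitted records.
    """
    config = config or GeneratorConfig()
    products = calibrate_products(config)
    if catalogue is None:
        catalogue = generate_catalogue(config)
    rng = np.random.default_rng(config.seed)

    n_p, n_s, n_w = len(products), config.n_stores, config.n_weeks
    store_ids = np.array(config.store_ids)
    e_total = config.total_energy_mj

    # store sizes (population share) and store-level category multipliers
    size = rng.lognormal(0.0, config.store_size_sigma, n_s)
    store_energy = e_total * size / size.sum()

    cats = products["category"].to_numpy()
    uniq_cats = pd.unique(cats)
    cv = np.where(uniq_cats == "salt",
                  config.between_store_cv * config.salt_store_cv_multiplier,
                  config.between_store_cv)
    sigma = np.sqrt(np.log1p(cv ** 2))
    mult = rng.lognormal(-0.5 * sigma[None, :] ** 2, sigma[None, :],
                         (n_s, len(uniq_cats)))
    # keep the pooled expectation at target: normalise by the
    # store-energy-weighted mean of each category multiplier
    wmean = np.average(mult, axis=0, weights=store_energy)
    mult /= wmean[None, :]
    cat_idx = pd.Series(range(len(uniq_cats)), index=uniq_cats)
    m_sp = mult[:, cat_idx[cats].to_numpy()]          # (store, product)

    # bounded week-to-week demand swings shared by all products of a store
    a = config.week_demand_halfwidth
    demand = 1.0 - a + 2.0 * a * rng.beta(2.0, 2.0, (n_s, n_w))

    w_p = products["w_g_per_mj"].to_numpy()
    unit = products["unit_g"].to_numpy(dtype=float)
    lam = (w_p[None, :, None] / unit[None, :, None]
           * (store_energy[:, None, None] / n_w)
           * m_sp[:, :, None] * demand[:, None, :])
    qty = _negative_binomial(rng, lam, config.nb_dispersion)

    outlier_mask = np.zeros((n_s, n_w), dtype=bool)
    for o in config.outliers:
        outlier_mask[int(np.where(store_ids == o.store_id)[0][0]),
                     o.week_index] = True

    # ensure every product appears at least once outside event weeks
    clean_weeks = ~outlier_mask
    q_clean = qty[:, :, :].transpose(1, 0, 2)[:, clean_weeks]  # (p, sw)
    zero = q_clean.sum(axis=1) == 0
    if zero.any():
        s_big = int(np.argmax(store_energy))
        w_ok = int(np.flatnonzero(clean_weeks[s_big])[0])
        qty[s_big, zero, w_ok] = 1

    # one-pass proportional correction: adjust effective unit weights so
    # pooled non-event-week totals equal the calibration targets exactly
    q_clean_tot = qty.transpose(1, 0, 2)[:, clean_weeks].sum(axis=1)
    unit_eff = (w_p * e_total) / q_clean_tot

    # inject event weeks by scaling that week's quantities
    for o in config.outliers:
        s = int(np.where(store_ids == o.store_id)[0][0])
        qty[s, :, o.week_index] = np.round(
            qty[s, :, o.week_index] * o.magnitude).astype(np.int64)

    weight = qty * unit_eff[None, :, None]

    s_ix, p_ix, w_ix = np.nonzero(qty)
    week_starts = np.array([d.isoformat() for d in config.week_starts])
    sales = pd.DataFrame({
        "store_id": store_ids[s_ix],
        "week_start": week_starts[w_ix],
        "product_id": products["product_id"].to_numpy()[p_ix],
        "quantity": qty[s_ix, p_ix, w_ix],
        "total_weight_g": weight[s_ix, p_ix, w_ix],
    }).sort_values(["store_id", "week_start", "product_id"],
                   ignore_index=True)

    truth = _bookkeep(config, products, qty, weight, outlier_mask,
                      len(sales))
    return sales, truth


def _bookkeep(config: GeneratorConfig, products: pd.DataFrame,
              qty: np.ndarray, weight: np.ndarray,
              outlier_mask: np.ndarray, n_records: int) -> GroundTruth:
    """Exact totals/shares from the emitted quantity and weight arrays."""
    clean = ~outlier_mask
    w_clean = weight.transpose(1, 0, 2)[:, clean].sum(axis=1)  # per product
    w_all = weight.transpose(1, 0, 2).reshape(len(products), -1).sum(axis=1)

    e = products["energy"].to_numpy() / 100.0      # kJ per g
    na = products["na"].to_numpy() / 100.0         # mg per g
    iod = products["iodine"].to_numpy() / 100.0    # μg per g

    def totals(w: np.ndarray) -> tuple[float, float, float]:
        return (float((w * e).sum()) / 1000.0, float((w * na).sum()),
                float((w * iod).sum()))

    energy_mj, sodium_mg, iodine_ug = totals(w_clean)
    e_all, na_all, i_all = totals(w_all)

    cat = products["category"]
    na_by_cat = pd.Series(w_clean * na * 100 / 100, index=products.index
                          ).groupby(cat).sum()
    i_by_cat = pd.Series(w_clean * iod, index=products.index
                         ).groupby(cat).sum()

    salt_rows = products["salt"].to_numpy()
    salt_w = float(w_clean[salt_rows].sum())
    iod_w = float(w_clean[salt_rows & products["iodised"].to_numpy()].sum())

    return GroundTruth(
        energy_mj=energy_mj,
        sodium_mg=sodium_mg,
        iodine_ug=iodine_ug,
        sodium_density=sodium_mg / energy_mj,
        iodine_density=iodine_ug / energy_mj,
        category_sodium_shares={str(k): 100.0 * v / sodium_mg
                                for k, v in na_by_cat.items()},
        category_iodine_shares={str(k): 100.0 * v / iodine_ug
                                for k, v in i_by_cat.items()},
        iodised_salt_weight_share=100.0 * iod_w / salt_w if salt_w else 0.0,
        outliers=config.outliers,
        with_outliers={"energy_mj": e_all, "sodium_mg": na_all,
                       "iodine_ug": i_all},
        n_records=n_records,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------

def generate_demography(config: GeneratorConfig | None = None
                        ) -> pd.DataFrame:
    """Age/gender counts for the store populations.

    The frozen cell fractions are calibrated so that, with the bundled
    2006 NRV table, population weighting reproduces the study's weighted
    reference values. Counts are integers (largest-remainder rounding)
    summing exactly to the configured population; births per year ride on
    ``attrs['births_per_year']`` and a total row when written to CSV.
    """
    config = config or GeneratorConfig()
    population = round(config.n_stores * config.persons_per_store)
    items = sorted(_DEMOGRAPHY_FRACTIONS.items())
    raw = np.array([f * population for _, f in items])
    counts = np.floor(raw).astype(int)
    remainder = population - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    counts[order[:remainder]] += 1
    df = pd.DataFrame(
        [{"age_band": band, "gender": gender, "count": int(c)}
         for ((band, gender), _), c in zip(items, counts)])
    df.attrs["births_per_year"] = round(
        config.birth_rate_per_person * population)
    return df


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _write_with_seed(df: pd.DataFrame, path: str | Path, seed: int) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# generated by saltmod synthetic module, seed={seed}\n")
        df.to_csv(fh, index=False)


def write_sales(sales: pd.DataFrame, path: str | Path, seed: int) -> None:
    _write_with_seed(sales, path, seed)


def write_demography(demography: pd.DataFrame, path: str | Path,
                     seed: int) -> None:
    df = demography.copy()
    df["births_per_year"] = ""
    total = pd.DataFrame([{"age_band": "all", "gender": "all",
                           "count": int(df["count"].sum()),
                           "births_per_year":
                           demography.attrs.get("births_per_year", 0)}])
    _write_with_seed(pd.concat([df, total], ignore_index=True), path, seed)


def write_catalogue(catalogue: CompositionTable, path: str | Path,
                    seed: int) -> None:
    catalogue.write_csv(path, header_comment=f"generated by saltmod "
                        f"synthetic module, seed={seed}")
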