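"""Apparent-consumption aggregation from linked store-sales records.

Given sales records linked to a composition table, this module computes
nutrient totals (pooled, per store, or per store-week), sodium/iodine
densities per MJ of purchased energy, category-level source attribution,
a discretionary-salt purchase profile, and a reproducible robust-z screen
for outlying sales weeks.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import SUBMAJOR_NAMES

LEVEL_COLUMNS = {"major": "major_code", "sub_major": "sub_major_code",
                 "minor": "minor_code"}

NUTRIENT_SUMS = {"energy_kj": "sum", "sodium_mg": "sum", "iodine_ug": "sum",
                 "total_weight_g": "sum"}


class UndefinedDensityError(ValueError):
    """Nutrient density is undefined because total energy is zero."""


@dataclass(frozen=True)
class NutrientTotals:
    """Energy (MJ), sodium (mg) and iodine (μg) totals for a record set."""

    energy_mj: float
    sodium_mg: float
    iodine_ug: float

    def __add__(self, other: "NutrientTotals") -> "NutrientTotals":
        return NutrientTotals(self.energy_mj + other.energy_mj,
                              self.sodium_mg + other.sodium_mg,
                              self.iodine_ug + other.iodine_ug)


@dataclass(frozen=True)
class NutrientDensity:
    """Sodium (mg) and iodine (μg) per MJ of dietary energy."""

    sodium_mg_per_mj: float
    iodine_ug_per_mj: float


def aggregate(linked: pd.DataFrame, by: str = "pooled"
              ) -> NutrientTotals | pd.DataFrame:
    """Nutrient totals over linked records.

    ``by='pooled'`` returns a single :class:`NutrientTotals`;
    ``by='store'`` / ``by='store-week'`` return a DataFrame indexed by
    store (and week) with ``energy_mj``, ``sodium_mg``, ``iodine_ug``
    columns. An empty record set yields totals of zero.
    """
    if by == "pooled":
        if linked.empty:
            return NutrientTotals(0.0, 0.0, 0.0)
        return NutrientTotals(float(linked["energy_kj"].sum()) / 1000.0,
                              float(linked["sodium_mg"].sum()),
                              float(linked["iodine_ug"].sum()))
    keys = {"store": ["store_id"], "store-week": ["store_id", "week_start"]}
    if by not in keys:
        raise ValueError(f"unknown grouping {by!r}; expected 'pooled', "
                         "'store' or 'store-week'")
    grouped = (linked.groupby(keys[by])[["energy_kj", "sodium_mg",
                                         "iodine_ug"]].sum())
    grouped["energy_mj"] = grouped.pop("energy_kj") / 1000.0
    return grouped[["energy_mj", "sodium_mg", "iodine_ug"]]


def density(totals: NutrientTotals) -> NutrientDensity:
    """Sodium and iodine density per MJ; total energy must be positive."""
    if totals.energy_mj <= 0:
        raise UndefinedDensityError(
            f"density undefined for energy {totals.energy_mj} MJ")
    return NutrientDensity(totals.sodium_mg / totals.energy_mj,
                           totals.iodine_ug / totals.energy_mj)


def store_densities(linked: pd.DataFrame) -> pd.DataFrame:
    """Per-store sodium and iodine density (mg/MJ, μg/MJ)."""
    per_store = aggregate(linked, by="store")
    if (per_store["energy_mj"] <= 0).any():
        bad = per_store.index[per_store["energy_mj"] <= 0].tolist()
        raise UndefinedDensityError(f"zero purchased energy for store(s) "
                                    f"{bad}")
    return pd.DataFrame({
        "sodium_mg_per_mj": per_store["sodium_mg"] / per_store["energy_mj"],
        "iodine_ug_per_mj": per_store["iodine_ug"] / per_store["energy_mj"],
    })


def attribute_sources(linked: pd.DataFrame, level: str = "sub_major"
                      ) -> pd.DataFrame:
    """Category shares of sodium and iodine at a taxonomy level.

    Returns a DataFrame indexed by category code with the percent of total
    sodium/iodine contributed by each category and the weight-weighted
    mean nutrient content per 100 g of that category's purchased weight.
    """
    if level not in LEVEL_COLUMNS:
        raise ValueError(f"unknown taxonomy level {level!r}; expected one of "
                         f"{sorted(LEVEL_COLUMNS)}")
    if linked.empty:
        raise ValueError("cannot attribute sources of an empty record set")
    col = LEVEL_COLUMNS[level]
    g = linked.groupby(col)[["sodium_mg", "iodine_ug",
                             "total_weight_g"]].sum()
    total_na = g["sodium_mg"].sum()
    total_i = g["iodine_ug"].sum()
    out = pd.DataFrame({
        "share_sodium_pct": 100.0 * g["sodium_mg"] / total_na,
        "share_iodine_pct": 100.0 * g["iodine_ug"] / total_i,
        "sodium_mg_per_100g": 100.0 * g["sodium_mg"] / g["total_weight_g"],
        "iodine_ug_per_100g": 100.0 * g["iodine_ug"] / g["total_weight_g"],
        "weight_g": g["total_weight_g"],
    })
    if level == "sub_major":
        out.insert(0, "category",
                   [SUBMAJOR_NAMES.get(c, "") for c in out.index])
    out.index.name = level
    out.attrs["level"] = level
    return out


def weekly_energy(linked: pd.DataFrame) -> pd.DataFrame:
    """Weekly purchased energy (MJ) per store, long format."""
    w = (linked.groupby(["store_id", "week_start"])["energy_kj"].sum()
         / 1000.0)
    return w.rename("energy_mj").reset_index()


def screen_outlier_weeks(weekly: pd.DataFrame, threshold: float = 4.0,
                         min_weeks: int = 8) -> pd.DataFrame:
    """Flag store-weeks whose energy deviates from the store median.

    A week is flagged when ``|energy - median| / (1.4826 * MAD)`` exceeds
    ``threshold`` for its store. When MAD is zero (an all-but-identical
    series) only exact deviants from the median are flagged. Stores with
    fewer than ``min_weeks`` weeks are an error — the screen would be
    meaningless.
    """
    flags = []
    for store, grp in weekly.groupby("store_id"):
        x = grp["energy_mj"].to_numpy(float)
        if len(x) < min_weeks:
            raise ValueError(
                f"store {store}: only {len(x)} weeks of data "
                f"(minimum {min_weeks}) — cannot screen outliers")
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0.0:
            z = np.where(x == med, 0.0, np.inf)
        else:
            z = np.abs(x - med) / (1.4826 * mad)
        hit = z > threshold
        for i in np.flatnonzero(hit):
            flags.append({"store_id": store,
                          "week_start": grp["week_start"].iloc[i],
                          "energy_mj": x[i], "robust_z": z[i]})
    cols = ["store_id", "week_start", "energy_mj", "robust_z"]
    return pd.DataFrame(flags, columns=cols)


def exclude_weeks(linked: pd.DataFrame, flagged: pd.DataFrame
                  ) -> pd.DataFrame:
    """Drop all records belonging to flagged (store, week) pairs."""
    if flagged.empty:
        return linked
    key = pd.MultiIndex.from_frame(flagged[["store_id", "week_start"]])
    idx = pd.MultiIndex.from_frame(linked[["store_id", "week_start"]])
    return linked[~idx.isin(key)]


def salt_profile(linked: pd.DataFrame) -> float:
    """Iodised share (percent, by weight) of all discretionary salt
    purchased."""
    salt = linked[linked["is_discretionary_salt"].astype(bool)]
    total = float(salt["total_weight_g"].sum())
    if total == 0:
        raise ValueError("no discretionary-salt purchases in record set")
    iodised = float(salt.loc[salt["is_iodised"].astype(bool),
                             "total_weight_g"].sum())
    return 100.0 * iodised / total


def plot_weekly_energy(weekly: pd.DataFrame, path: str | Path,
                       flagged: pd.DataFrame | None = None) -> None:
    """Diagnostic plot of weekly purchased energy per store."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 5))
    for store, grp in weekly.groupby("store_id"):
        ax.plot(pd.to_datetime(grp["week_start"]), grp["energy_mj"],
                lw=0.8, alpha=0.7, label=str(store))
    if flagged is not None and not flagged.empty:
        ax.scatter(pd.to_datetime(flagged["week_start"]),
                   flagged["energy_mj"], color="red", zorder=5,
                   label="flagged")
    ax.set_xlabel("week")
    ax.set_ylabel("purchased energy (MJ)")
    ax.set_title("Weekly store-sales energy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
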