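"""Population-weighted nutrient reference values and energy requirements.

Reference values are the 2006 Australian/New Zealand NRVs per age/gender
band (bundled as a versioned CSV; any table with the same columns can be
substituted). The estimated energy requirement (EER) for each band is
Schofield basal metabolic rate times a physical activity level, using a
reference body weight: BMI 22 at 1.70 m (men) / 1.60 m (women) for adults,
and bundled reference weights for children and adolescents.

Population weighting multiplies each band's reference value by the number
of people in that band, sums, and divides by the total count. Women aged
19-50 are fractionally reallocated to pregnancy and lactation reference
rows according to the community birth rate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NRV_VALUE_FIELDS = ["sodium_ai_mid", "sodium_ul", "iodine_rdi",
                    "iodine_ear", "iodine_ul"]

REPRODUCTIVE_BANDS = ("19-30", "31-50")


class RequirementsError(ValueError):
    """Demography or NRV table problem (unmatched cell, bad counts...)."""


@dataclass(frozen=True)
class EnergyParams:
    """Parameters of the EER calculation.

    pal: physical activity level multiplier on BMR ('sedentary' = 1.6).
    reference_bmi: BMI used with the reference heights to derive adult
        reference weight (kg/m^2).
    growth_allowance_frac: fractional addition to EER for under-19 bands
        (defaults to zero; child EER is BMR x PAL alone).
    """

    pal: float = 1.6
    height_m_male: float = 1.70
    height_m_female: float = 1.60
    reference_bmi: float = 22.0
    growth_allowance_frac: float = 0.0


@dataclass(frozen=True)
class PopulationWeightedNRV:
    """Count-weighted reference values, per day and (via the weighted EER)
    per MJ."""

    sodium_ai_mid_day: float
    sodium_ul_day: float
    iodine_rdi_day: float
    iodine_ear_day: float
    iodine_ul_day: float
    eer_mj: float

    @property
    def sodium_ai_mid_per_mj(self) -> float:
        return self.sodium_ai_mid_day / self.eer_mj

    @property
    def sodium_ul_per_mj(self) -> float:
        return self.sodium_ul_day / self.eer_mj

    @property
    def iodine_rdi_per_mj(self) -> float:
        return self.iodine_rdi_day / self.eer_mj

    @property
    def iodine_ear_per_mj(self) -> float:
        return self.iodine_ear_day / self.eer_mj

    @property
    def iodine_ul_per_mj(self) -> float:
        return self.iodine_ul_day / self.eer_mj

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            ("sodium", "AI (midpoint)", self.sodium_ai_mid_day,
             self.sodium_ai_mid_per_mj),
            ("sodium", "UL", self.sodium_ul_day, self.sodium_ul_per_mj),
            ("iodine", "RDI", self.iodine_rdi_day, self.iodine_rdi_per_mj),
            ("iodine", "EAR", self.iodine_ear_day, self.iodine_ear_per_mj),
            ("iodine", "UL", self.iodine_ul_day, self.iodine_ul_per_mj),
        ]
        return pd.DataFrame(rows, columns=["nutrient", "reference",
                                           "per_day", "per_mj"])


def _data_path(name: str):
    return resources.files("saltmod.data").joinpath(name)


def load_nrv(path: str | Path | None = None) -> pd.DataFrame:
    """Load an NRV table (bundled 2006 AU/NZ values by default)."""
    src = path if path is not None else _data_path("nrv_2006_au.csv")
    with resources.as_file(src) if path is None else _noop(src) as p:
        df = pd.read_csv(p, comment="#", dtype={"age_band": str,
                                                "gender": str})
    required = {"age_band", "gender", "sodium_ai_low", "sodium_ai_high",
                "sodium_ul", "iodine_rdi", "iodine_ear", "iodine_ul",
                "eer_offset_mj"}
    missing = required - set(df.columns)
    if missing:
        raise RequirementsError(f"NRV table missing column(s): "
                                f"{sorted(missing)}")
    bad = df["sodium_ai_low"] > df["sodium_ai_high"]
    if bad.any():
        raise RequirementsError("sodium AI low exceeds AI high in NRV table")
    df["sodium_ai_mid"] = (df["sodium_ai_low"] + df["sodium_ai_high"]) / 2.0
    return df


class _noop:
    def __init__(self, v):
        self.v = v

    def __enter__(self):
        return self.v

    def __exit__(self, *a):
        return False


def load_schofield(path: str | Path | None = None) -> pd.DataFrame:
    """Schofield BMR coefficient table (MJ/day; BMR = slope*kg +
    intercept)."""
    src = path if path is not None else _data_path("schofield_bmr.csv")
    with resources.as_file(src) if path is None else _noop(src) as p:
        return pd.read_csv(p, comment="#")


def load_demography(path: str | Path) -> pd.DataFrame:
    """Demography CSV: age_band,gender,count[,births_per_year].

    Births may be carried on a single population-total row
    (age_band='all'); that row is excluded from the cell list and its
    births attached as ``attrs['births_per_year']``.
    """
    df = pd.read_csv(path, comment="#", dtype={"age_band": str,
                                               "gender": str})
    for col in ("age_band", "gender", "count"):
        if col not in df.columns:
            raise RequirementsError(f"demography file missing column {col!r}")
    births = 0.0
    total_row = df["age_band"].str.lower() == "all"
    if "births_per_year" in df.columns:
        vals = pd.to_numeric(df["births_per_year"], errors="coerce")
        births = float(vals.dropna().sum())
    cells = df[~total_row].copy()
    cells["count"] = pd.to_numeric(cells["count"])
    if (cells["count"] < 0).any():
        raise RequirementsError("negative count in demography table")
    cells = cells[["age_band", "gender", "count"]].reset_index(drop=True)
    cells.attrs["births_per_year"] = births
    return cells


def _band_midpoint_age(age_band: str) -> float:
    if age_band.endswith("+"):
        return float(age_band[:-1]) + 5.0
    lo, hi = (float(x) for x in age_band.split("-"))
    return (lo + hi) / 2.0


def reference_weight(age_band: str, gender: str, params: EnergyParams,
                     nrv: pd.DataFrame) -> float:
    """Reference body weight: BMI-based for adults (19+), table-based for
    children."""
    age = _band_midpoint_age(age_band)
    if age >= 19:
        h = (params.height_m_male if gender == "M"
             else params.height_m_female)
        return params.reference_bmi * h * h
    row = nrv[(nrv["age_band"] == age_band) & (nrv["gender"] == gender)]
    if row.empty or pd.isna(row["ref_weight_kg"].iloc[0]):
        raise RequirementsError(
            f"no reference weight for band {age_band}/{gender}")
    return float(row["ref_weight_kg"].iloc[0])


def eer_for_group(age_band: str, gender: str,
                  params: EnergyParams = EnergyParams(), *,
                  nrv: pd.DataFrame | None = None,
                  schofield: pd.DataFrame | None = None) -> float:
    """Estimated energy requirement (MJ/day) for an age/gender band.

    EER = Schofield BMR(reference weight) x PAL, with an optional growth
    allowance for under-19 bands.
    """
    if gender not in ("M", "F"):
        raise RequirementsError(f"unknown gender {gender!r}")
    nrv = load_nrv() if nrv is None else nrv
    schofield = load_schofield() if schofield is None else schofield
    age = _band_midpoint_age(age_band)
    row = schofield[(schofield["gender"] == gender)
                    & (schofield["age_lo"] <= age)
                    & (age < schofield["age_hi"])]
    if row.empty:
        raise RequirementsError(
            f"age band {age_band!r} (midpoint {age}) not covered by the "
            "BMR coefficient table")
    w = reference_weight(age_band, gender, params, nrv)
    bmr = float(row["slope_mj_per_kg"].iloc[0]) * w + float(
        row["intercept_mj"].iloc[0])
    eer = bmr * params.pal
    if age < 19:
        eer *= 1.0 + params.growth_allowance_frac
    return eer


def pregnancy_lactation_fractions(births_per_year: float,
                                  women_19_50: float, *,
                                  gestation_weeks: float = 40.0,
                                  lactation_months: float = 6.0
                                  ) -> tuple[float, float]:
    """Fractions of women 19-50 pregnant / lactating at any one time.

    pregnant = births x (gestation/52) / women; lactating = births x
    (lactation/12) / women; each clipped to [0, 1] with a warning when
    clipping occurs.
    """
    if women_19_50 <= 0:
        raise RequirementsError("women_19_50 must be positive")
    preg = births_per_year * (gestation_weeks / 52.0) / women_19_50
    lact = births_per_year * (lactation_months / 12.0) / women_19_50
    if preg > 1 or lact > 1 or preg + lact > 1:
        log.warning("pregnancy/lactation fractions clipped (preg=%.3f, "
                    "lact=%.3f)", preg, lact)
        total = preg + lact
        if total > 1:
            preg, lact = preg / total, lact / total
    return min(preg, 1.0), min(lact, 1.0)


def _expanded_cells(demography: pd.DataFrame, nrv: pd.DataFrame,
                    params: EnergyParams,
                    births_per_year: float | None,
                    gestation_weeks: float, lactation_months: float
                    ) -> pd.DataFrame:
    """Demographic cells with women 19-50 fractionally reallocated to
    pregnancy/lactation rows, joined to NRV rows and per-band EERs."""
    if births_per_year is None:
        births_per_year = float(demography.attrs.get("births_per_year", 0.0))
    cells = demography.copy()
    women = float(cells.loc[(cells["gender"] == "F")
                            & cells["age_band"].isin(REPRODUCTIVE_BANDS),
                            "count"].sum())
    preg = lact = 0.0
    if births_per_year > 0:
        if women == 0:
            raise RequirementsError(
                "births reported but no women aged 19-50 in demography")
        preg, lact = pregnancy_lactation_fractions(
            births_per_year, women, gestation_weeks=gestation_weeks,
            lactation_months=lactation_months)

    schofield = load_schofield()
    rows = []
    for cell in cells.to_dict("records"):
        n = float(cell["count"])
        if n == 0:
            continue
        gender = cell["gender"]
        reallocatable = (gender == "F"
                         and cell["age_band"] in REPRODUCTIVE_BANDS)
        base_eer = eer_for_group(cell["age_band"], gender, params,
                                 nrv=nrv, schofield=schofield)
        parts = [(cell["age_band"], n * (1 - preg - lact) if reallocatable
                  else n)]
        if reallocatable:
            parts += [("pregnancy", n * preg), ("lactation", n * lact)]
        for band, count in parts:
            if count <= 0:
                continue
            match = nrv[(nrv["age_band"] == band)
                        & (nrv["gender"] == gender)]
            if match.empty:
                raise RequirementsError(
                    f"no NRV row for cell {band}/{gender}")
            r = match.iloc[0]
            rows.append({
                "age_band": band, "gender": gender, "count": count,
                "eer_mj": base_eer + float(r["eer_offset_mj"]),
                **{f: float(r[f]) if pd.notna(r[f]) else np.nan
                   for f in NRV_VALUE_FIELDS},
            })
    return pd.DataFrame(rows)


def weight_nrv(nrv: pd.DataFrame, demography: pd.DataFrame,
               params: EnergyParams = EnergyParams(), *,
               births_per_year: float | None = None,
               gestation_weeks: float = 40.0,
               lactation_months: float = 6.0) -> PopulationWeightedNRV:
    """Count-weighted mean of every reference value plus the weighted EER.

    Reference values not defined for a band (e.g. no sodium UL for
    infants) are weighted over the cells where they are defined. The
    sodium AI enters as the midpoint of its low-high range.
    """
    cells = _expanded_cells(demography, nrv, params, births_per_year,
                            gestation_weeks, lactation_months)
    if cells.empty:
        raise RequirementsError("demography contains no people")

    def wmean(col: str) -> float:
        sub = cells[["count", col]].dropna()
        if sub.empty:
            raise RequirementsError(f"no cells define {col}")
        return float(np.average(sub[col], weights=sub["count"]))

    return PopulationWeightedNRV(
        sodium_ai_mid_day=wmean("sodium_ai_mid"),
        sodium_ul_day=wmean("sodium_ul"),
        iodine_rdi_day=wmean("iodine_rdi"),
        iodine_ear_day=wmean("iodine_ear"),
        iodine_ul_day=wmean("iodine_ul"),
        eer_mj=wmean("eer_mj"),
    )
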