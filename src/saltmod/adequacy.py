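"""Intake estimates and percent-of-recommendation reporting.

The estimated average intake is the nutrient density of purchased food
(mg or μg per MJ) multiplied by the population-weighted EER — the amount
the average person meeting their energy requirement would consume.
Percent-of-recommendation is reported on both a per-day basis
(intake/day over NRV/day) and a per-MJ basis (density over NRV density);
the two agree exactly before rounding, but published tables sometimes mix
the bases after rounding, so both are emitted explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .consumption import NutrientDensity
from .requirements import PopulationWeightedNRV


@dataclass(frozen=True)
class IntakeEstimate:
    """Estimated average daily intake of one nutrient with
    percent-of-recommendation values on both bases."""

    nutrient: str
    density_per_mj: float
    intake_per_day: float
    pct_per_day: dict[str, float] = field(default_factory=dict)
    pct_per_mj: dict[str, float] = field(default_factory=dict)


def _refs_for(nrv: PopulationWeightedNRV, nutrient: str
              ) -> dict[str, float]:
    if nutrient == "sodium":
        return {"AI": nrv.sodium_ai_mid_day, "UL": nrv.sodium_ul_day}
    return {"RDI": nrv.iodine_rdi_day, "EAR": nrv.iodine_ear_day,
            "UL": nrv.iodine_ul_day}


def estimate_intake(density: NutrientDensity, nrv: PopulationWeightedNRV
                    ) -> dict[str, IntakeEstimate]:
    """Per-day intakes and %-of-recommendation for sodium and iodine."""
    if nrv.eer_mj <= 0:
        raise ValueError("population-weighted EER must be positive")
    out: dict[str, IntakeEstimate] = {}
    for nutrient, dens in (("sodium", density.sodium_mg_per_mj),
                           ("iodine", density.iodine_ug_per_mj)):
        intake = dens * nrv.eer_mj
        refs = _refs_for(nrv, nutrient)
        pct_day = {k: 100.0 * intake / v for k, v in refs.items()}
        pct_mj = {k: 100.0 * dens / (v / nrv.eer_mj)
                  for k, v in refs.items()}
        out[nutrient] = IntakeEstimate(nutrient, dens, intake, pct_day,
                                       pct_mj)
    return out


def adequacy_report(pooled: NutrientDensity, nrv: PopulationWeightedNRV,
                    per_store: pd.DataFrame | None = None, *,
                    round_output: bool = True) -> pd.DataFrame:
    """Table of apparent consumption against population-weighted NRVs.

    One row per nutrient/reference pair with density, per-day intake, the
    NRV on both bases, both percent bases, and (when per-store densities
    are supplied) the min-max range of per-day intake and per-day percent
    across individual stores. Rounding follows the usual presentation:
    per-day values to integers, per-MJ values to one decimal, percents to
    integers.
    """
    est = estimate_intake(pooled, nrv)
    rows = []
    for nutrient, ref_names in (("sodium", ("AI", "UL")),
                                ("iodine", ("UL", "RDI", "EAR"))):
        e = est[nutrient]
        col = ("sodium_mg_per_mj" if nutrient == "sodium"
               else "iodine_ug_per_mj")
        store_dens = (per_store[col] if per_store is not None else None)
        refs = _refs_for(nrv, nutrient)
        for ref in ref_names:
            row = {
                "nutrient": nutrient,
                "reference": ref,
                "density_per_mj": e.density_per_mj,
                "intake_per_day": e.intake_per_day,
                "nrv_per_mj": refs[ref] / nrv.eer_mj,
                "nrv_per_day": refs[ref],
                "pct_per_mj": e.pct_per_mj[ref],
                "pct_per_day": e.pct_per_day[ref],
            }
            if store_dens is not None:
                intakes = store_dens * nrv.eer_mj
                row["intake_per_day_min"] = float(intakes.min())
                row["intake_per_day_max"] = float(intakes.max())
                row["pct_per_day_min"] = float(
                    (100.0 * intakes / refs[ref]).min())
                row["pct_per_day_max"] = float(
                    (100.0 * intakes / refs[ref]).max())
            rows.append(row)
    report = pd.DataFrame(rows)
    if round_output:
        for c in report.columns:
            if c.startswith(("intake", "nrv_per_day", "pct")):
                report[c] = report[c].round(0).astype(int)
            elif c in ("density_per_mj", "nrv_per_mj"):
                report[c] = report[c].round(1)
    return report
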