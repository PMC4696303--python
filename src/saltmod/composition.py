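"""Food-composition table I/O, validation, and sales-composition linkage.

The composition table stores per-100 g energy (kJ), sodium (mg) and iodine
(μg) for every product, plus its three-level category code and two flags:
whether the product is discretionary (table/cooking) salt and whether it is
iodised. Sodium is always stored as sodium, never as salt, so no salt-to-
sodium conversion happens anywhere in the package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

log = logging.getLogger(__name__)

COMPOSITION_COLUMNS = [
    "product_id", "name", "major_code", "sub_major_code", "minor_code",
    "energy_kj_100g", "sodium_mg_100g", "iodine_ug_100g",
    "is_discretionary_salt", "is_iodised",
]
NUTRIENT_COLUMNS = ["energy_kj_100g", "sodium_mg_100g", "iodine_ug_100g"]

SALES_COLUMNS = ["store_id", "week_start", "product_id", "quantity",
                 "total_weight_g"]


class CompositionError(ValueError):
    """Fatal problem with a composition table or its linkage."""


class LinkageError(CompositionError):
    """Too many sales records could not be matched to the composition table."""


@dataclass(frozen=True)
class CategoryCode:
    """Three-level hierarchical category code (major > sub-major > minor)."""

    major: str
    sub_major: str
    minor: str

    def __post_init__(self) -> None:
        if not (self.major and self.sub_major and self.minor):
            raise CompositionError(f"empty level in category code {self!r}")
        if not self.sub_major.startswith(self.major):
            raise CompositionError(
                f"sub-major {self.sub_major!r} not within major {self.major!r}")
        if not self.minor.startswith(self.sub_major):
            raise CompositionError(
                f"minor {self.minor!r} not within sub-major {self.sub_major!r}")


@dataclass(frozen=True)
class CompositionEntry:
    """One product's per-100 g nutrient content and classification."""

    product_id: str
    name: str
    category: CategoryCode
    energy_kj_per_100g: float
    sodium_mg_per_100g: float
    iodine_ug_per_100g: float
    is_discretionary_salt: bool = False
    is_iodised: bool = False

    def __post_init__(self) -> None:
        for attr in ("energy_kj_per_100g", "sodium_mg_per_100g",
                     "iodine_ug_per_100g"):
            if getattr(self, attr) < 0:
                raise CompositionError(
                    f"{self.product_id}: negative {attr} "
                    f"({getattr(self, attr)})")


@dataclass
class CompositionTable:
    """Indexed collection of :class:`CompositionEntry`.

    ``validation_report`` lists ``(row_identifier, reason)`` pairs for rows
    rejected while loading; a table built directly from entries has an
    empty report.
    """

    entries: tuple[CompositionEntry, ...]
    validation_report: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.product_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CompositionError(f"duplicate product_id(s): {sorted(dupes)}")
        self._by_id = {e.product_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, product_id: str) -> bool:
        return product_id in self._by_id

    def __iter__(self) -> Iterator[CompositionEntry]:
        return iter(self.entries)

    def get(self, product_id: str) -> CompositionEntry:
        try:
            return self._by_id[product_id]
        except KeyError:
            raise KeyError(f"product_id {product_id!r} not in composition "
                           "table") from None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{
            "product_id": e.product_id,
            "name": e.name,
            "major_code": e.category.major,
            "sub_major_code": e.category.sub_major,
            "minor_code": e.category.minor,
            "energy_kj_100g": e.energy_kj_per_100g,
            "sodium_mg_100g": e.sodium_mg_per_100g,
            "iodine_ug_100g": e.iodine_ug_per_100g,
            "is_discretionary_salt": e.is_discretionary_salt,
            "is_iodised": e.is_iodised,
        } for e in self.entries]
        return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)

    def write_csv(self, path: str | Path, *, header_comment: str | None = None
                  ) -> None:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       validation_report: list[tuple[str, str]] | None = None
                       ) -> "CompositionTable":
        entries = tuple(
            CompositionEntry(
                product_id=str(r.product_id),
                name=str(r.name),
                category=CategoryCode(str(r.major_code), str(r.sub_major_code),
                                      str(r.minor_code)),
                energy_kj_per_100g=float(r.energy_kj_100g),
                sodium_mg_per_100g=float(r.sodium_mg_100g),
                iodine_ug_per_100g=float(r.iodine_ug_100g),
                is_discretionary_salt=bool(r.is_discretionary_salt),
                is_iodised=bool(r.is_iodised),
            )
            for r in df.itertuples(index=False)
        )
        return cls(entries, validation_report or [])


def _parse_bool(series: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    return series.astype(str).str.strip().str.lower().map(mapping)


def load_composition(path: str | Path) -> CompositionTable:
    """Read a composition CSV (UTF-8, comma separated, per-100 g basis).

    Rows with negative or missing nutrient values are rejected with a
    logged reason and reported in ``validation_report``; a missing
    mandatory column is fatal.
    """
    df = pd.read_csv(path, comment="#",
                     dtype={"product_id": str, "major_code": str,
                            "sub_major_code": str, "minor_code": str})
    missing = [c for c in COMPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise CompositionError(
            f"composition file {path} is missing mandatory column(s): "
            f"{missing}")
    report: list[tuple[str, str]] = []
    for col in NUTRIENT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("is_discretionary_salt", "is_iodised"):
        df[col] = _parse_bool(df[col])

    bad_nutrient = df[NUTRIENT_COLUMNS].isna().any(axis=1) | (
        df[NUTRIENT_COLUMNS] < 0).any(axis=1)
    bad_flag = df[["is_discretionary_salt", "is_iodised"]].isna().any(axis=1)
    bad = bad_nutrient | bad_flag
    for _, row in df[bad].iterrows():
        reason = ("invalid flag value" if bool(bad_flag.loc[row.name])
                  else "negative or non-numeric nutrient value")
        report.append((str(row["product_id"]), reason))
        log.warning("composition row %s rejected: %s", row["product_id"],
                    reason)
    return CompositionTable.from_dataframe(df[~bad], report)


def link_sales(sales: pd.DataFrame, table: CompositionTable, *,
               max_unmatched_weight_frac: float = 0.01) -> pd.DataFrame:
    """Annotate sales records with per-record nutrient totals.

    Each record gains ``energy_kj``, ``sodium_mg`` and ``iodine_ug``
    columns equal to ``total_weight_g / 100`` times the product's per-100 g
    values, plus the product's category codes and flags. Records whose
    ``product_id`` is absent from the table are excluded and counted; if
    the unmatched share of total purchased weight exceeds
    ``max_unmatched_weight_frac`` the linkage fails.

    The returned frame carries ``attrs['n_unmatched']`` and
    ``attrs['unmatched_weight_frac']``.
    """
    missing = [c for c in SALES_COLUMNS if c not in sales.columns]
    if missing:
        raise CompositionError(f"sales data missing column(s): {missing}")
    if (pd.to_numeric(sales["total_weight_g"], errors="coerce") < 0).any():
        raise CompositionError("negative total_weight_g in sales data")

    comp = table.to_dataframe()
    linked = sales.merge(comp, on="product_id", how="left", validate="m:1")
    unmatched = linked["sodium_mg_100g"].isna()
    n_unmatched = int(unmatched.sum())
    total_w = float(sales["total_weight_g"].sum())
    unmatched_w = float(linked.loc[unmatched, "total_weight_g"].sum())
    frac = unmatched_w / total_w if total_w > 0 else 0.0
    if frac > max_unmatched_weight_frac:
        raise LinkageError(
            f"{n_unmatched} sales records ({frac:.2%} of purchased weight) "
            f"have no composition entry (limit "
            f"{max_unmatched_weight_frac:.2%})")
    if n_unmatched:
        log.warning("%d sales records (%.3f%% of weight) unmatched and "
                    "excluded", n_unmatched, 100 * frac)
    linked = linked[~unmatched].copy()
    scale = linked["total_weight_g"] / 100.0
    linked["energy_kj"] = scale * linked["energy_kj_100g"]
    linked["sodium_mg"] = scale * linked["sodium_mg_100g"]
    linked["iodine_ug"] = scale * linked["iodine_ug_100g"]
    linked.attrs["n_unmatched"] = n_unmatched
    linked.attrs["unmatched_weight_frac"] = frac
    return linked


def load_sales(path: str | Path) -> pd.DataFrame:
    """Read a sales CSV (store_id, week_start, product_id, quantity,
    total_weight_g)."""
    df = pd.read_csv(path, comment="#",
                     dtype={"store_id": str, "product_id": str})
    missing = [c for c in SALES_COLUMNS if c not in df.columns]
    if missing:
        raise CompositionError(f"sales file {path} missing column(s): "
                               f"{missing}")
    return df
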