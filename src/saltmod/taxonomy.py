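"""Food-category taxonomy shared across the package.

Three-level hierarchical codes modelled on the Australian Health Survey
food classification: a 2-digit major group, a 3-digit sub-major group
(prefixed by its major) and a 4-digit minor group (prefixed by its
sub-major). The codes themselves are synthetic but the structure and
group names mirror the survey classification.
"""
from __future__ import annotations

# sub-major codes used by the scenario engine and the generator
SALT_SUBMAJOR = "251"          # discretionary salt (table & cooking salt)
BREAD_SUBMAJOR = "122"         # regular breads & bread rolls
MILK_SUBMAJOR = "191"
EGG_SUBMAJOR = "171"

SUBMAJOR_NAMES: dict[str, str] = {
    "111": "Soft drinks & flavoured mineral waters",
    "122": "Regular breads & bread rolls",
    "124": "Pasta & noodles (without sauce)",
    "131": "Mixed dishes where cereal is the major ingredient",
    "132": "Pastries",
    "163": "Dried & preserved fruit",
    "171": "Eggs",
    "181": "Fresh meat & poultry",
    "182": "Processed meats",
    "191": "Dairy milk",
    "241": "Gravies & savoury sauces",
    "251": "Salt",
    "301": "Other processed foods",
    "311": "Staple foods & fresh produce",
}

#: Sub-major groups counted as "processed foods" by the wide-reformulation
#: scenarios. Fresh produce, plain meat, plain dairy, eggs and discretionary
#: salt itself are excluded (salt enters only through the discretionary-salt
#: target).
PROCESSED_SUBMAJORS: frozenset[str] = frozenset(
    {"111", "122", "124", "131", "132", "163", "182", "241", "301"}
)

#: Fraction of each group's iodine that is carried by added (iodisable) salt
#: and therefore scales with the group's sodium when salt content is
#: reformulated. Bread is fully coupled (mandatory iodised-salt
#: fortification of bread); discretionary salt's own iodine is fully
#: coupled; other processed foods default to 0.4 — the share of their
#: iodine attributable to added salt under partial voluntary iodisation.
DEFAULT_SALT_IODINE_FRACTIONS: dict[str, float] = {
    SALT_SUBMAJOR: 1.0,
    BREAD_SUBMAJOR: 1.0,
    **{c: 0.4 for c in sorted(PROCESSED_SUBMAJORS - {BREAD_SUBMAJOR})},
}


def salt_iodine_fraction(sub_major: str,
                         overrides: dict[str, float] | None = None) -> float:
    """Salt-derived iodine fraction for a sub-major group (0 if uncoupled)."""
    table = dict(DEFAULT_SALT_IODINE_FRACTIONS)
    if overrides:
        table.update(overrides)
    return float(table.get(sub_major, 0.0))
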