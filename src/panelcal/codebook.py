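"""Category codebooks shared across the package.

Every categorical variable carried on a respondent record has a fixed,
ordered set of levels; validation of panels and of marginal-target configs
is against these. The recency scale is the shared ordinal scale used by the
drug-use timeline questions (least recent first).
"""

from __future__ import annotations

# Prescription drug classes covered by the instrument, in catalog order.
RX_DRUG_CLASSES: tuple[str, ...] = (
    "pain_relievers",
    "sedatives",
    "stimulants",
    "cannabinoids",
)

# Item categories.
CATEGORY_PRESCRIPTION = "prescription"
CATEGORY_ILLICIT = "illicit"
CATEGORY_NONPRESCRIPTION = "nonprescription"
ITEM_CATEGORIES: tuple[str, ...] = (
    CATEGORY_PRESCRIPTION,
    CATEGORY_ILLICIT,
    CATEGORY_NONPRESCRIPTION,
)

# Endorsement horizons a matrix can carry.
HORIZONS: tuple[str, ...] = ("lifetime", "last12m", "last30d")

# Ordinal recency scale for timeline (first/last use) answers, least recent
# to most recent.
RECENCY_SCALE: tuple[str, ...] = (
    "over_10y_ago",
    "1_10y_ago",
    "past_12m",
    "past_30d",
)
RECENCY_RANK: dict[str, int] = {lev: i for i, lev in enumerate(RECENCY_SCALE)}

# Demographic / health variables and their levels.
DEMOGRAPHIC_LEVELS: dict[str, tuple[str, ...]] = {
    "age": ("18-24", "25-34", "35-44", "45-54", "55-64", "65+"),
    "sex": ("male", "female"),
    "region": ("Northeast", "Midwest", "South", "West"),
    "income": ("<25k", "25-50k", "50-75k", "75-100k", "100k+"),
    "household_size": ("1", "2", "3", "4+"),
    "health_status": ("poor", "fair", "good", "very_good", "excellent"),
    "activity_limitation": ("yes", "no"),
    "smoking": ("current", "former", "never"),
}

# Weighting variables: the three core demographics enter every raked scheme;
# the five optional variables are searched over.
CORE_WEIGHTING_VARS: tuple[str, ...] = ("age", "sex", "region")
OPTIONAL_WEIGHTING_VARS: tuple[str, ...] = (
    "income",
    "household_size",
    "health_status",
    "activity_limitation",
    "smoking",
)

# Quota strata are sex x region cells.
STRATA: tuple[str, ...] = tuple(
    f"{sex}|{region}"
    for sex in DEMOGRAPHIC_LEVELS["sex"]
    for region in DEMOGRAPHIC_LEVELS["region"]
)


def stratum_label(sex: str, region: str) -> str:
    return f"{sex}|{region}"
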