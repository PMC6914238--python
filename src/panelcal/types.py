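"""Core in-memory containers for panel data and configuration.

The canonical respondent table, endorsement matrices, item catalog,
timeline answers, marginal raking targets, benchmark sets, and the
screening cut points all live here, together with their validation rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .codebook import (
    DEMOGRAPHIC_LEVELS,
    HORIZONS,
    ITEM_CATEGORIES,
    RECENCY_RANK,
)


class PanelError(Exception):
    """Base class for panel-processing errors."""


class SchemaError(PanelError):
    """A file or table is missing required structure (columns, keys)."""


class PanelValidationError(PanelError):
    """Structurally well-formed data violating a domain invariant."""


# Respondent-table columns that are not demographic variables.
RESPONDENT_ID = "respondent_id"
SECTION_TIME_COLUMNS = ("time_intro_s", "time_rx_s")
RESPONDENT_BASE_COLUMNS = (
    (RESPONDENT_ID,)
    + tuple(DEMOGRAPHIC_LEVELS)
    + SECTION_TIME_COLUMNS
    + ("stratum", "completed")
)


@dataclass
class EndorsementMatrix:
    """Binary respondents x items endorsements with per-respondent order.

    ``values[i, j]`` is 1 iff respondent ``i`` endorsed item ``j`` (items are
    in catalog order).  ``presentation_order[i]`` is the permutation of item
    *indices* giving the sequence in which respondent ``i`` saw the items;
    the instrument block-randomizes, so items of one drug class are
    contiguous within each permutation.
    """

    horizon: str
    respondents: list[str]
    items: list[str]
    values: np.ndarray
    presentation_order: np.ndarray

    @property
    def n(self) -> int:
        return len(self.respondents)

    @property
    def m(self) -> int:
        return len(self.items)

    def validate(self, class_of: Mapping[str, str] | None = None) -> None:
        if self.horizon not in HORIZONS:
            raise PanelValidationError(f"unknown horizon {self.horizon!r}")
        if self.values.shape != (self.n, self.m):
            raise PanelValidationError(
                f"values shape {self.values.shape} != ({self.n}, {self.m})"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelValidationError(
                f"non-binary endorsement cell at respondent "
                f"{self.respondents[i]!r}, item {self.items[j]!r}: "
                f"{self.values[i, j]!r}"
            )
        if self.presentation_order.shape != (self.n, self.m):
            raise PanelValidationError("presentation_order shape mismatch")
        expect = np.arange(self.m)
        sorted_orders = np.sort(self.presentation_order, axis=1)
        if not (sorted_orders == expect).all():
            i = int(np.argwhere((sorted_orders != expect).any(axis=1))[0])
            raise PanelValidationError(
                f"presentation_order for respondent {self.respondents[i]!r} "
                "is not a permutation of item indices"
            )
        if class_of is not None:
            self._validate_blocks(class_of)

    def _validate_blocks(self, class_of: Mapping[str, str]) -> None:
        labels = np.array([class_of[it] for it in self.items])
        ordered = labels[self.presentation_order]
        # A block-randomized permutation visits each class exactly once:
        # the number of label changes along the row is (#classes - 1).
        n_classes = len(set(labels))
        changes = (ordered[:, 1:] != ordered[:, :-1]).sum(axis=1)
        bad = np.nonzero(changes != n_classes - 1)[0]
        if bad.size:
            raise PanelValidationError(
                f"presentation order for respondent "
                f"{self.respondents[int(bad[0])]!r} is not block-contiguous"
            )

    def in_presentation_order(
        self, item_subset: Iterable[str] | None = None
    ) -> np.ndarray:
        """Values reordered into each respondent's presentation sequence.

        With ``item_subset``, restrict to those items while preserving each
        respondent's relative presentation order (the subsequence the
        respondent actually saw those items in).
        """
        if item_subset is None:
            return np.take_along_axis(self.values, self.presentation_order, axis=1)
        idx = {it: k for k, it in enumerate(self.items)}
        subset_idx = np.array([idx[it] for it in item_subset])
        member = np.zeros(self.m, dtype=bool)
        member[subset_idx] = True
        mask = member[self.presentation_order]
        sel = self.presentation_order[mask].reshape(self.n, len(subset_idx))
        return np.take_along_axis(self.values, sel, axis=1)

    def ordered_items(self, row: int) -> list[str]:
        return [self.items[k] for k in self.presentation_order[row]]


@dataclass
class ItemCatalog:
    """Item metadata: drug class, category, ingredient, dispensing volume.

    ``table`` has columns ``item_id``, ``drug_class``, ``category``,
    ``ingredient`` and nullable ``dispensing_volume`` (dosage units).
    """

    table: pd.DataFrame
    declared_sizes: dict[str, int] = field(default_factory=dict)

    REQUIRED = ("item_id", "drug_class", "category", "ingredient")

    def validate(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise SchemaError(f"item catalog missing column {col!r}")
        if self.table["item_id"].duplicated().any():
            dup = self.table.loc[self.table["item_id"].duplicated(), "item_id"].iloc[0]
            raise PanelValidationError(f"duplicate item_id {dup!r}")
        bad = ~self.table["category"].isin(ITEM_CATEGORIES)
        if bad.any():
            raise PanelValidationError(
                f"unknown item category {self.table.loc[bad, 'category'].iloc[0]!r}"
            )
        if "dispensing_volume" in self.table.columns:
            vols = self.table["dispensing_volume"].dropna()
            if (vols < 0).any():
                raise PanelValidationError("negative dispensing_volume")

    @property
    def item_ids(self) -> list[str]:
        return list(self.table["item_id"])

    def class_of(self) -> dict[str, str]:
        return dict(zip(self.table["item_id"], self.table["drug_class"]))

    def category_of(self) -> dict[str, str]:
        return dict(zip(self.table["item_id"], self.table["category"]))

    def items_in_category(self, category: str) -> list[str]:
        t = self.table
        return list(t.loc[t["category"] == category, "item_id"])

    def ingredient_of(self) -> dict[str, str]:
        return dict(zip(self.table["item_id"], self.table["ingredient"]))


@dataclass
class MarginalTargets:
    """Population size and per-variable category proportions for raking."""

    N: float
    variables: dict[str, dict[str, float]]
    source: str = ""

    def validate(self, tol: float = 1e-9) -> None:
        if self.N <= 0:
            raise PanelValidationError("population size N must be positive")
        for var, props in self.variables.items():
            total = sum(props.values())
            if abs(total - 1.0) > tol:
                raise PanelValidationError(
                    f"target proportions for {var!r} sum to {total}, not 1"
                )
            for level, p in props.items():
                if p <= 0:
                    raise PanelValidationError(
                        f"non-positive target proportion for {var}={level}"
                    )


@dataclass(frozen=True)
class Benchmark:
    """One external benchmark estimate (percentage scale)."""

    benchmark_id: str
    variable: str
    level: str
    value_pct: float
    source: str = ""
    included: bool = True
    group: str = "nonhealth"  # "health" or "nonhealth"


@dataclass
class BenchmarkSet:
    benchmarks: list[Benchmark]

    def validate(self) -> None:
        seen = set()
        for b in self.benchmarks:
            if b.benchmark_id in seen:
                raise PanelValidationError(f"duplicate benchmark {b.benchmark_id!r}")
            seen.add(b.benchmark_id)
            if b.included and b.value_pct <= 0:
                raise PanelValidationError(
                    f"benchmark {b.benchmark_id!r} included in the average has "
                    f"non-positive value {b.value_pct} (relative difference is "
                    "undefined)"
                )

    @property
    def included(self) -> list[Benchmark]:
        return [b for b in self.benchmarks if b.included]

    @property
    def b_n(self) -> int:
        return len(self.included)

    def __iter__(self):
        return iter(self.benchmarks)

    def __len__(self) -> int:
        return len(self.benchmarks)


@dataclass(frozen=True)
class CutPoints:
    """Cut points for the four exclusion criteria.

    Defaults: a run of 22 (over half of the 42-item prescription block)
    spanning at least two drug classes; even-odd consistency below -0.6 on
    the prescription block and below -0.8 on the (shorter) illicit block;
    35 or more of the 298 last-12-month products endorsed.  The introductory
    timing metric (under 16 s on 8 introductory questions) is reported but
    never flags: it added no discriminatory value.
    """

    c1_min_run: int = 22
    c1_min_classes: int = 2
    c2_threshold: float = -0.6
    c3_threshold: float = -0.8
    c4_max_endorsed: int = 35
    intro_fast_seconds: float = 16.0

    def validate(self) -> None:
        if not (-1 <= self.c2_threshold < 0 and -1 <= self.c3_threshold < 0):
            raise PanelValidationError("correlation thresholds must lie in [-1, 0)")
        if self.c1_min_run < 1 or self.c4_max_endorsed < 1:
            raise PanelValidationError("run/endorsement cuts must be positive")


@dataclass
class Panel:
    """A fully-loaded survey panel.

    ``respondents`` is one row per respondent (demographics, section times,
    stratum, completion); ``matrices`` maps horizon to its endorsement
    matrix; ``timelines`` is long-format first/last-use answers.
    """

    respondents: pd.DataFrame
    matrices: dict[str, EndorsementMatrix]
    catalog: ItemCatalog
    timelines: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.respondents)

    @property
    def respondent_ids(self) -> list[str]:
        return list(self.respondents[RESPONDENT_ID])

    def validate(self) -> None:
        for col in RESPONDENT_BASE_COLUMNS:
            if col not in self.respondents.columns:
                raise SchemaError(f"respondent table missing column {col!r}")
        ids = self.respondents[RESPONDENT_ID]
        if ids.duplicated().any():
            raise PanelValidationError(
                f"duplicate respondent_id {ids[ids.duplicated()].iloc[0]!r}"
            )
        for var, levels in DEMOGRAPHIC_LEVELS.items():
            bad = ~self.respondents[var].isin(levels)
            if bad.any():
                rid = self.respondents.loc[bad, RESPONDENT_ID].iloc[0]
                raise PanelValidationError(
                    f"unknown {var} category "
                    f"{self.respondents.loc[bad, var].iloc[0]!r} for "
                    f"respondent {rid!r}"
                )
        for col in SECTION_TIME_COLUMNS:
            if (self.respondents[col] < 0).any():
                raise PanelValidationError(f"negative section time in {col!r}")
        self.catalog.validate()
        class_of = self.catalog.class_of()
        for matrix in self.matrices.values():
            matrix.validate(class_of=class_of)
            if matrix.respondents != self.respondent_ids:
                raise PanelValidationError(
                    f"{matrix.horizon} matrix respondents do not match the "
                    "respondent table"
                )
        if len(self.timelines):
            bad = ~self.timelines["first_use_period"].isin(RECENCY_RANK) | ~(
                self.timelines["last_use_period"].isin(RECENCY_RANK)
            )
            if bad.any():
                raise PanelValidationError(
                    "unknown recency category in timeline answers: "
                    f"{self.timelines.loc[bad].iloc[0].to_dict()}"
                )


@dataclass(frozen=True)
class ParticipationCounts:
    """Fielding flow counters: invited -> initiated -> eligible-complete ->
    analyzed (after careless exclusions)."""

    invited: int
    initiated: int
    eligible_complete: int
    excluded: int

    @property
    def analyzed(self) -> int:
        return self.eligible_complete - self.excluded

    def flow_summary(self) -> dict[str, float]:
        """Flow percentages, reporting both published participation ratios.

        The completed-over-invited and eligible-over-initiated ratios are
        both reported rather than choosing one denominator.
        """
        return {
            "initiation_pct": round(100 * self.initiated / self.invited, 2),
            "eligible_complete_of_initiated_pct": round(
                100 * self.eligible_complete / self.initiated, 2
            ),
            "eligible_complete_of_invited_pct": round(
                100 * self.eligible_complete / self.invited, 2
            ),
            "excluded_pct": round(100 * self.excluded / self.eligible_complete, 2),
            "final_participation_pct": round(100 * self.analyzed / self.invited, 2),
        }
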