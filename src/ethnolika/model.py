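"""Survey data model for free-list ethnobiological use-record data.

A survey is a long table of *use records* — one row per (informant, taxon,
use-category) mention — plus a taxon registry. The free-list structure is
encoded through the ``rank`` column: the position at which the informant first
mentioned the taxon during the interview. All records of one taxon by one
informant share that rank, and distinct taxa carry distinct ranks, so every
informant's records can be collapsed back into an ordered free list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: The seven non-exclusive use-category codes recorded in the survey:
#: food/drink, medicine, alcoholic beverages, animal feed, construction and
#: tools, ceremonial use, and other unspecified uses.
CATEGORY_CODES: tuple[str, ...] = ("FO", "MD", "AL", "AF", "CT", "CE", "OT")

CATEGORY_NAMES: dict[str, str] = {
    "FO": "Food and drinks",
    "MD": "Medicine",
    "AL": "Alcoholic drinks",
    "AF": "Animal feed",
    "CT": "Construction or hand craft",
    "CE": "Ceremonies",
    "OT": "Other not specified",
}

#: Wild / cultivated / both / invasive.
STATUS_CODES: tuple[str, ...] = ("w", "c", "w/c", "inv")

KINGDOM_CODES: tuple[str, ...] = ("plant", "fungus")

RECORD_COLUMNS: tuple[str, ...] = (
    "informant_id",
    "locality",
    "taxon_id",
    "rank",
    "category",
    "plant_part",
    "ailment",
)

REGISTRY_COLUMNS: tuple[str, ...] = (
    "taxon_id",
    "scientific_name",
    "family",
    "status",
    "kingdom",
    "local_names",
    "categories",
)


class SurveyValidationError(ValueError):
    """Raised when a record or registry table violates the survey contract."""

    def __init__(self, issues: list[str]):
        self.issues = list(issues)
        super().__init__(
            "survey validation failed:\n" + "\n".join(f"  - {i}" for i in issues)
        )


@dataclass(frozen=True)
class FreeList:
    """One informant's ordered free list of distinct taxa (rank 1 first)."""

    informant_id: str
    taxa: tuple[str, ...]

    @property
    def L(self) -> int:
        return len(self.taxa)

    def rank_of(self, taxon_id: str) -> int:
        """1-based rank of ``taxon_id`` in this list (raises if absent)."""
        return self.taxa.index(taxon_id) + 1


@dataclass
class Survey:
    """Validated use-record survey: long record table + taxon registry.

    Parameters
    ----------
    records
        DataFrame with columns :data:`RECORD_COLUMNS`. ``plant_part`` and
        ``ailment`` may be empty strings (missing).
    registry
        DataFrame with at least ``taxon_id``, ``scientific_name``, ``family``,
        ``status``, ``kingdom``. The optional ``categories`` column lists the
        use categories documented for the taxon (semicolon-joined codes).
    """

    records: pd.DataFrame
    registry: pd.DataFrame
    _registry_index: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        reg = self.registry.reset_index(drop=True)
        self.registry = reg
        self._registry_index = reg.set_index("taxon_id", drop=False)

    # -- derived scalars -------------------------------------------------
    @property
    def n_informants(self) -> int:
        """N — number of distinct informants appearing in the records."""
        return int(self.records["informant_id"].nunique())

    @property
    def localities(self) -> set[str]:
        return set(self.records["locality"].unique())

    @property
    def taxa(self) -> list[str]:
        return list(self.registry["taxon_id"])

    def scientific_name(self, taxon_id: str) -> str:
        return str(self._registry_index.at[taxon_id, "scientific_name"])


def validate_registry(registry: pd.DataFrame) -> list[str]:
    """Return a list of contract violations for a registry table."""
    issues: list[str] = []
    required = {"taxon_id", "scientific_name", "family", "status", "kingdom"}
    missing = required - set(registry.columns)
    if missing:
        return [f"registry missing required columns: {sorted(missing)}"]
    dup = registry["taxon_id"][registry["taxon_id"].duplicated()]
    if len(dup):
        issues.append(f"duplicate taxon_id values in registry: {sorted(set(dup))}")
    bad_status = set(registry["status"]) - set(STATUS_CODES)
    if bad_status:
        issues.append(f"unknown status codes: {sorted(bad_status)}")
    bad_kingdom = set(registry["kingdom"]) - set(KINGDOM_CODES)
    if bad_kingdom:
        issues.append(f"unknown kingdom codes: {sorted(bad_kingdom)}")
    if "categories" in registry.columns:
        for _, row in registry.iterrows():
            cats = parse_category_list(row["categories"])
            bad = set(cats) - set(CATEGORY_CODES)
            if bad:
                issues.append(
                    f"taxon {row['taxon_id']}: unknown categories {sorted(bad)}"
                )
    return issues


def validate_records(records: pd.DataFrame, registry: pd.DataFrame) -> list[str]:
    """Return a list of contract violations for a record table.

    Checks: column set, non-empty, category codes, rank positivity, known
    taxon ids, and the free-list rank structure (one rank per taxon per
    informant; distinct taxa at distinct ranks).
    """
    issues: list[str] = []
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        return [f"records missing required columns: {sorted(missing)}"]
    if len(records) == 0:
        return ["no records"]

    bad_cat = set(records["category"]) - set(CATEGORY_CODES)
    if bad_cat:
        issues.append(f"unknown category codes: {sorted(bad_cat)}")

    ranks = pd.to_numeric(records["rank"], errors="coerce")
    if ranks.isna().any() or (ranks < 1).any() or (ranks != ranks.round()).any():
        issues.append("rank must be an integer >= 1 for every record")

    known = set(registry["taxon_id"])
    unknown = set(records["taxon_id"]) - known
    if unknown:
        issues.append(f"records reference unknown taxa: {sorted(unknown)[:10]}")

    if not issues:
        per = records.groupby(["informant_id", "taxon_id"])["rank"].nunique()
        split = per[per > 1]
        for (inf, tax) in split.index:
            issues.append(f"informant {inf}: taxon {tax} appears at multiple ranks")
        # distinct taxa must not share a rank within an informant
        first = records.drop_duplicates(["informant_id", "taxon_id"])
        coll = first.groupby(["informant_id", "rank"])["taxon_id"].nunique()
        for (inf, rnk) in coll[coll > 1].index:
            issues.append(f"informant {inf}: rank {rnk} shared by distinct taxa")
    return issues


def parse_category_list(value: object) -> list[str]:
    """Parse a semicolon-joined category-code field (empty -> [])."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    text = str(value).strip()
    if not text:
        return []
    return [c.strip() for c in text.split(";") if c.strip()]


def make_survey(
    records: pd.DataFrame,
    registry: pd.DataFrame,
    *,
    mode: str = "strict",
) -> Survey:
    """Assemble and validate a :class:`Survey`.

    In ``strict`` mode any violation raises :class:`SurveyValidationError`.
    In ``lenient`` mode rows with unknown taxa or categories are dropped
    (with a warning carrying the dropped count); structural rank violations
    still raise, because no index is well defined on them.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown validation mode: {mode!r}")

    reg_issues = validate_registry(registry)
    if reg_issues:
        raise SurveyValidationError(reg_issues)

    records = records.copy()
    for col in ("plant_part", "ailment"):
        if col not in records.columns:
            records[col] = ""
    records[["plant_part", "ailment"]] = (
        records[["plant_part", "ailment"]].fillna("").astype(str)
    )

    if mode == "lenient" and set(RECORD_COLUMNS) <= set(records.columns):
        known = set(registry["taxon_id"])
        keep = records["taxon_id"].isin(known) & records["category"].isin(
            CATEGORY_CODES
        )
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(
                f"lenient mode: dropped {n_drop} record(s) with unknown "
                "taxon or category",
                stacklevel=2,
            )
            records = records[keep].reset_index(drop=True)

    issues = validate_records(records, registry)
    if issues:
        raise SurveyValidationError(issues)

    records["rank"] = records["rank"].astype(int)

    # collapse exact duplicate (informant, taxon, category) mentions: an
    # informant contributes at most one use report per taxon per category.
    key = ["informant_id", "taxon_id", "category"]
    n_dup = int(records.duplicated(key).sum())
    if n_dup:
        warnings.warn(
            f"collapsed {n_dup} duplicate (informant, taxon, category) row(s)",
            stacklevel=2,
        )
        records = records.drop_duplicates(key).reset_index(drop=True)

    return Survey(records=records[list(RECORD_COLUMNS)], registry=registry)


def derive_freelists(survey: Survey) -> list[FreeList]:
    """Collapse the record table into one ordered free list per informant.

    Each taxon appears once, at the rank of its first mention; lists are
    ordered by ascending rank. Informants are returned in sorted id order so
    downstream computation is deterministic.
    """
    first = survey.records.drop_duplicates(["informant_id", "taxon_id"])
    out: list[FreeList] = []
    for informant_id, grp in first.sort_values(
        ["informant_id", "rank"]
    ).groupby("informant_id", sort=True):
        out.append(FreeList(str(informant_id), tuple(grp["taxon_id"])))
    return out


def use_reports(survey: Survey) -> pd.DataFrame:
    """Use-report matrix UR(taxon, category): distinct citing informants.

    Returns a DataFrame indexed by every registry taxon with one integer
    column per category code (zeros for unused categories), so that
    ``use_reports(s).sum(axis=1)`` is UR_total and every cell is bounded by
    the taxon's citation frequency FC.
    """
    counts = (
        survey.records.drop_duplicates(["informant_id", "taxon_id", "category"])
        .groupby(["taxon_id", "category"])["informant_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    ur = counts.reindex(
        index=survey.taxa, columns=list(CATEGORY_CODES), fill_value=0
    ).fillna(0)
    return ur.astype(int)


def citation_frequency(survey: Survey) -> pd.Series:
    """FC — number of distinct informants citing each taxon in any category."""
    fc = survey.records.groupby("taxon_id")["informant_id"].nunique()
    return fc.reindex(survey.taxa, fill_value=0).astype(int).rename("FC")


def subset_by_locality(survey: Survey, locality: str) -> Survey:
    """Restrict a survey to the records of one locality (registry kept)."""
    sub = survey.records[survey.records["locality"] == locality]
    return Survey(records=sub.reset_index(drop=True), registry=survey.registry)


def freelist_lengths(freelists: Iterable[FreeList]) -> pd.Series:
    return pd.Series({fl.informant_id: fl.L for fl in freelists}, name="L")
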