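"""Reading, writing and packaged-fixture handling for survey CSV files.

File dialect: UTF-8 comma-separated CSV with a header row; empty string
means missing. Record columns: informant_id, locality, taxon_id, rank,
category, plant_part, ailment. Registry columns: taxon_id, scientific_name,
family, status, kingdom, local_names (semicolon-joined) and categories
(semicolon-joined use-category codes documented for the taxon).

The packaged Lika fixtures hold the published count tables of the central
Lika survey (40 informants, 111 plant + 5 fungal taxa):

``fixtures/lika_registry.csv``
    one row per documented taxon (identity, family, wild/cultivated status,
    kingdom, local names, use-category list);
``fixtures/lika_counts.csv``
    per-taxon citation frequency FC plus the published per-category use
    reports where the survey report prints them (blank = unpublished; the
    two OT cells derivable from printed row totals are filled in);
``fixtures/lika_category_totals.csv``
    category-level totals (use reports, taxon counts, per-informant
    statistics) for the seven use categories.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CATEGORY_CODES,
    RECORD_COLUMNS,
    REGISTRY_COLUMNS,
    Survey,
    make_survey,
    parse_category_list,
)

LIKA_N_INFORMANTS = 40
#: informants per locality in the Lika survey (Perušić, Gospić, Lovinac)
LIKA_LOCALITY_SIZES = {"Perusic": 16, "Gospic": 11, "Lovinac": 13}


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read a taxon registry CSV (validated lazily by :func:`make_survey`)."""
    reg = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"taxon_id", "scientific_name", "family", "status", "kingdom"} - set(
        reg.columns
    )
    if missing:
        raise ValueError(f"registry {path}: missing columns {sorted(missing)}")
    return reg


def read_records(
    path: str | Path, registry: pd.DataFrame, *, mode: str = "strict"
) -> Survey:
    """Read a use-record CSV against a registry and return a validated Survey."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records {path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"records {path}: no records")
    df["rank"] = pd.to_numeric(df["rank"], errors="coerce")
    return make_survey(df, registry, mode=mode)


def write_records(survey: Survey, path: str | Path) -> None:
    """Write the record table in canonical order (stable, reproducible)."""
    out = survey.records.sort_values(
        ["informant_id", "rank", "category"], kind="mergesort"
    )
    out.to_csv(path, index=False, lineterminator="\n")


def write_registry(registry: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in REGISTRY_COLUMNS if c in registry.columns]
    registry[cols].to_csv(path, index=False, lineterminator="\n")


# ----------------------------------------------------------------------
# packaged Lika fixtures
# ----------------------------------------------------------------------

def _fixture_path(name: str):
    return importlib.resources.files("ethnolika") / "fixtures" / name


def load_lika_registry() -> pd.DataFrame:
    """Registry of the 116 documented Lika taxa (111 plants, 5 fungi)."""
    with importlib.resources.as_file(_fixture_path("lika_registry.csv")) as p:
        return read_registry(p)


def load_lika_counts() -> pd.DataFrame:
    """Per-taxon FC and published per-category UR counts, indexed by taxon.

    Category columns hold NaN where the per-category count was not
    published; FC is complete.
    """
    with importlib.resources.as_file(_fixture_path("lika_counts.csv")) as p:
        df = pd.read_csv(p)
    df = df.set_index("taxon_id")
    df["fc"] = df["fc"].astype(int)
    return df


def load_lika_category_totals() -> pd.DataFrame:
    """Category-level totals of the Lika survey (UR, n_taxa, informant stats)."""
    with importlib.resources.as_file(
        _fixture_path("lika_category_totals.csv")
    ) as p:
        return pd.read_csv(p)


def reconstruct_lika_survey() -> Survey:
    """Deterministically expand the Lika count fixtures into a record table.

    The published counts fix the marginals: every taxon's citation frequency
    FC, and — for the taxa whose per-category use reports were printed — the
    exact UR(taxon, category) cells. This routine builds one concrete record
    table consistent with those marginals:

    * 40 informants split 16/11/13 over the three localities;
    * for each taxon (in descending-FC order) the FC citing informants are
      assigned cyclically, so every informant ends up with a realistic list;
    * published category counts are laid out as consecutive cyclic blocks
      over the citing informants (each informant gets at most one use report
      per category, and every citing informant gets at least one category);
    * categories documented for the taxon but without a published count get
      a minimal count (>= 1, the first absorbing any remainder up to FC);
    * free-list ranks order each informant's taxa by descending global FC.

    The result passes strict validation and reproduces FC, RFC and all
    published UR / FLs / CVe cells exactly; it is *one* survey consistent
    with the published counts, not the (unavailable) raw interview data.
    """
    registry = load_lika_registry()
    counts = load_lika_counts()

    informants: list[tuple[str, str]] = []
    i = 1
    for loc, size in LIKA_LOCALITY_SIZES.items():
        for _ in range(size):
            informants.append((f"inf{i:02d}", loc))
            i += 1
    n = len(informants)

    cats_by_taxon = {
        row["taxon_id"]: parse_category_list(row["categories"])
        for _, row in registry.iterrows()
    }

    order = counts.sort_values("fc", ascending=False, kind="mergesort")
    order = order.loc[
        sorted(order.index, key=lambda t: (-order.at[t, "fc"], t))
    ]

    rows = []
    offset = 0
    for taxon_id, row in order.iterrows():
        fc = int(row["fc"])
        citing = [(offset + j) % n for j in range(fc)]
        offset = (offset + fc) % n

        cat_counts: dict[str, int] = {}
        for cat in CATEGORY_CODES:
            val = row.get(cat)
            if pd.notna(val):
                cat_counts[cat] = int(val)
        unknown = [c for c in cats_by_taxon.get(taxon_id, []) if c not in cat_counts]
        if not cat_counts and not unknown:
            unknown = ["OT"]  # taxon documented without categories: park in OT
        printed_total = sum(cat_counts.values())
        if unknown:
            remainder = max(fc - printed_total - (len(unknown) - 1), 1)
            cat_counts[unknown[0]] = min(remainder, fc)
            for c in unknown[1:]:
                cat_counts[c] = 1

        # consecutive cyclic blocks over the citing informants: preserves
        # each count exactly and covers every citing informant because the
        # block lengths sum to at least FC
        pos = 0
        assigned: dict[int, set[str]] = {j: set() for j in citing}
        for cat in sorted(cat_counts, key=CATEGORY_CODES.index):
            k = cat_counts[cat]
            for j in range(k):
                assigned[citing[(pos + j) % fc]].add(cat)
            pos += k

        for idx, cats in assigned.items():
            inf_id, loc = informants[idx]
            for cat in sorted(cats, key=CATEGORY_CODES.index):
                rows.append((inf_id, loc, taxon_id, cat))

    df = pd.DataFrame(rows, columns=["informant_id", "locality", "taxon_id", "category"])

    # dense 1-based ranks per informant, in descending global-FC order
    fc_order = {t: k for k, t in enumerate(order.index)}
    df["_order"] = df["taxon_id"].map(fc_order)
    first = df.drop_duplicates(["informant_id", "taxon_id"]).sort_values(
        ["informant_id", "_order"], kind="mergesort"
    )
    first = first.assign(rank=first.groupby("informant_id").cumcount() + 1)
    rank_map = {
        (r.informant_id, r.taxon_id): r.rank for r in first.itertuples()
    }
    df["rank"] = [
        rank_map[(r.informant_id, r.taxon_id)] for r in df.itertuples()
    ]
    df = df.drop(columns="_order")
    df["plant_part"] = ""
    df["ailment"] = ""
    return make_survey(df, registry, mode="strict")
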