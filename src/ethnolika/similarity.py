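"""Locality comparison: per-locality taxon inventories and Jaccard similarity."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Collection

import pandas as pd

from .model import Survey


@dataclass(frozen=True)
class LocalityInventory:
    """The set of taxa cited by at least one informant of one locality."""

    locality: str
    taxa: frozenset[str]
    n_informants: int
    mean_taxa_per_informant: float

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


def jaccard(a: Collection[str], b: Collection[str]) -> float:
    """Jaccard similarity of two taxon sets, as a percentage.

    ``100 * |a & b| / |a | b|``; symmetric, 100 for identical sets, 0 for
    disjoint ones. Undefined (error) when both sets are empty.
    """
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise ValueError("Jaccard index is undefined for two empty sets")
    return 100.0 * len(sa & sb) / len(union)


def inventories(survey: Survey) -> pd.DataFrame:
    """One row per locality: taxon inventory, size, mean list length.

    A taxon belongs to a locality's inventory if at least one informant from
    that locality cites it in any use category.
    """
    rows = []
    for loc, grp in survey.records.groupby("locality", sort=True):
        taxa = frozenset(grp["taxon_id"])
        n_inf = grp["informant_id"].nunique()
        mean_per_inf = (
            grp.groupby("informant_id")["taxon_id"].nunique().mean()
        )
        rows.append(
            {
                "locality": loc,
                "taxa": taxa,
                "n_taxa": len(taxa),
                "n_informants": int(n_inf),
                "mean_taxa_per_informant": float(mean_per_inf),
            }
        )
    return pd.DataFrame(rows)


def overlap_summary(inv: pd.DataFrame) -> dict:
    """Counts of taxa shared by all localities and by at least two."""
    sets = list(inv["taxa"])
    if not sets:
        return {"in_all": 0, "in_at_least_two": 0, "unique_by_locality": {}}
    in_all = set.intersection(*[set(s) for s in sets]) if sets else set()
    counts: dict[str, int] = {}
    for s in sets:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    at_least_two = {t for t, c in counts.items() if c >= 2}
    unique = {
        row["locality"]: sum(1 for t in row["taxa"] if counts[t] == 1)
        for _, row in inv.iterrows()
    }
    return {
        "in_all": len(in_all),
        "in_at_least_two": len(at_least_two),
        "unique_by_locality": unique,
    }


def jaccard_matrix(survey: Survey) -> pd.DataFrame:
    """Symmetric locality-by-locality Jaccard matrix (percent, diagonal 100)."""
    inv = inventories(survey)
    locs = list(inv["locality"])
    sets = {row["locality"]: row["taxa"] for _, row in inv.iterrows()}
    mat = pd.DataFrame(100.0, index=locs, columns=locs)
    for a, b in combinations(locs, 2):
        ji = jaccard(sets[a], sets[b])
        mat.loc[a, b] = ji
        mat.loc[b, a] = ji
    return mat
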