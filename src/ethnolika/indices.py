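"""Citation, salience, consensus and fidelity indices for use-record surveys.

Count-level primitives (``*_from_counts``) implement the index formulas on
plain numbers, so they can be applied both to a full record table and to
published count tables; the survey-level functions aggregate a
:class:`~ethnolika.model.Survey` and delegate to them.

Indices
-------
RFC
    Relative frequency of citation, ``FC / N``: the share of informants who
    mention a taxon at all.
Smith's S (Sj)
    Free-list salience: the position-weighted credit ``(L - Rj + 1) / L`` of
    taxon *j* in each list, averaged over all N lists (taxa absent from a
    list contribute 0).
CVe
    Cultural value: ``(n_categories / n_possible) * (FC / N) * (UR_total / N)``
    — breadth of use, share of informants, and mean use reports per
    informant, multiplied.
Fic
    Informant consensus per use category,
    ``(n_ur - n_taxa) / (n_ur - 1)``: 1 when all reports concentrate on a
    single taxon, 0 when every report names a different taxon.
FLs
    Fidelity level, ``100 * UR(t, c) / FC(t)``: the percentage of a taxon's
    citing informants who name it for one specific category.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import (
    CATEGORY_CODES,
    CATEGORY_NAMES,
    FreeList,
    Survey,
    citation_frequency,
    derive_freelists,
    use_reports,
)

__all__ = [
    "rfc_from_counts",
    "cultural_value_from_counts",
    "informant_consensus",
    "fidelity_from_counts",
    "rfc",
    "smiths_s",
    "cultural_value",
    "fidelity_level",
    "ailment_fidelity",
    "category_summary",
    "index_table",
    "rank_table",
    "round_display",
]


def round_display(x, ndigits: int):
    """Display rounding used when mirroring published tables.

    IEEE round-half-to-even on the decimal digit (numpy's ``round``), applied
    only at presentation time; all internal values stay at full precision.
    """
    return np.round(x, ndigits)


# ----------------------------------------------------------------------
# count-level primitives
# ----------------------------------------------------------------------

def rfc_from_counts(fc, n_informants: int):
    """Relative frequency of citation ``FC / N``."""
    if n_informants < 1:
        raise ValueError("RFC requires at least one informant (N >= 1)")
    return np.asarray(fc, dtype=float) / n_informants if np.ndim(fc) else float(fc) / n_informants


def cultural_value_from_counts(
    n_categories, fc, ur_total, n_informants: int, n_possible_uses: int = 8
):
    """Cultural value ``CVe = Uce * Ice * sum(IUce)``.

    ``Uce = n_categories / n_possible_uses``, ``Ice = FC / N`` and
    ``sum(IUce) = UR_total / N``. The default number of possible uses is 8
    (the seven recorded modalities plus ethnoveterinary use counted
    separately), which is the convention the index is usually reported
    under; it is configurable for surveys with other category schemes.
    """
    if n_possible_uses <= 0:
        raise ValueError("n_possible_uses must be positive")
    if n_informants < 1:
        raise ValueError("CVe requires at least one informant")
    n_cat = np.asarray(n_categories, dtype=float)
    if np.any(n_cat > n_possible_uses):
        raise ValueError(
            "n_possible_uses must be >= the observed number of use categories"
        )
    uce = n_cat / n_possible_uses
    ice = np.asarray(fc, dtype=float) / n_informants
    iuce = np.asarray(ur_total, dtype=float) / n_informants
    out = uce * ice * iuce
    return float(out) if out.ndim == 0 else out


def informant_consensus(n_ur, n_taxa):
    """Informant consensus factor ``Fic = (n_ur - n_taxa) / (n_ur - 1)``.

    Undefined when a category holds a single use report (0/0); returned as
    NaN with a warning so callers can flag the category rather than receive
    an arbitrary 0 or 1.
    """
    n_ur_a = np.asarray(n_ur, dtype=float)
    n_taxa_a = np.asarray(n_taxa, dtype=float)
    if np.any(n_ur_a < 1):
        raise ValueError("Fic requires at least one use report")
    if np.any(n_taxa_a < 1) or np.any(n_taxa_a > n_ur_a):
        raise ValueError("Fic requires 1 <= n_taxa <= n_ur")
    single = n_ur_a == 1
    if np.any(single):
        warnings.warn(
            "Fic is undefined for categories with a single use report; "
            "returning NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(single, np.nan, (n_ur_a - n_taxa_a) / (n_ur_a - 1.0))
    return float(out) if out.ndim == 0 else out


def fidelity_from_counts(ns, fc):
    """Fidelity level ``FLs = 100 * Ns / FC`` (percentage, 0-100).

    ``Ns`` is the number of informants citing the taxon for the given
    purpose and ``FC`` its overall citation frequency, so a taxon cited for
    a single purpose scores 100.
    """
    fc_a = np.asarray(fc, dtype=float)
    if np.any(fc_a < 1):
        raise ValueError("FLs requires FC >= 1")
    out = 100.0 * np.asarray(ns, dtype=float) / fc_a
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# survey-level indices
# ----------------------------------------------------------------------

def rfc(survey: Survey) -> pd.Series:
    """Per-taxon relative frequency of citation over the whole survey."""
    n = survey.n_informants
    if n < 1:
        raise ValueError("survey has no informants")
    return (citation_frequency(survey) / n).rename("RFC")


def smiths_s(freelists: Iterable[FreeList]) -> pd.Series:
    """Smith's salience index over a collection of free lists.

    Sj = (sum over lists containing j of (L - Rj + 1)/L) / N, with N the
    total number of lists. Taxa absent from every list are simply absent
    from the returned Series (use ``.reindex(taxa, fill_value=0.0)``).
    """
    freelists = list(freelists)
    if not freelists:
        raise ValueError("smiths_s requires at least one free list")
    acc: dict[str, float] = {}
    for fl in freelists:
        L = fl.L
        if L == 0:
            raise ValueError(f"informant {fl.informant_id} has an empty list")
        for pos, taxon in enumerate(fl.taxa, start=1):
            acc[taxon] = acc.get(taxon, 0.0) + (L - pos + 1) / L
    n = len(freelists)
    return pd.Series({t: v / n for t, v in acc.items()}, name="Sj").sort_index()


def cultural_value(survey: Survey, n_possible_uses: int = 8) -> pd.Series:
    """Per-taxon cultural value coefficient CVe."""
    ur = use_reports(survey)
    fc = citation_frequency(survey)
    n_cat = (ur > 0).sum(axis=1)
    vals = cultural_value_from_counts(
        n_cat.to_numpy(),
        fc.to_numpy(),
        ur.sum(axis=1).to_numpy(),
        survey.n_informants,
        n_possible_uses,
    )
    return pd.Series(vals, index=ur.index, name="CVe")


def fidelity_level(survey: Survey) -> pd.DataFrame:
    """Per-taxon, per-category fidelity level (percent of citing informants).

    Rows are restricted to taxa with FC >= 1; columns are the seven category
    codes. Because categories are non-exclusive, one taxon's row sums to
    ``100 * UR_total / FC >= 100``.
    """
    fc = citation_frequency(survey)
    ur = use_reports(survey)
    cited = fc[fc >= 1].index
    vals = fidelity_from_counts(
        ur.loc[cited].to_numpy(), fc.loc[cited].to_numpy()[:, None]
    )
    return pd.DataFrame(vals, index=cited, columns=ur.columns)


def ailment_fidelity(survey: Survey) -> pd.DataFrame:
    """Ailment-level fidelity for medicinal records, on a 0-1 scale.

    FL(t, h) = (# informants citing taxon t for ailment h) /
    (# informants citing t for any medicinal use). Taxa without medicinal
    citations are excluded; medicinal records without an ailment label count
    toward the denominator only.
    """
    md = survey.records[survey.records["category"] == "MD"]
    if len(md) == 0:
        return pd.DataFrame(columns=["ailment", "taxon_id", "FL"])
    denom = md.groupby("taxon_id")["informant_id"].nunique()
    lab = md[md["ailment"].astype(str) != ""]
    num = (
        lab.drop_duplicates(["informant_id", "taxon_id", "ailment"])
        .groupby(["taxon_id", "ailment"])["informant_id"]
        .nunique()
    )
    rows = [
        {
            "ailment": ailment,
            "taxon_id": taxon,
            "FL": count / denom[taxon],
        }
        for (taxon, ailment), count in num.items()
    ]
    out = pd.DataFrame(rows, columns=["ailment", "taxon_id", "FL"])
    return out.sort_values(
        ["ailment", "FL", "taxon_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def category_summary(
    survey: Survey,
    category_totals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-category use-report totals, taxon counts and per-informant stats.

    For each use category: total UR, number of taxa with UR >= 1, and the
    median / mean / sd (sample) / coefficient of variation (percent) of the
    number of distinct taxa each informant cites in that category.
    Informants citing nothing in a category count as zeros. Fic is appended
    where the category holds more than one use report.

    If ``category_totals`` is given (columns ``category``, ``UR``,
    ``n_taxa``), Fic is computed from those published totals instead of the
    record table — used when only aggregate counts are available.
    """
    ur = use_reports(survey)
    informants = sorted(survey.records["informant_id"].unique())
    per_inf = (
        survey.records.drop_duplicates(["informant_id", "taxon_id", "category"])
        .groupby(["category", "informant_id"])["taxon_id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(index=list(CATEGORY_CODES), columns=informants, fill_value=0)
    )
    rows = []
    for cat in CATEGORY_CODES:
        counts = per_inf.loc[cat]
        n_ur = int(ur[cat].sum())
        n_taxa = int((ur[cat] > 0).sum())
        if category_totals is not None:
            sel = category_totals[category_totals["category"] == cat]
            if len(sel):
                n_ur = int(sel["UR"].iloc[0])
                n_taxa = int(sel["n_taxa"].iloc[0])
        mean = float(counts.mean())
        sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
        if n_ur >= 2 and n_taxa >= 1:
            fic = informant_consensus(n_ur, n_taxa)
        else:
            fic = np.nan
        rows.append(
            {
                "category": cat,
                "category_name": CATEGORY_NAMES[cat],
                "UR": n_ur,
                "n_taxa": n_taxa,
                "median": float(counts.median()),
                "mean": mean,
                "sd": sd,
                "cv_pct": 100.0 * sd / mean if mean > 0 else np.nan,
                "Fic": fic,
            }
        )
    return pd.DataFrame(rows)


def index_table(survey: Survey, n_possible_uses: int = 8) -> pd.DataFrame:
    """Full per-taxon index table: FC, RFC, per-category UR, Sj, CVe.

    One row per registry taxon (taxa never cited get zeros). Fidelity levels
    live in their own wide table (:func:`fidelity_level`) because their rows
    are percentages of FC rather than counts.
    """
    fc = citation_frequency(survey)
    ur = use_reports(survey)
    sj = smiths_s(derive_freelists(survey)).reindex(fc.index, fill_value=0.0)
    table = pd.DataFrame(
        {
            "taxon_id": fc.index,
            "scientific_name": [survey.scientific_name(t) for t in fc.index],
            "FC": fc.to_numpy(),
            "RFC": (fc / survey.n_informants).to_numpy(),
        }
    ).set_index("taxon_id")
    for cat in CATEGORY_CODES:
        table[f"UR_{cat}"] = ur[cat].to_numpy()
    table["UR_total"] = ur.sum(axis=1).to_numpy()
    table["n_categories"] = (ur > 0).sum(axis=1).to_numpy()
    table["Sj"] = sj.to_numpy()
    table["CVe"] = cultural_value(survey, n_possible_uses).to_numpy()
    return table


_RANK_KEYS = ("FC", "RFC", "Sj", "CVe", "UR_total") + tuple(
    f"UR_{c}" for c in CATEGORY_CODES
)


def rank_table(table: pd.DataFrame, key: str, k: int) -> pd.DataFrame:
    """Top-k rows of an index table by one index, with deterministic ties.

    Sorted descending on ``key``; ties broken alphabetically by scientific
    name so repeated runs produce identical orderings.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; expected one of {_RANK_KEYS}")
    if key not in table.columns:
        raise ValueError(f"table has no column {key!r}")
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = table.sort_values(
        [key, "scientific_name"], ascending=[False, True], kind="mergesort"
    )
    return ordered.head(k)


def tidy_long(
    table: pd.DataFrame, fls: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Melt an index table (and optional FLs matrix) into tidy long form.

    Columns: taxon_id, metric, category, value. Category is empty for
    whole-survey metrics and the category code for UR_<cat> / FLs entries.
    """
    rows = []
    for taxon_id, row in table.iterrows():
        for metric in ("FC", "RFC", "UR_total", "n_categories", "Sj", "CVe"):
            rows.append((taxon_id, metric, "", float(row[metric])))
        for cat in CATEGORY_CODES:
            rows.append((taxon_id, "UR", cat, float(row[f"UR_{cat}"])))
    if fls is not None:
        for taxon_id, row in fls.iterrows():
            for cat in CATEGORY_CODES:
                rows.append((taxon_id, "FLs", cat, float(row[cat])))
    return pd.DataFrame(rows, columns=["taxon_id", "metric", "category", "value"])
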