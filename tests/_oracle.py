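"""Naive brute-force recomputation of every index by direct enumeration.

Kept deliberately independent of the package internals: plain Python loops
over informants and records, no pandas aggregation, so it can serve as an
oracle for the vectorized implementations on small surveys.
"""

from __future__ import annotations

from ethnolika.model import CATEGORY_CODES, Survey


def _informants(survey: Survey) -> list[str]:
    return sorted({r.informant_id for r in survey.records.itertuples()})


def _records(survey: Survey) -> list[tuple]:
    return [
        (r.informant_id, r.taxon_id, r.category, int(r.rank))
        for r in survey.records.itertuples()
    ]


def oracle_fc(survey: Survey, taxon: str) -> int:
    return len({i for (i, t, _, _) in _records(survey) if t == taxon})


def oracle_rfc(survey: Survey, taxon: str) -> float:
    return oracle_fc(survey, taxon) / len(_informants(survey))


def oracle_ur(survey: Survey, taxon: str, category: str) -> int:
    return len(
        {i for (i, t, c, _) in _records(survey) if t == taxon and c == category}
    )


def oracle_ur_total(survey: Survey, taxon: str) -> int:
    return sum(oracle_ur(survey, taxon, c) for c in CATEGORY_CODES)


def oracle_freelists(survey: Survey) -> dict[str, list[str]]:
    lists: dict[str, list[str]] = {}
    for informant in _informants(survey):
        pairs = sorted(
            {(rk, t) for (i, t, _, rk) in _records(survey) if i == informant}
        )
        lists[informant] = [t for (_, t) in pairs]
    return lists


def oracle_smiths_s(survey: Survey, taxon: str) -> float:
    lists = oracle_freelists(survey)
    total = 0.0
    for taxa in lists.values():
        if taxon in taxa:
            L = len(taxa)
            rj = taxa.index(taxon) + 1
            total += (L - rj + 1) / L
    return total / len(lists)


def oracle_cve(survey: Survey, taxon: str, n_possible: int = 8) -> float:
    n = len(_informants(survey))
    n_cats = sum(1 for c in CATEGORY_CODES if oracle_ur(survey, taxon, c) > 0)
    return (
        (n_cats / n_possible)
        * (oracle_fc(survey, taxon) / n)
        * (oracle_ur_total(survey, taxon) / n)
    )


def oracle_fls(survey: Survey, taxon: str, category: str) -> float:
    return 100.0 * oracle_ur(survey, taxon, category) / oracle_fc(survey, taxon)


def oracle_fic(survey: Survey, category: str) -> float | None:
    n_ur = sum(oracle_ur(survey, t, category) for t in set(survey.registry["taxon_id"]))
    n_taxa = len(
        {t for t in set(survey.registry["taxon_id"]) if oracle_ur(survey, t, category)}
    )
    if n_ur <= 1:
        return None
    return (n_ur - n_taxa) / (n_ur - 1)
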