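from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import strategies as st

from ethnolika.model import CATEGORY_CODES, make_survey
from ethnolika.io import reconstruct_lika_survey


def build_survey(freelists: dict[str, list[str]], categories: dict[tuple[str, str], list[str]],
                 localities: dict[str, str] | None = None, registry_taxa: list[str] | None = None,
                 ailments: dict[tuple[str, str], str] | None = None):
    """Assemble a Survey from explicit free lists and category assignments."""
    rows = []
    for informant, taxa in freelists.items():
        loc = (localities or {}).get(informant, "Loc1")
        for rank, taxon in enumerate(taxa, start=1):
            for cat in categories.get((informant, taxon), ["FO"]):
                ail = (ailments or {}).get((informant, taxon), "")
                rows.append((informant, loc, taxon, rank, cat, "", ail))
    records = pd.DataFrame(rows, columns=[
        "informant_id", "locality", "taxon_id", "rank", "category",
        "plant_part", "ailment",
    ])
    taxa_all = registry_taxa or sorted({t for taxa in freelists.values() for t in taxa})
    registry = pd.DataFrame({
        "taxon_id": taxa_all,
        "scientific_name": [f"Species {t}" for t in taxa_all],
        "family": ["Fam"] * len(taxa_all),
        "status": ["w"] * len(taxa_all),
        "kingdom": ["plant"] * len(taxa_all),
        "local_names": [""] * len(taxa_all),
        "categories": [""] * len(taxa_all),
    })
    return make_survey(records, registry)


@pytest.fixture
def tiny_survey():
    """Two informants, three taxa, mixed categories."""
    return build_survey(
        freelists={"i1": ["A", "B", "C"], "i2": ["B", "A"]},
        categories={
            ("i1", "A"): ["FO", "MD"],
            ("i1", "B"): ["FO"],
            ("i1", "C"): ["AF"],
            ("i2", "B"): ["FO", "MD"],
            ("i2", "A"): ["FO"],
        },
    )


@pytest.fixture(scope="session")
def lika_survey():
    """Record table reconstructed from the packaged Lika count fixtures."""
    return reconstruct_lika_survey()


# ----------------------------------------------------------------------
# hypothesis strategy: arbitrary small valid surveys (<= 5 informants,
# <= 6 taxa) for oracle-equivalence and invariance properties
# ----------------------------------------------------------------------

TAXA_POOL = ["A", "B", "C", "D", "E", "F"]


@st.composite
def small_surveys(draw):
    n_inf = draw(st.integers(1, 5))
    n_taxa = draw(st.integers(1, 6))
    taxa = TAXA_POOL[:n_taxa]
    freelists = {}
    categories = {}
    for i in range(n_inf):
        informant = f"i{i + 1}"
        listed = draw(
            st.lists(st.sampled_from(taxa), min_size=1, max_size=n_taxa, unique=True)
        )
        freelists[informant] = listed
        for taxon in listed:
            cats = draw(
                st.lists(st.sampled_from(CATEGORY_CODES), min_size=1,
                         max_size=3, unique=True)
            )
            categories[(informant, taxon)] = cats
    return build_survey(freelists, categories, registry_taxa=taxa)
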