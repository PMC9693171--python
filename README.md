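# ethnolika

Quantitative ethnobiology indices for free-list use-record surveys, built
around the central Lika (continental Croatia) ethnobotanical survey: 40
semi-structured interviews across three localities (Perušić, Gospić,
Lovinac) documenting 111 plant and 5 fungal taxa in seven non-exclusive use
categories (food/drink, medicine, alcoholic beverages, animal feed,
construction and tools, ceremonial, other).

The package is for ethnobiologists and survey methodologists who need the
standard citation/salience/consensus/fidelity statistics over long-format
interview data, with validation, deterministic outputs, and a seeded
synthetic interview generator for method checks.

## The indices

For a survey of *N* informants, with *FC* the number of distinct informants
citing a taxon and *UR(t, c)* the number of distinct informants citing
taxon *t* in category *c*:

- **RFC** = *FC / N* — relative frequency of citation.
- **Smith's S** — free-list salience:
  *Sj* = Σ over lists containing *j* of ((*L* − *Rj* + 1)/*L*) / *N*, where
  *L* is the list length and *Rj* the taxon's rank of first mention.
- **CVe** = (*n_categories* / *n_possible*) · (*FC* / *N*) · (*UR_total* / *N*)
  — cultural value; *n_possible* defaults to 8.
- **Fic** = (*n_ur* − *n_taxa*) / (*n_ur* − 1) — informant consensus per
  category; undefined (NaN) for a single use report.
- **FLs** = 100 · *UR(t, c)* / *FC(t)* — fidelity level, the percentage of a
  taxon's citing informants naming it for one specific purpose; at ailment
  level, the fraction of a taxon's medicinal citations for one ailment
  (0–1 scale).
- **Jaccard** = 100 · |A ∩ B| / |A ∪ B| — similarity of two locality taxon
  inventories.

## Worked example

The packaged fixtures hold the published count tables of the Lika survey
(per-taxon citation frequencies, the published per-category use reports,
and the category totals). `analysis/02_compute_indices.py` expands them
into a validated record table and computes everything:

```sh
$ python analysis/02_compute_indices.py
survey: 40 informants, 116 registry taxa, 1230 records
top taxa by RFC:
  Achillea millefolium L.        FC=37  RFC=0.925  CVe=0.356
  Rosa canina L.                 FC=36  RFC=0.900  CVe=0.329
  Cornus mas L.                  FC=33  RFC=0.825  CVe=0.812
food & drinks consensus: Fic = 0.89
walnut fidelity for alcoholic drinks: FLs = 63.33
```

Reading: yarrow is the most universally known taxon (37 of 40 informants),
but cornelian cherry — cited slightly less often — carries the highest
cultural value (CVe 0.812) because it is used across five categories with
63 use reports. Food uses show the strongest informant consensus
(Fic 0.89), and 63.33 % of the informants who cite walnut name it for
liqueur making.

The other drivers exercise the synthetic half of the package:
`01_simulate_survey.py` draws a seeded 40-informant survey with the same
marginal structure, `03_compare_localities.py` computes per-locality
inventories and the pairwise Jaccard matrix, and `04_salience_recovery.py`
shows that Smith's S recovers the generator's true salience ranking
(Spearman ≈ 0.87 at Zipf exponent 1.2).

Library use:

```python
from ethnolika import read_registry, read_records, index_table, fidelity_level

registry = read_registry("registry.csv")
survey = read_records("records.csv", registry)
table = index_table(survey)          # FC, RFC, UR by category, Sj, CVe
fls = fidelity_level(survey)         # taxon x category percentages
```

or from the shell: `ethnolika compute`, `ethnolika simulate`,
`ethnolika compare-localities` (see `ethnolika --help`).

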