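# searchminer

Candidate search-term mining for systematic-review search strategies — a
library and command-line tool implementing the *objective approach*: derive
candidate free-text and MeSH terms statistically from a set of known
relevant bibliographic records, instead of purely conceptually.

## Who it is for

Information specialists and review teams developing Boolean search
strategies for bibliographic databases (PubMed/MEDLINE, Ovid). Given a
**test set** of known relevant records in RIS format, searchminer:

1. splits it 2:1 into a **development set** (terms are derived from it) and
   a **validation set** (to check that chosen terms also retrieve held-out
   records), reproducibly under a reported random seed, with PMID lists in
   Ovid `.ui.` syntax;
2. ranks every free-text term from titles and abstracts, every MeSH
   descriptor and every qualifier (subheading) by an overrepresentation
   z-score against a **population set** — a random background sample of
   database records;
3. shows each term in its original context (KWIC, configurable word
   window) and tabulates all 2-word **skip-grams** (ordered word pairs with
   0, 1, 2, … intervening words) to guide proximity searching;
4. exports every table as CSV in the Western European dialect (semicolon
   separator, decimal comma) or the standard dialect.

## The statistic

For a term occurring in `x` of the `n` development-set records, with
document probability `p0` in the population set (population document
frequency / population size), the overrepresentation score is the normal
approximation of the binomial test, without continuity correction:

```
z = (x − n·p0) / sqrt(n·p0·(1 − p0))
```

Terms with `z ≥ 20` (an empirically established cut-off) are flagged as
candidate search terms. A term absent from the population set cannot be
scored and receives the sentinel `z = 10000` — it is maximally
overrepresented by construction. Frequencies are *document* frequencies
(records containing the term), matching the per-document sampling model;
total occurrence counts are reported separately as term frequency.

A term is a word without hyphens, Unicode symbols or punctuation, and is
not a number: `self-aware` is analysed as the two terms `self` and
`aware`, in line with how major search platforms treat hyphenated words.

## Worked example

```python
from searchminer import *
from searchminer.fixtures import FixtureSpec

# background of 2000 records: "screening" rare, "mammography" very rare
pop_spec = FixtureSpec(
    n_records=2000,
    vocabulary=[("patients", 0.6, 1.5), ("cancer", 0.08, 1.5),
                ("screening", 0.03, 1.2), ("mammography", 0.002, 1.0)],
    seed=1,
)
pop_records, _ = generate_records(pop_spec)
pop = build_population_model(pop_records, mini_mesh_dictionary())

# 30 known relevant records: screening vocabulary strongly enriched
test_spec = FixtureSpec(
    n_records=30,
    vocabulary=[("patients", 0.6, 1.5), ("cancer", 0.9, 2.0),
                ("screening", 0.85, 1.5), ("mammography", 0.7, 1.3),
                ("tomosynthesis", 0.5, 1.0)],
    seed=2,
)
test_records, _ = generate_records(test_spec)

split = split_records(test_records, seed=42)
table = freetext_table(split.development, pop)
for r in table:
    print(f"{r.term:14s} documents={r.documents:2d} ({r.documents_pct:6.2f}%) "
          f"z={r.z:10.4f} tf={r.term_frequency} candidate={r.is_candidate}")
```

prints

```
tomosynthesis  documents=10 ( 50.00%) z=10000.0000 tf=10 candidate=True
mammography    documents=11 ( 55.00%) z=   44.7295 tf=15 candidate=True
screening      documents=15 ( 75.00%) z=   21.2139 tf=21 candidate=True
cancer         documents=18 ( 90.00%) z=   13.2884 tf=36 candidate=False
patients       documents=14 ( 70.00%) z=    0.9041 tf=21 candidate=False
```

Reading: the 30-record test set split into 20 development and 10
validation records under seed 42. `tomosynthesis` never occurs in the
background, so it gets the z = 10000 sentinel. `mammography` and
`screening` are strongly overrepresented (z ≥ 20) and become candidate
terms. `cancer` is common in the set (90% of records) but also common in
the background, so its z stays below the cut-off — frequency alone does not
make a good search term. `patients` is near its background rate (z ≈ 0.9).
`export_table(table, WESTERN)` renders the same rows as semicolon-separated
CSV with decimal commas:

```
Candidate terms;Documents;Documents in %;Z-Score;Term frequency
tomosynthesis;10;50,0000;10000;10
mammography;11;55,0000;44,7295;15
...
```

## Command line

```sh
searchminer split testset.ris --seed 42 --dev-out dev.ris --val-out val.ris
searchminer build-population background.ris pop.tsv
searchminer freetext dev.ris --population pop.tsv > freetext.csv
searchminer mesh dev.ris --population pop.tsv --mesh-dict desc.txt --mesh-dict qual.txt
searchminer kwic testset.ris --term "decision-making" --window 2
searchminer phrases testset.ris --max-skip 2
```

Tables go to stdout (or `--out`), logs to stderr. Exit codes: 0 success,
1 usage error, 2 data error. The MeSH dictionary is pluggable: two
plain-text name lists (descriptors, qualifiers) or a MeSH descriptor XML
file; a miniature built-in dictionary backs tests and quick starts.

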