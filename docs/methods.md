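# Methods

## The objective approach and its statistical model

Search strategies for systematic reviews combine free-text terms and
controlled vocabulary in Boolean queries. The *objective approach* derives
candidate terms from a test set of known relevant records rather than from
concept analysis alone: a term is a good candidate when it is
**overrepresented** in the relevant records relative to the database at
large, not merely frequent.

The model treats each population record as an independent Bernoulli trial
for the presence of a term. With `p0` the term's document probability in
the population set, the number of development-set records containing it is
Binomial(n, p0) under the null that the test set is an ordinary sample.
searchminer reports the normal-approximation score statistic

    z = (x − n·p0) / sqrt(n·p0·(1 − p0))

with no continuity correction. The uncorrected score statistic is the
standard reading of "normal approximation of a binomial test", keeps z
exactly 0 at x = n·p0, and is monotone in x. The statistic is intentionally
crude as an inferential quantity — it is used as a *ranking* score, not a
hypothesis test; its scale is what the established z ≥ 20 cut-off was
calibrated on.

Assumptions worth keeping in mind:

- **Per-document sampling.** All frequencies entering z are document
  frequencies (a record counts once however often it repeats a term).
  Term frequencies are shown but never scored.
- **Independence across records** and a fixed background `p0`; both are
  approximations for real bibliographic databases.
- **The population set stands for the database.** Scores are only as
  representative as the background sample; the model file records its
  provenance label.

### Edge rules

- Term present in the development set but absent from the population:
  z cannot be computed; the sentinel **z = 10000** is assigned, ranking
  such terms above all computed scores (they are maximally
  overrepresented relative to a background that never shows them).
- `p0 = 1` (term in every population record): the variance vanishes;
  z is defined as 0 when x = n and as the clamp sentinel −10000 when
  x < n. This cannot demote a genuine candidate — a term in every
  background record is useless for search anyway — but keeps the ranking
  deterministic.
- Degenerate development sets (every title and abstract empty) yield an
  empty table with a logged warning rather than an error: the MeSH tables
  may still be meaningful.

## Term definition

A free-text term is obtained by splitting on whitespace and on the hyphen
inventory U+002D, U+2010–U+2015 and U+2212 (PubMed exports mix ASCII and
typographic hyphens), stripping every character in Unicode categories
Symbol (S\*) and Punctuation (P\*), dropping pieces that are purely numeric
(optional sign, digits, `.`/`,` group separators — so `2022` and `1,000`
vanish while `p53` and `cd4` survive), and case-folding the remainder.
Letters of any script are kept (Greek `β`, micro `µ` → `μ` under case
folding). Punctuation *strips* rather than splits: only hyphens and
whitespace create term boundaries, so `mg/kg` becomes `mgkg`. No stemming,
no stop-word removal — common words are demoted by their z-scores, not by
a list.

Case folding and untouched diacritics are this package's choices: folding
is required for frequency merging across sentence positions; diacritic
normalization is out of scope.

## Controlled vocabulary

Keyword strings decompose as `[*]descriptor[/qualifier]`: a leading `*`
(major-topic flag) is stripped and recorded (carried but unused in the
v1 tables), the first `/` separates the qualifier. Descriptors count once
per record; qualifiers may occur several times per record (attached to
different descriptors), so the qualifier table keeps a term-frequency
column while the MeSH table omits it (it would equal the document count).
Only names present in the MeSH dictionary appear in the MeSH/qualifier
tables; everything imported from the keyword tags appears verbatim in the
all-keywords table, which carries no z-scores. A qualifier counts whenever
its *name* is in the dictionary, regardless of whether its descriptor is —
the stricter joint check would silently drop typos one level up.

The dictionary is pluggable (plain-text name lists or MeSH descriptor
XML); matching is case-insensitive, display uses dictionary casing. The
bundled miniature dictionary (30 descriptors, 10 qualifiers) exists so
tests and examples run without distributing the full MeSH vocabulary.

## Splitting and reproducibility

The 2:1 development/validation split samples `round_half_up(2n/3)` record
indices without replacement using CPython's Mersenne Twister
(`random.Random`), which the Python language reference fixes across
platforms and versions; the applied seed is always reported so a split can
be reproduced, e.g. for peer review. Seeds recorded with R-based tools for
the same workflow are **not** transferable — a different PRNG produces a
different split for the same seed. Subset order follows
input order. PMID lists render as `(id1 or id2 or …).ui.`; the `.ui.`
field and lowercase connectors are this package's reading of Ovid
unique-identifier syntax.

## Context and phrases

KWIC tokenizes the query with the same rules as record text (so
`decision-making` and `decision making` are the same 2-token query) and
reports every contiguous occurrence with up to `window` (default 2) words
of context per side, per field; blank titles/abstracts render as
`NO_TITLE`/`NO_ABSTRACT`. All uploaded records are searched, not only the
development set.

The skip-gram table counts every *ordered* token pair with at most
`max_skip` (default 2) intervening words, per occurrence, within a field —
pairs never span the title/abstract boundary, but no sentence segmentation
is attempted (the simplest deterministic rule; gaps may cross sentence
ends). Totals sort the table; per-distance counts support choosing
proximity operators.

## Export

CSV export renders reals to 4 decimal places (display precision is a
package choice), integers plain, and the ±10000 sentinels as bare integers
so they stay visually distinct from computed scores. The default Western
European dialect uses `;` separators, decimal commas and CRLF; the
standard dialect `,`, `.`, LF. Exports re-parse to the same values at
4-decimal precision, property-tested in both dialects. The rare-term
filter (hide terms in fewer than 2 records or under 10% of records, two
independently configurable thresholds combined with OR) is a view filter:
exports contain all terms unless filtering is requested.

## Synthetic data

The fixture generator builds record sets whose titles/abstracts are bags
of vocabulary terms drawn with per-term inclusion probabilities and mean
repeat counts, and whose keywords come from a weighted pool of
descriptor/qualifier strings. It returns the *realized* counts of its own
output, so table tests assert exact equality instead of statistical
closeness. What it emulates: controlled document frequencies, term
repetition, MeSH/qualifier combinations, missing fields. What it does not:
English syntax, sentence structure, real MeSH co-occurrence patterns, or
encoding noise — passing tests demonstrate correct counting, scoring,
ranking and round-tripping, not linguistic robustness, which is covered
separately by property tests over arbitrary Unicode in the tokenizer
suite.

The acceptance script's scenario uses a 2000-record synthetic background
and a 30-record test set with planted overrepresentation ("screening"
3% → 85%, "mammography" 0.2% → 70%, "tomosynthesis" absent from the
background), sizes chosen as a realistic desk-scale instance of the
workflow (real population sets are tens of thousands of records; the
binomial null only needs `p0`, which is size-independent).

## Known limitations

- No truncation/stemming, no phrase ranking beyond raw frequency, no
  n-grams beyond pairs, no MeSH tree traversal ("explode"), no
  precision/accuracy estimation — the relative recall of a single term is
  its document percentage, nothing more.
- The population model must be built from a user-supplied background
  corpus; no live database fetching.
- z-scores for MeSH/qualifier tables need the matching sections in the
  population model; with a free-text-only model every controlled-
  vocabulary term receives the 10000 sentinel (a loud warning is logged).
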