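# Methods

## Scope and model of the data

The package treats a herbarium occurrence table as a set of voucher
records, each carrying Darwin Core fields plus two derived values: a
parsed collection year and a higher group (angiosperm, gymnosperm,
lycophyte/fern). The catalogue-building problem is modelled as a fixed
sequence of record-level filters followed by a name-level resolution
step and species-level aggregation. All verbatim text (names,
localities, collector strings, dates) is preserved as read; folding —
case, accents, punctuation, whitespace — is applied only inside
comparison functions, because the source material is Portuguese-language
label text where accents are meaningful to a reader but unreliable in
transcription.

Coordinates are stored but never used for filtering: the protocol being
modelled filters on locality strings with a manual backstop, not on
point-in-polygon tests, and digitized coordinates in historical material
are too sparse and too error-prone to be the primary signal.

## Stage semantics and parameters

**Year parsing.** Collection dates in herbarium ledgers mix ISO-8601,
`DD/MM/YYYY` and bare years. All three contain the year as a standalone
4-digit token, so the parser scans for the first such token in
[1750, current year]. Anything else (e.g. "s.d.", month-only dates)
yields an absent year, which is counted in the parse report rather than
guessed.

**Determination filter.** A record counts as determined to species when
it has a specific epithet and its rank string is empty or at/below
species. Infraspecific determinations are kept but all downstream logic
uses the collapsed binomial, because the catalogue deliberately excludes
infraspecific taxa. Unrecognizable rank strings without an epithet count
as undetermined.

**Locality gazetteer.** Two term lists: *include* terms assert the
target area, *exclude* terms assert outside-area places. An exclude
match removes a record unless an include term matches on a word
boundary; an include match that is only an accidental substring (e.g. a
term for the park hiding inside the name of a different municipality)
creates a conflict, and conflicts are queued for manual review instead
of being resolved automatically — the protocol being modelled also
needed a manual pass for exactly these cases. Records matching neither
list follow a configurable default (`keep_and_queue` by default, `drop`
for strict runs).

**Deduplication.** The gathering key is (normalized collector, collector
number, collection year). Only complete keys merge: collector
normalization maps absent/empty to a distinguished UNKNOWN token and
records with UNKNOWN collector, missing number or missing year are never
merged, since merging on partial keys fabricates links. Within a key
group the record with the lexicographically smallest catalogue number is
kept — an arbitrary but deterministic, permutation-invariant choice.
Collection codes are ignored so duplicates across herbaria merge.
Collector normalization does not attempt initial reordering
("Brade, A.C." and "A.C. Brade" produce different keys); this
under-merges rather than over-merges, and such cases surface in
collector statistics instead of silently fusing records.

**Name matching.** Binomial-only (authorship is too heterogeneous to key
on), case/accent-insensitive, hybrid markers stripped. Preference:
exact accepted > exact synonym > fuzzy. The fuzzy search sums
Levenshtein distances over genus and epithet, bounded by `max_distance`
(default 1 — the reference name-matching tools do orthographic
suggestion without publishing a threshold, and a single edit covers the
common transcription slips without inviting false matches). Distances
are computed with edlib's banded alignment. If every minimal-distance
candidate points to the same accepted name the match resolves (typed
`fuzzy_accepted` / `fuzzy_synonym`); otherwise the result is ambiguous
and the record goes to the review queue — ties are never auto-broken,
mirroring reliance on taxonomists.

**Review.** A 3-column file (catalogNumber, action, name) with actions
`accept_as` (override/admit), `remove`, `add` (externally documented
records, e.g. vouchers from other herbaria); `add` rows may carry
taxonomist-supplied trait columns (`trait:origin`, `trait:category`),
used for species absent from the backbone. Review removals and
additions are logged to the ledger as separate stages, additions with a
signed `delta` field so the conservation invariant `input = kept +
removed` is preserved for true filtering stages.

**Traits.** Vegetation labels collapse to forest/grassland/both via an
editable label map seeded with the park's named vegetation types
(ombrophilous and seasonal forests on one side; high-altitude
grasslands, campos rupestres and inselbergs on the other). Life form
uses the majority rule: a single backbone form wins outright; several
backbone forms are decided by the most frequent form among the species'
own records (restricted to the backbone set), with ties and missing
evidence broken by the fixed precedence tree > shrub > subshrub >
liana > herb. The precedence order is an explicit stand-in for
unstated tie behaviour; it prefers the taller, more conspicuous habit,
and is exposed for configuration. Origin: cultivated/naturalised/
not-occurring tokens normalize to non-native. Threat categories come
from the assessment table; absent species are NE, never invented.

**Temporal classes and priority.** Old = year ≤ cutoff, recent = year >
cutoff, with cutoff 1969 by default. The cutoff's boundary year is
genuinely ambiguous in the source protocol ("after 1969" for recent,
"before 1969" for priority, 1969 itself unassigned); ≤ is the
priority-friendly reading and the cutoff is a parameter
(`--cutoff-year`). A species whose only record lacks a year is *not* a
priority: the rule requires a dated old record. Priority ⇔ record count
= 1 ∧ only-old ∧ category ∈ {CR, EN, VU, DD}.

**Percentages.** Composition percentages use half-up rounding at a
configurable precision (integer by default), since published summaries
mix integer and one-decimal reporting; the unrounded shares always sum
to 100%.

## The synthetic generator

The generator emulates the structure of a large park flora export:
~800 species split over three groups in realistic proportions
(overwhelmingly angiosperms, a handful of gymnosperms), ~5,000 base
records with a geometric (right-skewed, support ≥ 1) records-per-species
distribution, a zipf-skewed pool of 40 collectors, old (1871–1969) and
recent (1970–2018) collection years with a boosted peak year (1995),
and per-species backbone traits drawn to echo published magnitudes
(~3.4% non-native, ~50% endemic, a threat-category mix dominated by LC
with a few percent threatened). Planted imperfections: 10% duplicate
twins sharing a complete gathering key under a different barcode and
collection code, 5% one-edit misspellings, 2% out-of-area localities,
5% genus-level determinations, 2% each missing years and collectors,
synonym usage on a quarter of the records of synonym-bearing species.

Names are synthesized from pronounceable consonant–vowel syllables
rather than taken from real floras. This serves correctness, not just
hygiene: each planted misspelling is accepted only if its only backbone
neighbour within the matcher's distance budget is its source name, so
resolution ground truth is unambiguous by construction. The first
record of every species and all records of forced priority species are
exempt from destructive corruptions, guaranteeing each planted species
survives cleaning. The truth manifest (species sets, removal counts,
per-species record counts, temporal statuses, traits, the priority set,
collector tallies, the peak year) is computed from the generator's own
bookkeeping, independently of the pipeline; `verify_recovery` compares
the two exactly, with ties in the peak-year histogram broken to the
earliest year on both sides.

One seeded NumPy generator is consumed in a fixed stage order, giving
byte-identical output files for identical seed and config (verified
across processes). The generator's temporal truth uses the top of the
old-year range as its cutoff, so configs that move `old_year_range`
away from the pipeline's cutoff year must adjust both together.

What the generator does *not* emulate: spatially explicit localities,
realistic collector-effort time series, partial or reordered collector
name variants, label damage beyond single-edit misspellings, and
ambiguous name pairs. Passing recovery tests therefore demonstrate that
the pipeline's bookkeeping and matching are exact under controlled
noise — not that real-world herbarium data will resolve as cleanly;
real exports will route more records through the review queues.

## Problem sizes and numerical choices

Tests run the generator at two sizes: a small configuration (53 species,
~200 records) for unit and property tests, and the standard conditions
(800 species, ~5,000 records) for the end-to-end recovery check, which
completes in a few seconds. The acceptance script uses the standard
conditions with the caller's seed. Edit distances are exact (banded
only by the distance budget); no floating-point tolerances are involved
anywhere except percentage rounding, which is decimal half-up.

## Known limitations

- Collector keys are verbatim-order sensitive; heavily reformatted
  collector strings under-merge.
- The locality filter is purely lexical; a misspelled locality that
  matches no gazetteer term follows the default policy rather than
  being detected.
- Fuzzy matching is bounded by a global edit budget and does not weight
  by character class (e.g. vowel confusions) or name frequency.
- The review mechanism models taxonomist decisions as a flat action
  file; it does not track provenance or rounds of review.
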