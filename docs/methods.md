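# Methods

## Data model

The knowledge base holds six entity kinds — drugs, interactions, side
effects, molecules (as drug–molecule links), diseases, pathways — with
per-assertion provenance: the set of source tags supporting the
assertion. Interactions are keyed by the canonical (lexicographic)
unordered drug-id pair; side effects by (drug id, canonical term).
Re-asserting an existing key merges provenance instead of duplicating
the assertion, which is what makes concordance statistics well defined.
Effect texts are retained per asserting source rather than
concatenated, so the original wording of each database stays auditable;
when one source supplies several texts for the same pair, the
lexicographically smallest is kept so that row order never influences
the result.

Name handling uses a single normalization everywhere (case-fold, strip
punctuation, collapse whitespace). This keeps name-based drug mapping,
the auto-complete index, and diagnosis/side-effect matching mutually
consistent. No salt or stereochemistry suffix stripping is attempted:
without a vetted rule it fuses distinct substances more often than it
helps. Drugs may carry several ATC codes (true of real classifications);
codes shorter than the full 7 characters are dropped at parse time so a
class-level prefix can never cause a false fusion.

## Cross-source drug mapping

Two strategies mirror how real integrations reconcile sources:

* **identifier + ATC** (pharmaceutical ↔ molecular): a candidate link
  scores highest when one source's cross-reference names the other's
  native id (or both share an xref value), lower when the two drugs
  share a full 7-character ATC code;
* **name** (molecular ↔ side-effect source): normalized display names
  and synonyms must coincide.

Candidates are resolved to a 1:1 mapping greedily: higher score first,
ties broken by the lexicographically smallest native-id pair; losers
stay unlinked and enter the knowledge base as single-source drugs. The
tie-break is a declared convention — deterministic and auditable — not a
reconstruction of any production system's behavior. Contradictory
mappings (one native id linked to two ids of the same other source, or
a transitive chain fusing two drugs of one source) abort the merge
before any record is written.

A consequence of hub-based mapping worth knowing: a drug present in the
pharmaceutical and side-effect sources but absent from the molecular
hub has no mapping path, so its two copies remain separate records and
its name resolves ambiguously. The synthetic generator's demo profile
deliberately avoids such drugs.

## Concordance statistics

A *hit* is one distinct assertion key per source, not a row count —
required for the identities `union = a_only + b_only + shared` and
`shared = a_total + b_total − union` to hold. Both published counting
conventions are implemented: exclusive counts (whole-database
distribution style, integer percentages) and inclusive totals plus
union (top-N style, two decimals). `a_share`/`b_share` are the
inclusive per-source totals over the union (the top-N printing
convention), while `a_only_share`/`b_only_share` are the exclusive
shares (the distribution printing convention); both are carried so
either report style can be emitted from one summary. Percentages round
half-up via decimal arithmetic; an all-zero input defines every share
as 0 rather than raising. `kb_overlap` reports inclusive counts. The
top-N aggregate uses distinct hits involving at least one listed drug,
so a pair of two listed drugs is never double-counted.

## Medication analysis

All checks are deterministic set operations; result lists are sorted
(alphabetically by name, or by canonical pair) so repeated runs and the
network export are stable. The CYP rule is applied per ordered
(perpetrator, victim) pair sharing an enzyme-role molecule: inducer ×
substrate → the victim's dose may need *raising* (faster clearance),
inhibitor × substrate → *lowering*. The flag names the metabolized
(victim) drug as the one whose dose is at issue and records the
perpetrator and a plain-language rationale; it is advisory only.
Defective CYPs from the profile flag their substrate drugs as risks;
unknown CYP ids produce a warning and are skipped.

Diagnosis ↔ side-effect matching is exact on normalized canonical
terms (after routing the diagnosis through disease-record synonyms and
the side-effect synonym table). No fuzzy or hierarchical terminology
matching is attempted: without a stated distance or hierarchy the
false-positive behavior would be uncontrolled. Observed side effects in
a profile never create findings; they only annotate which prescribed
drugs could explain them. Duplicate drugs in an input list are silently
deduplicated.

## Radial network export

The document is topology plus levels; layout coordinates are left to
the renderer. For two-source partitions: inputs at level 0, shared
results ring 1 (green), first-source-only ring 2 (red),
second-source-only ring 3 (yellow). For composite medication reports
the color encodes the finding category (interactions red, enzyme links
violet, side effects yellow, no-risk drugs blue); one edge is emitted
per finding, where a finding is an interaction, a CYP flag, or one
drug's contribution to a cumulative effect or induced disease. Colors
are symbolic names, not pixel values. Serialization is JSON with sorted
keys and sorted node/edge order, so identical documents are
byte-identical and parse → serialize is a fixed point.

## Synthetic data generator

The generator emulates the integration setting the package targets: a
drug universe covered partially by each source, assertion sets with a
controlled cross-source overlap, synonym usage in side-effect mentions,
and identifier gaps forcing ATC- or name-based mapping. Defaults are
the package's study conditions: 120 drugs; coverage 0.85/0.90/0.80 for
the pharmaceutical/molecular/side-effect sources; 200 interaction hits
with overlap fraction 0.12 and 400 side-effect hits with 0.09 (the
concordance levels the tool is designed to surface); synonym rate 0.25;
mapping noise 0.2. Overlap is planted by exact counts
(`floor(fraction × universe)`), not coin flips, so recovery checks are
exact rather than within sampling error; shared side-effect hits are
planted only on drugs present in all three drug-carrying sources,
because only those fuse across the pharmaceutical–molecular–side-effect
chain. ATC codes are generated unique per drug, which makes noise-free
mapping recovery exact by construction. Everything derives from one
seeded RNG; identical parameters give byte-identical files.

What the generator does **not** emulate: realistic pharmacology or
dose–effect structure, real database size distributions, many-to-many
ATC collisions, misspelled or partially translated terms, or
frequency-class semantics. Passing tests therefore demonstrate the
correctness of the integration and analysis machinery under controlled
conditions, not performance on real commercial databases.

The bundled demo profile contains seven drugs chosen so that, by
construction, the analysis yields at least two pairwise interactions,
at least one cumulative side effect, at least one CYP
perpetrator/victim flag, one diagnosis that is a (cumulative)
drug-induced disease candidate, and — when an assertion-free drug
exists — a populated no-risk list. Expected answers are recorded in the
ground truth by brute-force bookkeeping over the generator's realized
structures, independent of the ingestion/analysis code path.

## Numerical and degenerate-input choices

* Rounding: half-up, integer or two-decimal, matching the two report
  styles.
* Empty inputs: an empty profile is an error; a single-drug profile
  yields an empty combined-interaction result with a logged notice; an
  all-zero overlap summary is defined, not an error.
* Ingestion is strict on schema (missing required column or missing
  drugs table fails the file) and lenient on content (malformed rows,
  unknown endpoints, invalid ATC codes are skipped and reported with
  line numbers).
* Unknown side-effect terms pass through normalized and are flagged
  unmapped rather than dropped, so no assertion is lost to an
  incomplete synonym table.

## Problem sizes

The test suite and the acceptance script run on generated bases of
40–120 drugs with 80–400 assertion hits and 100+ random profiles for
oracle comparisons — sizes at which brute-force oracles are exact and
the full suite completes in seconds.

## Known limitations

Severity labels are passed through, never interpreted or ranked. No
dose computation, pharmacokinetics, or benefit/risk quantification.
Disease matching is string-exact; a hierarchical terminology would
catch paraphrased diagnoses this package misses. The persistence format
(normalized TSVs + manifest) is meant for inspection and
reproducibility, not concurrent or incremental update.
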