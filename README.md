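# drugkb

Adverse drug reactions are a leading cause of preventable harm in
polypharmacy: no single drug-knowledge source lists all theoretically
possible drug–drug interactions or side effects, so a reliable
medication review has to consult both pharmaceutical (package-insert
derived) and molecular (target/enzyme derived) databases at once.
`drugkb` is a toolkit for exactly that workflow, aimed at medical
informatics researchers and decision-support developers. It

* **integrates** heterogeneous drug-knowledge sources — a pharmaceutical
  interaction/side-effect source, a molecular drug source, a side-effect
  source coded in a controlled vocabulary, and a pathway/disease
  source — into one knowledge base in which every assertion carries its
  *provenance* (the set of sources supporting it). Drugs are fused
  across sources by shared identifiers and full 7-character ATC codes,
  or by normalized names where no identifiers exist; side-effect terms
  are resolved through a synonym table to canonical forms;
* **analyzes medications**: single and combined drug–drug interactions,
  drug–molecule links, cytochrome-P450 dosage flags, cumulative side
  effects, and drug-induced disease candidates;
* **quantifies concordance** between two sources' hit sets;
* **exports** results as level-coded radial network JSON documents for
  visualization.

## The statistics at the core

A *hit* is one distinct assertion key per source: a canonical
(lexicographically ordered) drug pair for interactions, a
(drug, canonical term) pair for side effects. For two sources A and B
with hit sets H_A, H_B:

* union `u = |H_A ∪ H_B|`, intersection
  `s = |H_A ∩ H_B| = |H_A| + |H_B| − u` (inclusion–exclusion),
* concordance (shared share) `s/u`, non-correlative share `(u − s)/u`,
* unmatched share `(u − s)/(|H_A| + |H_B|)` — the fraction of the
  *multiset* of recorded hits with no counterpart in the other source.

Both published counting conventions are supported: exclusive counts
(A-only, B-only, shared; used for whole-database distributions with
integer percentages) and inclusive per-source totals plus the union
(used for top-N drug tables with two-decimal percentages). Percentages
round half-up.

The medication checks are set operations over the merged base: combined
interactions are the asserted pairs within the prescription; a
*cumulative side effect* is a canonical term asserted for ≥ 2 of the
prescribed drugs; a *drug-induced disease* candidate is a diagnosis
whose normalized name matches a canonical side-effect term of ≥ 1
prescribed drug (cumulative when matched by ≥ 2). CYP flags follow the
induction/inhibition rule: if drug P induces an enzyme that metabolizes
drug V, V's clearance speeds up and its dose may need raising; if P
inhibits it, V's dose may be lowered; a defective CYP makes its
substrate drugs a risk. Flags are advisory, never a dose computation.

## Worked example

```bash
python examples/02_medication_check.py
```

generates a synthetic four-source file set (120 drugs, 200 interaction
hits with a planted 12% overlap, 400 side-effect hits with 9%), ingests
it, and analyzes the bundled seven-drug demo profile:

```
profile: DRUG_0012, DRUG_0076, DRUG_0028, DRUG_0040, DRUG_0016, DRUG_0001, DRUG_0002

2 pairwise interaction(s):
  DRUG_0012 -- DRUG_0076 [MOLDB, PHARM]
  DRUG_0016 -- DRUG_0076 [MOLDB]

2 CYP dosage flag(s):
  DRUG_0012 induces CYP1A2, which metabolizes DRUG_0016; faster clearance may call for a higher dose of the metabolized drug to stay therapeutic
  ...

cumulative side effects (>= 2 drugs):
  abdominal pain: DRUG_0028, DRUG_0040
  ...

drug-induced disease candidates (50% of diagnoses):
  abdominal pain: DRUG_0028, DRUG_0040

drugs without potential risks: DRUG_0001, DRUG_0002
```

The first interaction is asserted by both the pharmaceutical and the
molecular source (it would sit on the green inner ring of the radial
network); the second is molecular-only — the kind of finding a checker
restricted to one database would miss. "abdominal pain" is both a
cumulative side effect (two drugs cause it) and, because it also appears
among the diagnoses, a cumulative drug-induced disease candidate.

The other examples cover knowledge-base construction
(`01_build_knowledge_base.py`), concordance statistics
(`03_concordance_stats.py`) and network export (`04_radial_network.py`).

## Command line

```bash
drugkb simulate --seed 1 --out sources/          # synthetic file set
drugkb ingest --source-dir sources/ --out kb/    # merge into a KB artifact
drugkb check medication --kb kb/ --drugs DRUG_0012,DRUG_0076,...
drugkb stats --kb kb/ --kind interactions
drugkb stats --exclusive-counts 29854,15518,6148 --rounding int
drugkb suggest --kb kb/ --prefix DRUG_00
```

Exit codes: 0 success, 2 usage/configuration error, 3 data/schema
error, 5 ran with warnings. Logs go to stderr, results to stdout.

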