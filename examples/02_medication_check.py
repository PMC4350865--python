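"""Run the composite molecular medication analysis on the bundled demo
profile (seven drugs, two observed side effects, two diagnoses).

The report combines four checks: pairwise interactions among the
prescribed drugs, CYP induction/inhibition dosage flags, cumulative
side effects (terms asserted for two or more of the drugs), and
drug-induced disease candidates (diagnoses matching a side-effect term
of a prescribed drug).
"""

import tempfile
from pathlib import Path

from drugkb import synth
from drugkb.analysis import molecular_medication_analysis

workdir = Path(tempfile.mkdtemp())
gt = synth.generate(synth.GeneratorParams(seed=1), workdir)
kb = synth.ingest_generated(workdir)

profile = synth.demo_profile(gt, kb)
report = molecular_medication_analysis(profile, kb)

print("profile:", ", ".join(kb.drug_name(d) for d in profile.drug_ids))
print(f"\n{len(report.pairwise_interactions)} pairwise interaction(s):")
for a in report.pairwise_interactions:
    print(f"  {kb.drug_name(a.pair[0])} -- {kb.drug_name(a.pair[1])} "
          f"[{', '.join(sorted(a.provenance))}]")
print(f"\n{len(report.cyp_flags)} CYP dosage flag(s):")
for f in report.cyp_flags:
    print(f"  {f.rationale}")
print(f"\ncumulative side effects (>= 2 drugs):")
for term, drugs in report.cumulative_effects.items():
    print(f"  {term}: {', '.join(sorted(kb.drug_name(d) for d in drugs))}")
print(f"\ndrug-induced disease candidates "
      f"({report.induced_diseases.fraction_flagged:.0%} of diagnoses):")
for diag, drugs in report.induced_diseases.matches.items():
    print(f"  {diag}: {', '.join(sorted(kb.drug_name(d) for d in drugs))}")
print("\ndrugs without potential risks:",
      ", ".join(kb.drug_name(d) for d in report.no_risk_drug_ids) or "-")
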