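"""Export a single-drug interaction query as a radial network document.

Inputs sit at level 0 in the center; partners shared by both sources on
ring 1 (green), pharmaceutical-source-only partners on ring 2 (red),
molecular-source-only partners on ring 3 (yellow). The JSON is
byte-deterministic, so downstream renderers can cache it.
"""

import tempfile
from pathlib import Path

from drugkb import synth
from drugkb.analysis import single_drug_interactions
from drugkb.network import build_radial_network, serialize_network

workdir = Path(tempfile.mkdtemp())
gt = synth.generate(synth.GeneratorParams(seed=1), workdir)
kb = synth.ingest_generated(workdir)

center = gt.demo["drugs"][0]
part = single_drug_interactions(center, kb, sources=(synth.PHARM, synth.MOLDB))
doc = build_radial_network(part, kb)

print(f"center: {part.center}")
print(f"ring 1 (shared, green): {part.shared}")
print(f"ring 2 ({part.source_a} only, red): {part.only_a}")
print(f"ring 3 ({part.source_b} only, yellow): {part.only_b}")
print(f"{len(doc.nodes)} nodes, {len(doc.edges)} edges "
      f"(one edge per interaction finding)")
text = serialize_network(doc)
assert text == serialize_network(build_radial_network(
    single_drug_interactions(center, kb, sources=(synth.PHARM, synth.MOLDB)), kb))
print("serialization is byte-identical across runs")
print(text[:400], "...")
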