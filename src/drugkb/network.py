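"""Radial, level-coded network documents for result visualization.

Analysis results are converted into a serializable node/edge document:
input entities sit at level 0 in the center, result entities on
concentric rings whose level and symbolic color encode provenance or
finding category. For a two-source partition the scheme is
shared → ring 1 (green), first-source-only → ring 2 (red),
second-source-only → ring 3 (yellow). For a composite medication report
the coloring follows finding category: drug-drug interactions red,
drug-enzyme links violet, side effects yellow, no-risk drugs blue.

Layout coordinates are deliberately not computed — the document is
topology plus levels, and pixel styling is left to the consumer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

from .model import DrugKBError, KnowledgeBase
from .analysis import (
    MedicationReport,
    PathwayView,
    ProvenancePartition,
)

COLOR_SHARED = "green"
COLOR_SOURCE_A = "red"
COLOR_SOURCE_B = "yellow"
COLOR_INTERACTION = "red"
COLOR_MOLECULE = "violet"
COLOR_SIDE_EFFECT = "yellow"
COLOR_NO_RISK = "blue"
COLOR_INPUT = "grey"

_PARTITION_RELATION = {"interactions": "interacts", "side_effects": "causes"}
_PARTITION_ENTITY = {"interactions": "drug", "side_effects": "side_effect"}


@dataclass
class RadialNetworkDoc:
    """Serializable radial network: nodes with levels and symbolic colors,
    edges with relation/provenance/detail, and a level legend."""

    nodes: list[dict[str, Any]] = field(default_factory=list)
    edges: list[dict[str, Any]] = field(default_factory=list)
    legend: dict[str, str] = field(default_factory=dict)

    def add_node(self, node_id: str, label: str, entity_type: str,
                 level: int, color_code: str) -> None:
        self.nodes.append({
            "node_id": node_id, "label": label, "entity_type": entity_type,
            "level": level, "color_code": color_code,
        })

    def add_edge(self, from_id: str, to_id: str, relation: str,
                 provenance: list[str], detail: str = "") -> None:
        self.edges.append({
            "from": from_id, "to": to_id, "relation": relation,
            "provenance": sorted(provenance), "detail": detail,
        })

    def finalize(self) -> "RadialNetworkDoc":
        """Deterministic ordering: nodes by (level, label, id), edges by
        their full key."""
        self.nodes.sort(key=lambda n: (n["level"], n["label"], n["node_id"]))
        self.edges.sort(key=lambda e: (e["from"], e["to"], e["relation"], e["detail"]))
        node_ids = {n["node_id"] for n in self.nodes}
        for edge in self.edges:
            if edge["from"] not in node_ids or edge["to"] not in node_ids:
                raise DrugKBError(f"edge references missing node: {edge}")
        return self

    def to_dict(self) -> dict[str, Any]:
        return {"nodes": self.nodes, "edges": self.edges, "legend": self.legend}

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RadialNetworkDoc":
        return cls(nodes=list(data.get("nodes", [])),
                   edges=list(data.get("edges", [])),
                   legend=dict(data.get("legend", {})))


def _build_from_partition(result: ProvenancePartition) -> RadialNetworkDoc:
    doc = RadialNetworkDoc(legend={
        "0": "input",
        "1": f"shared by {result.source_a} and {result.source_b} ({COLOR_SHARED})",
        "2": f"{result.source_a} only ({COLOR_SOURCE_A})",
        "3": f"{result.source_b} only ({COLOR_SOURCE_B})",
    })
    center_id = f"center:{result.center}"
    doc.add_node(center_id, result.center, "drug", 0, COLOR_INPUT)
    relation = _PARTITION_RELATION[result.kind]
    entity = _PARTITION_ENTITY[result.kind]
    ring_spec = [
        (1, COLOR_SHARED, result.shared, [result.source_a, result.source_b]),
        (2, COLOR_SOURCE_A, result.only_a, [result.source_a]),
        (3, COLOR_SOURCE_B, result.only_b, [result.source_b]),
    ]
    for level, color, labels, provenance in ring_spec:
        for label in labels:
            node_id = f"{entity}:{label}"
            doc.add_node(node_id, label, entity, level, color)
            doc.add_edge(center_id, node_id, relation, provenance)
    return doc.finalize()


def _build_from_report(result: MedicationReport, kb: KnowledgeBase) -> RadialNetworkDoc:
    doc = RadialNetworkDoc(legend={
        "0": f"prescribed drugs (at-risk {COLOR_INTERACTION}, "
             f"no-risk {COLOR_NO_RISK})",
        "1": f"enzymes/molecules ({COLOR_MOLECULE})",
        "2": f"cumulative side effects ({COLOR_SIDE_EFFECT})",
        "3": f"drug-induced disease candidates ({COLOR_SIDE_EFFECT})",
    })
    no_risk = set(result.no_risk_drug_ids)
    for drug_id in result.profile.drug_ids:
        color = COLOR_NO_RISK if drug_id in no_risk else COLOR_INTERACTION
        doc.add_node(f"drug:{drug_id}", kb.drug_name(drug_id), "drug", 0, color)
    for assertion in result.pairwise_interactions:
        a, b = assertion.pair
        doc.add_edge(f"drug:{a}", f"drug:{b}", "interacts",
                     sorted(assertion.provenance), assertion.effect)
    molecule_ids = {flag.cyp_molecule_id for flag in result.cyp_flags}
    for mol in sorted(molecule_ids):
        doc.add_node(f"molecule:{mol}", mol, "molecule", 1, COLOR_MOLECULE)
    for flag in result.cyp_flags:
        doc.add_edge(f"drug:{flag.perpetrator_drug_id}",
                     f"molecule:{flag.cyp_molecule_id}", "metabolizes",
                     [], f"{flag.direction}: {flag.rationale}")
    for term in sorted(result.cumulative_effects):
        doc.add_node(f"side_effect:{term}", term, "side_effect", 2,
                     COLOR_SIDE_EFFECT)
        for drug_id in sorted(result.cumulative_effects[term]):
            doc.add_edge(f"drug:{drug_id}", f"side_effect:{term}", "causes", [])
    for diagnosis in sorted(result.induced_diseases.matches):
        doc.add_node(f"disease:{diagnosis}", diagnosis, "disease", 3,
                     COLOR_SIDE_EFFECT)
        for drug_id in sorted(result.induced_diseases.matches[diagnosis]):
            doc.add_edge(f"drug:{drug_id}", f"disease:{diagnosis}",
                         "induces_disease", [])
    return doc.finalize()


def _build_from_pathway(result: PathwayView, kb: KnowledgeBase) -> RadialNetworkDoc:
    doc = RadialNetworkDoc(legend={
        "0": "pathway (input)",
        "1": f"drugs of {result.chosen_source} ({COLOR_INTERACTION})",
        "2": f"linked diseases ({COLOR_SIDE_EFFECT})",
    })
    center_id = f"pathway:{result.pathway_id}"
    doc.add_node(center_id, result.pathway_name, "pathway", 0, COLOR_INPUT)
    for drug_id in result.drug_ids:
        node_id = f"drug:{drug_id}"
        doc.add_node(node_id, kb.drug_name(drug_id), "drug", 1, COLOR_INTERACTION)
        doc.add_edge(node_id, center_id, "member_of", [result.chosen_source])
    for disease_id in result.disease_ids:
        label = kb.diseases[disease_id].name if disease_id in kb.diseases else disease_id
        node_id = f"disease:{disease_id}"
        doc.add_node(node_id, label, "disease", 2, COLOR_SIDE_EFFECT)
        doc.add_edge(center_id, node_id, "induces_disease", [])
    return doc.finalize()


def build_radial_network(result, kb: KnowledgeBase) -> RadialNetworkDoc:
    """Convert an analysis result into a radial network document.

    Accepts a :class:`ProvenancePartition`, a :class:`MedicationReport`
    or a :class:`PathwayView`. An empty result yields a document with
    only its central input nodes.
    """
    if isinstance(result, ProvenancePartition):
        return _build_from_partition(result)
    if isinstance(result, MedicationReport):
        return _build_from_report(result, kb)
    if isinstance(result, PathwayView):
        return _build_from_pathway(result, kb)
    raise DrugKBError(f"cannot build a network from {type(result).__name__}")


def serialize_network(doc: RadialNetworkDoc) -> str:
    """Deterministic JSON serialization (sorted keys, stable node order);
    parse → serialize is a fixed point."""
    return json.dumps(doc.to_dict(), sort_keys=True, indent=2,
                      ensure_ascii=False) + "\n"


def parse_network(text: str) -> RadialNetworkDoc:
    return RadialNetworkDoc.from_dict(json.loads(text))
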