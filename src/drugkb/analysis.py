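"""Medication analysis over the merged knowledge base.

Implements the query features a clinician-facing interaction checker
offers: interaction partners of one drug, pairwise interactions within a
multi-medication, drug–molecule links, cytochrome-P450 dosage flags,
single and cumulative side effects, drug-induced disease detection,
pathway networks, and the composite molecular medication analysis that
ties them together.

Results that compare two sources are returned as a
:class:`ProvenancePartition` — items asserted by both sources, by the
first only, and by the second only — mirroring the ring structure of the
radial result network (shared hits innermost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from ._text import normalize
from .model import (
    AmbiguousMatchError,
    InteractionAssertion,
    KnowledgeBase,
    MOLECULE_ROLES,
    MoleculeLink,
    NotFoundError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: CYP flag directions and the advisory dose consequence attached to each.
DIRECTION_RAISE = "induction:raise_dose"
DIRECTION_LOWER = "inhibition:lower_dose"
DIRECTION_RISK = "defective:risk"


@dataclass
class MedicationProfile:
    """A patient's medication context: prescribed drugs, diagnoses,
    observed side effects, and CYP enzymes known to be defective."""

    drug_ids: list[str]
    diagnoses: list[str] = field(default_factory=list)
    observed_effects: list[str] = field(default_factory=list)
    defective_cyps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.drug_ids = list(dict.fromkeys(self.drug_ids))

    @classmethod
    def from_names(
        cls,
        kb: KnowledgeBase,
        drugs: Iterable[str],
        diagnoses: Iterable[str] = (),
        observed_effects: Iterable[str] = (),
        defective_cyps: Iterable[str] = (),
    ) -> "MedicationProfile":
        return cls(
            drug_ids=[kb.require_drug(d) for d in drugs],
            diagnoses=list(diagnoses),
            observed_effects=list(observed_effects),
            defective_cyps=list(defective_cyps),
        )


@dataclass
class ProvenancePartition:
    """Items split by which of two sources assert them; the three parts
    are pairwise disjoint and each is sorted."""

    center: str
    kind: str  # "interactions" | "side_effects"
    source_a: str
    source_b: str
    shared: list[str] = field(default_factory=list)
    only_a: list[str] = field(default_factory=list)
    only_b: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CypFlag:
    """Advisory dose/risk flag from CYP induction, inhibition or defect.

    The victim is the drug metabolized by the CYP; for induction its
    clearance speeds up (dose may need raising to stay therapeutic), for
    inhibition it slows (dose may be lowered), and a defective CYP makes
    the substrate drug itself a risk. Advisory only — not a dosing
    computation.
    """

    perpetrator_drug_id: str
    cyp_molecule_id: str
    victim_drug_id: str
    direction: str
    rationale: str


@dataclass
class InducedDiseaseResult:
    """Diagnoses that match a side-effect term of a prescribed drug."""

    matches: dict[str, frozenset[str]]          # diagnosis -> contributing drugs
    cumulative: dict[str, frozenset[str]]       # subset matched by >= 2 drugs
    fraction_flagged: float                     # flagged / total diagnoses
    unresolved: list[str] = field(default_factory=list)


@dataclass
class PathwayView:
    """Drugs of a chosen source mapped on one pathway, hit counts for the
    remaining sources, and the pathway's linked diseases."""

    pathway_id: str
    pathway_name: str
    chosen_source: str
    drug_ids: list[str]
    other_source_counts: dict[str, int]
    disease_ids: list[str]


@dataclass
class MedicationReport:
    """Composite result of the molecular medication analysis."""

    profile: MedicationProfile
    pairwise_interactions: list[InteractionAssertion]
    cyp_flags: list[CypFlag]
    cumulative_effects: dict[str, frozenset[str]]
    induced_diseases: InducedDiseaseResult
    no_risk_drug_ids: list[str]
    explained_observed: dict[str, frozenset[str]]
    warnings: list[str] = field(default_factory=list)


def _infer_source_pair(kb: KnowledgeBase, kind: str) -> tuple[str, str]:
    """Default comparison pair: the two sources (in registration order)
    that actually assert items of this kind."""
    assertions = kb.interactions if kind == "interactions" else kb.side_effects
    tags_seen = set()
    for a in assertions.values():
        tags_seen.update(a.provenance)
    ordered = [t for t in kb.source_tags if t in tags_seen]
    if len(ordered) < 2:
        # degenerate: fall back to the first registered tags
        ordered = (ordered + [t for t in kb.source_tags if t not in ordered])[:2]
    if len(ordered) < 2:
        raise ValidationError("knowledge base has fewer than two source tags")
    return ordered[0], ordered[1]


def _partition(
    items: dict[str, frozenset[str]], source_a: str, source_b: str
) -> tuple[list[str], list[str], list[str]]:
    shared, only_a, only_b = [], [], []
    for label in sorted(items):
        prov = items[label]
        if source_a in prov and source_b in prov:
            shared.append(label)
        elif source_a in prov:
            only_a.append(label)
        elif source_b in prov:
            only_b.append(label)
    return shared, only_a, only_b


def single_drug_interactions(
    drug: str,
    kb: KnowledgeBase,
    sources: Optional[tuple[str, str]] = None,
) -> ProvenancePartition:
    """Interaction partners of one drug, partitioned by asserting source
    and sorted alphabetically by partner name."""
    drug_id = kb.require_drug(drug)
    source_a, source_b = sources or _infer_source_pair(kb, "interactions")
    partners: dict[str, frozenset[str]] = {}
    for assertion in kb.interactions_of(drug_id):
        partner = assertion.partner_of(drug_id)
        partners[kb.drug_name(partner)] = assertion.provenance
    shared, only_a, only_b = _partition(partners, source_a, source_b)
    return ProvenancePartition(
        center=kb.drug_name(drug_id), kind="interactions",
        source_a=source_a, source_b=source_b,
        shared=shared, only_a=only_a, only_b=only_b,
    )


def combined_drug_interactions(
    profile: MedicationProfile, kb: KnowledgeBase
) -> list[InteractionAssertion]:
    """All asserted interactions among the profile's drugs, in canonical
    pair order. Fewer than two drugs yields an empty result (logged)."""
    if len(profile.drug_ids) < 2:
        logger.info("combined interaction check needs >= 2 drugs; got %d",
                    len(profile.drug_ids))
        return []
    for d in profile.drug_ids:
        if d not in kb.drugs:
            raise NotFoundError(f"unknown drug_id {d!r} in profile")
    drug_set = set(profile.drug_ids)
    return [
        kb.interactions[pair]
        for pair in sorted(kb.interactions)
        if pair[0] in drug_set and pair[1] in drug_set
    ]


def drug_molecule_interactions(
    drug: str, kb: KnowledgeBase
) -> dict[str, list[MoleculeLink]]:
    """Molecule links of one drug grouped by role in fixed order
    target → enzyme → transporter → carrier, each sorted by molecule id."""
    drug_id = kb.require_drug(drug)
    groups: dict[str, list[MoleculeLink]] = {role: [] for role in MOLECULE_ROLES}
    for link in kb.molecule_links_of(drug_id):
        groups[link.molecule_role].append(link)
    for role in groups:
        groups[role].sort(key=lambda l: (l.molecule_id, l.action))
    return groups


def cyp_dosage_flags(
    profile: MedicationProfile,
    kb: KnowledgeBase,
    warnings: Optional[list[str]] = None,
) -> list[CypFlag]:
    """CYP induction/inhibition flags for every ordered perpetrator/victim
    pair of profile drugs sharing an enzyme, plus risk flags for profile
    drugs metabolized by a defective CYP."""
    for d in profile.drug_ids:
        if d not in kb.drugs:
            raise NotFoundError(f"unknown drug_id {d!r} in profile")
    enzyme_links = [
        l for l in kb.molecule_links.values()
        if l.molecule_role == "enzyme" and l.drug_id in set(profile.drug_ids)
    ]
    by_drug: dict[str, list[MoleculeLink]] = {}
    for link in enzyme_links:
        by_drug.setdefault(link.drug_id, []).append(link)

    flags: list[CypFlag] = []
    for perp in profile.drug_ids:
        for victim in profile.drug_ids:
            if perp == victim:
                continue
            for p_link in by_drug.get(perp, ()):
                if p_link.action not in ("inducer", "inhibitor"):
                    continue
                for v_link in by_drug.get(victim, ()):
                    if (v_link.action == "substrate"
                            and v_link.molecule_id == p_link.molecule_id):
                        if p_link.action == "inducer":
                            direction = DIRECTION_RAISE
                            rationale = (
                                f"{kb.drug_name(perp)} induces {p_link.molecule_id}, "
                                f"which metabolizes {kb.drug_name(victim)}; faster "
                                f"clearance may call for a higher dose of the "
                                f"metabolized drug to stay therapeutic")
                        else:
                            direction = DIRECTION_LOWER
                            rationale = (
                                f"{kb.drug_name(perp)} inhibits {p_link.molecule_id}, "
                                f"which metabolizes {kb.drug_name(victim)}; slower "
                                f"clearance may allow a lower dose and fewer side "
                                f"effects")
                        flags.append(CypFlag(perp, p_link.molecule_id, victim,
                                             direction, rationale))

    known_molecules = kb.molecule_ids()
    for cyp in profile.defective_cyps:
        if cyp not in known_molecules:
            msg = f"defective CYP {cyp!r} is not a known molecule; skipped"
            logger.warning(msg)
            if warnings is not None:
                warnings.append(msg)
            continue
        for victim in profile.drug_ids:
            for v_link in by_drug.get(victim, ()):
                if v_link.action == "substrate" and v_link.molecule_id == cyp:
                    flags.append(CypFlag(
                        victim, cyp, victim, DIRECTION_RISK,
                        f"{kb.drug_name(victim)} is a substrate of defective "
                        f"{cyp}; impaired clearance is a risk"))
    flags.sort(key=lambda f: (f.victim_drug_id, f.cyp_molecule_id,
                              f.perpetrator_drug_id, f.direction))
    return flags


def single_drug_side_effects(
    drug: str,
    kb: KnowledgeBase,
    sources: Optional[tuple[str, str]] = None,
) -> ProvenancePartition:
    """Canonical side-effect terms of one drug partitioned by asserting
    source, each part alphabetically sorted."""
    drug_id = kb.require_drug(drug)
    source_a, source_b = sources or _infer_source_pair(kb, "side_effects")
    terms = {a.term: a.provenance for a in kb.side_effects_of(drug_id)}
    shared, only_a, only_b = _partition(terms, source_a, source_b)
    return ProvenancePartition(
        center=kb.drug_name(drug_id), kind="side_effects",
        source_a=source_a, source_b=source_b,
        shared=shared, only_a=only_a, only_b=only_b,
    )


def cumulative_side_effects(
    profile: MedicationProfile, kb: KnowledgeBase
) -> dict[str, frozenset[str]]:
    """Side-effect terms asserted for at least two distinct profile drugs,
    mapped to their contributing drug sets."""
    if not profile.drug_ids:
        raise ValidationError("empty medication profile")
    contributors: dict[str, set[str]] = {}
    for drug_id in profile.drug_ids:
        if drug_id not in kb.drugs:
            raise NotFoundError(f"unknown drug_id {drug_id!r} in profile")
        for assertion in kb.side_effects_of(drug_id):
            contributors.setdefault(assertion.term, set()).add(drug_id)
    return {
        term: frozenset(drugs)
        for term, drugs in sorted(contributors.items())
        if len(drugs) >= 2
    }


def drug_induced_diseases(
    profile: MedicationProfile, kb: KnowledgeBase
) -> InducedDiseaseResult:
    """Flag diagnoses whose normalized name (or a known synonym) equals a
    canonical side-effect term of at least one profile drug; the
    cumulative subset is matched by two or more drugs."""
    terms_by_drug: dict[str, set[str]] = {
        d: {a.term for a in kb.side_effects_of(d)} for d in profile.drug_ids
    }
    disease_by_name: dict[str, list[str]] = {}
    for disease in kb.diseases.values():
        for name in [disease.name, *disease.synonyms]:
            disease_by_name.setdefault(normalize(name), []).append(disease.disease_id)

    matches: dict[str, frozenset[str]] = {}
    unresolved: list[str] = []
    for diagnosis in profile.diagnoses:
        if not diagnosis.strip():
            unresolved.append(diagnosis)
            continue
        # candidate canonical terms for this diagnosis: its own normalized
        # name plus the names/synonyms of any disease record it resolves to
        names = {normalize(diagnosis)}
        for did in disease_by_name.get(normalize(diagnosis), ()):
            record = kb.diseases[did]
            names.update(normalize(n) for n in [record.name, *record.synonyms])
        candidate_terms = {kb.canonicalize_term(n) for n in names}
        contributing = {
            d for d, terms in terms_by_drug.items() if terms & candidate_terms
        }
        if contributing:
            matches[diagnosis] = frozenset(contributing)
    fraction = len(matches) / len(profile.diagnoses) if profile.diagnoses else 0.0
    return InducedDiseaseResult(
        matches=matches,
        cumulative={d: s for d, s in matches.items() if len(s) >= 2},
        fraction_flagged=fraction,
        unresolved=unresolved,
    )


def pathway_network(
    query: str, kb: KnowledgeBase, chosen_source: str
) -> PathwayView:
    """Drugs of the chosen source linked to a pathway, hit counts for the
    remaining sources, and the pathway's disease links."""
    if chosen_source not in kb.source_tags:
        raise ValidationError(f"unknown source tag {chosen_source!r}")
    if query in kb.pathways:
        pathway = kb.pathways[query]
    else:
        norm = normalize(query)
        hits = [p for p in kb.pathways.values() if normalize(p.name) == norm]
        if not hits:
            raise NotFoundError(f"unknown pathway {query!r}")
        if len(hits) > 1:
            raise AmbiguousMatchError(query, [p.pathway_id for p in hits])
        pathway = hits[0]
    chosen: list[str] = []
    other_counts = {t: 0 for t in kb.source_tags if t != chosen_source}
    for drug_id in pathway.linked_drug_ids:
        drug = kb.drugs.get(drug_id)
        if drug is None:
            continue
        if chosen_source in drug.source_ids:
            chosen.append(drug_id)
        for tag in drug.source_ids:
            if tag != chosen_source:
                other_counts[tag] = other_counts.get(tag, 0) + 1
    chosen.sort(key=kb.drug_name)
    return PathwayView(
        pathway_id=pathway.pathway_id, pathway_name=pathway.name,
        chosen_source=chosen_source, drug_ids=chosen,
        other_source_counts=other_counts,
        disease_ids=sorted(pathway.linked_disease_ids),
    )


def molecular_medication_analysis(
    profile: MedicationProfile, kb: KnowledgeBase
) -> MedicationReport:
    """Composite medication check: pairwise interactions, CYP dosage
    flags, cumulative side effects and drug-induced disease candidates,
    plus the profile drugs with no findings at all.

    Observed side effects never create findings; they only annotate which
    profile drugs could explain them.
    """
    if not profile.drug_ids:
        raise ValidationError("empty medication profile")
    warnings: list[str] = []
    interactions = combined_drug_interactions(profile, kb)
    flags = cyp_dosage_flags(profile, kb, warnings)
    cumulative = cumulative_side_effects(profile, kb)
    induced = drug_induced_diseases(profile, kb)

    explained: dict[str, frozenset[str]] = {}
    for observed in profile.observed_effects:
        term = kb.canonicalize_term(observed)
        causing = {
            d for d in profile.drug_ids
            if any(a.term == term for a in kb.side_effects_of(d))
        }
        if causing:
            explained[observed] = frozenset(causing)

    at_risk: set[str] = set()
    for assertion in interactions:
        at_risk.update(assertion.pair)
    for flag in flags:
        at_risk.add(flag.perpetrator_drug_id)
        at_risk.add(flag.victim_drug_id)
    for drugs in cumulative.values():
        at_risk.update(drugs)
    for drugs in induced.matches.values():
        at_risk.update(drugs)
    no_risk = sorted(
        (d for d in profile.drug_ids if d not in at_risk), key=kb.drug_name
    )
    return MedicationReport(
        profile=profile,
        pairwise_interactions=interactions,
        cyp_flags=flags,
        cumulative_effects=cumulative,
        induced_diseases=induced,
        no_risk_drug_ids=no_risk,
        explained_observed=explained,
        warnings=warnings,
    )
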