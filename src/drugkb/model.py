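"""Core entity types and the merged knowledge-base container.

The knowledge base holds six entity kinds — drugs, interactions, side
effects, molecules (via drug–molecule links), diseases, and pathways —
with every assertion tagged by the set of sources that support it
(its *provenance*). Drug lookup is name-based: a normalized name index
covers display names and synonyms and backs both exact resolution and
prefix auto-completion.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from ._text import is_valid_atc, normalize

MOLECULE_ROLES = ("target", "enzyme", "transporter", "carrier")
MOLECULE_ACTIONS = ("inhibitor", "inducer", "substrate", "unknown")

_KB_FORMAT_VERSION = 1


class DrugKBError(Exception):
    """Base class for knowledge-base errors."""


class NotFoundError(DrugKBError, KeyError):
    """An entity referenced by name or id does not exist."""


class AmbiguousMatchError(DrugKBError):
    """A name query matches more than one distinct entity."""

    def __init__(self, query: str, candidates: Sequence[str]):
        self.query = query
        self.candidates = sorted(candidates)
        super().__init__(
            f"query {query!r} is ambiguous; candidates: {', '.join(self.candidates)}"
        )


class ValidationError(DrugKBError, ValueError):
    """An entity violates a structural invariant."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered drug pair ``{a, b}`` in canonical (lexicographic) order.

    Raises :class:`ValidationError` for a self-pair. Idempotent on
    already-canonical pairs.
    """
    if a == b:
        raise ValidationError(f"self-interaction pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def _dedupe_normalized(items: Iterable[str]) -> list[str]:
    """Drop later items whose normalized form repeats an earlier one."""
    seen: set[str] = set()
    out: list[str] = []
    for item in items:
        key = normalize(item)
        if key and key not in seen:
            seen.add(key)
            out.append(item)
    return out


@dataclass
class DrugRecord:
    """A drug (active agent) with its names, ATC codes and per-source ids."""

    drug_id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    atc_codes: list[str] = field(default_factory=list)
    source_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValidationError(f"drug {self.drug_id!r} has an empty name")
        for code in self.atc_codes:
            if not is_valid_atc(code):
                raise ValidationError(
                    f"drug {self.drug_id!r}: invalid ATC code {code!r}"
                )
        self.synonyms = _dedupe_normalized(self.synonyms)

    def all_names(self) -> list[str]:
        return [self.name, *self.synonyms]


@dataclass
class InteractionAssertion:
    """An unordered drug pair asserted to interact, with source provenance.

    Effect/mechanism texts are kept per asserting source rather than
    concatenated; :attr:`effect` is a deterministic joined view.
    """

    pair: tuple[str, str]
    effects: dict[str, str] = field(default_factory=dict)
    severity: Optional[str] = None
    provenance: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.pair = canonical_pair(*self.pair)
        self.provenance = frozenset(self.provenance)
        if not self.provenance:
            raise ValidationError(f"interaction {self.pair} has empty provenance")

    @property
    def effect(self) -> str:
        texts: list[str] = []
        for tag in sorted(self.effects):
            if self.effects[tag] and self.effects[tag] not in texts:
                texts.append(self.effects[tag])
        return "; ".join(texts)

    def involves(self, drug_id: str) -> bool:
        return drug_id in self.pair

    def partner_of(self, drug_id: str) -> str:
        if drug_id == self.pair[0]:
            return self.pair[1]
        if drug_id == self.pair[1]:
            return self.pair[0]
        raise NotFoundError(f"{drug_id!r} not in pair {self.pair}")


@dataclass
class SideEffectAssertion:
    """A (drug, canonical side-effect term) assertion with provenance.

    ``term`` is always the canonical form after synonym resolution,
    never a raw synonym.
    """

    drug_id: str
    term: str
    frequency: Optional[str] = None
    provenance: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.provenance = frozenset(self.provenance)
        if not self.provenance:
            raise ValidationError(
                f"side effect ({self.drug_id}, {self.term}) has empty provenance"
            )


@dataclass(frozen=True)
class MoleculeLink:
    """A drug–molecule relation (target/enzyme/transporter/carrier)."""

    drug_id: str
    molecule_id: str
    molecule_role: str
    action: str = "unknown"
    provenance: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.molecule_role not in MOLECULE_ROLES:
            raise ValidationError(f"unknown molecule role {self.molecule_role!r}")
        if self.action not in MOLECULE_ACTIONS:
            raise ValidationError(f"unknown molecule action {self.action!r}")
        object.__setattr__(self, "provenance", frozenset(self.provenance))

    def key(self) -> tuple[str, str, str, str]:
        return (self.drug_id, self.molecule_id, self.molecule_role, self.action)


@dataclass
class PathwayRecord:
    """A metabolic pathway with member molecules, linked drugs and diseases."""

    pathway_id: str
    name: str
    member_molecule_ids: list[str] = field(default_factory=list)
    linked_drug_ids: list[str] = field(default_factory=list)
    linked_disease_ids: list[str] = field(default_factory=list)


@dataclass
class DiseaseRecord:
    disease_id: str
    name: str
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValidationError(f"disease {self.disease_id!r} has an empty name")
        self.synonyms = _dedupe_normalized(self.synonyms)


class KnowledgeBase:
    """Merged, indexed, provenance-tagged drug knowledge base.

    Invariants maintained by the mutator methods:

    * every drug_id referenced by any assertion exists in :attr:`drugs`;
    * the name index covers every drug display name and synonym;
    * no two interactions share a canonical pair — provenance and
      per-source effect texts are merged instead;
    * no two side-effect assertions share a (drug, canonical term) key.
    """

    def __init__(self, source_tags: Iterable[str] = ()) -> None:
        self.source_tags: list[str] = list(dict.fromkeys(source_tags))
        self.drugs: dict[str, DrugRecord] = {}
        self.interactions: dict[tuple[str, str], InteractionAssertion] = {}
        self.side_effects: dict[tuple[str, str], SideEffectAssertion] = {}
        self.molecule_links: dict[tuple[str, str, str, str], MoleculeLink] = {}
        self.pathways: dict[str, PathwayRecord] = {}
        self.diseases: dict[str, DiseaseRecord] = {}
        # raw term (normalized) -> canonical term; canonical maps to itself
        self.synonym_table: dict[str, str] = {}
        # normalized name -> set of drug ids (>1 marks an ambiguous name)
        self._name_index: dict[str, set[str]] = {}

    # -- mutation -----------------------------------------------------------

    def register_source(self, tag: str) -> None:
        if tag not in self.source_tags:
            self.source_tags.append(tag)

    def _check_provenance(self, provenance: Iterable[str]) -> frozenset[str]:
        prov = frozenset(provenance)
        unknown = prov - set(self.source_tags)
        if unknown:
            raise ValidationError(f"unregistered source tags: {sorted(unknown)}")
        return prov

    def add_drug(self, drug: DrugRecord) -> None:
        if drug.drug_id in self.drugs:
            raise ValidationError(f"duplicate drug_id {drug.drug_id!r}")
        self.drugs[drug.drug_id] = drug
        for name in drug.all_names():
            self._name_index.setdefault(normalize(name), set()).add(drug.drug_id)

    def add_interaction(
        self,
        drug_a: str,
        drug_b: str,
        *,
        effects: Mapping[str, str] | None = None,
        severity: Optional[str] = None,
        provenance: Iterable[str],
    ) -> InteractionAssertion:
        pair = canonical_pair(drug_a, drug_b)
        for d in pair:
            if d not in self.drugs:
                raise NotFoundError(f"unknown drug_id {d!r} in interaction")
        prov = self._check_provenance(provenance)
        existing = self.interactions.get(pair)
        if existing is None:
            assertion = InteractionAssertion(
                pair=pair, effects=dict(effects or {}), severity=severity,
                provenance=prov,
            )
            self.interactions[pair] = assertion
            return assertion
        existing.provenance = existing.provenance | prov
        for tag, text in (effects or {}).items():
            # deterministic under arbitrary row order: keep the smaller text
            if tag not in existing.effects or (text and text < existing.effects[tag]):
                existing.effects[tag] = text
        if severity and (existing.severity is None or severity < existing.severity):
            existing.severity = severity
        return existing

    def add_side_effect(
        self,
        drug_id: str,
        term: str,
        *,
        frequency: Optional[str] = None,
        provenance: Iterable[str],
    ) -> SideEffectAssertion:
        if drug_id not in self.drugs:
            raise NotFoundError(f"unknown drug_id {drug_id!r} in side effect")
        prov = self._check_provenance(provenance)
        key = (drug_id, term)
        existing = self.side_effects.get(key)
        if existing is None:
            assertion = SideEffectAssertion(
                drug_id=drug_id, term=term, frequency=frequency, provenance=prov
            )
            self.side_effects[key] = assertion
            return assertion
        existing.provenance = existing.provenance | prov
        if frequency and (existing.frequency is None or frequency < existing.frequency):
            existing.frequency = frequency
        return existing

    def add_molecule_link(self, link: MoleculeLink) -> MoleculeLink:
        if link.drug_id not in self.drugs:
            raise NotFoundError(f"unknown drug_id {link.drug_id!r} in molecule link")
        prov = self._check_provenance(link.provenance)
        existing = self.molecule_links.get(link.key())
        if existing is None:
            link = MoleculeLink(*link.key(), provenance=prov)
            self.molecule_links[link.key()] = link
            return link
        merged = MoleculeLink(*link.key(), provenance=existing.provenance | prov)
        self.molecule_links[link.key()] = merged
        return merged

    def add_pathway(self, pathway: PathwayRecord) -> None:
        self.pathways[pathway.pathway_id] = pathway

    def add_disease(self, disease: DiseaseRecord) -> None:
        existing = self.diseases.get(disease.disease_id)
        if existing is None:
            self.diseases[disease.disease_id] = disease
        else:
            existing.synonyms = _dedupe_normalized(
                [*existing.synonyms, *disease.synonyms]
            )

    # -- lookup -------------------------------------------------------------

    def molecule_ids(self) -> set[str]:
        """All molecule ids known from links and pathway memberships."""
        ids = {link.molecule_id for link in self.molecule_links.values()}
        for pw in self.pathways.values():
            ids.update(pw.member_molecule_ids)
        return ids

    def resolve_drug(self, query: str) -> Optional[str]:
        """Resolve a drug id, name or synonym to a drug_id.

        Returns ``None`` when nothing matches; raises
        :class:`AmbiguousMatchError` when two distinct drugs share the
        normalized name.
        """
        if not query or not query.strip():
            raise ValidationError("empty drug query")
        if query in self.drugs:
            return query
        candidates = self._name_index.get(normalize(query), set())
        if not candidates:
            return None
        if len(candidates) > 1:
            raise AmbiguousMatchError(query, [self.drugs[d].name for d in candidates])
        return next(iter(candidates))

    def require_drug(self, query: str) -> str:
        drug_id = self.resolve_drug(query)
        if drug_id is None:
            raise NotFoundError(f"unknown drug {query!r}")
        return drug_id

    def suggest_drugs(self, prefix: str, limit: int = 10) -> list[str]:
        """Auto-complete: display names whose normalized name or synonym
        starts with the normalized prefix, alphabetically, at most ``limit``."""
        if limit < 1:
            raise ValidationError("limit must be >= 1")
        norm = normalize(prefix)
        hits: set[str] = set()
        for drug in self.drugs.values():
            if any(normalize(n).startswith(norm) for n in drug.all_names()):
                hits.add(drug.name)
        return sorted(hits)[:limit]

    def canonicalize_term(self, raw: str) -> str:
        """Map a raw side-effect term to its canonical form (normalized
        pass-through when unknown)."""
        norm = normalize(raw)
        return self.synonym_table.get(norm, norm)

    def interactions_of(self, drug_id: str) -> list[InteractionAssertion]:
        return [a for a in self.interactions.values() if a.involves(drug_id)]

    def side_effects_of(self, drug_id: str) -> list[SideEffectAssertion]:
        return [a for a in self.side_effects.values() if a.drug_id == drug_id]

    def molecule_links_of(self, drug_id: str) -> list[MoleculeLink]:
        return [l for l in self.molecule_links.values() if l.drug_id == drug_id]

    def drug_name(self, drug_id: str) -> str:
        return self.drugs[drug_id].name

    # -- persistence --------------------------------------------------------
    # The on-disk artifact is a directory of normalized TSVs plus a JSON
    # manifest: human-diffable, no database dependency. List-valued cells are
    # pipe-packed; structured cells (per-source effects) are JSON-encoded.

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)

        def writer(name: str, header: list[str]):
            fh = (directory / name).open("w", newline="", encoding="utf-8")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(header)
            return fh, w

        fh, w = writer("drugs.tsv", ["drug_id", "name", "synonyms", "atc_codes", "source_ids"])
        with fh:
            for drug_id in sorted(self.drugs):
                d = self.drugs[drug_id]
                w.writerow([
                    d.drug_id, d.name, "|".join(d.synonyms), "|".join(d.atc_codes),
                    "|".join(f"{k}:{v}" for k, v in sorted(d.source_ids.items())),
                ])

        fh, w = writer("interactions.tsv", ["drug_a", "drug_b", "effects_json", "severity", "provenance"])
        with fh:
            for pair in sorted(self.interactions):
                a = self.interactions[pair]
                w.writerow([
                    pair[0], pair[1], json.dumps(a.effects, sort_keys=True),
                    a.severity or "", "|".join(sorted(a.provenance)),
                ])

        fh, w = writer("side_effects.tsv", ["drug_id", "term", "frequency", "provenance"])
        with fh:
            for key in sorted(self.side_effects):
                a = self.side_effects[key]
                w.writerow([a.drug_id, a.term, a.frequency or "", "|".join(sorted(a.provenance))])

        fh, w = writer("molecule_links.tsv", ["drug_id", "molecule_id", "molecule_role", "action", "provenance"])
        with fh:
            for key in sorted(self.molecule_links):
                l = self.molecule_links[key]
                w.writerow([*key, "|".join(sorted(l.provenance))])

        fh, w = writer("pathways.tsv", ["pathway_id", "name", "member_molecules", "drugs", "diseases"])
        with fh:
            for pid in sorted(self.pathways):
                p = self.pathways[pid]
                w.writerow([
                    p.pathway_id, p.name, "|".join(p.member_molecule_ids),
                    "|".join(p.linked_drug_ids), "|".join(p.linked_disease_ids),
                ])

        fh, w = writer("diseases.tsv", ["disease_id", "name", "synonyms"])
        with fh:
            for did in sorted(self.diseases):
                d = self.diseases[did]
                w.writerow([d.disease_id, d.name, "|".join(d.synonyms)])

        fh, w = writer("synonyms.tsv", ["raw_term", "canonical_term"])
        with fh:
            for raw in sorted(self.synonym_table):
                w.writerow([raw, self.synonym_table[raw]])

        manifest = {
            "format_version": _KB_FORMAT_VERSION,
            "source_tags": self.source_tags,
            "counts": {
                "drugs": len(self.drugs),
                "interactions": len(self.interactions),
                "side_effects": len(self.side_effects),
                "molecule_links": len(self.molecule_links),
                "pathways": len(self.pathways),
                "diseases": len(self.diseases),
            },
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "KnowledgeBase":
        directory = Path(directory)
        manifest_path = directory / "manifest.json"
        if not manifest_path.exists():
            raise NotFoundError(f"no knowledge-base manifest in {directory}")
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        kb = cls(source_tags=manifest.get("source_tags", []))

        def rows(name: str) -> Iterator[dict[str, str]]:
            path = directory / name
            if not path.exists():
                return
            with path.open(newline="", encoding="utf-8") as fh:
                yield from csv.DictReader(fh, delimiter="\t")

        def split(cell: str) -> list[str]:
            return [x for x in cell.split("|") if x] if cell else []

        for r in rows("drugs.tsv"):
            source_ids = dict(x.split(":", 1) for x in split(r["source_ids"]))
            kb.add_drug(DrugRecord(
                drug_id=r["drug_id"], name=r["name"],
                synonyms=split(r["synonyms"]), atc_codes=split(r["atc_codes"]),
                source_ids=source_ids,
            ))
        for r in rows("synonyms.tsv"):
            kb.synonym_table[r["raw_term"]] = r["canonical_term"]
        for r in rows("interactions.tsv"):
            kb.add_interaction(
                r["drug_a"], r["drug_b"],
                effects=json.loads(r["effects_json"]) if r["effects_json"] else {},
                severity=r["severity"] or None,
                provenance=split(r["provenance"]),
            )
        for r in rows("side_effects.tsv"):
            kb.add_side_effect(
                r["drug_id"], r["term"], frequency=r["frequency"] or None,
                provenance=split(r["provenance"]),
            )
        for r in rows("molecule_links.tsv"):
            kb.add_molecule_link(MoleculeLink(
                r["drug_id"], r["molecule_id"], r["molecule_role"], r["action"],
                provenance=split(r["provenance"]),
            ))
        for r in rows("pathways.tsv"):
            kb.add_pathway(PathwayRecord(
                pathway_id=r["pathway_id"], name=r["name"],
                member_molecule_ids=split(r["member_molecules"]),
                linked_drug_ids=split(r["drugs"]),
                linked_disease_ids=split(r["diseases"]),
            ))
        for r in rows("diseases.tsv"):
            kb.add_disease(DiseaseRecord(
                disease_id=r["disease_id"], name=r["name"], synonyms=split(r["synonyms"]),
            ))
        return kb


def resolve_drug(query: str, kb: KnowledgeBase) -> Optional[str]:
    """Functional alias for :meth:`KnowledgeBase.resolve_drug`."""
    return kb.resolve_drug(query)


def suggest_drugs(prefix: str, kb: KnowledgeBase, limit: int = 10) -> list[str]:
    """Functional alias for :meth:`KnowledgeBase.suggest_drugs`."""
    return kb.suggest_drugs(prefix, limit)
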