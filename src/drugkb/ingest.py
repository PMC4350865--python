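"""Source ingestion: parse the four TSV source dialects, map drugs across
sources, resolve side-effect synonyms and merge everything into one
provenance-tagged :class:`~drugkb.model.KnowledgeBase`.

A source directory holds files named ``<TAG>_drugs.tsv``,
``<TAG>_interactions.tsv``, ``<TAG>_side_effects.tsv``,
``<TAG>_molecule_links.tsv``, ``<TAG>_pathways.tsv`` and optionally
``<TAG>_diseases.tsv`` (all UTF-8, tab-separated, header row, ``""`` for
missing, pipe-packed list cells). Ingestion is strict on schema (a
missing required column fails the file) and lenient on content
(malformed rows are skipped and reported with their line numbers).

Cross-source drug mapping follows two strategies, mirroring how a
pharmaceutical source is reconciled with a molecular one (shared
cross-reference identifiers, then full ATC codes) and how two sources
without common identifiers are reconciled (normalized names and
synonyms). Candidate links are scored shared-identifier > shared-ATC >
shared-name and resolved to a 1:1 mapping with a deterministic
lexicographic tie-break.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from ._text import is_valid_atc, normalize
from .model import (
    DiseaseRecord,
    DrugKBError,
    DrugRecord,
    KnowledgeBase,
    MOLECULE_ACTIONS,
    MOLECULE_ROLES,
    MoleculeLink,
    PathwayRecord,
)


class SchemaError(DrugKBError):
    """A source file is missing, unreadable, or lacks a required column."""


class MappingConflictError(DrugKBError):
    """Drug mappings are contradictory (a native id linked to two
    distinct native ids of the same other source)."""


@dataclass
class RawDrug:
    native_id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    atc_codes: list[str] = field(default_factory=list)
    xrefs: dict[str, str] = field(default_factory=dict)

    def all_names_normalized(self) -> set[str]:
        return {normalize(n) for n in [self.name, *self.synonyms]} - {""}


@dataclass
class RawInteraction:
    native_id_a: str
    native_id_b: str
    effect: str = ""
    severity: str = ""


@dataclass
class RawSideEffect:
    native_id: str
    term: str
    frequency: str = ""


@dataclass
class RawMoleculeLink:
    native_id: str
    molecule_id: str
    molecule_role: str
    action: str


@dataclass
class Rejection:
    file: str
    line: int
    reason: str


@dataclass
class SourceRecordSet:
    """Raw per-source records keyed by native ids, plus parse rejections."""

    source_tag: str
    drugs: dict[str, RawDrug] = field(default_factory=dict)
    interactions: list[RawInteraction] = field(default_factory=list)
    side_effects: list[RawSideEffect] = field(default_factory=list)
    molecule_links: list[RawMoleculeLink] = field(default_factory=list)
    pathways: dict[str, PathwayRecord] = field(default_factory=dict)
    diseases: dict[str, DiseaseRecord] = field(default_factory=dict)
    rejections: list[Rejection] = field(default_factory=list)


@dataclass
class DrugMapping:
    """1:1 links between native drug ids of two sources.

    ``method`` names the overall strategy; ``pair_methods`` records, per
    link, which evidence established it (``shared_identifier``,
    ``atc_and_identifier`` or ``name``).
    """

    source_a: str
    source_b: str
    method: str
    pairs: set[tuple[str, str]] = field(default_factory=set)
    pair_methods: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side in (0, 1):
            seen: dict[str, tuple[str, str]] = {}
            for pair in self.pairs:
                if pair[side] in seen and seen[pair[side]] != pair:
                    raise MappingConflictError(
                        f"{pair[side]!r} linked to two ids: {seen[pair[side]]}, {pair}"
                    )
                seen[pair[side]] = pair


@dataclass
class IngestReport:
    """What happened during parsing and merging, for auditing."""

    rejections: list[Rejection] = field(default_factory=list)
    unmapped_terms: set[str] = field(default_factory=set)
    dropped_references: list[str] = field(default_factory=list)
    mapped_drug_count: int = 0
    unmapped_drug_count: int = 0

    def summary(self) -> dict:
        return {
            "rejected_rows": len(self.rejections),
            "unmapped_terms": sorted(self.unmapped_terms),
            "dropped_references": self.dropped_references,
            "mapped_drugs": self.mapped_drug_count,
            "unmapped_drugs": self.unmapped_drug_count,
        }


# ---------------------------------------------------------------------------
# parsing

def _split(cell: str) -> list[str]:
    return [x.strip() for x in cell.split("|") if x.strip()] if cell else []


def _read_rows(path: Path, required: Sequence[str], rejections: list[Rejection]):
    try:
        fh = path.open(newline="", encoding="utf-8")
    except OSError as exc:
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    with fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise SchemaError(f"{path.name}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            if None in row or any(v is None for v in row.values()):
                rejections.append(Rejection(path.name, lineno, "wrong field count"))
                continue
            yield lineno, {k: (v or "").strip() for k, v in row.items()}


def parse_source(directory: str | Path, source_tag: str,
                 files: Optional[dict[str, str | Path]] = None) -> SourceRecordSet:
    """Parse one source's dialect files from ``directory``.

    ``files`` may override individual file paths by kind
    (``drugs``, ``interactions``, ``side_effects``, ``molecule_links``,
    ``pathways``, ``diseases``). The drugs table is required; the others
    are optional. Row order never affects the result.
    """
    directory = Path(directory)
    if not source_tag or not source_tag.strip():
        raise SchemaError("empty source tag")
    files = {k: Path(v) for k, v in (files or {}).items()}

    def path_for(kind: str) -> Path:
        return files.get(kind, directory / f"{source_tag}_{kind}.tsv")

    rs = SourceRecordSet(source_tag=source_tag)

    drugs_path = path_for("drugs")
    if not drugs_path.exists():
        raise SchemaError(f"required drugs table not found: {drugs_path}")
    for lineno, row in _read_rows(
        drugs_path, ["native_id", "name", "synonyms", "atc_codes", "xrefs"], rs.rejections
    ):
        if not row["native_id"] or not row["name"]:
            rs.rejections.append(
                Rejection(drugs_path.name, lineno, "missing native_id or name"))
            continue
        if row["native_id"] in rs.drugs:
            rs.rejections.append(
                Rejection(drugs_path.name, lineno, f"duplicate native_id {row['native_id']!r}"))
            continue
        atc = []
        for code in _split(row["atc_codes"]):
            if is_valid_atc(code):
                atc.append(code)
            else:
                # partial/invalid codes are dropped so they can never match
                rs.rejections.append(
                    Rejection(drugs_path.name, lineno, f"dropped invalid ATC code {code!r}"))
        xrefs: dict[str, str] = {}
        for entry in _split(row["xrefs"]):
            if ":" not in entry:
                rs.rejections.append(
                    Rejection(drugs_path.name, lineno, f"malformed xref {entry!r}"))
                continue
            key, value = entry.split(":", 1)
            xrefs[key.strip()] = value.strip()
        rs.drugs[row["native_id"]] = RawDrug(
            native_id=row["native_id"], name=row["name"],
            synonyms=_split(row["synonyms"]), atc_codes=atc, xrefs=xrefs,
        )

    p = path_for("interactions")
    if p.exists():
        for lineno, row in _read_rows(
            p, ["native_id_a", "native_id_b", "effect", "severity"], rs.rejections
        ):
            a, b = row["native_id_a"], row["native_id_b"]
            if not a or not b:
                rs.rejections.append(Rejection(p.name, lineno, "missing endpoint id"))
                continue
            if a == b:
                rs.rejections.append(Rejection(p.name, lineno, f"self-interaction {a!r}"))
                continue
            if a not in rs.drugs or b not in rs.drugs:
                rs.rejections.append(
                    Rejection(p.name, lineno, f"unknown endpoint in pair ({a!r}, {b!r})"))
                continue
            rs.interactions.append(
                RawInteraction(a, b, effect=row["effect"], severity=row["severity"]))

    p = path_for("side_effects")
    if p.exists():
        for lineno, row in _read_rows(p, ["native_id", "term", "frequency"], rs.rejections):
            if not row["native_id"] or not row["term"]:
                rs.rejections.append(Rejection(p.name, lineno, "missing id or term"))
                continue
            if row["native_id"] not in rs.drugs:
                rs.rejections.append(
                    Rejection(p.name, lineno, f"unknown drug {row['native_id']!r}"))
                continue
            rs.side_effects.append(
                RawSideEffect(row["native_id"], row["term"], frequency=row["frequency"]))

    p = path_for("molecule_links")
    if p.exists():
        for lineno, row in _read_rows(
            p, ["native_id", "molecule_id", "molecule_role", "action"], rs.rejections
        ):
            if not row["native_id"] or not row["molecule_id"]:
                rs.rejections.append(Rejection(p.name, lineno, "missing id"))
                continue
            if row["native_id"] not in rs.drugs:
                rs.rejections.append(
                    Rejection(p.name, lineno, f"unknown drug {row['native_id']!r}"))
                continue
            role = row["molecule_role"] or "target"
            action = row["action"] or "unknown"
            if role not in MOLECULE_ROLES or action not in MOLECULE_ACTIONS:
                rs.rejections.append(
                    Rejection(p.name, lineno, f"unknown role/action ({role!r}, {action!r})"))
                continue
            rs.molecule_links.append(
                RawMoleculeLink(row["native_id"], row["molecule_id"], role, action))

    p = path_for("pathways")
    if p.exists():
        for lineno, row in _read_rows(
            p, ["pathway_id", "name", "member_molecules", "drugs", "diseases"], rs.rejections
        ):
            if not row["pathway_id"] or not row["name"]:
                rs.rejections.append(Rejection(p.name, lineno, "missing id or name"))
                continue
            rs.pathways[row["pathway_id"]] = PathwayRecord(
                pathway_id=row["pathway_id"], name=row["name"],
                member_molecule_ids=_split(row["member_molecules"]),
                linked_drug_ids=_split(row["drugs"]),
                linked_disease_ids=_split(row["diseases"]),
            )

    p = path_for("diseases")
    if p.exists():
        for lineno, row in _read_rows(p, ["native_id", "name", "synonyms"], rs.rejections):
            if not row["native_id"] or not row["name"]:
                rs.rejections.append(Rejection(p.name, lineno, "missing id or name"))
                continue
            rs.diseases[row["native_id"]] = DiseaseRecord(
                disease_id=row["native_id"], name=row["name"],
                synonyms=_split(row["synonyms"]),
            )
    return rs


def load_synonym_table(path: str | Path) -> dict[str, str]:
    """Read ``synonyms.tsv`` (raw_term, canonical_term) into a normalized
    raw→canonical map; every canonical term also maps to itself."""
    table: dict[str, str] = {}
    rejections: list[Rejection] = []
    for _lineno, row in _read_rows(Path(path), ["raw_term", "canonical_term"], rejections):
        if not row["raw_term"] or not row["canonical_term"]:
            continue
        canonical = normalize(row["canonical_term"])
        table[normalize(row["raw_term"])] = canonical
        table.setdefault(canonical, canonical)
    return table


def canonicalize_term(raw: str, synonym_table: dict[str, str],
                      report: Optional[IngestReport] = None) -> str:
    """Resolve a raw side-effect term to its canonical form.

    Unknown terms pass through normalized and are flagged as unmapped in
    the ingest report.
    """
    norm = normalize(raw)
    if norm in synonym_table:
        return synonym_table[norm]
    if report is not None:
        report.unmapped_terms.add(norm)
    return norm


# ---------------------------------------------------------------------------
# mapping

_SCORE_ID, _SCORE_ATC, _SCORE_NAME = 3, 2, 1
_METHOD_NAMES = {_SCORE_ID: "shared_identifier", _SCORE_ATC: "atc_and_identifier",
                 _SCORE_NAME: "name"}


def _resolve_one_to_one(
    candidates: dict[tuple[str, str], int], a_tag: str, b_tag: str, method: str
) -> DrugMapping:
    """Greedy 1:1 resolution: higher score wins, ties broken by the
    lexicographically smallest native-id pair; losers stay unlinked."""
    taken_a: set[str] = set()
    taken_b: set[str] = set()
    mapping = DrugMapping(source_a=a_tag, source_b=b_tag, method=method)
    for (a_id, b_id), score in sorted(
        candidates.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        if a_id in taken_a or b_id in taken_b:
            continue
        taken_a.add(a_id)
        taken_b.add(b_id)
        mapping.pairs.add((a_id, b_id))
        mapping.pair_methods[(a_id, b_id)] = _METHOD_NAMES[score]
    return mapping


def map_by_atc_and_id(a: SourceRecordSet, b: SourceRecordSet) -> DrugMapping:
    """Link drugs of two sources by shared cross-reference identifiers,
    then by shared full 7-character ATC codes; 1:1 after conflict
    resolution. Unmappable drugs stay unlinked (they still enter the
    knowledge base as single-source drugs)."""
    candidates: dict[tuple[str, str], int] = {}

    b_by_xref_value: dict[str, set[str]] = {}
    for b_id, b_drug in b.drugs.items():
        for value in b_drug.xrefs.values():
            b_by_xref_value.setdefault(value, set()).add(b_id)
    for a_id, a_drug in a.drugs.items():
        for value in a_drug.xrefs.values():
            # an xref of A naming B's native id, or A and B sharing an xref value
            if value in b.drugs:
                candidates[(a_id, value)] = _SCORE_ID
            for b_id in b_by_xref_value.get(value, ()):
                candidates[(a_id, b_id)] = _SCORE_ID
    a_ids_set = set(a.drugs)
    for b_id, b_drug in b.drugs.items():
        for value in b_drug.xrefs.values():
            if value in a_ids_set:
                candidates[(value, b_id)] = _SCORE_ID

    b_by_atc: dict[str, set[str]] = {}
    for b_id, b_drug in b.drugs.items():
        for code in b_drug.atc_codes:
            b_by_atc.setdefault(code, set()).add(b_id)
    for a_id, a_drug in a.drugs.items():
        for code in a_drug.atc_codes:
            for b_id in b_by_atc.get(code, ()):
                candidates.setdefault((a_id, b_id), _SCORE_ATC)

    return _resolve_one_to_one(candidates, a.source_tag, b.source_tag, "atc_and_identifier")


def map_by_name(a: SourceRecordSet, b: SourceRecordSet) -> DrugMapping:
    """Link drugs of two sources whose normalized names or synonyms
    coincide; used between sources lacking shared identifiers."""
    candidates: dict[tuple[str, str], int] = {}
    b_by_name: dict[str, set[str]] = {}
    for b_id, b_drug in b.drugs.items():
        for name in b_drug.all_names_normalized():
            b_by_name.setdefault(name, set()).add(b_id)
    for a_id, a_drug in a.drugs.items():
        for name in a_drug.all_names_normalized():
            for b_id in b_by_name.get(name, ()):
                candidates[(a_id, b_id)] = _SCORE_NAME
    return _resolve_one_to_one(candidates, a.source_tag, b.source_tag, "name")


# ---------------------------------------------------------------------------
# merging

class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[tuple[str, str], tuple[str, str]] = {}

    def add(self, x: tuple[str, str]) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: tuple[str, str]) -> tuple[str, str]:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x: tuple[str, str], y: tuple[str, str]) -> None:
        self.add(x)
        self.add(y)
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            # deterministic root: lexicographically smallest node
            if ry < rx:
                rx, ry = ry, rx
            self.parent[ry] = rx


def merge_sources(
    record_sets: Sequence[SourceRecordSet],
    mappings: Sequence[DrugMapping] = (),
    synonym_table: Optional[dict[str, str]] = None,
    report: Optional[IngestReport] = None,
) -> KnowledgeBase:
    """Fuse per-source record sets into one knowledge base.

    Mapped drugs become a single record (union of names, synonyms and
    ATC codes; native ids preserved per source); interactions are
    re-expressed over fused ids and deduplicated by canonical pair with
    provenance union; side effects are canonicalized and deduplicated by
    (drug, term); pathway drug references are resolved through any
    source's native-id namespace. The result is independent of the order
    of ``record_sets`` up to internal id assignment.
    """
    report = report if report is not None else IngestReport()
    by_tag = {rs.source_tag: rs for rs in record_sets}
    if len(by_tag) != len(record_sets):
        raise MappingConflictError("duplicate source tags in record sets")
    for rs in record_sets:
        report.rejections.extend(rs.rejections)

    # consistency: within each source pair, mappings must be 1:1 overall
    per_pair: dict[tuple[str, str], dict[str, str]] = {}
    for m in mappings:
        if m.source_a not in by_tag or m.source_b not in by_tag:
            raise MappingConflictError(
                f"mapping references unknown source {m.source_a!r}/{m.source_b!r}")
        fwd = per_pair.setdefault((m.source_a, m.source_b), {})
        rev = per_pair.setdefault((m.source_b, m.source_a), {})
        for a_id, b_id in m.pairs:
            if fwd.get(a_id, b_id) != b_id or rev.get(b_id, a_id) != a_id:
                raise MappingConflictError(
                    f"contradictory mapping for {a_id!r}/{b_id!r} between "
                    f"{m.source_a} and {m.source_b}")
            fwd[a_id] = b_id
            rev[b_id] = a_id

    uf = _UnionFind()
    for rs in record_sets:
        for native_id in rs.drugs:
            uf.add((rs.source_tag, native_id))
    for m in mappings:
        for a_id, b_id in m.pairs:
            if a_id not in by_tag[m.source_a].drugs or b_id not in by_tag[m.source_b].drugs:
                raise MappingConflictError(
                    f"mapping pair ({a_id!r}, {b_id!r}) references unknown drugs")
            uf.union((m.source_a, a_id), (m.source_b, b_id))

    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in uf.parent:
        groups.setdefault(uf.find(node), []).append(node)

    kb = KnowledgeBase(source_tags=[rs.source_tag for rs in record_sets])
    kb.synonym_table = dict(synonym_table or {})

    fused_id_of: dict[tuple[str, str], str] = {}
    for members in groups.values():
        tags = [tag for tag, _ in members]
        if len(set(tags)) != len(tags):
            raise MappingConflictError(
                f"transitive mapping fuses two drugs of the same source: {sorted(members)}")
        # stable fused id: smallest native id across the fused records
        fused_id = "KB:" + min(native for _, native in members)
        primary_tag, primary_native = min(members, key=lambda n: (n[1], n[0]))
        primary = by_tag[primary_tag].drugs[primary_native]
        synonyms: list[str] = []
        atc: list[str] = []
        source_ids: dict[str, str] = {}
        for tag, native in sorted(members, key=lambda n: (n[1], n[0])):
            raw = by_tag[tag].drugs[native]
            source_ids[tag] = native
            for name in [raw.name, *raw.synonyms]:
                synonyms.append(name)
            atc.extend(raw.atc_codes)
        synonyms = [s for s in synonyms if normalize(s) != normalize(primary.name)]
        record = DrugRecord(
            drug_id=fused_id, name=primary.name, synonyms=synonyms,
            atc_codes=sorted(set(atc)), source_ids=source_ids,
        )
        kb.add_drug(record)
        for node in members:
            fused_id_of[node] = fused_id
        if len(members) > 1:
            report.mapped_drug_count += len(members)
        else:
            report.unmapped_drug_count += 1

    # native id -> fused id, across all source namespaces (for pathway refs)
    native_global: dict[str, set[str]] = {}
    for (tag, native), fused in fused_id_of.items():
        native_global.setdefault(native, set()).add(fused)

    for rs in record_sets:
        tag = rs.source_tag
        for raw in rs.interactions:
            a = fused_id_of[(tag, raw.native_id_a)]
            b = fused_id_of[(tag, raw.native_id_b)]
            if a == b:
                report.dropped_references.append(
                    f"{tag}: interaction endpoints fused to one drug "
                    f"({raw.native_id_a}, {raw.native_id_b})")
                continue
            kb.add_interaction(
                a, b, effects={tag: raw.effect} if raw.effect else {},
                severity=raw.severity or None, provenance={tag},
            )
        for raw_se in rs.side_effects:
            term = canonicalize_term(raw_se.term, kb.synonym_table, report)
            kb.add_side_effect(
                fused_id_of[(tag, raw_se.native_id)], term,
                frequency=raw_se.frequency or None, provenance={tag},
            )
        for raw_ml in rs.molecule_links:
            kb.add_molecule_link(MoleculeLink(
                fused_id_of[(tag, raw_ml.native_id)], raw_ml.molecule_id,
                raw_ml.molecule_role, raw_ml.action, provenance={tag},
            ))
        for disease in rs.diseases.values():
            kb.add_disease(disease)

    for rs in record_sets:
        for pw in rs.pathways.values():
            linked: list[str] = []
            for native in pw.linked_drug_ids:
                fused_set = native_global.get(native, set())
                if len(fused_set) == 1:
                    linked.append(next(iter(fused_set)))
                elif not fused_set:
                    report.dropped_references.append(
                        f"{rs.source_tag}: pathway {pw.pathway_id} references "
                        f"unknown drug id {native!r}")
                else:
                    report.dropped_references.append(
                        f"{rs.source_tag}: pathway {pw.pathway_id} drug id "
                        f"{native!r} is ambiguous across sources")
            diseases: list[str] = []
            for did in pw.linked_disease_ids:
                if did in kb.diseases:
                    diseases.append(did)
                else:
                    report.dropped_references.append(
                        f"{rs.source_tag}: pathway {pw.pathway_id} references "
                        f"unknown disease id {did!r}")
            kb.add_pathway(PathwayRecord(
                pathway_id=pw.pathway_id, name=pw.name,
                member_molecule_ids=sorted(set(pw.member_molecule_ids)),
                linked_drug_ids=sorted(set(linked)),
                linked_disease_ids=sorted(set(diseases)),
            ))
    return kb


def ingest_directory(
    directory: str | Path,
    source_tags: Sequence[str],
    mapping_methods: Iterable[tuple[str, str, str]] = (),
    synonyms_file: str | Path | None = None,
    report: Optional[IngestReport] = None,
) -> KnowledgeBase:
    """One-call ingest: parse every source from ``directory``, build the
    requested mappings (``(tag_a, tag_b, 'atc_and_identifier'|'name')``
    triples) and merge.
    """
    directory = Path(directory)
    record_sets = [parse_source(directory, tag) for tag in source_tags]
    by_tag = {rs.source_tag: rs for rs in record_sets}
    mappings = []
    for a_tag, b_tag, method in mapping_methods:
        if a_tag not in by_tag or b_tag not in by_tag:
            raise SchemaError(f"mapping references unknown source {a_tag!r}/{b_tag!r}")
        if method == "atc_and_identifier":
            mappings.append(map_by_atc_and_id(by_tag[a_tag], by_tag[b_tag]))
        elif method == "name":
            mappings.append(map_by_name(by_tag[a_tag], by_tag[b_tag]))
        else:
            raise SchemaError(f"unknown mapping method {method!r}")
    synonym_table = None
    if synonyms_file is None:
        default = directory / "synonyms.tsv"
        synonyms_file = default if default.exists() else None
    if synonyms_file is not None:
        synonym_table = load_synonym_table(synonyms_file)
    return merge_sources(record_sets, mappings, synonym_table, report)
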