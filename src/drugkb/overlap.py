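"""Inter-source concordance statistics.

Given two sources' hit sets — a *hit* is one distinct canonical
assertion key per source: a canonical drug pair for interactions, a
(drug, canonical term) pair for side effects — the summary reports
union/intersection/exclusive counts and the derived percentage shares.

Two counting conventions occur in published concordance reports and both
are supported:

* *exclusive* inputs: counts of A-only, B-only and shared hits (which
  sum to the union);
* *inclusive* inputs: per-source totals (shared hits counted in both)
  plus the union, from which the intersection follows by
  inclusion–exclusion: ``shared = a_total + b_total - union``.

Percentages use half-up rounding at either integer precision
(distribution-style reports) or two decimals (top-N-style reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .model import DrugKBError, KnowledgeBase, NotFoundError, ValidationError

ROUNDING_MODES = ("int", "2dp")


def round_half_up(value: float, mode: str = "2dp") -> float:
    """Half-up rounding to integer ('int') or two decimals ('2dp')."""
    if mode not in ROUNDING_MODES:
        raise ValidationError(f"unknown rounding mode {mode!r}")
    quantum = Decimal("1") if mode == "int" else Decimal("0.01")
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class OverlapSummary:
    """Union/intersection/exclusive counts and percentage shares for two
    sources' hit sets.

    Count identities: ``union = a_only + b_only + shared``,
    ``a_total = a_only + shared``, ``b_total = b_only + shared``,
    ``multiset_total = a_total + b_total``.

    Shares of the union: ``a_share``/``b_share`` use the inclusive
    per-source totals (the convention of top-N reports), while
    ``a_only_share``/``b_only_share`` use the exclusive counts (the
    convention of whole-database distribution reports).
    ``shared_share + noncorrelative_share = 100`` up to rounding.
    ``unmatched_share`` is the fraction of the multiset total left
    unmatched: ``(a_only + b_only) / multiset_total``.
    """

    source_a: str
    source_b: str
    a_only: int
    b_only: int
    shared: int
    rounding_mode: str = "int"
    a_total: int = field(init=False)
    b_total: int = field(init=False)
    union: int = field(init=False)
    multiset_total: int = field(init=False)
    a_share: float = field(init=False)
    b_share: float = field(init=False)
    a_only_share: float = field(init=False)
    b_only_share: float = field(init=False)
    shared_share: float = field(init=False)
    noncorrelative_share: float = field(init=False)
    unmatched_share: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.a_only, self.b_only, self.shared) < 0:
            raise ValidationError("counts must be non-negative")
        if self.rounding_mode not in ROUNDING_MODES:
            raise ValidationError(f"unknown rounding mode {self.rounding_mode!r}")
        self.a_total = self.a_only + self.shared
        self.b_total = self.b_only + self.shared
        self.union = self.a_only + self.b_only + self.shared
        self.multiset_total = self.a_total + self.b_total

        def pct(numer: int, denom: int) -> float:
            if denom == 0:
                return 0.0
            return round_half_up(100.0 * numer / denom, self.rounding_mode)

        self.a_share = pct(self.a_total, self.union)
        self.b_share = pct(self.b_total, self.union)
        self.a_only_share = pct(self.a_only, self.union)
        self.b_only_share = pct(self.b_only, self.union)
        self.shared_share = pct(self.shared, self.union)
        self.noncorrelative_share = pct(self.union - self.shared, self.union)
        self.unmatched_share = pct(self.a_only + self.b_only, self.multiset_total)

    @property
    def noncorrelative(self) -> int:
        """Distinct hits asserted by exactly one source."""
        return self.a_only + self.b_only

    def swapped(self) -> "OverlapSummary":
        return OverlapSummary(
            source_a=self.source_b, source_b=self.source_a,
            a_only=self.b_only, b_only=self.a_only, shared=self.shared,
            rounding_mode=self.rounding_mode,
        )

    def to_dict(self) -> dict:
        return {
            "source_a": self.source_a, "source_b": self.source_b,
            "a_only": self.a_only, "b_only": self.b_only, "shared": self.shared,
            "a_total": self.a_total, "b_total": self.b_total,
            "union": self.union, "multiset_total": self.multiset_total,
            "a_share": self.a_share, "b_share": self.b_share,
            "a_only_share": self.a_only_share, "b_only_share": self.b_only_share,
            "shared_share": self.shared_share,
            "noncorrelative": self.noncorrelative,
            "noncorrelative_share": self.noncorrelative_share,
            "unmatched_share": self.unmatched_share,
            "rounding_mode": self.rounding_mode,
        }

    TSV_COLUMNS = (
        "source_a", "source_b", "a_only", "b_only", "shared", "a_total",
        "b_total", "union", "multiset_total", "a_share", "b_share",
        "shared_share", "noncorrelative_share", "unmatched_share",
    )

    def to_tsv_row(self) -> str:
        d = self.to_dict()
        return "\t".join(str(d[c]) for c in self.TSV_COLUMNS)


def summary_from_exclusive(
    a_only: int, b_only: int, shared: int,
    rounding: str = "int", source_a: str = "A", source_b: str = "B",
) -> OverlapSummary:
    """Build a summary from exclusive counts (A-only, B-only, shared)."""
    return OverlapSummary(source_a=source_a, source_b=source_b,
                          a_only=a_only, b_only=b_only, shared=shared,
                          rounding_mode=rounding)


def summary_from_inclusive(
    a_total: int, b_total: int, union: int,
    rounding: str = "2dp", source_a: str = "A", source_b: str = "B",
) -> OverlapSummary:
    """Build a summary from inclusive per-source totals and the union;
    the intersection follows by inclusion–exclusion."""
    if min(a_total, b_total, union) < 0:
        raise ValidationError("counts must be non-negative")
    if union > a_total + b_total:
        raise ValidationError(
            f"union {union} exceeds a_total + b_total = {a_total + b_total}")
    if union < max(a_total, b_total):
        raise ValidationError(
            f"union {union} smaller than max per-source total "
            f"{max(a_total, b_total)}")
    shared = a_total + b_total - union
    return OverlapSummary(source_a=source_a, source_b=source_b,
                          a_only=a_total - shared, b_only=b_total - shared,
                          shared=shared, rounding_mode=rounding)


def _hit_sets(
    kb: KnowledgeBase, assertion_kind: str, source_a: str, source_b: str
) -> tuple[set, set]:
    for tag in (source_a, source_b):
        if tag not in kb.source_tags:
            raise DrugKBError(f"unknown source tag {tag!r}")
    if assertion_kind == "interactions":
        items = [(a.pair, a.provenance) for a in kb.interactions.values()]
    elif assertion_kind == "side_effects":
        items = [((a.drug_id, a.term), a.provenance)
                 for a in kb.side_effects.values()]
    else:
        raise ValidationError(f"unknown assertion kind {assertion_kind!r}")
    hits_a = {key for key, prov in items if source_a in prov}
    hits_b = {key for key, prov in items if source_b in prov}
    return hits_a, hits_b


def kb_overlap(
    kb: KnowledgeBase, assertion_kind: str, source_a: str, source_b: str,
    rounding: str = "2dp",
) -> OverlapSummary:
    """Concordance of two sources' hit sets in a merged knowledge base,
    reported with inclusive per-source totals."""
    hits_a, hits_b = _hit_sets(kb, assertion_kind, source_a, source_b)
    return summary_from_inclusive(
        a_total=len(hits_a), b_total=len(hits_b), union=len(hits_a | hits_b),
        rounding=rounding, source_a=source_a, source_b=source_b,
    )


@dataclass
class TopDrugRow:
    drug_id: str
    drug_name: str
    a_hits: int
    b_hits: int
    shared_hits: int

    def to_tsv_row(self) -> str:
        return "\t".join(str(x) for x in
                         (self.drug_name, self.a_hits, self.b_hits, self.shared_hits))


@dataclass
class TopDrugEvaluation:
    rows: list[TopDrugRow]
    aggregate: OverlapSummary
    unresolved: list[str]


def top_n_evaluation(
    kb: KnowledgeBase,
    drugs: Sequence[str],
    assertion_kind: str,
    source_a: str,
    source_b: str,
    rounding: str = "2dp",
) -> TopDrugEvaluation:
    """Per-drug per-source hit counts for a list of leading drugs, plus an
    aggregate summary over distinct hits involving at least one listed
    drug. Unresolvable names are reported and excluded."""
    resolved: list[str] = []
    unresolved: list[str] = []
    for name in drugs:
        drug_id = kb.resolve_drug(name)
        if drug_id is None:
            unresolved.append(name)
        else:
            resolved.append(drug_id)
    hits_a, hits_b = _hit_sets(kb, assertion_kind, source_a, source_b)

    def involves(key, drug_id: str) -> bool:
        if assertion_kind == "interactions":
            return drug_id in key
        return key[0] == drug_id

    rows = []
    for drug_id in resolved:
        da = {k for k in hits_a if involves(k, drug_id)}
        db = {k for k in hits_b if involves(k, drug_id)}
        rows.append(TopDrugRow(
            drug_id=drug_id, drug_name=kb.drug_name(drug_id),
            a_hits=len(da), b_hits=len(db), shared_hits=len(da & db),
        ))
    listed = set(resolved)
    agg_a = {k for k in hits_a if any(involves(k, d) for d in listed)}
    agg_b = {k for k in hits_b if any(involves(k, d) for d in listed)}
    aggregate = summary_from_inclusive(
        a_total=len(agg_a), b_total=len(agg_b), union=len(agg_a | agg_b),
        rounding=rounding, source_a=source_a, source_b=source_b,
    )
    return TopDrugEvaluation(rows=rows, aggregate=aggregate, unresolved=unresolved)
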