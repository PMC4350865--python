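"""Synthetic four-source knowledge-base generator with exact ground truth.

Emits the TSV dialects of a pharmaceutical interaction/side-effect
source (PHARM), a molecular drug source (MOLDB), a side-effect source
coded in a controlled vocabulary (SEDB) and a pathway/disease source
(PATHDB), with controllable cross-source drug coverage, planted
interaction and side-effect overlap fractions, synonym usage and
identifier gaps — so that ingestion, mapping, medication analysis and
concordance statistics are all testable without any real database.

Overlap is planted by exact counts (``floor(fraction × universe)``), not
per-item coin flips: the realized intersection equals the planted count
exactly and is recorded in the ground truth. Everything is reproducible
from the seed; identical parameters yield byte-identical files.

The drug universe is synthetic (``DRUG_0001`` …) with valid-pattern ATC
codes; side-effect terms come from a bundled 50-term controlled
vocabulary with fixed synonym pairs, loosely modeled on how a clinical
adverse-event terminology pairs preferred terms with synonyms.
"""

from __future__ import annotations

import csv
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .analysis import MedicationProfile
from .ingest import IngestReport, ingest_directory
from .model import DrugKBError, KnowledgeBase

PHARM, MOLDB, SEDB, PATHDB = "PHARM", "MOLDB", "SEDB", "PATHDB"

#: Canonical side-effect vocabulary (50 preferred terms).
SIDE_EFFECT_TERMS = (
    "nausea", "vomiting", "headache", "dizziness", "fatigue", "insomnia",
    "somnolence", "diarrhea", "constipation", "dyspepsia", "abdominal pain",
    "dry mouth", "rash", "pruritus", "urticaria", "alopecia", "sweating",
    "tremor", "seizure", "confusion", "anxiety", "depression", "hypertension",
    "hypotension", "bradycardia", "tachycardia", "palpitations", "edema",
    "weight gain", "weight loss", "anorexia", "dysgeusia", "blurred vision",
    "tinnitus", "cough", "dyspnea", "bronchospasm", "anemia", "leukopenia",
    "thrombocytopenia", "hyperglycemia", "hypoglycemia", "hyponatremia",
    "hepatotoxicity", "nephrotoxicity", "myalgia", "arthralgia", "back pain",
    "fever", "hot flush",
)

#: Fixed raw-synonym → preferred-term pairs used when ``synonym_rate`` > 0.
SIDE_EFFECT_SYNONYMS = {
    "emesis": "vomiting",
    "cephalalgia": "headache",
    "vertigo": "dizziness",
    "tiredness": "fatigue",
    "sleeplessness": "insomnia",
    "drowsiness": "somnolence",
    "loose stools": "diarrhea",
    "indigestion": "dyspepsia",
    "stomach ache": "abdominal pain",
    "xerostomia": "dry mouth",
    "itching": "pruritus",
    "hives": "urticaria",
    "hair loss": "alopecia",
    "hyperhidrosis": "sweating",
    "convulsion": "seizure",
    "high blood pressure": "hypertension",
    "low blood pressure": "hypotension",
    "shortness of breath": "dyspnea",
    "loss of appetite": "anorexia",
    "pyrexia": "fever",
}

CYP_MOLECULES = ("CYP1A2", "CYP2B6", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4")

_SEVERITIES = ("minor", "moderate", "major", "")
_FREQUENCIES = ("common", "uncommon", "rare", "")
_ATC_LETTERS = "ABCDGHJLMNPRSV"


class GenerationError(DrugKBError):
    """Requested parameters cannot be realized exactly."""


@dataclass
class GeneratorParams:
    """Generation conditions.

    ``coverage`` gives the fraction of the drug universe present in each
    drug-carrying source; ``overlap_fraction_*`` the fraction of each
    assertion universe asserted by both paired sources (planted as an
    exact count); ``synonym_rate`` the fraction of side-effect mentions
    written as a raw synonym instead of the preferred term;
    ``mapping_noise`` the fraction of PHARM/MOLDB common drugs lacking a
    shared identifier (forcing ATC-based mapping).
    """

    n_drugs: int = 120
    coverage: dict[str, float] = field(
        default_factory=lambda: {PHARM: 0.85, MOLDB: 0.9, SEDB: 0.8})
    overlap_fraction_interactions: float = 0.12
    overlap_fraction_side_effects: float = 0.09
    n_interactions: int = 200
    n_side_effects: int = 400
    n_molecules: int = 30
    n_pathways: int = 8
    n_diseases: int = 24
    synonym_rate: float = 0.25
    mapping_noise: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = [self.overlap_fraction_interactions,
                     self.overlap_fraction_side_effects,
                     self.synonym_rate, self.mapping_noise,
                     *self.coverage.values()]
        if any(not (0.0 <= f <= 1.0) for f in fractions):
            raise GenerationError("all fractions must lie in [0, 1]")
        counts = [self.n_drugs, self.n_interactions, self.n_side_effects,
                  self.n_molecules, self.n_pathways, self.n_diseases]
        if any(c < 0 for c in counts):
            raise GenerationError("all counts must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_drugs": self.n_drugs, "coverage": dict(self.coverage),
            "overlap_fraction_interactions": self.overlap_fraction_interactions,
            "overlap_fraction_side_effects": self.overlap_fraction_side_effects,
            "n_interactions": self.n_interactions,
            "n_side_effects": self.n_side_effects,
            "n_molecules": self.n_molecules, "n_pathways": self.n_pathways,
            "n_diseases": self.n_diseases, "synonym_rate": self.synonym_rate,
            "mapping_noise": self.mapping_noise, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorParams":
        return cls(**data)


@dataclass
class GroundTruth:
    """Exact bookkeeping of what the emitted files contain."""

    params: dict
    # source-pair key "A|B" -> list of [a_native_id, b_native_id]
    true_mappings: dict[str, list[list[str]]]
    # per-kind: counts {a_only, b_only, shared, union, a_total, b_total}
    interaction_counts: dict[str, int]
    side_effect_counts: dict[str, int]
    # realized hit sets, keyed by drug *name* (stable across ingestion)
    interaction_hits: dict[str, list[list[str]]]   # tag -> [[name_a, name_b]]
    side_effect_hits: dict[str, list[list[str]]]   # tag -> [[name, term]]
    demo: Optional[dict] = None
    demo_reason: Optional[str] = None

    def to_json(self) -> str:
        data = {
            "params": self.params, "true_mappings": self.true_mappings,
            "interaction_counts": self.interaction_counts,
            "side_effect_counts": self.side_effect_counts,
            "interaction_hits": self.interaction_hits,
            "side_effect_hits": self.side_effect_hits,
            "demo": self.demo, "demo_reason": self.demo_reason,
        }
        return json.dumps(data, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _drug_name(i: int) -> str:
    return f"DRUG_{i + 1:04d}"


def _atc_code(i: int, alt: bool = False) -> str:
    letter = "Z" if alt else _ATC_LETTERS[i % len(_ATC_LETTERS)]
    return f"{letter}{(i // 100) % 100:02d}AB{i % 100:02d}"


def _sample_pairs(rng: random.Random, pool: Sequence[int], count: int,
                  used: set[tuple[int, int]], what: str) -> list[tuple[int, int]]:
    """Draw ``count`` distinct unordered index pairs from ``pool`` that are
    not in ``used``; exact, by enumerate-shuffle-take."""
    if count == 0:
        return []
    pool = sorted(pool)
    candidates = [(a, b) for i, a in enumerate(pool) for b in pool[i + 1:]
                  if (a, b) not in used]
    if len(candidates) < count:
        raise GenerationError(
            f"cannot plant {count} {what} pairs: only {len(candidates)} "
            f"unused pairs available in a pool of {len(pool)} drugs")
    rng.shuffle(candidates)
    picked = candidates[:count]
    used.update(picked)
    return picked


def _sample_hits(rng: random.Random, pool: Sequence[int], terms: Sequence[str],
                 count: int, used: set[tuple[int, str]], what: str,
                 forced: Sequence[tuple[int, str]] = ()) -> list[tuple[int, str]]:
    """Draw ``count`` distinct (drug index, term) hits from ``pool`` × terms."""
    picked: list[tuple[int, str]] = []
    for hit in forced:
        if hit in used:
            raise GenerationError(f"forced {what} hit {hit} already used")
        used.add(hit)
        picked.append(hit)
    remaining = count - len(picked)
    if remaining < 0:
        raise GenerationError(f"more forced {what} hits than requested count")
    candidates = [(d, t) for d in sorted(pool) for t in terms
                  if (d, t) not in used]
    if len(candidates) < remaining:
        raise GenerationError(
            f"cannot plant {count} {what} hits: universe exhausted "
            f"({len(candidates)} unused of pool {len(pool)} × {len(terms)} terms)")
    rng.shuffle(candidates)
    picked.extend(candidates[:remaining])
    used.update(candidates[:remaining])
    return picked


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def generate(params: GeneratorParams, out_dir: str | Path) -> GroundTruth:
    """Write the four source-dialect file sets plus ``synonyms.tsv``,
    ``ground_truth.json`` and ``params.yaml`` into ``out_dir``.

    Raises :class:`GenerationError` before writing anything if the
    requested counts cannot be realized exactly.
    """
    rng = random.Random(params.seed)
    n = params.n_drugs

    # -- drug universe ------------------------------------------------------
    names = [_drug_name(i) for i in range(n)]
    synonyms = {i: f"{names[i]}_ALT" for i in range(n) if rng.random() < 0.30}
    atc = {i: [_atc_code(i)] for i in range(n)}
    for i in range(n):
        if rng.random() < 0.20:
            atc[i].append(_atc_code(i, alt=True))

    member: dict[str, list[int]] = {}
    for tag in (PHARM, MOLDB, SEDB):
        k = round(params.coverage.get(tag, 0.0) * n)
        member[tag] = sorted(rng.sample(range(n), k))
    in_pharm, in_mol, in_se = (set(member[t]) for t in (PHARM, MOLDB, SEDB))

    native = {
        PHARM: {i: f"P{i + 1:04d}" for i in member[PHARM]},
        MOLDB: {i: f"DB{i + 1:05d}" for i in member[MOLDB]},
        SEDB: {i: f"S{i + 1:04d}" for i in member[SEDB]},
    }

    # -- planted structure sizes (validated before any file is written) ----
    pm_common = sorted(in_pharm & in_mol)
    pms_common = sorted(in_pharm & in_mol & in_se)
    n_shared_int = math.floor(params.overlap_fraction_interactions
                              * params.n_interactions)
    rest = params.n_interactions - n_shared_int
    n_a_int, n_b_int = (rest + 1) // 2, rest // 2
    n_shared_se = math.floor(params.overlap_fraction_side_effects
                             * params.n_side_effects)
    rest_se = params.n_side_effects - n_shared_se
    n_a_se, n_b_se = (rest_se + 1) // 2, rest_se // 2

    used_pairs: set[tuple[int, int]] = set()
    shared_pairs = _sample_pairs(rng, pm_common, n_shared_int, used_pairs,
                                 "shared interaction")
    a_pairs = _sample_pairs(rng, member[PHARM], n_a_int, used_pairs,
                            "pharmaceutical-only interaction")
    b_pairs = _sample_pairs(rng, member[MOLDB], n_b_int, used_pairs,
                            "molecular-only interaction")

    terms = list(SIDE_EFFECT_TERMS)
    used_hits: set[tuple[int, str]] = set()
    shared_hits = _sample_hits(rng, pms_common, terms, n_shared_se, used_hits,
                               "shared side-effect")
    # plant one cumulative pair inside the PHARM-only budget when possible,
    # so the bundled demo profile always has a cumulative side effect
    forced_a: list[tuple[int, str]] = []
    if n_a_se >= 2 and len(member[PHARM]) >= 2 and terms:
        d1, d2 = rng.sample(member[PHARM], 2)
        t0 = rng.choice(terms)
        if (d1, t0) not in used_hits and (d2, t0) not in used_hits:
            forced_a = [(d1, t0), (d2, t0)]
    a_hits = _sample_hits(rng, member[PHARM], terms, n_a_se, used_hits,
                          "pharmaceutical-only side-effect", forced=forced_a)
    b_hits = _sample_hits(rng, member[SEDB], terms, n_b_se, used_hits,
                          "side-effect-source-only side-effect")

    # -- molecules and links ------------------------------------------------
    cyps = list(CYP_MOLECULES[:min(len(CYP_MOLECULES), params.n_molecules)])
    n_targets = max(params.n_molecules - len(cyps), 0)
    targets = [f"T{i + 1:04d}" for i in range(n_targets)]
    molecules = cyps + targets
    link_rows: list[tuple[int, str, str, str]] = []  # (drug idx, molecule, role, action)
    link_keys: set[tuple[int, str, str, str]] = set()

    def add_link(d: int, mol: str, role: str, action: str) -> None:
        key = (d, mol, role, action)
        if key not in link_keys:
            link_keys.add(key)
            link_rows.append(key)

    for d in member[MOLDB]:
        if cyps and rng.random() < 0.70:
            action = rng.choices(["substrate", "inhibitor", "inducer"],
                                 weights=[0.60, 0.25, 0.15])[0]
            add_link(d, rng.choice(cyps), "enzyme", action)
        if cyps and rng.random() < 0.30:
            action = rng.choices(["substrate", "inhibitor", "inducer"],
                                 weights=[0.60, 0.25, 0.15])[0]
            add_link(d, rng.choice(cyps), "enzyme", action)
        if targets and rng.random() < 0.50:
            add_link(d, rng.choice(targets), "target",
                     rng.choice(["inhibitor", "unknown"]))
        if rng.random() < 0.15:
            add_link(d, "TRANSP01", "transporter", "substrate")
        if rng.random() < 0.10:
            add_link(d, "CARR01", "carrier", "substrate")
    # guarantee one CYP inducer/substrate perpetrator-victim pair
    if cyps and len(member[MOLDB]) >= 2:
        c1, c2 = rng.sample(member[MOLDB], 2)
        add_link(c1, cyps[-1], "enzyme", "inducer")
        add_link(c2, cyps[-1], "enzyme", "substrate")

    # -- diseases and pathways ---------------------------------------------
    diseases: list[tuple[str, str, list[str]]] = []
    for i in range(params.n_diseases):
        if i < params.n_diseases // 2 and i < len(terms):
            # diseases named after side-effect terms, enabling
            # drug-induced disease detection
            diseases.append((f"DIS{i + 1:04d}", terms[i].title(), []))
        else:
            diseases.append((f"DIS{i + 1:04d}", f"Condition {i + 1}", []))
    disease_ids = [d[0] for d in diseases]

    pathways: list[tuple[str, str, list[str], list[str], list[str]]] = []
    for i in range(params.n_pathways):
        members_m = sorted(rng.sample(molecules, min(4, len(molecules)))) if molecules else []
        drugs_pw = sorted(
            native[MOLDB][d]
            for d in rng.sample(member[MOLDB], min(5, len(member[MOLDB])))
        ) if member[MOLDB] else []
        dis_pw = sorted(rng.sample(disease_ids, min(3, len(disease_ids)))) if disease_ids else []
        pathways.append((f"PW{i + 1:04d}", f"Synthetic pathway {i + 1}",
                         members_m, drugs_pw, dis_pw))

    # -- write files --------------------------------------------------------
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    syn_by_term: dict[str, list[str]] = {}
    for raw, canon in SIDE_EFFECT_SYNONYMS.items():
        syn_by_term.setdefault(canon, []).append(raw)

    def render_term(term: str) -> str:
        alts = syn_by_term.get(term)
        if alts and rng.random() < params.synonym_rate:
            return rng.choice(sorted(alts))
        return term

    # drug tables
    noise_count = math.floor(params.mapping_noise * len(pm_common))
    noise_drugs = set(rng.sample(pm_common, noise_count)) if noise_count else set()
    drug_header = ["native_id", "name", "synonyms", "atc_codes", "xrefs"]
    rows = []
    for d in member[PHARM]:
        xref = "" if (d not in in_mol or d in noise_drugs) \
            else f"{MOLDB}:{native[MOLDB][d]}"
        rows.append([native[PHARM][d], names[d], synonyms.get(d, ""),
                     "|".join(atc[d]), xref])
    _write_tsv(out_dir / f"{PHARM}_drugs.tsv", drug_header, rows)
    rows = [[native[MOLDB][d], names[d], synonyms.get(d, ""),
             "|".join(atc[d]), ""] for d in member[MOLDB]]
    _write_tsv(out_dir / f"{MOLDB}_drugs.tsv", drug_header, rows)
    rows = [[native[SEDB][d], names[d], synonyms.get(d, ""), "", ""]
            for d in member[SEDB]]
    _write_tsv(out_dir / f"{SEDB}_drugs.tsv", drug_header, rows)
    _write_tsv(out_dir / f"{PATHDB}_drugs.tsv", drug_header, [])

    # interactions
    int_header = ["native_id_a", "native_id_b", "effect", "severity"]
    effects: dict[tuple[int, int], tuple[str, str]] = {}
    for k, pair in enumerate(shared_pairs + a_pairs + b_pairs):
        effects[pair] = (f"Synthetic interaction effect {k + 1}",
                         rng.choice(_SEVERITIES))
    rows = [[native[PHARM][a], native[PHARM][b], *effects[(a, b)]]
            for a, b in shared_pairs + a_pairs]
    _write_tsv(out_dir / f"{PHARM}_interactions.tsv", int_header, rows)
    rows = [[native[MOLDB][a], native[MOLDB][b], *effects[(a, b)]]
            for a, b in shared_pairs + b_pairs]
    _write_tsv(out_dir / f"{MOLDB}_interactions.tsv", int_header, rows)

    # side effects
    se_header = ["native_id", "term", "frequency"]
    rows = [[native[PHARM][d], render_term(t), rng.choice(_FREQUENCIES)]
            for d, t in shared_hits + a_hits]
    _write_tsv(out_dir / f"{PHARM}_side_effects.tsv", se_header, rows)
    rows = [[native[SEDB][d], render_term(t), rng.choice(_FREQUENCIES)]
            for d, t in shared_hits + b_hits]
    _write_tsv(out_dir / f"{SEDB}_side_effects.tsv", se_header, rows)

    # molecule links, pathways, diseases
    _write_tsv(out_dir / f"{MOLDB}_molecule_links.tsv",
               ["native_id", "molecule_id", "molecule_role", "action"],
               [[native[MOLDB][d], mol, role, action]
                for d, mol, role, action in link_rows])
    _write_tsv(out_dir / f"{PATHDB}_pathways.tsv",
               ["pathway_id", "name", "member_molecules", "drugs", "diseases"],
               [[pid, pname, "|".join(mm), "|".join(dd), "|".join(dis)]
                for pid, pname, mm, dd, dis in pathways])
    _write_tsv(out_dir / f"{PATHDB}_diseases.tsv",
               ["native_id", "name", "synonyms"],
               [[did, dname, "|".join(syn)] for did, dname, syn in diseases])
    _write_tsv(out_dir / "synonyms.tsv", ["raw_term", "canonical_term"],
               sorted(SIDE_EFFECT_SYNONYMS.items()))

    # -- ground truth -------------------------------------------------------
    gt = GroundTruth(
        params=params.to_dict(),
        true_mappings={
            f"{PHARM}|{MOLDB}": [[native[PHARM][d], native[MOLDB][d]]
                                 for d in pm_common],
            f"{MOLDB}|{SEDB}": [[native[MOLDB][d], native[SEDB][d]]
                                for d in sorted(in_mol & in_se)],
        },
        interaction_counts={
            "a_only": n_a_int, "b_only": n_b_int, "shared": n_shared_int,
            "union": params.n_interactions,
            "a_total": n_a_int + n_shared_int, "b_total": n_b_int + n_shared_int,
        },
        side_effect_counts={
            "a_only": n_a_se, "b_only": n_b_se, "shared": n_shared_se,
            "union": params.n_side_effects,
            "a_total": n_a_se + n_shared_se, "b_total": n_b_se + n_shared_se,
        },
        interaction_hits={
            PHARM: sorted([names[a], names[b]] for a, b in shared_pairs + a_pairs),
            MOLDB: sorted([names[a], names[b]] for a, b in shared_pairs + b_pairs),
        },
        side_effect_hits={
            PHARM: sorted([names[d], t] for d, t in shared_hits + a_hits),
            SEDB: sorted([names[d], t] for d, t in shared_hits + b_hits),
        },
    )
    _plan_demo(gt, params, names, shared_pairs, a_pairs, b_pairs,
               shared_hits, a_hits, b_hits, link_rows,
               [in_pharm, in_mol, in_se])
    (out_dir / "ground_truth.json").write_text(gt.to_json(), encoding="utf-8")
    (out_dir / "params.yaml").write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=True), encoding="utf-8")
    return gt


def _plan_demo(gt: GroundTruth, params: GeneratorParams, names: list[str],
               shared_pairs, a_pairs, b_pairs, shared_hits, a_hits, b_hits,
               link_rows, member_sets) -> None:
    """Pick a 7-drug demo profile with planted findings and record the
    expected analysis answers by brute-force bookkeeping over the
    realized structures."""
    all_pairs = shared_pairs + a_pairs + b_pairs
    all_hits = shared_hits + a_hits + b_hits
    if not all_pairs:
        gt.demo_reason = "no interactions were generated (n_interactions = 0?)"
        return
    if not all_hits:
        gt.demo_reason = "no side effects were generated (n_side_effects = 0?)"
        return
    # drugs in both PHARM and SEDB but absent from MOLDB cannot fuse (no
    # direct mapping path) and so resolve ambiguously by name; the demo
    # profile is restricted to drugs that fuse into a single record
    in_pharm, in_mol, in_se = member_sets
    unsplit = (in_pharm | in_mol | in_se) - ((in_pharm & in_se) - in_mol)
    by_term: dict[str, set[int]] = {}
    for d, t in all_hits:
        by_term.setdefault(t, set()).add(d)
    cumulative_candidates = sorted(
        (t, ds) for t, ds in by_term.items() if len(ds & unsplit) >= 2)
    if not cumulative_candidates:
        gt.demo_reason = "no side-effect term is shared by two drugs"
        return
    term0, _ = cumulative_candidates[0]
    term0_drugs = by_term[term0] & unsplit
    usable_pairs = [p for p in all_pairs
                    if p[0] in unsplit and p[1] in unsplit]
    if not usable_pairs:
        gt.demo_reason = "no interaction pair with unambiguous drugs"
        return
    cyp_pair: Optional[tuple[int, str, int]] = None
    inducers: dict[str, list[int]] = {}
    substrates: dict[str, list[int]] = {}
    for d, mol, role, action in link_rows:
        if role == "enzyme":
            if action == "inducer":
                inducers.setdefault(mol, []).append(d)
            elif action == "substrate":
                substrates.setdefault(mol, []).append(d)
    for mol in sorted(inducers):
        for perp in sorted(inducers[mol]):
            for victim in sorted(substrates.get(mol, [])):
                if perp != victim:
                    cyp_pair = (perp, mol, victim)
                    break
            if cyp_pair:
                break
        if cyp_pair:
            break
    if cyp_pair is None:
        gt.demo_reason = "no CYP inducer/substrate drug pair exists"
        return

    profile: list[int] = []
    for d in [*usable_pairs[0], *sorted(term0_drugs)[:2], cyp_pair[0], cyp_pair[2]]:
        if d not in profile:
            profile.append(d)
    # plant a second interaction so every demo medication carries at least
    # two pairwise interactions, preferring pairs adding fewest new drugs
    def pairs_within(drugs: set[int]) -> int:
        return sum(1 for a, b in all_pairs if a in drugs and b in drugs)

    if pairs_within(set(profile)) < 2:
        candidates = sorted(
            usable_pairs[1:],
            key=lambda p: (len(set(p) - set(profile)), p))
        for pair in candidates:
            new = [d for d in pair if d not in profile]
            if len(profile) + len(new) <= 7:
                profile.extend(new)
                if pairs_within(set(profile)) >= 2:
                    break
    if pairs_within(set(profile)) < 2:
        gt.demo_reason = "cannot plant two interactions within seven drugs"
        return
    eligible = sorted(unsplit)
    # a drug free of any assertion, to populate the no-risk list
    risky = {d for p in all_pairs for d in p}
    risky.update(d for d, _ in all_hits)
    risky.update(d for d, _, role, _a in link_rows if role == "enzyme")
    clean = [d for d in eligible if d not in risky and d not in profile]
    if clean and len(profile) < 7:
        profile.append(clean[0])
    extra = [d for d in eligible if d not in profile]
    while len(profile) < 7 and extra:
        profile.append(extra.pop(0))
    profile = profile[:7]
    pset = set(profile)

    expected_pairwise = sorted(
        sorted([names[a], names[b]])
        for a, b in all_pairs if a in pset and b in pset)
    expected_cumulative = {
        t: sorted(names[d] for d in ds & pset)
        for t, ds in by_term.items() if len(ds & pset) >= 2}
    flags = []
    enzyme_links = [(d, mol, action) for d, mol, role, action in link_rows
                    if role == "enzyme" and d in pset]
    for perp, mol, action in enzyme_links:
        if action not in ("inducer", "inhibitor"):
            continue
        for victim, mol2, action2 in enzyme_links:
            if victim != perp and mol2 == mol and action2 == "substrate":
                flags.append([names[perp], mol, names[victim],
                              "raise_dose" if action == "inducer" else "lower_dose"])
    diagnoses = [term0, "Unrelated synthetic condition"]
    expected_induced = {term0: sorted(names[d] for d in by_term[term0] & pset)}
    observed_terms = sorted({t for d, t in all_hits if d in pset})
    observed = [term0] + [t for t in observed_terms if t != term0][:1]
    if len(observed) < 2:  # pad from the vocabulary so the demo has 2
        observed += [t for t in SIDE_EFFECT_TERMS if t not in observed][:1]
    finding_drugs = {n for pair in expected_pairwise for n in pair}
    finding_drugs.update(n for ns in expected_cumulative.values() for n in ns)
    finding_drugs.update({f[0] for f in flags} | {f[2] for f in flags})
    finding_drugs.update(n for ns in expected_induced.values() for n in ns)
    gt.demo = {
        "drugs": [names[d] for d in profile],
        "observed_effects": observed,
        "diagnoses": diagnoses,
        "defective_cyps": [],
        "expected": {
            "pairwise_interactions": expected_pairwise,
            "cumulative_effects": {t: v for t, v in sorted(expected_cumulative.items())},
            "cyp_flags": sorted(flags),
            "induced_diseases": expected_induced,
            "induced_fraction": len(expected_induced) / len(diagnoses),
            "no_risk_drugs": sorted(names[d] for d in profile
                                    if names[d] not in finding_drugs),
        },
    }


def demo_profile(ground_truth: GroundTruth, kb: KnowledgeBase) -> MedicationProfile:
    """The bundled demo medication profile (7 drugs, 2 observed effects,
    2 diagnoses), resolved against an ingested knowledge base."""
    if ground_truth.demo is None:
        raise GenerationError(
            f"no demo profile available: {ground_truth.demo_reason}")
    demo = ground_truth.demo
    return MedicationProfile.from_names(
        kb, demo["drugs"], diagnoses=demo["diagnoses"],
        observed_effects=demo["observed_effects"],
        defective_cyps=demo["defective_cyps"],
    )


def default_mapping_methods() -> list[tuple[str, str, str]]:
    """The mapping plan matching the emitted sources: identifier/ATC
    between the pharmaceutical and molecular sources, names between the
    molecular and side-effect sources."""
    return [(PHARM, MOLDB, "atc_and_identifier"), (MOLDB, SEDB, "name")]


def ingest_generated(directory: str | Path,
                     report: Optional[IngestReport] = None) -> KnowledgeBase:
    """Ingest a generated file set with the default source tags and
    mapping plan."""
    return ingest_directory(
        directory, [PHARM, MOLDB, SEDB, PATHDB],
        mapping_methods=default_mapping_methods(),
        report=report,
    )


def load_ground_truth(directory: str | Path) -> GroundTruth:
    return GroundTruth.from_json(
        (Path(directory) / "ground_truth.json").read_text(encoding="utf-8"))
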