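import random

import pytest

from drugkb._text import normalize
from drugkb.analysis import (
    MedicationProfile,
    combined_drug_interactions,
    cumulative_side_effects,
    cyp_dosage_flags,
    drug_induced_diseases,
    drug_molecule_interactions,
    molecular_medication_analysis,
    pathway_network,
    single_drug_interactions,
    single_drug_side_effects,
)
from drugkb.model import (
    AmbiguousMatchError,
    NotFoundError,
    ValidationError,
    canonical_pair,
)


# --------------------------------------------------------------------------
# brute-force oracles, independent of the library implementations

def oracle_combined(profile, kb):
    found = []
    ids = profile.drug_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pair = canonical_pair(ids[i], ids[j])
            if pair in kb.interactions:
                found.append(pair)
    return sorted(found)


def oracle_cumulative(profile, kb):
    counts = {}
    for assertion in kb.side_effects.values():
        if assertion.drug_id in profile.drug_ids:
            counts.setdefault(assertion.term, set()).add(assertion.drug_id)
    return {t: ds for t, ds in counts.items() if len(ds) >= 2}


def oracle_cyp(profile, kb):
    links = [l for l in kb.molecule_links.values() if l.molecule_role == "enzyme"]
    flags = set()
    for p in profile.drug_ids:
        for v in profile.drug_ids:
            if p == v:
                continue
            for lp in links:
                if lp.drug_id != p or lp.action not in ("inducer", "inhibitor"):
                    continue
                for lv in links:
                    if (lv.drug_id == v and lv.action == "substrate"
                            and lv.molecule_id == lp.molecule_id):
                        flags.add((p, lp.molecule_id, v,
                                   "raise" if lp.action == "inducer" else "lower"))
    known = kb.molecule_ids()
    for cyp in profile.defective_cyps:
        if cyp not in known:
            continue
        for v in profile.drug_ids:
            for lv in links:
                if lv.drug_id == v and lv.action == "substrate" and lv.molecule_id == cyp:
                    flags.add((v, cyp, v, "risk"))
    return flags


def oracle_induced(profile, kb):
    matches = {}
    for diagnosis in profile.diagnoses:
        if not diagnosis.strip():
            continue
        names = {normalize(diagnosis)}
        for disease in kb.diseases.values():
            all_names = {normalize(n) for n in [disease.name, *disease.synonyms]}
            if normalize(diagnosis) in all_names:
                names |= all_names
        terms = {kb.canonicalize_term(n) for n in names}
        drugs = set()
        for assertion in kb.side_effects.values():
            if assertion.drug_id in profile.drug_ids and assertion.term in terms:
                drugs.add(assertion.drug_id)
        if drugs:
            matches[diagnosis] = drugs
    return matches


def random_profiles(kb, n_profiles, seed):
    rng = random.Random(seed)
    drug_ids = sorted(kb.drugs)
    terms = sorted({t for _, t in kb.side_effects})
    disease_names = sorted(d.name for d in kb.diseases.values())
    cyps = sorted(m for m in kb.molecule_ids() if m.startswith("CYP"))
    for _ in range(n_profiles):
        yield MedicationProfile(
            drug_ids=rng.sample(drug_ids, rng.randint(2, min(8, len(drug_ids)))),
            diagnoses=rng.sample(disease_names, min(3, len(disease_names)))
            + rng.sample(terms, min(2, len(terms))),
            observed_effects=rng.sample(terms, min(2, len(terms))),
            defective_cyps=rng.sample(cyps, min(1, len(cyps))) + ["CYPFAKE9"],
        )


# --------------------------------------------------------------------------

class TestSingleDrugInteractions:
    def test_partition_by_provenance(self, tiny_kb):
        part = single_drug_interactions("Clonazepam", tiny_kb,
                                        sources=("PHARM", "MOLDB"))
        assert part.shared == ["Zeta"]
        assert part.only_a == ["Clopidogrel"]
        assert part.only_b == ["Alpha"]

    def test_no_interactions_gives_empty_parts(self, tiny_kb):
        part = single_drug_interactions("Dextro", tiny_kb, sources=("PHARM", "MOLDB"))
        assert part.shared == part.only_a == part.only_b == []

    def test_parts_sorted_alphabetically(self, tiny_kb):
        tiny_kb.add_interaction("D1", "D3", provenance={"MOLDB"})
        part = single_drug_interactions("Clonazepam", tiny_kb,
                                        sources=("PHARM", "MOLDB"))
        assert part.only_b == sorted(part.only_b) == ["Alpha", "Atenolol"]

    def test_unknown_drug_not_found(self, tiny_kb):
        with pytest.raises(NotFoundError):
            single_drug_interactions("Missingol", tiny_kb)


class TestCombinedInteractions:
    def test_only_pairs_within_profile(self, tiny_kb):
        profile = MedicationProfile(drug_ids=["D1", "D2", "D6"])
        found = combined_drug_interactions(profile, tiny_kb)
        assert [a.pair for a in found] == [("D1", "D2")]

    def test_single_drug_profile_is_empty_not_error(self, tiny_kb):
        assert combined_drug_interactions(
            MedicationProfile(drug_ids=["D1"]), tiny_kb) == []

    def test_dedup_gives_single_assertion_with_both_sources(self, tiny_kb):
        found = combined_drug_interactions(
            MedicationProfile(drug_ids=["D1", "D4"]), tiny_kb)
        assert len(found) == 1 and found[0].provenance == {"PHARM", "MOLDB"}

    def test_invariant_under_profile_permutation(self, tiny_kb):
        a = combined_drug_interactions(
            MedicationProfile(drug_ids=["D1", "D2", "D3", "D4"]), tiny_kb)
        b = combined_drug_interactions(
            MedicationProfile(drug_ids=["D4", "D3", "D2", "D1"]), tiny_kb)
        assert [x.pair for x in a] == [x.pair for x in b]


class TestDrugMoleculeInteractions:
    def test_groups_in_fixed_role_order(self, tiny_kb):
        groups = drug_molecule_interactions("Clonazepam", tiny_kb)
        assert list(groups) == ["target", "enzyme", "transporter", "carrier"]
        assert [l.molecule_id for l in groups["enzyme"]] == ["CYP3A4"]
        assert [l.molecule_id for l in groups["transporter"]] == ["TRANSP01"]

    def test_no_links_gives_empty_groups(self, tiny_kb):
        groups = drug_molecule_interactions("Dextro", tiny_kb)
        assert all(v == [] for v in groups.values())


class TestCypFlags:
    def test_inducer_substrate_raises_dose(self, tiny_kb):
        # Clopidogrel (D2) induces CYP3A4; Clonazepam (D1) is a substrate
        flags = cyp_dosage_flags(MedicationProfile(drug_ids=["D1", "D2"]), tiny_kb)
        assert len(flags) == 1
        f = flags[0]
        assert (f.perpetrator_drug_id, f.victim_drug_id) == ("D2", "D1")
        assert "raise_dose" in f.direction

    def test_inhibitor_substrate_lowers_dose(self, tiny_kb):
        flags = cyp_dosage_flags(MedicationProfile(drug_ids=["D3", "D7"]), tiny_kb)
        assert len(flags) == 1 and "lower_dose" in flags[0].direction

    def test_no_shared_cyp_no_flags(self, tiny_kb):
        assert cyp_dosage_flags(
            MedicationProfile(drug_ids=["D1", "D3"]), tiny_kb) == []

    def test_defective_cyp_flags_substrate_drug(self, tiny_kb):
        flags = cyp_dosage_flags(
            MedicationProfile(drug_ids=["D7"], defective_cyps=["CYP2D6"]), tiny_kb)
        assert len(flags) == 1
        assert flags[0].perpetrator_drug_id == flags[0].victim_drug_id == "D7"
        assert "risk" in flags[0].direction

    def test_unknown_defective_cyp_warns_and_skips(self, tiny_kb):
        warnings = []
        flags = cyp_dosage_flags(
            MedicationProfile(drug_ids=["D7"], defective_cyps=["CYP9Z9"]),
            tiny_kb, warnings)
        assert flags == [] and len(warnings) == 1


class TestSingleDrugSideEffects:
    def test_partition_and_sort(self, tiny_kb):
        part = single_drug_side_effects("Clonazepam", tiny_kb,
                                        sources=("PHARM", "SEDB"))
        assert part.shared == ["nausea"]
        assert part.only_a == ["headache"]
        assert part.only_b == []

    def test_drug_without_effects_is_empty(self, tiny_kb):
        part = single_drug_side_effects("Dextro", tiny_kb, sources=("PHARM", "SEDB"))
        assert part.shared == part.only_a == part.only_b == []


class TestCumulativeSideEffects:
    def test_threshold_of_two_drugs(self, tiny_kb):
        result = cumulative_side_effects(
            MedicationProfile(drug_ids=["D1", "D2", "D3"]), tiny_kb)
        assert result == {"nausea": frozenset({"D1", "D2"})}

    def test_single_drug_profile_empty(self, tiny_kb):
        assert cumulative_side_effects(
            MedicationProfile(drug_ids=["D1"]), tiny_kb) == {}

    def test_same_term_from_two_sources_counts_drug_once(self, tiny_kb):
        # D1's nausea is asserted by PHARM and SEDB but contributes once
        result = cumulative_side_effects(
            MedicationProfile(drug_ids=["D1", "D2"]), tiny_kb)
        assert result["nausea"] == frozenset({"D1", "D2"})

    def test_empty_profile_is_error(self, tiny_kb):
        with pytest.raises(ValidationError):
            cumulative_side_effects(MedicationProfile(drug_ids=[]), tiny_kb)


class TestDrugInducedDiseases:
    def test_diagnosis_matching_side_effect_term(self, tiny_kb):
        result = drug_induced_diseases(
            MedicationProfile(drug_ids=["D1"], diagnoses=["nausea"]), tiny_kb)
        assert result.matches == {"nausea": frozenset({"D1"})}
        assert result.fraction_flagged == 1.0

    def test_no_overlap_gives_empty_and_zero_fraction(self, tiny_kb):
        result = drug_induced_diseases(
            MedicationProfile(drug_ids=["D3"], diagnoses=["Condition X"]), tiny_kb)
        assert result.matches == {} and result.fraction_flagged == 0.0

    def test_two_contributors_enter_cumulative_subset(self, tiny_kb):
        result = drug_induced_diseases(
            MedicationProfile(drug_ids=["D1", "D2"], diagnoses=["Nausea"]), tiny_kb)
        assert result.cumulative == {"Nausea": frozenset({"D1", "D2"})}

    def test_diagnosis_via_synonym_table(self, tiny_kb):
        # "cephalalgia" canonicalizes to "headache", a D1 side effect
        result = drug_induced_diseases(
            MedicationProfile(drug_ids=["D1"], diagnoses=["Cephalalgia"]), tiny_kb)
        assert result.matches == {"Cephalalgia": frozenset({"D1"})}


class TestPathwayNetwork:
    def test_chosen_source_filter_and_other_counts(self, tiny_kb):
        view = pathway_network("PW1", tiny_kb, "MOLDB")
        assert view.drug_ids == ["D1"]  # D7 has no MOLDB id
        assert view.other_source_counts["PHARM"] == 2
        assert view.disease_ids == ["DIS1"]

    def test_query_by_name(self, tiny_kb):
        assert pathway_network("arachidonate METABOLISM", tiny_kb,
                               "PHARM").pathway_id == "PW1"

    def test_unknown_pathway_not_found(self, tiny_kb):
        with pytest.raises(NotFoundError):
            pathway_network("PW999", tiny_kb, "PHARM")

    def test_duplicate_name_is_ambiguous(self, tiny_kb):
        from drugkb.model import PathwayRecord
        tiny_kb.add_pathway(PathwayRecord("PW2", "Arachidonate metabolism"))
        with pytest.raises(AmbiguousMatchError):
            pathway_network("Arachidonate metabolism", tiny_kb, "PHARM")


class TestCompositeReport:
    def test_empty_profile_is_error(self, tiny_kb):
        with pytest.raises(ValidationError):
            molecular_medication_analysis(MedicationProfile(drug_ids=[]), tiny_kb)

    def test_no_findings_puts_all_drugs_in_no_risk(self, tiny_kb):
        report = molecular_medication_analysis(
            MedicationProfile(drug_ids=["D6"]), tiny_kb)
        assert report.no_risk_drug_ids == ["D6"]

    def test_component_consistency(self, tiny_kb):
        profile = MedicationProfile(drug_ids=["D1", "D2", "D4"],
                                    diagnoses=["nausea"])
        report = molecular_medication_analysis(profile, tiny_kb)
        assert [a.pair for a in report.pairwise_interactions] == \
               [a.pair for a in combined_drug_interactions(profile, tiny_kb)]
        assert report.cumulative_effects == cumulative_side_effects(profile, tiny_kb)

    def test_observed_effects_annotate_but_never_create_findings(self, tiny_kb):
        base = molecular_medication_analysis(
            MedicationProfile(drug_ids=["D1", "D3"]), tiny_kb)
        with_obs = molecular_medication_analysis(
            MedicationProfile(drug_ids=["D1", "D3"],
                              observed_effects=["emesis", "rash"]), tiny_kb)
        assert len(with_obs.pairwise_interactions) == len(base.pairwise_interactions)
        assert with_obs.cumulative_effects == base.cumulative_effects
        assert with_obs.explained_observed == {"rash": frozenset({"D3"})}

    def test_monotone_in_profile_size(self, tiny_kb):
        small = molecular_medication_analysis(
            MedicationProfile(drug_ids=["D1", "D2"]), tiny_kb)
        large = molecular_medication_analysis(
            MedicationProfile(drug_ids=["D1", "D2", "D3", "D4"]), tiny_kb)
        assert {a.pair for a in small.pairwise_interactions} <= \
               {a.pair for a in large.pairwise_interactions}
        for term, drugs in small.cumulative_effects.items():
            assert drugs <= large.cumulative_effects[term]


class TestOracleEquivalence:
    """Every operation matches an independent brute-force scan on a
    compact synthetic knowledge base, over many random profiles."""

    N_PROFILES = 120

    def test_operations_match_brute_force(self, small_generated):
        kb = small_generated["kb"]
        for profile in random_profiles(kb, self.N_PROFILES, seed=11):
            found = combined_drug_interactions(profile, kb)
            assert [a.pair for a in found] == oracle_combined(profile, kb)

            assert {t: set(d) for t, d in
                    cumulative_side_effects(profile, kb).items()} == \
                   oracle_cumulative(profile, kb)

            flags = cyp_dosage_flags(profile, kb)
            got = {(f.perpetrator_drug_id, f.cyp_molecule_id, f.victim_drug_id,
                    f.direction.split(":")[0].replace("induction", "raise")
                    .replace("inhibition", "lower").replace("defective", "risk"))
                   for f in flags}
            assert got == oracle_cyp(profile, kb)

            induced = drug_induced_diseases(profile, kb)
            assert {d: set(s) for d, s in induced.matches.items()} == \
                   oracle_induced(profile, kb)
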