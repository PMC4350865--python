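import pytest
from hypothesis import settings

from drugkb import synth
from drugkb.model import (
    DiseaseRecord,
    DrugRecord,
    KnowledgeBase,
    MoleculeLink,
    PathwayRecord,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture()
def tiny_kb() -> KnowledgeBase:
    """Small hand-built knowledge base with known provenance layout.

    Interactions: Clonazepam-Clopidogrel (PHARM), Clonazepam-Alpha
    (MOLDB), Clonazepam-Zeta (both), Clopidogrel-Atenolol (PHARM).
    """
    kb = KnowledgeBase(source_tags=["PHARM", "MOLDB", "SEDB"])
    drugs = [
        DrugRecord("D1", "Clonazepam", source_ids={"PHARM": "P1", "MOLDB": "DB1"}),
        DrugRecord("D2", "Clopidogrel", source_ids={"PHARM": "P2"}),
        DrugRecord("D3", "Atenolol", source_ids={"PHARM": "P3", "MOLDB": "DB3"}),
        DrugRecord("D4", "Zeta", source_ids={"MOLDB": "DB4"}),
        DrugRecord("D5", "Alpha", source_ids={"MOLDB": "DB5"}),
        DrugRecord("D6", "Dextro", source_ids={"PHARM": "P6"}),
        DrugRecord("D7", "Acetylsalicylic acid", synonyms=["ASS", "Aspirin"],
                   atc_codes=["N02BA01"], source_ids={"PHARM": "P7"}),
    ]
    for d in drugs:
        kb.add_drug(d)
    kb.synonym_table = {"emesis": "vomiting", "cephalalgia": "headache",
                        "vomiting": "vomiting", "headache": "headache"}
    kb.add_interaction("D1", "D2", provenance={"PHARM"},
                       effects={"PHARM": "CNS depression"})
    kb.add_interaction("D1", "D5", provenance={"MOLDB"})
    kb.add_interaction("D1", "D4", provenance={"PHARM"})
    kb.add_interaction("D1", "D4", provenance={"MOLDB"})
    kb.add_interaction("D2", "D3", provenance={"PHARM"})
    kb.add_side_effect("D1", "nausea", provenance={"PHARM"})
    kb.add_side_effect("D1", "nausea", provenance={"SEDB"})
    kb.add_side_effect("D1", "headache", provenance={"PHARM"})
    kb.add_side_effect("D2", "nausea", provenance={"SEDB"})
    kb.add_side_effect("D3", "rash", provenance={"SEDB"})
    kb.add_side_effect("D7", "headache", provenance={"PHARM"})
    kb.add_molecule_link(MoleculeLink("D1", "CYP3A4", "enzyme", "substrate",
                                      provenance={"MOLDB"}))
    kb.add_molecule_link(MoleculeLink("D1", "TRANSP01", "transporter", "substrate",
                                      provenance={"MOLDB"}))
    kb.add_molecule_link(MoleculeLink("D2", "CYP3A4", "enzyme", "inducer",
                                      provenance={"MOLDB"}))
    kb.add_molecule_link(MoleculeLink("D3", "CYP2D6", "enzyme", "inhibitor",
                                      provenance={"MOLDB"}))
    kb.add_molecule_link(MoleculeLink("D7", "CYP2D6", "enzyme", "substrate",
                                      provenance={"MOLDB"}))
    kb.add_disease(DiseaseRecord("DIS1", "Nausea"))
    kb.add_disease(DiseaseRecord("DIS2", "Condition X"))
    kb.add_pathway(PathwayRecord("PW1", "Arachidonate metabolism",
                                 member_molecule_ids=["CYP3A4"],
                                 linked_drug_ids=["D1", "D7"],
                                 linked_disease_ids=["DIS1"]))
    return kb


@pytest.fixture(scope="session")
def generated(tmp_path_factory):
    """Default-condition synthetic file set, its ground truth and the
    ingested knowledge base (shared across tests)."""
    out = tmp_path_factory.mktemp("synth_default")
    params = synth.GeneratorParams(seed=1)
    gt = synth.generate(params, out)
    kb = synth.ingest_generated(out)
    return {"dir": out, "params": params, "gt": gt, "kb": kb}


@pytest.fixture(scope="session")
def small_generated(tmp_path_factory):
    """Compact synthetic knowledge base (<= 50 drugs) used for
    brute-force oracle comparisons."""
    out = tmp_path_factory.mktemp("synth_small")
    params = synth.GeneratorParams(
        n_drugs=50, n_interactions=80, n_side_effects=150,
        n_molecules=12, n_pathways=4, n_diseases=16, seed=7)
    gt = synth.generate(params, out)
    kb = synth.ingest_generated(out)
    return {"dir": out, "params": params, "gt": gt, "kb": kb}
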