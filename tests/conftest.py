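"""Shared fixtures: small hand-built dictionaries exercising the normalization rules."""

from __future__ import annotations

import pytest

from didkit.defaults import default_scheme
from didkit.lexicon import Authority, ConceptDictionary, ConceptEntry, RemapTable


@pytest.fixture
def chemid() -> ConceptDictionary:
    """ChemIDplus-like chemical dictionary (rank 1, carries CAS numbers)."""
    return ConceptDictionary(
        Authority("chemidplus", 1),
        [
            ConceptEntry(
                "103-90-2",
                "Acetaminophen",
                synonyms=(("Acetaminophen", "P"), ("paracetamol", "S")),
                cas_number="103-90-2",
            ),
            ConceptEntry("50-78-2", "Aspirin", synonyms=(("Aspirin", "P"),),
                         cas_number="50-78-2"),
            ConceptEntry("67346-49-0", "Arformoterol",
                         synonyms=(("Arformoterol", "P"),),
                         cas_number="67346-49-0"),
            ConceptEntry("113852-37-2", "Cidofovir",
                         synonyms=(("Cidofovir", "P"),),
                         cas_number="113852-37-2"),
        ],
    )


@pytest.fixture
def chebi() -> ConceptDictionary:
    """ChEBI-like dictionary whose PT for CAS 103-90-2 is 'paracetamol'."""
    return ConceptDictionary(
        Authority("chebi", 2),
        [
            ConceptEntry(
                "CHEBI:46195",
                "paracetamol",
                synonyms=(("paracetamol", "P"), ("acetaminophen", "S")),
                cas_number="103-90-2",
            ),
        ],
    )


@pytest.fixture
def umls_ind() -> ConceptDictionary:
    """UMLS-like indication dictionary with phenotypic and class concepts."""
    return ConceptDictionary(
        Authority("umls", 3),
        [
            ConceptEntry(
                "C0004623",
                "Bacterial Infections",
                synonyms=(("Bacterial Infections", "P"),),
                semantic_types=("DSYN",),
            ),
            ConceptEntry(
                "C0279516",
                "Anti-Bacterial Agents",
                synonyms=(("Anti-Bacterial Agents", "P"),
                          ("antibacterial agent", "S")),
                semantic_types=("ANTB",),
            ),
            ConceptEntry(
                "C2266959",
                "Cephalosporins",
                synonyms=(("Cephalosporins", "P"),),
                semantic_types=("ANTB",),
            ),
            ConceptEntry(
                "C0020538",
                "Hypertensive Disease",
                synonyms=(("Hypertensive Disease", "P"), ("hypertension", "S")),
                semantic_types=("DSYN",),
            ),
            ConceptEntry(
                "C0002962",
                "Angina Pectoris",
                synonyms=(("Angina Pectoris", "P"), ("angina", "S")),
                semantic_types=("DSYN",),
            ),
            ConceptEntry("C0027497", "Nausea", synonyms=(("Nausea", "P"),),
                         semantic_types=("DSYN",)),
            ConceptEntry("C0042963", "Vomiting", synonyms=(("Vomiting", "P"),),
                         semantic_types=("DSYN",)),
            ConceptEntry("C0030193", "Pain", synonyms=(("Pain", "P"),),
                         semantic_types=("DSYN",)),
        ],
    )


@pytest.fixture
def scheme():
    return default_scheme()


@pytest.fixture
def remap() -> RemapTable:
    return RemapTable({"C0279516": "C0004623"})
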