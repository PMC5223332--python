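"""Shipped default configuration tables.

Everything here is data a user can override from files: the phenotypic
semantic-type scheme, the salt/formulation and quasi-synonym lexicons used in
drug-name match classification, the indication-subtype cue and rollup tables,
and the relation allow/block lists applied when ingesting pair-style sources.
The tables are deliberately small seeds — real deployments are expected to
supply curated ones.
"""

from __future__ import annotations

from .lexicon import SemanticType, SemanticTypeScheme

# --- semantic types -------------------------------------------------------
# Phenotypic types cover diseases and other biological conditions, processes
# and functions; non-phenotypic exemplars are the pharmacologic-substance
# branch under which therapeutic-class terms live.
DEFAULT_SEMANTIC_TYPES = (
    SemanticType("DSYN", "B2.2.1.2.1", "Disease or Syndrome", True),
    SemanticType("NEOP", "B2.2.1.2.1.2", "Neoplastic Process", True),
    SemanticType("MOBD", "B2.2.1.2.1.1", "Mental or Behavioral Dysfunction", True),
    SemanticType("PATF", "B2.2.1.2", "Pathologic Function", True),
    SemanticType("SOSY", "A2.2.2", "Sign or Symptom", True),
    SemanticType("ORGF", "A2.2.1", "Organism Function", True),
    SemanticType("PHYF", "A2.2", "Physiologic Function", True),
    SemanticType("PHSU", "A1.4.1.1.1", "Pharmacologic Substance", False),
    SemanticType("ANTB", "A1.4.1.1.1.1", "Antibiotic", False),
    SemanticType("ORCH", "A1.4.1.2.1", "Organic Chemical", False),
)


def default_scheme() -> SemanticTypeScheme:
    return SemanticTypeScheme(DEFAULT_SEMANTIC_TYPES)


# --- drug-name match lexicons --------------------------------------------
# Trailing tokens that signal a salt / derivative / formulation (raw name =
# base name + token -> narrower-term match) ...
DEFAULT_SALT_TOKENS = frozenset(
    {
        "hydrochloride",
        "fumarate",
        "sodium",
        "sulfate",
        "maleate",
        "tartrate",
        "acetate",
        "mesylate",
        "besylate",
        "hydrate",
        "dihydrate",
    }
)

# ... and modifiers that leave the chemical identity essentially unchanged
# (quasi-synonym match).
DEFAULT_QUASI_TOKENS = frozenset({"anhydrous", "monohydrate", "racemic"})

# --- pair-source relation filtering --------------------------------------
DEFAULT_RELATION_ALLOWLIST = frozenset(
    {"may_treat", "may_prevent", "may_diagnose", "therapeutic", "has_role"}
)
DEFAULT_ROLE_BLOCKLIST = frozenset({"metabolite", "prodrug", "epitope"})

# --- combination / ill-formed drug-name detection -------------------------
DEFAULT_COMBINATION_TOKENS = (" and ", "/", "+", ", combinations", " with ")

# --- indication subtypes --------------------------------------------------
# (kind, surface, leaf) triples; see didkit.subtypes for matching semantics.
DEFAULT_CUE_ROWS = (
    ("KEYWORD", "treatment", "treatment"),
    ("KEYWORD", "treating", "treating"),
    ("KEYWORD", "treats", "treats"),
    ("KEYWORD", "treat", "treat"),
    ("KEYWORD", "prevention", "prevention"),
    ("KEYWORD", "preventing", "preventing"),
    ("KEYWORD", "prevents", "prevents"),
    ("KEYWORD", "prevent", "prevent"),
    ("KEYWORD", "management", "management"),
    ("KEYWORD", "managing", "managing"),
    ("KEYWORD", "manage", "manage"),
    ("KEYWORD", "diagnosis", "diagnosis"),
    ("KEYWORD", "diagnose", "diagnose"),
    ("KEYWORD", "inhibitor", "inhibitor"),
    ("KEYWORD", "inhibitors", "inhibitors"),
    ("KEYWORD", "inhibition", "inhibition"),
    ("KEYWORD", "inhibit", "inhibit"),
    ("PREFIX", "anti", "anti"),
    ("SUFFIX", "lytic", "lytic"),
    ("HEAD_NOUN", "agonist", "agonist"),
    ("HEAD_NOUN", "agonists", "agonists"),
    ("HEAD_NOUN", "activator", "activator"),
    ("HEAD_NOUN", "activators", "activators"),
    ("HEAD_NOUN", "adjunct", "adjunct"),
    ("HEAD_NOUN", "carcinogen", "carcinogen"),
    ("HEAD_NOUN", "carcinogens", "carcinogens"),
)

# leaf -> (lexical root, polarity). Polarity is a function of the root:
# therapy-directed roots are NEGATIVE (inhibitory with respect to the
# indication), causative roots POSITIVE, undecidable ones UNKNOWN.
DEFAULT_ROLLUP_ROWS = (
    ("treatment", "treat", "NEGATIVE"),
    ("treating", "treat", "NEGATIVE"),
    ("treats", "treat", "NEGATIVE"),
    ("treat", "treat", "NEGATIVE"),
    ("prevention", "prevent", "NEGATIVE"),
    ("preventing", "prevent", "NEGATIVE"),
    ("prevents", "prevent", "NEGATIVE"),
    ("prevent", "prevent", "NEGATIVE"),
    ("management", "manage", "NEGATIVE"),
    ("managing", "manage", "NEGATIVE"),
    ("manage", "manage", "NEGATIVE"),
    ("diagnosis", "diagnose", "UNKNOWN"),
    ("diagnose", "diagnose", "UNKNOWN"),
    ("inhibitor", "inhibit", "NEGATIVE"),
    ("inhibitors", "inhibit", "NEGATIVE"),
    ("inhibition", "inhibit", "NEGATIVE"),
    ("inhibit", "inhibit", "NEGATIVE"),
    ("anti", "anti", "NEGATIVE"),
    ("lytic", "lytic", "NEGATIVE"),
    ("agonist", "agonist", "POSITIVE"),
    ("agonists", "agonist", "POSITIVE"),
    ("activator", "activator", "POSITIVE"),
    ("activators", "activator", "POSITIVE"),
    ("adjunct", "adjunct", "UNKNOWN"),
    ("carcinogen", "carcinogen", "POSITIVE"),
    ("carcinogens", "carcinogen", "POSITIVE"),
)
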