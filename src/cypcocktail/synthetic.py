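"""Packaged fixtures and deterministic random generators.

Ships the reference ALL (acute lymphoblastic leukemia) treatment knowledge
base — every drug, role assignment, extrarenal fraction (Q0) and
elimination half-life (EHL) of the published before/after regimen tables —
plus seeded generators for random knowledge bases, regimens and abstract
corpora with planted drug–CYP relations, so every module is testable
without network access.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import ValidationError
from .kb import (
    DrugRecord,
    InteractionRecord,
    KnowledgeBase,
    Purpose,
    Regimen,
    RegimenEntry,
    Role,
    normalize_enzyme_name,
)
from .textmine import AbstractRecord, Lexicons, lexicons_from_kb

__all__ = [
    "GeneratorConfig",
    "PlantedRelation",
    "fixture_tables_kb",
    "fixture_regimen_initial",
    "fixture_regimen_optimized",
    "fixture_lexicons",
    "generate_kb",
    "generate_regimen",
    "generate_corpus",
]

# ---------------------------------------------------------------------------
# Reference ALL-treatment knowledge base.
#
# Row layout: name, synonyms, ATC codes (public WHO index), purpose, Q0,
# EHL [h], prodrug, substrates-of, inducers-of, inhibitors-of.
# "L-Asparagine" is recorded as a synonym of L-asparaginase (a typo in the
# source table); HDMTX is high-dose methotrexate.
# Cyclophosphamide and trofosfamide are oxazaphosphorine prodrugs requiring
# CYP activation.
_FIXTURE_ROWS = [
    (
        "Cyclophosphamide",
        {"CPM", "cytophosphane"},
        {"L01AA01"},
        Purpose.ANTINEOPLASTIC,
        0.75,
        7.0,
        True,
        ["2A6", "2B6", "2C8", "2C9", "2C18", "2C19", "3A4", "3A5"],
        ["2B6", "2C8", "2C9", "3A4"],
        ["3A4"],
    ),
    (
        "Cytarabine",
        {"cytosine arabinoside", "ara-C"},
        {"L01BC01"},
        Purpose.ANTINEOPLASTIC,
        0.9,
        2.0,
        False,
        ["3A4"],
        [],
        [],
    ),
    (
        "Dexamethasone",
        set(),
        {"H02AB02"},
        Purpose.CORTICOSTEROID,
        0.9,
        3.0,
        False,
        ["3A4"],
        [
            "1A1",
            "1A2",
            "2B6",
            "2C8",
            "2C9",
            "2C18",
            "2C19",
            "2D6",
            "3A4",
            "3A5",
            "3A7",
            "3A43",
            "4A11",
            "UGT",
            "27A",
        ],
        ["3A4", "11A", "11B1", "17A"],
    ),
    (
        "Vincristine",
        {"leurocristine"},
        {"L01CA02"},
        Purpose.ANTINEOPLASTIC,
        0.8,
        85.0,
        False,
        ["3A4", "3A5", "3A7"],
        [],
        ["3A4"],
    ),
    (
        "HDMTX",
        {"HdMTX", "methotrexate", "high-dose methotrexate"},
        {"L01BA01"},
        Purpose.ANTINEOPLASTIC,
        None,
        None,
        False,
        [],
        [],
        [],
    ),
    (
        "L-asparaginase",
        {"L-Asparaginase", "L-Asparagine", "asparaginase"},
        {"L01XX02"},
        Purpose.ANTINEOPLASTIC,
        None,
        None,
        False,
        [],
        [],
        [],
    ),
    (
        "Gemcitabine",
        set(),
        {"L01BC05"},
        Purpose.ANTINEOPLASTIC,
        0.9,
        1.2,
        False,
        [],
        [],
        [],
    ),
    (
        "Prednisolone",
        set(),
        {"H02AB06"},
        Purpose.CORTICOSTEROID,
        0.7,
        3.0,
        False,
        ["3A4", "3A5"],
        ["3A4", "3A5"],
        ["2A6"],
    ),
    (
        "Trofosfamide",
        set(),
        {"L01AA07"},
        Purpose.ANTINEOPLASTIC,
        0.9,
        1.0,
        True,
        ["2B6", "3A4"],
        [],
        [],
    ),
    (
        "Vindesine",
        set(),
        {"L01CA03"},
        Purpose.ANTINEOPLASTIC,
        0.87,
        24.0,
        False,
        ["3A4"],
        [],
        [],
    ),
]


def fixture_tables_kb() -> KnowledgeBase:
    """The packaged ALL-treatment knowledge base (10 drugs, 46 triples)."""
    kb = KnowledgeBase()
    for name, syn, atc, purpose, q0, ehl, prodrug, subs, inds, inhs in _FIXTURE_ROWS:
        kb.add_drug(
            DrugRecord(
                name=name,
                synonyms=frozenset(syn),
                atc_codes=frozenset(atc),
                purpose=purpose,
                q0=q0,
                ehl_hours=ehl,
                prodrug=prodrug,
            )
        )
        for role, enzymes in (
            (Role.SUBSTRATE, subs),
            (Role.INDUCER, inds),
            (Role.INHIBITOR, inhs),
        ):
            for enzyme in enzymes:
                kb.add_interaction(
                    InteractionRecord(name, normalize_enzyme_name(enzyme), role)
                )
    return kb


def fixture_regimen_initial() -> Regimen:
    """The ALL regimen before optimization (six drugs, initial diagnosis)."""
    return Regimen(
        [
            RegimenEntry("Cyclophosphamide", "antineoplastic"),
            RegimenEntry("Cytarabine", "antineoplastic"),
            RegimenEntry("Dexamethasone", "corticosteroid"),
            RegimenEntry("Vincristine", "antineoplastic"),
            RegimenEntry("HDMTX", "antineoplastic"),
            RegimenEntry("L-asparaginase", "antineoplastic"),
        ]
    )


def fixture_regimen_optimized() -> Regimen:
    """The published alternative ALL regimen (after substitution)."""
    return Regimen(
        [
            RegimenEntry("Gemcitabine", "antineoplastic"),
            RegimenEntry("Prednisolone", "corticosteroid"),
            RegimenEntry("Trofosfamide", "antineoplastic"),
            RegimenEntry("Vindesine", "antineoplastic"),
            RegimenEntry("HDMTX", "antineoplastic"),
            RegimenEntry("L-asparaginase", "antineoplastic"),
        ]
    )


def fixture_lexicons() -> Lexicons:
    """Mining lexicons derived from the packaged knowledge base."""
    return lexicons_from_kb(fixture_tables_kb())


# ---------------------------------------------------------------------------
# random generators


@dataclass(frozen=True)
class GeneratorConfig:
    """Dimensions and rates of the random generators.

    Identical config + seed always produce identical output.  Role
    probabilities are independent Bernoulli rates per (drug, enzyme, role);
    defaults give a triple density comparable to the packaged fixture.
    ``planted_rate`` is the fraction of generated abstracts carrying exactly
    one planted relation; ``distractor_rate`` the per-abstract chance of a
    drug/enzyme co-occurrence sentence without an interaction term.
    """

    seed: int = 0
    n_drugs: int = 12
    n_enzymes: int = 8
    n_abstracts: int = 100
    p_substrate: float = 0.15
    p_inducer: float = 0.05
    p_inhibitor: float = 0.05
    planted_rate: float = 0.4
    distractor_rate: float = 0.3
    synonyms_per_entity: int = 2

    def __post_init__(self) -> None:
        for attr in ("p_substrate", "p_inducer", "p_inhibitor", "planted_rate", "distractor_rate"):
            value = getattr(self, attr)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{attr}={value} outside [0, 1]")
        if self.n_drugs < 0 or self.n_enzymes <= 0 or self.n_abstracts <= 0:
            raise ValidationError("counts must be positive (n_drugs may be 0)")
        if self.synonyms_per_entity < 0:
            raise ValidationError("synonyms_per_entity must be non-negative")


def _enzyme_pool() -> list[str]:
    return [
        f"CYP{family}{sub}{iso}"
        for family in (1, 2, 3, 4)
        for sub in "ABCD"
        for iso in range(1, 21)
    ]


def generate_kb(config: GeneratorConfig) -> KnowledgeBase:
    """Random knowledge base with the configured dimensions and role rates.

    Drugs are grouped pairwise into shared level-4 ATC subgroups (so the
    optimizer always has candidate pools), with purpose assigned per group.
    """
    rng = random.Random(config.seed)
    enzymes = [
        normalize_enzyme_name(e)
        for e in rng.sample(_enzyme_pool(), config.n_enzymes)
    ]
    kb = KnowledgeBase()
    purposes = (Purpose.ANTINEOPLASTIC, Purpose.CORTICOSTEROID, Purpose.SUPPORTIVE)
    for i in range(config.n_drugs):
        group = i // 2
        prefix = f"L{group % 100:02d}{chr(65 + (group // 100) % 26)}A"
        purpose = purposes[group % len(purposes)]
        q0 = round(rng.random(), 2) if rng.random() > 0.15 else None
        ehl = round(rng.uniform(0.5, 96.0), 1) if rng.random() > 0.15 else None
        kb.add_drug(
            DrugRecord(
                name=f"drug{i:03d}",
                synonyms=frozenset(
                    f"drug{i:03d}syn{j}" for j in range(config.synonyms_per_entity)
                ),
                atc_codes=frozenset({f"{prefix}{i % 100:02d}"}),
                purpose=purpose,
                q0=q0,
                ehl_hours=ehl,
                prodrug=rng.random() < 0.15,
            )
        )
    role_probs = (
        (Role.SUBSTRATE, config.p_substrate),
        (Role.INDUCER, config.p_inducer),
        (Role.INHIBITOR, config.p_inhibitor),
    )
    for i in range(config.n_drugs):
        for enzyme in enzymes:
            for role, p in role_probs:
                if rng.random() < p:
                    pmids = (
                        frozenset({str(rng.randrange(10_000_000, 40_000_000))})
                        if rng.random() < 0.5
                        else frozenset()
                    )
                    kb.add_interaction(
                        InteractionRecord(f"drug{i:03d}", enzyme, role, pmids)
                    )
    return kb


def generate_regimen(kb: KnowledgeBase, n_drugs: int, seed: int) -> Regimen:
    """Random regimen drawn without replacement from the KB's drugs."""
    rng = random.Random(seed)
    names = [d.name for d in kb.drugs]
    chosen = rng.sample(names, min(n_drugs, len(names)))
    return Regimen(
        [RegimenEntry(n, kb.lookup_drug(n).purpose.value) for n in chosen]
    )


@dataclass(frozen=True)
class PlantedRelation:
    pmid: str
    drug: str
    enzyme: str
    role: Role


#: templates per planted role; the verbs are in the default term lexicon
_TEMPLATES = {
    Role.SUBSTRATE: "{drug} is metabolized by {cyp} in human liver microsomes.",
    Role.INDUCER: "{drug} markedly induces {cyp} in cultured hepatocytes.",
    Role.INHIBITOR: "{drug} potently inhibits {cyp} at clinical concentrations.",
}

#: neutral filler placed between content sentences; 40 tokens, none of which
#: appear in any lexicon, so cross-sentence mention pairs always exceed the
#: default scoring distance cutoff
_FILLER = (
    "The longitudinal cohort was monitored across repeated clinical visits "
    "while baseline covariates, laboratory panels and demographic factors "
    "were recorded, and additional follow up assessments captured adherence, "
    "tolerability, vital signs, imaging findings, questionnaire responses "
    "and routine safety outcomes throughout the observation period overall."
)

_DISTRACTOR = "Plasma levels of {drug} and {cyp} expression were measured."


def generate_corpus(
    kb: KnowledgeBase, config: GeneratorConfig
) -> tuple[list[AbstractRecord], list[PlantedRelation]]:
    """Template-generated abstract corpus with planted drug–CYP relations.

    Exactly ``round(planted_rate * n_abstracts)`` abstracts carry one
    planted relation each (drug synonym, interaction verb, enzyme synonym in
    a single sentence); distractor sentences co-mention a drug and an
    enzyme without any interaction term.  Content sentences are separated
    by neutral filler longer than the default scoring distance cutoff.
    Returns the records and the exact ground truth of planted relations.
    """
    if not kb.drugs:
        raise ValidationError("corpus generation needs a non-empty knowledge base")
    rng = random.Random(config.seed)
    drug_records = list(kb.drugs)
    enzyme_names = [e.name for e in kb.enzymes()] or ["CYP3A4"]
    roles = (Role.SUBSTRATE, Role.INDUCER, Role.INHIBITOR)

    n_planted = round(config.planted_rate * config.n_abstracts)
    planted_flags = [i < n_planted for i in range(config.n_abstracts)]
    rng.shuffle(planted_flags)

    records: list[AbstractRecord] = []
    truth: list[PlantedRelation] = []
    for i, plant in enumerate(planted_flags):
        pmid = str(90_000_000 + i)
        sentences: list[str] = []
        if plant:
            drug = rng.choice(drug_records)
            mention = rng.choice(sorted({drug.name, *drug.synonyms}))
            enzyme = rng.choice(enzyme_names)
            role = rng.choice(roles)
            sentences.append(_TEMPLATES[role].format(drug=mention, cyp=enzyme))
            truth.append(PlantedRelation(pmid, drug.name, enzyme, role))
        if rng.random() < config.distractor_rate:
            d = rng.choice(drug_records)
            mention = rng.choice(sorted({d.name, *d.synonyms}))
            enzyme = rng.choice(enzyme_names)
            if sentences:
                sentences.append(_FILLER)
            sentences.append(_DISTRACTOR.format(drug=mention, cyp=enzyme))
        if not sentences:
            sentences.append(_FILLER)
        records.append(
            AbstractRecord(
                pmid=pmid,
                title=f"Observational pharmacology report {i:04d}.",
                abstract=" ".join(sentences),
            )
        )
    return records, truth
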