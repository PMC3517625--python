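"""Drug–CYP knowledge base: domain types, validation and flat-file I/O.

The knowledge base holds drug records (pharmacokinetic parameters, ATC codes,
synonyms, prodrug flags) and (drug, enzyme, role) interaction assertions with
literature provenance.  Two equivalent on-disk dialects are supported: a
two-section tab-separated file and a single YAML document.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import yaml

from .errors import (
    DrugNotFoundError,
    DuplicateRecordError,
    ParseError,
    ReferentialIntegrityError,
    ValidationError,
)

__all__ = [
    "EnzymeID",
    "Role",
    "Modulation",
    "Purpose",
    "DrugRecord",
    "InteractionRecord",
    "KnowledgeBase",
    "Regimen",
    "RegimenEntry",
    "normalize_enzyme_name",
    "load_knowledge_base",
    "write_knowledge_base",
    "load_regimen",
    "write_regimen",
    "lookup_drug",
    "atc_group_members",
]

# CYP isoform names follow family digits + subfamily letter + isoform digits
# (e.g. 3A4, 2C19, 3A43); an optional "CYP" prefix with whitespace/hyphen is
# tolerated on input.  Anything else (UGT, 11A, 17A, 27A ...) is kept verbatim.
_P450_RE = re.compile(r"^(?:CYP[\s\-]?)?(\d{1,2})([A-Za-z])(\d{1,2})$", re.IGNORECASE)
_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: prefix length of an ATC code at each classification level
ATC_LEVEL_LENGTHS = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


@dataclass(frozen=True)
class EnzymeID:
    """A normalized metabolic enzyme identifier.

    ``is_p450`` distinguishes cytochrome P450 isoforms from other entries
    (e.g. UGT conjugating enzymes) that appear in the same role columns but
    are excluded from CYP-focused metrics by default.
    """

    name: str
    is_p450: bool = True

    def __str__(self) -> str:
        return self.name


def normalize_enzyme_name(raw: str) -> EnzymeID:
    """Canonicalize an enzyme token.

    ``"3A4"``, ``"cyp3a4"`` and ``"CYP 3A4"`` all normalize to ``CYP3A4``
    with ``is_p450=True``; tokens that do not match the P450 isoform pattern
    are upper-cased and kept verbatim with ``is_p450=False``.
    """
    token = raw.strip()
    if not token:
        raise ValidationError("enzyme name is empty")
    m = _P450_RE.match(token)
    if m:
        family, sub, iso = m.groups()
        return EnzymeID(f"CYP{int(family)}{sub.upper()}{int(iso)}", is_p450=True)
    return EnzymeID(token.upper(), is_p450=False)


class Role(Enum):
    """Relation of a drug to an enzyme (paper-style codes S/E/I accepted)."""

    SUBSTRATE = "substrate"
    INDUCER = "inducer"
    INHIBITOR = "inhibitor"

    @classmethod
    def parse(cls, code: str) -> "Role":
        key = code.strip().lower()
        mapping = {
            "s": cls.SUBSTRATE,
            "substrate": cls.SUBSTRATE,
            "e": cls.INDUCER,
            "inducer": cls.INDUCER,
            "i": cls.INHIBITOR,
            "inhibitor": cls.INHIBITOR,
        }
        try:
            return mapping[key]
        except KeyError:
            raise ValidationError(f"unknown role code {code!r}") from None


class Modulation(Enum):
    """Direction of a perpetrator's effect on an enzyme."""

    INDUCTION = "induction"
    INHIBITION = "inhibition"


class Purpose(Enum):
    """Therapeutic purpose of a drug within a regimen."""

    ANTINEOPLASTIC = "antineoplastic"
    CORTICOSTEROID = "corticosteroid"
    SUPPORTIVE = "supportive"

    @classmethod
    def parse(cls, text: str) -> "Purpose":
        key = text.strip().lower()
        mapping = {
            "antineoplastic": cls.ANTINEOPLASTIC,
            "antineoplastic agent": cls.ANTINEOPLASTIC,
            "corticosteroid": cls.CORTICOSTEROID,
            "supportive": cls.SUPPORTIVE,
            "supportive treatment": cls.SUPPORTIVE,
        }
        try:
            return mapping[key]
        except KeyError:
            raise ValidationError(f"unknown purpose {text!r}") from None


@dataclass(frozen=True)
class DrugRecord:
    """One drug: identity, classification and pharmacokinetic parameters.

    ``q0`` is the extrarenal fraction (fraction eliminated by routes other
    than unchanged renal excretion, in [0, 1]); ``ehl_hours`` the elimination
    half-life.  Both may be missing and are never imputed.
    """

    name: str
    synonyms: frozenset[str] = frozenset()
    atc_codes: frozenset[str] = frozenset()
    purpose: Purpose = Purpose.ANTINEOPLASTIC
    q0: float | None = None
    ehl_hours: float | None = None
    prodrug: bool = False

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValidationError("drug name is empty")
        if self.q0 is not None and not 0.0 <= self.q0 <= 1.0:
            raise ValidationError(f"{self.name}: q0={self.q0} outside [0, 1]")
        if self.ehl_hours is not None and self.ehl_hours <= 0:
            raise ValidationError(f"{self.name}: ehl_hours={self.ehl_hours} not positive")
        for code in self.atc_codes:
            if not _ATC_RE.match(code):
                raise ValidationError(f"{self.name}: malformed ATC code {code!r}")


@dataclass(frozen=True)
class InteractionRecord:
    """One (drug, enzyme, role) assertion with optional PubMed provenance."""

    drug: str
    enzyme: EnzymeID
    role: Role
    pmids: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.drug.lower(), self.enzyme.name, self.role.value)


class KnowledgeBase:
    """Validated collection of drug records and interaction triples.

    Drug names are unique (case-insensitively); synonyms resolve
    case-insensitively to their canonical record; (drug, enzyme, role)
    triples are unique and referentially tied to a drug record.
    """

    def __init__(
        self,
        drugs: Iterable[DrugRecord] = (),
        interactions: Iterable[InteractionRecord] = (),
    ) -> None:
        self._drugs: dict[str, DrugRecord] = {}  # lower canonical -> record
        self._aliases: dict[str, str] = {}  # lower alias -> canonical name
        self._triples: dict[tuple[str, str, str], InteractionRecord] = {}
        for d in drugs:
            self.add_drug(d)
        for r in interactions:
            self.add_interaction(r)

    # -- construction -----------------------------------------------------
    def add_drug(self, record: DrugRecord) -> None:
        key = record.name.lower()
        if key in self._drugs:
            raise DuplicateRecordError(f"duplicate drug record {record.name!r}")
        for alias in {key, *(s.lower() for s in record.synonyms)}:
            owner = self._aliases.get(alias)
            if owner is not None and owner.lower() != key:
                raise ValidationError(
                    f"synonym {alias!r} of {record.name!r} already maps to {owner!r}"
                )
        self._drugs[key] = record
        self._aliases[key] = record.name
        for s in record.synonyms:
            self._aliases[s.lower()] = record.name

    def add_interaction(self, record: InteractionRecord) -> None:
        canonical = self._aliases.get(record.drug.lower())
        if canonical is None:
            raise ReferentialIntegrityError(
                f"interaction references unknown drug {record.drug!r}"
            )
        if canonical != record.drug:
            record = InteractionRecord(canonical, record.enzyme, record.role, record.pmids)
        if record.key in self._triples:
            raise DuplicateRecordError(
                f"duplicate interaction triple ({record.drug}, {record.enzyme}, "
                f"{record.role.value})"
            )
        self._triples[record.key] = record

    # -- access -----------------------------------------------------------
    @property
    def drugs(self) -> tuple[DrugRecord, ...]:
        return tuple(sorted(self._drugs.values(), key=lambda d: d.name.lower()))

    @property
    def interactions(self) -> tuple[InteractionRecord, ...]:
        return tuple(sorted(self._triples.values(), key=lambda r: r.key))

    def lookup_drug(self, query: str) -> DrugRecord:
        """Resolve ``query`` (canonical name or synonym, case-insensitive)."""
        canonical = self._aliases.get(query.strip().lower())
        if canonical is None:
            near = difflib.get_close_matches(
                query.lower(), sorted(self._aliases), n=3, cutoff=0.6
            )
            suggestions = tuple(dict.fromkeys(self._aliases[a] for a in near))
            raise DrugNotFoundError(query, suggestions)
        return self._drugs[canonical.lower()]

    def canonical_name(self, query: str) -> str:
        return self.lookup_drug(query).name

    def __contains__(self, query: object) -> bool:
        return isinstance(query, str) and query.strip().lower() in self._aliases

    def interactions_for(
        self,
        drug: str | None = None,
        enzyme: EnzymeID | None = None,
        role: Role | None = None,
    ) -> tuple[InteractionRecord, ...]:
        canonical = self.canonical_name(drug).lower() if drug is not None else None
        return tuple(
            r
            for r in self.interactions
            if (canonical is None or r.drug.lower() == canonical)
            and (enzyme is None or r.enzyme == enzyme)
            and (role is None or r.role == role)
        )

    def enzymes(self, p450_only: bool = False) -> tuple[EnzymeID, ...]:
        seen = {r.enzyme for r in self._triples.values()}
        if p450_only:
            seen = {e for e in seen if e.is_p450}
        return tuple(sorted(seen, key=lambda e: e.name))

    def atc_group_members(self, atc_prefix: str, level: int = 4) -> set[str]:
        """All drugs with at least one ATC code under ``atc_prefix``.

        The prefix length must match the requested classification level
        (level 4 = chemical subgroup = 5 characters).
        """
        if level not in ATC_LEVEL_LENGTHS:
            raise ValidationError(f"ATC level must be 1..5, got {level}")
        expected = ATC_LEVEL_LENGTHS[level]
        prefix = atc_prefix.strip().upper()
        if len(prefix) != expected:
            raise ValidationError(
                f"ATC prefix {atc_prefix!r} has length {len(prefix)}, "
                f"level {level} requires {expected}"
            )
        template = "LDDLLDD"  # letter/digit template of a full ATC code
        for ch, kind in zip(prefix, template):
            if (kind == "L") != ch.isalpha():
                raise ValidationError(f"malformed ATC prefix {atc_prefix!r}")
        return {
            d.name
            for d in self._drugs.values()
            if any(code.startswith(prefix) for code in d.atc_codes)
        }

    # -- comparison -------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return set(self.drugs) == set(other.drugs) and set(self.interactions) == set(
            other.interactions
        )

    def __repr__(self) -> str:
        return (
            f"KnowledgeBase({len(self._drugs)} drugs, "
            f"{len(self._triples)} interactions)"
        )


# -- regimens --------------------------------------------------------------


@dataclass(frozen=True)
class RegimenEntry:
    drug: str
    purpose: str = ""
    locked: bool = False


@dataclass
class Regimen:
    """Ordered list of co-administered drugs with purpose tags and lock flags."""

    entries: list[RegimenEntry] = field(default_factory=list)

    @classmethod
    def from_names(cls, names: Iterable[str], purpose: str = "") -> "Regimen":
        return cls([RegimenEntry(n, purpose) for n in names])

    def drug_names(self) -> list[str]:
        return [e.drug for e in self.entries]

    def with_swap(self, original: str, alternative: str) -> "Regimen":
        """Copy of the regimen with ``original`` replaced by ``alternative``
        (purpose tag and lock flag carried over)."""
        out = []
        for e in self.entries:
            if e.drug.lower() == original.lower():
                out.append(RegimenEntry(alternative, e.purpose, e.locked))
            else:
                out.append(e)
        return Regimen(out)

    def __iter__(self) -> Iterator[RegimenEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# -- file I/O ---------------------------------------------------------------

_DRUG_COLUMNS = ["name", "synonyms", "atc_codes", "purpose", "q0", "ehl_hours", "prodrug"]
_INTERACTION_COLUMNS = ["drug", "enzyme", "role", "pmids"]


def _fmt_opt(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def _parse_opt(text: str, line: int) -> float | None:
    text = text.strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"not a number: {text!r}", line) from None


def _split_set(text: str) -> frozenset[str]:
    return frozenset(p for p in (s.strip() for s in text.split("|")) if p)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"tsv", "yaml"}:
            raise ValidationError(f"unknown knowledge-base format {fmt!r}")
        return fmt
    if path.suffix.lower() in {".yaml", ".yml"}:
        return "yaml"
    return "tsv"


def write_knowledge_base(kb: KnowledgeBase, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if _infer_format(path, fmt) == "yaml":
        doc = {
            "drugs": [
                {
                    "name": d.name,
                    "synonyms": sorted(d.synonyms),
                    "atc_codes": sorted(d.atc_codes),
                    "purpose": d.purpose.value,
                    "q0": d.q0,
                    "ehl_hours": d.ehl_hours,
                    "prodrug": d.prodrug,
                }
                for d in kb.drugs
            ],
            "interactions": [
                {
                    "drug": r.drug,
                    "enzyme": r.enzyme.name,
                    "role": r.role.value,
                    "pmids": sorted(r.pmids),
                }
                for r in kb.interactions
            ],
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
        return
    lines = ["#drugs", "\t".join(_DRUG_COLUMNS)]
    for d in kb.drugs:
        lines.append(
            "\t".join(
                [
                    d.name,
                    "|".join(sorted(d.synonyms)),
                    "|".join(sorted(d.atc_codes)),
                    d.purpose.value,
                    _fmt_opt(d.q0),
                    _fmt_opt(d.ehl_hours),
                    "true" if d.prodrug else "false",
                ]
            )
        )
    lines.append("#interactions")
    lines.append("\t".join(_INTERACTION_COLUMNS))
    for r in kb.interactions:
        lines.append("\t".join([r.drug, r.enzyme.name, r.role.value, "|".join(sorted(r.pmids))]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_knowledge_base(path: str | Path, fmt: str | None = None) -> KnowledgeBase:
    """Load and validate a knowledge base from TSV or YAML.

    Raises :class:`ParseError` for malformed content (with line numbers for
    the TSV dialect), :class:`ReferentialIntegrityError` for dangling drug
    references and :class:`DuplicateRecordError` for repeated triples.
    """
    path = Path(path)
    if _infer_format(path, fmt) == "yaml":
        doc = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        kb = KnowledgeBase()
        for row in doc.get("drugs", []):
            kb.add_drug(
                DrugRecord(
                    name=row["name"],
                    synonyms=frozenset(row.get("synonyms", [])),
                    atc_codes=frozenset(row.get("atc_codes", [])),
                    purpose=Purpose.parse(row.get("purpose", "antineoplastic")),
                    q0=row.get("q0"),
                    ehl_hours=row.get("ehl_hours"),
                    prodrug=bool(row.get("prodrug", False)),
                )
            )
        for row in doc.get("interactions", []):
            kb.add_interaction(
                InteractionRecord(
                    drug=row["drug"],
                    enzyme=normalize_enzyme_name(row["enzyme"]),
                    role=Role.parse(row["role"]),
                    pmids=frozenset(str(p) for p in row.get("pmids", [])),
                )
            )
        return kb

    kb = KnowledgeBase()
    section: str | None = None
    header_seen = False
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            marker = line.strip().lower()
            if marker not in {"#drugs", "#interactions"}:
                raise ParseError(f"unknown section marker {line.strip()!r}", lineno)
            section = marker[1:]
            header_seen = False
            continue
        if section is None:
            raise ParseError("content before a #drugs/#interactions section", lineno)
        if not header_seen:
            header_seen = True  # header row carries column names; order is fixed
            continue
        fields = line.split("\t")
        if section == "drugs":
            if len(fields) != len(_DRUG_COLUMNS):
                raise ParseError(
                    f"expected {len(_DRUG_COLUMNS)} drug columns, got {len(fields)}", lineno
                )
            name, syn, atc, purpose, q0, ehl, prodrug = fields
            try:
                record = DrugRecord(
                    name=name.strip(),
                    synonyms=_split_set(syn),
                    atc_codes=_split_set(atc),
                    purpose=Purpose.parse(purpose),
                    q0=_parse_opt(q0, lineno),
                    ehl_hours=_parse_opt(ehl, lineno),
                    prodrug=prodrug.strip().lower() in {"true", "1", "yes"},
                )
            except ValidationError as exc:
                raise ParseError(str(exc), lineno) from exc
            kb.add_drug(record)
        else:
            if len(fields) != len(_INTERACTION_COLUMNS):
                raise ParseError(
                    f"expected {len(_INTERACTION_COLUMNS)} interaction columns, "
                    f"got {len(fields)}",
                    lineno,
                )
            drug, enzyme, role, pmids = fields
            try:
                parsed_role = Role.parse(role)
            except ValidationError as exc:
                raise ParseError(str(exc), lineno) from exc
            kb.add_interaction(
                InteractionRecord(
                    drug=drug.strip(),
                    enzyme=normalize_enzyme_name(enzyme),
                    role=parsed_role,
                    pmids=_split_set(pmids),
                )
            )
    return kb


def write_regimen(regimen: Regimen, path: str | Path) -> None:
    lines = ["drug\tpurpose\tlocked"]
    for e in regimen.entries:
        lines.append(f"{e.drug}\t{e.purpose}\t{'true' if e.locked else 'false'}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_regimen(path: str | Path) -> Regimen:
    entries = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if lineno == 1 and line.split("\t")[0].strip().lower() == "drug":
            continue
        fields = line.split("\t")
        if not 1 <= len(fields) <= 3:
            raise ParseError(f"expected 1..3 regimen columns, got {len(fields)}", lineno)
        drug = fields[0].strip()
        purpose = fields[1].strip() if len(fields) > 1 else ""
        locked = len(fields) > 2 and fields[2].strip().lower() in {"true", "1", "yes"}
        if not drug:
            raise ParseError("empty drug name", lineno)
        entries.append(RegimenEntry(drug, purpose, locked))
    return Regimen(entries)


# -- module-level convenience wrappers -------------------------------------


def lookup_drug(kb: KnowledgeBase, query: str) -> DrugRecord:
    return kb.lookup_drug(query)


def atc_group_members(kb: KnowledgeBase, atc_prefix: str, level: int = 4) -> set[str]:
    return kb.atc_group_members(atc_prefix, level)
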