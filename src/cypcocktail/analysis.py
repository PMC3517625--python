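"""Per-regimen CYP interaction analysis.

Quantifies how a drug cocktail loads the cytochrome P450 system: which
enzymes each drug uses and in what role, which perpetrator→CYP→victim
modulation events exist between distinct drugs, how many distinct CYPs
mediate such events (the headline regimen-comparison metric), Venn-style
enzyme overload partitions, extrarenal-fraction classification and
prodrug-activation warnings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping

from .errors import ValidationError
from .kb import (
    DrugRecord,
    EnzymeID,
    KnowledgeBase,
    Modulation,
    Regimen,
    Role,
)

__all__ = [
    "DDIEdge",
    "RoleSets",
    "UsageMap",
    "VennPartition",
    "Q0Class",
    "ProdrugWarning",
    "OverloadReport",
    "cyp_usage_map",
    "ddi_edges",
    "interaction_cyp_count",
    "venn_partition",
    "q0_class",
    "prodrug_warnings",
    "overload_report",
]

#: perpetrator roles and the modulation they exert on victims
_MODULATING = {Role.INDUCER: Modulation.INDUCTION, Role.INHIBITOR: Modulation.INHIBITION}


@dataclass(frozen=True)
class DDIEdge:
    """A perpetrator→CYP→victim modulation event between distinct drugs.

    The victim is a substrate of the enzyme; the perpetrator induces
    (``modulation=INDUCTION``) or inhibits (``INHIBITION``) the same enzyme.
    """

    perpetrator: str
    enzyme: EnzymeID
    victim: str
    modulation: Modulation

    @property
    def sort_key(self) -> tuple[str, str, str, str]:
        return (self.enzyme.name, self.perpetrator, self.victim, self.modulation.value)


@dataclass
class RoleSets:
    """Regimen drugs using one enzyme, split by role."""

    substrates: set[str] = field(default_factory=set)
    inducers: set[str] = field(default_factory=set)
    inhibitors: set[str] = field(default_factory=set)

    def all_drugs(self) -> set[str]:
        return self.substrates | self.inducers | self.inhibitors

    def by_role(self, role: Role) -> set[str]:
        return {
            Role.SUBSTRATE: self.substrates,
            Role.INDUCER: self.inducers,
            Role.INHIBITOR: self.inhibitors,
        }[role]


UsageMap = dict[EnzymeID, RoleSets]


def _resolve_regimen(
    regimen: Regimen, kb: KnowledgeBase, on_missing: str
) -> list[DrugRecord]:
    """Resolve every regimen drug to its record (deduplicated, order kept)."""
    records: dict[str, DrugRecord] = {}
    for entry in regimen:
        try:
            rec = kb.lookup_drug(entry.drug)
        except KeyError:
            if on_missing == "warn":
                warnings.warn(f"regimen drug {entry.drug!r} not in knowledge base")
                continue
            raise
        records.setdefault(rec.name, rec)
    return list(records.values())


def cyp_usage_map(
    regimen: Regimen,
    kb: KnowledgeBase,
    p450_only: bool = True,
    *,
    on_missing: str = "error",
) -> UsageMap:
    """Project the KB's (drug, enzyme, role) triples onto a regimen.

    Enzymes touched by no regimen drug are absent from the map; with
    ``p450_only`` non-P450 entries (UGT etc.) are excluded.  A drug may
    appear in several role sets of the same enzyme.
    """
    records = _resolve_regimen(regimen, kb, on_missing)
    usage: UsageMap = {}
    for rec in records:
        for triple in kb.interactions_for(drug=rec.name):
            if p450_only and not triple.enzyme.is_p450:
                continue
            usage.setdefault(triple.enzyme, RoleSets()).by_role(triple.role).add(rec.name)
    return usage


def ddi_edges(
    regimen: Regimen,
    kb: KnowledgeBase,
    p450_only: bool = True,
    *,
    include_self: bool = False,
    on_missing: str = "error",
) -> set[DDIEdge]:
    """All perpetrator→enzyme→victim modulation events within the regimen.

    Self-modulation (a drug inducing or inhibiting its own metabolizing
    enzyme, e.g. cyclophosphamide auto-induction) is excluded unless
    ``include_self`` is set.  Induction and inhibition of the same enzyme by
    the same perpetrator are distinct edges.
    """
    usage = cyp_usage_map(regimen, kb, p450_only, on_missing=on_missing)
    edges: set[DDIEdge] = set()
    for enzyme, roles in usage.items():
        for perp_role, modulation in _MODULATING.items():
            for perp in roles.by_role(perp_role):
                for victim in roles.substrates:
                    if victim == perp and not include_self:
                        continue
                    edges.add(DDIEdge(perp, enzyme, victim, modulation))
    return edges


def interaction_cyp_count(
    regimen: Regimen, kb: KnowledgeBase, *, on_missing: str = "error"
) -> int:
    """Number of distinct CYPs mediating at least one cross-drug modulation.

    This is the headline metric used to compare regimens before and after
    optimization (an optimized cocktail ideally leaves few or no enzymes
    with both a victim substrate and a distinct modulating drug).
    """
    return len(
        {e.enzyme for e in ddi_edges(regimen, kb, p450_only=True, on_missing=on_missing)}
    )


@dataclass
class VennPartition:
    """Exclusive-region drug counts for 2–4 enzymes."""

    enzymes: tuple[EnzymeID, ...]
    region_members: dict[frozenset[str], frozenset[str]]

    @property
    def region_counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.region_members.items()}

    def count(self, *enzyme_names: str) -> int:
        return len(self.region_members[frozenset(enzyme_names)])

    def total(self) -> int:
        return sum(len(v) for v in self.region_members.values())


def venn_partition(
    kb: KnowledgeBase,
    enzymes: Iterable[EnzymeID | str],
    *,
    roles: Iterable[Role] = (Role.SUBSTRATE,),
    purpose=None,
) -> VennPartition:
    """Partition KB drugs into exclusive Venn regions over 2–4 enzymes.

    Membership defaults to the substrate role ("metabolized by"); pass other
    ``roles`` to widen it.  ``purpose`` optionally restricts the drugs
    counted (e.g. antineoplastics only).
    """
    from .kb import normalize_enzyme_name

    ids = tuple(
        e if isinstance(e, EnzymeID) else normalize_enzyme_name(e) for e in enzymes
    )
    if not 2 <= len(ids) <= 4:
        raise ValidationError(f"venn_partition needs 2..4 enzymes, got {len(ids)}")
    if len({e.name for e in ids}) != len(ids):
        raise ValidationError("venn_partition enzymes must be distinct")
    role_set = set(roles)
    members: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            members[frozenset(e.name for e in combo)] = set()
    for drug in kb.drugs:
        if purpose is not None and drug.purpose != purpose:
            continue
        touched = frozenset(
            t.enzyme.name
            for t in kb.interactions_for(drug=drug.name)
            if t.enzyme in ids and t.role in role_set
        )
        if touched:
            members[touched].add(drug.name)
    return VennPartition(ids, {k: frozenset(v) for k, v in members.items()})


class Q0Class(Enum):
    """Elimination class from the extrarenal fraction Q0.

    Drugs with Q0 below the threshold (default 0.3) are largely excreted
    unchanged via the kidneys and occupy the CYP system less; drugs at or
    above it are predominantly metabolized.
    """

    RENAL_UNCHANGED = "renal_unchanged"
    METABOLIZED = "metabolized"
    UNKNOWN = "unknown"


def q0_class(drug: DrugRecord, threshold: float = 0.3) -> Q0Class:
    if drug.q0 is None:
        return Q0Class.UNKNOWN
    return Q0Class.RENAL_UNCHANGED if drug.q0 < threshold else Q0Class.METABOLIZED


@dataclass(frozen=True)
class ProdrugWarning:
    """A prodrug whose activating enzyme is inhibited by a co-administered drug."""

    prodrug: str
    enzyme: EnzymeID
    inhibitor: str


def prodrug_warnings(
    regimen: Regimen,
    kb: KnowledgeBase,
    *,
    p450_only: bool = True,
    on_missing: str = "error",
) -> list[ProdrugWarning]:
    """Warnings for inhibited prodrug activation within the regimen.

    One warning per (prodrug P, enzyme E, drug D) where P is flagged as a
    prodrug and substrate of E, and a distinct regimen drug D inhibits E —
    the situation that risks therapy failure through blocked activation.
    """
    records = _resolve_regimen(regimen, kb, on_missing)
    usage = cyp_usage_map(regimen, kb, p450_only, on_missing=on_missing)
    prodrugs = {r.name for r in records if r.prodrug}
    out = []
    for enzyme in sorted(usage, key=lambda e: e.name):
        roles = usage[enzyme]
        for p in sorted(roles.substrates & prodrugs):
            for d in sorted(roles.inhibitors - {p}):
                out.append(ProdrugWarning(p, enzyme, d))
    return out


@dataclass
class OverloadReport:
    """Aggregated, serializable interaction analysis of one regimen."""

    regimen_drugs: list[str]
    enzyme_loads: dict[str, int]  # enzyme -> number of regimen drugs with any role
    shared_enzymes: dict[str, bool]  # load >= 2
    edges: list[DDIEdge]
    interacting_cyp_count: int
    pk_table: list[dict]  # drug, q0, ehl_hours, q0_class
    warnings: list[ProdrugWarning]

    def to_dict(self) -> dict:
        return {
            "regimen_drugs": list(self.regimen_drugs),
            "enzyme_loads": dict(sorted(self.enzyme_loads.items())),
            "shared_enzymes": dict(sorted(self.shared_enzymes.items())),
            "edges": [
                {
                    "perpetrator": e.perpetrator,
                    "enzyme": e.enzyme.name,
                    "victim": e.victim,
                    "modulation": e.modulation.value,
                }
                for e in self.edges
            ],
            "interacting_cyp_count": self.interacting_cyp_count,
            "pk_table": list(self.pk_table),
            "prodrug_warnings": [
                {"prodrug": w.prodrug, "enzyme": w.enzyme.name, "inhibitor": w.inhibitor}
                for w in self.warnings
            ],
        }

    def to_text(self) -> str:
        lines = ["Regimen: " + ", ".join(self.regimen_drugs) or "(empty)"]
        lines.append(f"Interacting CYPs: {self.interacting_cyp_count}")
        lines.append("")
        lines.append("Enzyme load (regimen drugs with any role):")
        for name, load in sorted(self.enzyme_loads.items()):
            flag = "  [shared]" if self.shared_enzymes[name] else ""
            lines.append(f"  {name:<8} {load}{flag}")
        lines.append("")
        lines.append("Cross-drug modulation edges:")
        if not self.edges:
            lines.append("  (none)")
        for e in self.edges:
            lines.append(
                f"  {e.perpetrator} --{e.modulation.value}--> {e.enzyme.name} "
                f"--metabolizes--> {e.victim}"
            )
        lines.append("")
        lines.append("Pharmacokinetics (Q0 = extrarenal fraction, EHL in hours):")
        for row in self.pk_table:
            q0 = "?" if row["q0"] is None else f"{row['q0']:g}"
            ehl = "?" if row["ehl_hours"] is None else f"{row['ehl_hours']:g}"
            lines.append(f"  {row['drug']:<20} Q0={q0:<5} EHL={ehl:<6} {row['q0_class']}")
        if self.warnings:
            lines.append("")
            lines.append("Prodrug activation warnings:")
            for w in self.warnings:
                lines.append(
                    f"  {w.prodrug} is activated via {w.enzyme.name}, "
                    f"inhibited by {w.inhibitor}"
                )
        return "\n".join(lines) + "\n"


def overload_report(
    regimen: Regimen,
    kb: KnowledgeBase,
    *,
    p450_only: bool = True,
    include_self: bool = False,
    on_missing: str = "error",
) -> OverloadReport:
    """One deterministic report aggregating the per-regimen analyses."""
    records = _resolve_regimen(regimen, kb, on_missing)
    usage = cyp_usage_map(regimen, kb, p450_only, on_missing=on_missing)
    edges = sorted(
        ddi_edges(
            regimen, kb, p450_only, include_self=include_self, on_missing=on_missing
        ),
        key=lambda e: e.sort_key,
    )
    loads = {e.name: len(r.all_drugs()) for e, r in usage.items()}
    pk = [
        {
            "drug": r.name,
            "q0": r.q0,
            "ehl_hours": r.ehl_hours,
            "q0_class": q0_class(r).value,
        }
        for r in records
    ]
    return OverloadReport(
        regimen_drugs=[r.name for r in records],
        enzyme_loads=loads,
        shared_enzymes={name: load >= 2 for name, load in loads.items()},
        edges=edges,
        interacting_cyp_count=len(
            {e.enzyme for e in edges if e.enzyme.is_p450 and e.perpetrator != e.victim}
        ),
        pk_table=pk,
        warnings=prodrug_warnings(
            regimen, kb, p450_only=p450_only, on_missing=on_missing
        ),
    )
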