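"""Independent brute-force oracles used to cross-check the implementation.

These deliberately work straight off the raw interaction-triple listing
(and off nothing else), so they share no code path with the analysis,
optimizer or mining modules they verify.
"""

from __future__ import annotations

from itertools import product

from cypcocktail.kb import KnowledgeBase, Regimen, Role


def resolve_names(regimen: Regimen, kb: KnowledgeBase) -> set[str]:
    return {kb.lookup_drug(e.drug).name for e in regimen}


def brute_force_edges(
    regimen: Regimen,
    kb: KnowledgeBase,
    p450_only: bool = True,
    include_self: bool = False,
) -> set[tuple[str, str, str, str]]:
    """Exhaustive (perpetrator, enzyme, victim, modulation) enumeration."""
    names = resolve_names(regimen, kb)
    triples = [
        (t.drug, t.enzyme.name, t.enzyme.is_p450, t.role)
        for t in kb.interactions
        if t.drug in names and (t.enzyme.is_p450 or not p450_only)
    ]
    edges = set()
    modulating = {Role.INDUCER: "induction", Role.INHIBITOR: "inhibition"}
    for (perp, enz_p, _, role_p), (victim, enz_v, _, role_v) in product(triples, triples):
        if role_v is not Role.SUBSTRATE or role_p not in modulating:
            continue
        if enz_p != enz_v:
            continue
        if perp == victim and not include_self:
            continue
        edges.add((perp, enz_p, victim, modulating[role_p]))
    return edges


def brute_force_cyp_count(regimen: Regimen, kb: KnowledgeBase) -> int:
    return len({e[1] for e in brute_force_edges(regimen, kb, p450_only=True)})


def brute_force_usage(
    regimen: Regimen, kb: KnowledgeBase, p450_only: bool = True
) -> dict[tuple[str, str], set[str]]:
    """(enzyme, role-value) -> drug set, by linear triple scan."""
    names = resolve_names(regimen, kb)
    usage: dict[tuple[str, str], set[str]] = {}
    for t in kb.interactions:
        if t.drug in names and (t.enzyme.is_p450 or not p450_only):
            usage.setdefault((t.enzyme.name, t.role.value), set()).add(t.drug)
    return usage


def brute_force_venn(
    kb: KnowledgeBase, enzyme_names: list[str], roles=(Role.SUBSTRATE,)
) -> dict[frozenset, set[str]]:
    members: dict[frozenset, set[str]] = {}
    for d in kb.drugs:
        touched = frozenset(
            t.enzyme.name
            for t in kb.interactions
            if t.drug == d.name and t.enzyme.name in enzyme_names and t.role in set(roles)
        )
        if touched:
            members.setdefault(touched, set()).add(d.name)
    return members


def brute_force_prodrug_warnings(
    regimen: Regimen, kb: KnowledgeBase
) -> set[tuple[str, str, str]]:
    names = resolve_names(regimen, kb)
    prodrugs = {d.name for d in kb.drugs if d.prodrug and d.name in names}
    warnings = set()
    for s in kb.interactions:
        if s.role is not Role.SUBSTRATE or s.drug not in prodrugs or not s.enzyme.is_p450:
            continue
        for i in kb.interactions:
            if (
                i.role is Role.INHIBITOR
                and i.enzyme.name == s.enzyme.name
                and i.drug in names
                and i.drug != s.drug
            ):
                warnings.add((s.drug, s.enzyme.name, i.drug))
    return warnings


def exhaustive_best_metrics(
    regimen: Regimen, kb: KnowledgeBase, atc_level: int = 4
) -> tuple[int, int]:
    """Global optimum (edge count, CYP count) over all per-slot substitutions.

    Every regimen entry may stay or be replaced by any same-purpose drug
    sharing its ATC prefix at ``atc_level``; combinations with duplicate
    drugs are skipped.  Exponential — only for small instances.
    """
    from cypcocktail.kb import ATC_LEVEL_LENGTHS, RegimenEntry

    length = ATC_LEVEL_LENGTHS[atc_level]
    choices = []
    for entry in regimen:
        rec = kb.lookup_drug(entry.drug)
        options = [rec.name]
        if not entry.locked:
            prefixes = {c[:length] for c in rec.atc_codes}
            for other in kb.drugs:
                if other.name == rec.name or other.purpose != rec.purpose:
                    continue
                if any(c[:length] in prefixes for c in other.atc_codes):
                    options.append(other.name)
        choices.append(options)
    best = None
    for combo in product(*choices):
        if len(set(combo)) != len(combo):
            continue
        trial = Regimen([RegimenEntry(n) for n in combo])
        edges = brute_force_edges(trial, kb)
        metrics = (len(edges), len({e[1] for e in edges}))
        if best is None or metrics < best:
            best = metrics
    assert best is not None
    return best
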