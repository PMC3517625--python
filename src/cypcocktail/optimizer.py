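"""ATC-group-constrained regimen optimization.

Greedy single-swap descent: at each step every admissible substitution of a
regimen drug by a same-purpose drug from the same ATC chemical subgroup is
evaluated, and the best strictly-improving one (lexicographic objective:
fewer modulation edges, then fewer distinct interacting CYPs, then lower
elimination half-life, then lower extrarenal fraction, then name) is
applied until no strict improvement remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError
from .kb import DrugRecord, KnowledgeBase, Regimen, RegimenEntry
from .analysis import ddi_edges, interaction_cyp_count, q0_class

__all__ = [
    "SubstitutionProposal",
    "OptimizationStep",
    "OptimizationResult",
    "candidates",
    "substitution_score",
    "optimize_regimen",
]


def candidates(
    drug: DrugRecord | str, kb: KnowledgeBase, atc_level: int = 4
) -> set[DrugRecord]:
    """Same-purpose KB drugs sharing an ATC prefix with ``drug`` at ``atc_level``.

    Drugs without ATC codes have no candidates (empty set, not an error);
    exclusion of drugs already present in a working regimen happens at
    proposal time, not here.
    """
    record = kb.lookup_drug(drug) if isinstance(drug, str) else drug
    from .kb import ATC_LEVEL_LENGTHS

    if atc_level not in ATC_LEVEL_LENGTHS:
        raise ValidationError(f"ATC level must be 1..5, got {atc_level}")
    length = ATC_LEVEL_LENGTHS[atc_level]
    prefixes = {code[:length] for code in record.atc_codes}
    out: set[DrugRecord] = set()
    for prefix in sorted(prefixes):
        for name in kb.atc_group_members(prefix, atc_level):
            other = kb.lookup_drug(name)
            if other.name != record.name and other.purpose == record.purpose:
                out.add(other)
    return out


@dataclass(frozen=True)
class SubstitutionProposal:
    """One evaluated single-drug substitution with its effect on the metrics."""

    original: str
    alternative: str
    atc_group: str
    result_edges: int
    result_cyps: int
    delta_edges: int
    delta_cyps: int
    q0_note: str  # elimination class of the alternative
    ehl_note: str  # EHL comparison, alternative vs original

    #: lexicographic ordering used to pick among proposals; missing EHL/Q0
    #: sort last (an unknown parameter is never preferred over a known one)
    sort_key: tuple = field(default=(), compare=False)


def _shared_prefix(a: DrugRecord, b: DrugRecord, length: int) -> str:
    shared = sorted(
        {c[:length] for c in a.atc_codes} & {c[:length] for c in b.atc_codes}
    )
    return shared[0] if shared else ""


def substitution_score(
    regimen: Regimen,
    original: str,
    alternative: str,
    kb: KnowledgeBase,
    *,
    atc_level: int = 4,
    p450_only: bool = True,
) -> SubstitutionProposal:
    """Evaluate replacing ``original`` by ``alternative`` in ``regimen``.

    The alternative must be an admissible candidate of the original (same
    purpose, shared ATC subgroup).  Edge and CYP counts are recomputed on
    the swapped regimen; EHL and Q0 enter only the tie-breaking tail of the
    lexicographic key, never overriding an interaction-count reduction.
    """
    orig = kb.lookup_drug(original)
    alt = kb.lookup_drug(alternative)
    if alt.name not in {c.name for c in candidates(orig, kb, atc_level)}:
        raise ValidationError(
            f"{alt.name!r} is not an admissible alternative of {orig.name!r}"
        )
    base_edges = len(ddi_edges(regimen, kb, p450_only))
    base_cyps = interaction_cyp_count(regimen, kb)
    # swap by canonical identity so synonym-named regimen entries are matched
    swapped = Regimen(
        [
            RegimenEntry(alt.name, e.purpose, e.locked)
            if kb.canonical_name(e.drug) == orig.name
            else e
            for e in regimen
        ]
    )
    new_edges = len(ddi_edges(swapped, kb, p450_only))
    new_cyps = interaction_cyp_count(swapped, kb)

    ehl_alt = alt.ehl_hours if alt.ehl_hours is not None else math.inf
    q0_alt = alt.q0 if alt.q0 is not None else math.inf
    ehl_note = (
        f"{'?' if alt.ehl_hours is None else f'{alt.ehl_hours:g}h'} vs "
        f"{'?' if orig.ehl_hours is None else f'{orig.ehl_hours:g}h'}"
    )
    from .kb import ATC_LEVEL_LENGTHS

    return SubstitutionProposal(
        original=orig.name,
        alternative=alt.name,
        atc_group=_shared_prefix(orig, alt, ATC_LEVEL_LENGTHS[atc_level]),
        result_edges=new_edges,
        result_cyps=new_cyps,
        delta_edges=new_edges - base_edges,
        delta_cyps=new_cyps - base_cyps,
        q0_note=q0_class(alt).value,
        ehl_note=ehl_note,
        sort_key=(new_edges, new_cyps, ehl_alt, q0_alt, alt.name.lower()),
    )


@dataclass
class OptimizationStep:
    """Audit record of one descent step: everything evaluated, one applied."""

    applied: SubstitutionProposal
    evaluated: list[SubstitutionProposal]
    edges_before: int
    cyps_before: int


@dataclass
class OptimizationResult:
    initial_regimen: Regimen
    final_regimen: Regimen
    steps: list[OptimizationStep]
    initial_edge_count: int
    initial_cyp_count: int
    final_edge_count: int
    final_cyp_count: int

    @property
    def substitutions(self) -> list[SubstitutionProposal]:
        return [s.applied for s in self.steps]

    def to_dict(self) -> dict:
        def prop(p: SubstitutionProposal) -> dict:
            return {
                "original": p.original,
                "alternative": p.alternative,
                "atc_group": p.atc_group,
                "result_edges": p.result_edges,
                "result_cyps": p.result_cyps,
                "delta_edges": p.delta_edges,
                "delta_cyps": p.delta_cyps,
                "q0_note": p.q0_note,
                "ehl_note": p.ehl_note,
            }

        return {
            "initial_regimen": self.initial_regimen.drug_names(),
            "final_regimen": self.final_regimen.drug_names(),
            "initial_edge_count": self.initial_edge_count,
            "initial_cyp_count": self.initial_cyp_count,
            "final_edge_count": self.final_edge_count,
            "final_cyp_count": self.final_cyp_count,
            "steps": [
                {
                    "edges_before": s.edges_before,
                    "cyps_before": s.cyps_before,
                    "applied": prop(s.applied),
                    "evaluated": [prop(p) for p in s.evaluated],
                }
                for s in self.steps
            ],
        }

    def to_text(self, kb: KnowledgeBase | None = None) -> str:
        lines = [
            "Regimen optimization",
            f"  initial: {', '.join(self.initial_regimen.drug_names())}",
            f"  final:   {', '.join(self.final_regimen.drug_names())}",
            f"  edges: {self.initial_edge_count} -> {self.final_edge_count}; "
            f"interacting CYPs: {self.initial_cyp_count} -> {self.final_cyp_count}",
        ]
        if not self.steps:
            lines.append("  no substitutions (no strict improvement available)")
        for i, step in enumerate(self.steps, start=1):
            p = step.applied
            lines.append(
                f"  step {i}: {p.original} -> {p.alternative} [{p.atc_group}]  "
                f"edges {step.edges_before}->{p.result_edges}, "
                f"CYPs {step.cyps_before}->{p.result_cyps}, "
                f"EHL {p.ehl_note}, alternative {p.q0_note}"
            )
        return "\n".join(lines) + "\n"


def optimize_regimen(
    regimen: Regimen,
    kb: KnowledgeBase,
    *,
    atc_level: int = 4,
    max_iterations: int = 20,
    p450_only: bool = True,
) -> OptimizationResult:
    """Greedy iterative improvement of a regimen by single ATC-group swaps.

    At each step every admissible substitution (unlocked entry, same-purpose
    same-subgroup alternative not already in the regimen) is scored; the
    best proposal is applied only if it strictly reduces the (edge count,
    distinct-CYP count) pair lexicographically.  Deterministic given KB and
    configuration; terminates because each step strictly decreases a
    bounded, integer-valued objective.
    """
    if max_iterations <= 0:
        raise ValidationError(f"max_iterations must be positive, got {max_iterations}")
    current = Regimen(list(regimen.entries))
    initial_edges = len(ddi_edges(current, kb, p450_only))
    initial_cyps = interaction_cyp_count(current, kb)
    steps: list[OptimizationStep] = []
    cur_edges, cur_cyps = initial_edges, initial_cyps

    for _ in range(max_iterations):
        present = {kb.canonical_name(e.drug).lower() for e in current}
        evaluated: list[SubstitutionProposal] = []
        for entry in current:
            if entry.locked:
                continue
            orig = kb.lookup_drug(entry.drug)
            for alt in sorted(candidates(orig, kb, atc_level), key=lambda d: d.name):
                if alt.name.lower() in present:
                    continue
                evaluated.append(
                    substitution_score(
                        current,
                        orig.name,
                        alt.name,
                        kb,
                        atc_level=atc_level,
                        p450_only=p450_only,
                    )
                )
        if not evaluated:
            break
        best = min(evaluated, key=lambda p: p.sort_key)
        if (best.result_edges, best.result_cyps) >= (cur_edges, cur_cyps):
            break  # no strict improvement
        steps.append(
            OptimizationStep(
                applied=best,
                evaluated=evaluated,
                edges_before=cur_edges,
                cyps_before=cur_cyps,
            )
        )
        current = Regimen(
            [
                RegimenEntry(best.alternative, e.purpose, e.locked)
                if kb.canonical_name(e.drug) == best.original
                else e
                for e in current
            ]
        )
        cur_edges, cur_cyps = best.result_edges, best.result_cyps

    return OptimizationResult(
        initial_regimen=regimen,
        final_regimen=current,
        steps=steps,
        initial_edge_count=initial_edges,
        initial_cyp_count=initial_cyps,
        final_edge_count=cur_edges,
        final_cyp_count=cur_cyps,
    )
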