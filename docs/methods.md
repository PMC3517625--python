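# Methods

## Interaction model

The knowledge base is a set of assertions (drug, enzyme, role) with role ∈
{substrate, inducer, inhibitor} and optional PubMed provenance. Enzyme
identifiers are normalized to `CYP` + family digits + subfamily letter +
isoform digits (`3A4` → `CYP3A4`, case-insensitive); tokens that do not
match this isoform pattern (`UGT`, `11A`, `17A`, `27A`) are stored
verbatim and flagged non-P450. All CYP-focused metrics exclude non-P450
entries by default (`p450_only=True`); note that `11B1` and `4A11` *do*
match the isoform pattern and are treated as P450s — they never affect the
interaction metrics because no drug in the reference tables is their
substrate.

A **drug–drug interaction edge** is the quadruple
(perpetrator, enzyme, victim, modulation): the victim is a substrate of
the enzyme and a *different* regimen drug induces or inhibits that enzyme.
Induction and inhibition by the same perpetrator are distinct edges (they
have opposite pharmacological consequences: under-dosing vs toxicity).
Self-modulation (e.g. cyclophosphamide auto-induction of CYP3A4) is
excluded by default and reportable via `include_self=True` — it changes a
drug's own clearance but is not a cocktail-design degree of freedom.

Two summary metrics are reported per regimen: the fine-grained edge count
and the number of **distinct CYPs** mediating at least one edge. The
latter is the headline comparison metric; on the reference ALL tables it
is 8 before and 1 after optimization (23 vs 2 fine-grained edges). No
convention we could reconstruct reproduces a count of "eleven
interactions" sometimes quoted for the initial regimen, so we report our
two well-defined metrics and do not assert that figure.

**Venn overload partitions** count drugs in the exclusive regions of 2–4
enzymes. Membership defaults to the substrate role ("metabolized by"),
which is the reading under which the reference tables give regions
(6, 1, 0) for CYP3A4/CYP2C9; any-role membership is available through the
`roles` parameter (dexamethasone, an inducer but not substrate of CYP2C9,
then moves into the intersection).

**Q0 classification**: the extrarenal fraction Q0 is the fraction of a
dose eliminated by routes other than unchanged renal excretion. Drugs
with Q0 strictly below 0.3 are classed `renal_unchanged` (low CYP
occupancy); Q0 ≥ 0.3 is `metabolized`; missing Q0 is `unknown` and never
imputed. The boundary is a strict `<` at exactly 0.3.

**Prodrug warnings** enumerate (prodrug P, enzyme E, inhibitor D ≠ P)
with P substrate of E. In the reference regimen this flags
cyclophosphamide's CYP3A4 activation against dexamethasone and
vincristine.

## Optimizer

The search is greedy single-swap descent. Admissible substitutions keep
the therapeutic purpose (antineoplastic / corticosteroid / supportive)
and require a shared WHO ATC prefix at a configurable level, default
level 4 (chemical subgroup, 5 characters) — the finest level at which
"same group, different metabolism" alternatives exist; all reference
pairs (cyclophosphamide→trofosfamide, cytarabine→gemcitabine,
dexamethasone→prednisolone, vincristine→vindesine) share level-4 groups.
Locked regimen entries and drugs already present are never proposed.

Proposals are ordered lexicographically: resulting edge count, resulting
distinct-CYP count, alternative's EHL (lower preferred — long half-lives
prolong CYP occupancy), alternative's Q0 (lower preferred — less CYP
involvement), then name for determinism. Missing EHL/Q0 sort last: an
unknown parameter never beats a known one. A step is applied only if it
strictly decreases the (edges, CYPs) pair, which bounds the run by the
initial edge count and guarantees termination; `max_iterations`
(default 20) is a safety cap only. EHL and Q0 are tie-breaks and never
override an interaction-count reduction.

Greedy descent has no multi-swap look-ahead and can end above the global
optimum on adversarial inputs. The test suite compares it against
exhaustive search over all substitution combinations on small random
instances and prints any divergence rather than hiding it; on the
reference tables greedy reaches the optimum (one interacting CYP).

## Relation miner

The miner is deliberately dictionary- and rule-based; no statistical NLP.
Sentences split on `.`/`!`/`?` + whitespace with a small abbreviation
guard list; tokens are word-like spans (letters/digits, internal hyphens)
carrying character offsets. Finer topic segmentation than sentences is
not implemented. Entity mentions come from case-insensitive
longest-match-wins dictionary matching over token n-grams, scanned left
to right without overlaps.

Records are screened with the boolean query: drug synonym AND enzyme
synonym in the title, OR drug synonym AND interaction term AND enzyme
synonym in the abstract. For each drug–enzyme mention pair the nearest
usable interaction term supplies the role (inhibit- → inhibitor,
induce- → inducer, metabolize-/substrate- → substrate, via a small
suffix-stripping stemmer; no external stemming library).

The confidence score is a linear rule,

```
score = base − w_dist·dist(drug, enzyme)
        + b_sent·[all three in one sentence]
        + b_order·[term lies between drug and enzyme]
        + b_redund·(extra co-occurrences of the pair in the record)
```

floored at 0, with defaults base = 10, w_dist = 0.5 (per token),
b_sent = 5, b_order = 2, b_redund = 1, max_distance = 30 tokens. The
named ingredients (order, redundancy, distance, sentence boundaries) are
established; the specific linear form and weights are this package's
formalization, kept as data (`ScoringParams`), not code. The positional
restriction is a hard gate, applied both to the pair (different
sentences and > 30 tokens apart → no candidate) and to the term (usable
only within the pair's sentence or within 30 tokens of both entities);
treating it as a mere score of 0 would let a distant term attach to an
unrelated co-occurrence. Deduplication keeps the best-scoring hit per
(pmid, drug, enzyme, role) — or per (drug, enzyme, role) corpus-wide in
KB-building mode — with ties broken toward the lower PMID and earlier
span. The score threshold defaults to 0 (report everything that passed
the gates), since downstream manual curation is out of scope.

## Synthetic data

`generate_kb` samples each (drug, enzyme, role) triple independently with
per-role Bernoulli rates (defaults 0.15/0.05/0.05 substrate/inducer/
inhibitor, a density comparable to the reference tables), assigns drugs
pairwise to shared level-4 ATC subgroups with purpose constant per group
(so the optimizer always has candidate pools), and draws Q0 uniform on
[0, 1] and EHL uniform on [0.5, 96] h with 15 % missing each. All
generators are pure functions of (config, seed).

`generate_corpus` writes template abstracts: by default 40 of 100
abstracts carry exactly one planted relation ("<drug> is metabolized by
<CYP> …", verb chosen per role), 30 % carry a distractor sentence
co-mentioning a drug and an enzyme without any interaction term, and
content sentences are separated by a fixed 40-token neutral filler so
cross-sentence mention pairs always exceed the distance gate. Under these
conditions the miner's precision and recall against the planted ground
truth are exactly 1.0 — which validates the pipeline's rules, not its
robustness to real prose: real abstracts paraphrase, negate, hedge and
coordinate entities in ways the templates do not emulate, so measured
performance on them would be lower. The corpus-level record counts of any
live literature snapshot are likewise out of scope.

## Reference fixture

The packaged knowledge base transcribes the published before/after ALL
regimen tables: 10 drugs, 46 role assertions, all printed Q0/EHL values,
purposes, and prodrug flags (cyclophosphamide, trofosfamide). ATC codes
are not printed in those tables; the fixture carries the standard WHO
codes (cyclophosphamide L01AA01, trofosfamide L01AA07, cytarabine
L01BC01, gemcitabine L01BC05, vincristine L01CA02, vindesine L01CA03,
dexamethasone H02AB02, prednisolone H02AB06, methotrexate L01BA01,
asparaginase L01XX02). "L-Asparagine" in the source table is treated as
a typo for L-asparaginase and recorded as a synonym; HDMTX (high-dose
methotrexate) likewise resolves via synonyms. Missing Q0/EHL (HDMTX,
L-asparaginase) stay missing.

## Problem sizes and numerics

Oracle cross-checks run on 200 random knowledge bases of 6–12 drugs and
4–10 enzymes with regimens of 3–7 drugs — large enough to exercise every
role combination, small enough for the exhaustive oracles (the
brute-force edge scan is O(triples²); the exhaustive optimizer oracle is
exponential in regimen slots and used at ≤ 6 drugs). All comparisons are
exact set or integer equalities; there is no floating-point tolerance
anywhere in the core metrics. File round-trips compare field-by-field
after normalization; floats serialize via `repr` and so round-trip
exactly.

## Known limitations

- Interaction *presence* only: no Km/Vmax kinetics, no magnitude or
  direction of exposure change, no dose advice, no genotype/SNP effects.
- The optimizer establishes metabolic preferability only; clinical
  equivalence of alternatives requires oncologist curation by design.
- Greedy descent, single swaps, no look-ahead (divergences from the
  exhaustive optimum are flagged in tests).
- The miner's sentence-level segmentation and template-validated rules do
  not constitute an NLP benchmark claim.
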