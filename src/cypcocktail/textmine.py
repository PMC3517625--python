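"""Dictionary/rule-based mining of drug–CYP relations from abstracts.

The pipeline screens Medline-style records with a boolean query
(drug synonym AND CYP synonym in the title, OR drug synonym AND interaction
term AND CYP synonym in the abstract), finds entity mentions by
longest-match dictionary lookup, scores candidate (drug, enzyme) pairs with
a linear rule combining token distance, sentence co-occurrence, canonical
ordering and redundancy, classifies the role from the nearest interaction
term, and deduplicates the surviving hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .errors import ParseError, UnknownTermError, ValidationError
from .kb import EnzymeID, KnowledgeBase, Role, normalize_enzyme_name

__all__ = [
    "AbstractRecord",
    "Lexicons",
    "Token",
    "Mention",
    "RelationHit",
    "ScoringParams",
    "MiningSummary",
    "DEFAULT_INTERACTION_TERMS",
    "segment",
    "find_mentions",
    "query_match",
    "score_relation",
    "classify_role",
    "deduplicate",
    "mine_corpus",
    "lexicons_from_kb",
    "read_medline_xml",
    "read_abstracts_tsv",
    "write_abstracts_tsv",
    "read_synonym_lexicon",
    "read_term_lexicon",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class AbstractRecord:
    """One Medline-style record; title and abstract may be empty."""

    pmid: str
    title: str = ""
    abstract: str = ""


#: built-in interaction-term lexicon covering the three term families
DEFAULT_INTERACTION_TERMS: dict[str, Role] = {
    **{
        t: Role.SUBSTRATE
        for t in (
            "metabolize metabolizes metabolized metabolizing "
            "metabolise metabolises metabolised metabolising "
            "metabolism substrate substrates"
        ).split()
    },
    **{
        t: Role.INDUCER
        for t in "induce induces induced inducing induction inducer inducers".split()
    },
    **{
        t: Role.INHIBITOR
        for t in (
            "inhibit inhibits inhibited inhibiting inhibition "
            "inhibitor inhibitors inhibitory"
        ).split()
    },
}


@dataclass
class Lexicons:
    """Entity dictionaries: drug synonyms, enzyme synonyms, interaction terms."""

    drugs: dict[str, frozenset[str]]
    enzymes: dict[str, frozenset[str]]
    terms: dict[str, Role] = field(default_factory=lambda: dict(DEFAULT_INTERACTION_TERMS))

    def __post_init__(self) -> None:
        for label, lex in (("drug", self.drugs), ("enzyme", self.enzymes)):
            seen: dict[str, str] = {}
            for canonical, synonyms in lex.items():
                if not synonyms:
                    raise ValidationError(f"{label} lexicon entry {canonical!r} has no synonyms")
                for s in synonyms:
                    owner = seen.setdefault(s.lower(), canonical)
                    if owner != canonical:
                        raise ValidationError(
                            f"{label} synonym {s!r} maps to both {owner!r} and {canonical!r}"
                        )


def lexicons_from_kb(
    kb: KnowledgeBase, terms: Mapping[str, Role] | None = None
) -> Lexicons:
    """Build mining lexicons from a knowledge base.

    Each drug contributes its canonical name plus synonyms; each enzyme seen
    in the interaction triples contributes its normalized name plus a spaced
    variant ("CYP 3A4").
    """
    drugs = {d.name: frozenset({d.name, *d.synonyms}) for d in kb.drugs}
    enzymes: dict[str, frozenset[str]] = {}
    for e in kb.enzymes():
        variants = {e.name}
        if e.is_p450:
            variants.add(f"CYP {e.name[3:]}")
        enzymes[e.name] = frozenset(variants)
    return Lexicons(drugs, enzymes, dict(terms) if terms is not None else dict(DEFAULT_INTERACTION_TERMS))


# -- segmentation and tokenization -----------------------------------------

#: word-ish tokens: letters/digits with internal hyphens ("L-asparaginase")
_TOKEN_RE = re.compile(r"[A-Za-z0-9](?:[\w\-]*\w)?")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")
#: sentence-final fragments that end with a period but do not end a sentence
_ABBREVIATIONS = ("e.g.", "i.e.", "et al.", "vs.", "fig.", "ca.", "approx.", "resp.")


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # character offset into the original text
    index: int = 0  # running token index within the record
    sentence: int = 0

    @property
    def end(self) -> int:
        return self.start + len(self.text)


def segment(text: str) -> list[list[Token]]:
    """Rule-based sentence splitting and tokenization with offsets.

    Sentences break after ``.``/``!``/``?`` followed by whitespace unless
    the preceding text ends in a guarded abbreviation; tokens are word-like
    spans carrying their character offsets, so every token indexes back into
    the original string exactly.
    """
    if not text.strip():
        return []
    # candidate boundaries, then merge the ones blocked by abbreviations
    pieces: list[tuple[int, str]] = []
    pos = 0
    for m in _SENT_SPLIT_RE.finditer(text):
        pieces.append((pos, text[pos : m.start()]))
        pos = m.end()
    pieces.append((pos, text[pos:]))
    merged: list[tuple[int, str]] = []
    for start, piece in pieces:
        if merged and merged[-1][1].strip().lower().endswith(_ABBREVIATIONS):
            pstart, prev = merged[-1]
            gap = text[pstart + len(prev) : start]
            merged[-1] = (pstart, prev + gap + piece)
        else:
            merged.append((start, piece))

    sentences: list[list[Token]] = []
    tok_index = 0
    for sent_idx, (start, piece) in enumerate(merged):
        tokens = []
        for m in _TOKEN_RE.finditer(piece):
            tokens.append(
                Token(m.group(), start + m.start(), index=tok_index, sentence=sent_idx)
            )
            tok_index += 1
        if tokens:
            sentences.append(tokens)
    return sentences


@dataclass(frozen=True)
class Mention:
    """A dictionary match covering tokens ``first..last`` (inclusive)."""

    canonical: str
    first: Token
    last: Token
    pmid: str = ""

    @property
    def token_index(self) -> int:
        return self.first.index

    @property
    def sentence(self) -> int:
        return self.first.sentence

    @property
    def span(self) -> tuple[int, int]:
        return (self.first.start, self.last.end)


def _phrase_map(lexicon: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], str]:
    phrases: dict[tuple[str, ...], str] = {}
    for canonical in sorted(lexicon):
        for synonym in lexicon[canonical]:
            key = tuple(m.group().lower() for m in _TOKEN_RE.finditer(synonym))
            if key:
                phrases.setdefault(key, canonical)
    return phrases


def find_mentions(
    tokens: Sequence[Token],
    lexicon: Mapping[str, Iterable[str]],
    pmid: str = "",
) -> list[Mention]:
    """Longest-match-wins, non-overlapping dictionary matching over tokens.

    Matching is case-insensitive on token n-grams, scanned left to right;
    at each position the longest matching synonym is taken and the scan
    resumes after it.
    """
    phrases = _phrase_map(lexicon)
    if not phrases:
        return []
    max_len = max(len(p) for p in phrases)
    lowered = [t.text.lower() for t in tokens]
    mentions: list[Mention] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            canonical = phrases.get(tuple(lowered[i : i + length]))
            if canonical is not None:
                hit = (canonical, length)
                break
        if hit is None:
            i += 1
        else:
            canonical, length = hit
            mentions.append(Mention(canonical, tokens[i], tokens[i + length - 1], pmid))
            i += length
    return mentions


def _flat_tokens(record: AbstractRecord) -> list[Token]:
    text = record.title + "\n" + record.abstract if record.title else record.abstract
    return [t for sent in segment(text) for t in sent]


def query_match(record: AbstractRecord, lexicons: Lexicons) -> bool:
    """Boolean screening query.

    True iff a drug synonym and an enzyme synonym co-occur in the title, or
    a drug synonym, an interaction term and an enzyme synonym all occur in
    the abstract.
    """
    term_lex = {"term": frozenset(lexicons.terms)}
    title_tokens = [t for s in segment(record.title) for t in s]
    if find_mentions(title_tokens, lexicons.drugs) and find_mentions(
        title_tokens, lexicons.enzymes
    ):
        return True
    abstract_tokens = [t for s in segment(record.abstract) for t in s]
    return bool(
        find_mentions(abstract_tokens, lexicons.drugs)
        and find_mentions(abstract_tokens, term_lex)
        and find_mentions(abstract_tokens, lexicons.enzymes)
    )


# -- scoring and role classification ---------------------------------------


@dataclass(frozen=True)
class ScoringParams:
    """Weights of the linear rule score; all tunable, defaults documented.

    ``score = base - w_dist * dist(drug, enzyme) + b_sent * [same sentence]
    + b_order * [term lies between drug and enzyme] + b_redund * extra
    co-occurrences of the pair``, floored at 0.  Pairs in different
    sentences farther apart than ``max_distance`` tokens are rejected.
    """

    base: float = 10.0
    w_dist: float = 0.5
    b_sent: float = 5.0
    b_order: float = 2.0
    b_redund: float = 1.0
    max_distance: int = 30


def score_relation(
    drug_mention: Mention,
    cyp_mention: Mention,
    term_mention: Mention,
    params: ScoringParams = ScoringParams(),
    *,
    redundancy: int = 0,
) -> float:
    """Rule-based confidence of one (drug, enzyme, term) co-occurrence."""
    pmids = {m.pmid for m in (drug_mention, cyp_mention, term_mention)}
    if len(pmids) > 1:
        raise ValidationError(f"mentions come from different records: {sorted(pmids)}")
    dist = abs(drug_mention.token_index - cyp_mention.token_index)
    same_sentence = (
        drug_mention.sentence == cyp_mention.sentence == term_mention.sentence
    )
    if drug_mention.sentence != cyp_mention.sentence and dist > params.max_distance:
        return 0.0
    lo = min(drug_mention.token_index, cyp_mention.token_index)
    hi = max(drug_mention.token_index, cyp_mention.token_index)
    canonical_order = lo < term_mention.token_index < hi
    score = (
        params.base
        - params.w_dist * dist
        + params.b_sent * same_sentence
        + params.b_order * canonical_order
        + params.b_redund * redundancy
    )
    return max(0.0, score)


_SUFFIXES = (
    "ization",
    "isation",
    "ation",
    "ition",
    "ions",
    "ion",
    "ings",
    "ing",
    "ers",
    "er",
    "ors",
    "or",
    "ory",
    "ism",
    "es",
    "ed",
    "s",
    "e",
)


def _stem(term: str) -> str:
    """Tiny suffix stripper sufficient for the three term families."""
    word = term.strip().lower()
    changed = True
    while changed and len(word) > 4:
        changed = False
        for suffix in _SUFFIXES:
            if word.endswith(suffix) and len(word) - len(suffix) >= 4:
                word = word[: -len(suffix)]
                changed = True
                break
    return word


def classify_role(term: str, lexicons: Lexicons) -> Role:
    """Map an interaction term (any inflection) to its relation role."""
    key = term.strip().lower()
    if key in {t.lower() for t in lexicons.terms}:
        return {t.lower(): r for t, r in lexicons.terms.items()}[key]
    stem = _stem(key)
    # longest lexicon stems first so the most specific family wins
    by_stem = sorted(
        {(_stem(t), r) for t, r in lexicons.terms.items()},
        key=lambda item: (-len(item[0]), item[0]),
    )
    for lex_stem, role in by_stem:
        if stem == lex_stem or stem.startswith(lex_stem) or lex_stem.startswith(stem):
            return role
    raise UnknownTermError(f"interaction term {term!r} not in lexicon")


# -- relation hits ----------------------------------------------------------


@dataclass(frozen=True)
class RelationHit:
    """A mined (drug, enzyme, role) candidate with score and evidence spans."""

    pmid: str
    drug: str
    enzyme: EnzymeID
    role: Role
    score: float
    evidence: tuple[tuple[int, int], ...] = ()

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.pmid, self.drug, self.enzyme.name, self.role.value)


def _pmid_order(pmid: str) -> tuple[int, str]:
    return (int(pmid), "") if pmid.isdigit() else (1 << 62, pmid)


def deduplicate(hits: Iterable[RelationHit], *, per_corpus: bool = False) -> list[RelationHit]:
    """Keep the best hit per key; idempotent, never lengthens the list.

    The key is (pmid, drug, enzyme, role) by default, or (drug, enzyme,
    role) across the whole corpus in KB-building mode.  The highest score
    wins; ties break toward the lower PMID, then the earlier evidence span.
    First-seen key order is preserved.
    """
    best: dict[tuple, RelationHit] = {}
    for hit in hits:
        key = hit.key[1:] if per_corpus else hit.key
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = hit
            continue
        offset = hit.evidence[0][0] if hit.evidence else 0
        inc_offset = incumbent.evidence[0][0] if incumbent.evidence else 0
        if (-hit.score, _pmid_order(hit.pmid), offset) < (
            -incumbent.score,
            _pmid_order(incumbent.pmid),
            inc_offset,
        ):
            best[key] = hit
    return list(best.values())


@dataclass
class MiningSummary:
    records_screened: int = 0
    query_hits: int = 0
    candidate_pairs: int = 0
    hits_above_threshold: int = 0
    duplicates_removed: int = 0
    hits_returned: int = 0

    def to_dict(self) -> dict:
        return {
            "records_screened": self.records_screened,
            "query_hits": self.query_hits,
            "candidate_pairs": self.candidate_pairs,
            "hits_above_threshold": self.hits_above_threshold,
            "duplicates_removed": self.duplicates_removed,
            "hits_returned": self.hits_returned,
        }


def mine_corpus(
    records: Iterable[AbstractRecord],
    lexicons: Lexicons,
    params: ScoringParams = ScoringParams(),
    threshold: float = 0.0,
    *,
    per_corpus_dedup: bool = False,
) -> tuple[list[RelationHit], MiningSummary]:
    """Run the full extraction pipeline over a corpus.

    Records failing the boolean query are skipped.  For every (drug, enzyme)
    mention pair the nearest interaction term supplies the role; pairs in
    different sentences farther apart than ``params.max_distance`` tokens
    are rejected outright.  Hits scoring at least ``threshold`` survive to
    deduplication.  The summary counts satisfy
    ``hits_above_threshold - duplicates_removed == hits_returned``.
    """
    summary = MiningSummary()
    term_lex = {"term": frozenset(lexicons.terms)}
    raw_hits: list[RelationHit] = []
    for record in records:
        summary.records_screened += 1
        if not query_match(record, lexicons):
            continue
        summary.query_hits += 1
        tokens = _flat_tokens(record)
        drug_mentions = find_mentions(tokens, lexicons.drugs, record.pmid)
        cyp_mentions = find_mentions(tokens, lexicons.enzymes, record.pmid)
        term_mentions = find_mentions(tokens, term_lex, record.pmid)
        if not term_mentions:
            continue
        pair_counts: dict[tuple[str, str], int] = {}
        for d in drug_mentions:
            for c in cyp_mentions:
                pair_counts[(d.canonical, c.canonical)] = (
                    pair_counts.get((d.canonical, c.canonical), 0) + 1
                )
        for d in drug_mentions:
            for c in cyp_mentions:
                if d.sentence != c.sentence and abs(
                    d.token_index - c.token_index
                ) > params.max_distance:
                    continue  # hard distance gate: no candidate formed
                # the positional restriction applies to the interaction term
                # as well: a term is usable only in the pair's sentence or
                # within the distance cutoff of both entities
                usable = [
                    t
                    for t in term_mentions
                    if (t.sentence == d.sentence == c.sentence)
                    or (
                        abs(t.token_index - d.token_index) <= params.max_distance
                        and abs(t.token_index - c.token_index) <= params.max_distance
                    )
                ]
                if not usable:
                    continue
                summary.candidate_pairs += 1
                term = min(
                    usable,
                    key=lambda t: (
                        abs(t.token_index - d.token_index)
                        + abs(t.token_index - c.token_index),
                        t.token_index,
                    ),
                )
                redundancy = pair_counts[(d.canonical, c.canonical)] - 1
                score = score_relation(d, c, term, params, redundancy=redundancy)
                if score >= threshold:
                    summary.hits_above_threshold += 1
                    raw_hits.append(
                        RelationHit(
                            pmid=record.pmid,
                            drug=d.canonical,
                            enzyme=normalize_enzyme_name(c.canonical),
                            role=classify_role(term.first.text, lexicons),
                            score=score,
                            evidence=(d.span, term.span, c.span),
                        )
                    )
    hits = deduplicate(raw_hits, per_corpus=per_corpus_dedup)
    summary.duplicates_removed = summary.hits_above_threshold - len(hits)
    summary.hits_returned = len(hits)
    return hits, summary


# -- corpus and lexicon I/O -------------------------------------------------


def read_medline_xml(path: str | Path) -> list[AbstractRecord]:
    """Read a PubmedArticle XML subset (PMID, ArticleTitle, AbstractText)."""
    tree = etree.parse(str(path))
    records = []
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//PMID")
        if pmid is None:
            raise ParseError("PubmedArticle without PMID element")
        title = article.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            (node.text or "") for node in article.iter("AbstractText")
        ).strip()
        records.append(AbstractRecord(pmid.strip(), title.strip(), abstract))
    return records


def read_abstracts_tsv(path: str | Path) -> list[AbstractRecord]:
    records = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        if lineno == 1 and line.split("\t")[0].strip().lower() == "pmid":
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"expected 3 columns (pmid, title, abstract), got {len(fields)}", lineno)
        records.append(AbstractRecord(fields[0].strip(), fields[1], fields[2]))
    return records


def write_abstracts_tsv(records: Iterable[AbstractRecord], path: str | Path) -> None:
    lines = ["pmid\ttitle\tabstract"]
    for r in records:
        lines.append(f"{r.pmid}\t{r.title}\t{r.abstract}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_synonym_lexicon(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a (canonical, synonym) two-column TSV into a synonym map."""
    out: dict[str, set[str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"expected 2 columns (canonical, synonym), got {len(fields)}", lineno)
        canonical, synonym = (f.strip() for f in fields)
        out.setdefault(canonical, set()).add(synonym)
        out[canonical].add(canonical)
    return {k: frozenset(v) for k, v in out.items()}


def read_term_lexicon(path: str | Path) -> dict[str, Role]:
    out: dict[str, Role] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"expected 2 columns (term, role), got {len(fields)}", lineno)
        out[fields[0].strip().lower()] = Role.parse(fields[1])
    return out


def write_hits_tsv(hits: Iterable[RelationHit], path: str | Path) -> None:
    lines = ["pmid\tdrug\tenzyme\trole\tscore"]
    for h in hits:
        lines.append(f"{h.pmid}\t{h.drug}\t{h.enzyme.name}\t{h.role.value}\t{h.score:g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
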