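"""Exception hierarchy shared across the package."""

from __future__ import annotations


class CypCocktailError(Exception):
    """Base class for all package errors."""


class ValidationError(CypCocktailError, ValueError):
    """A record or argument violates an invariant."""


class ParseError(CypCocktailError):
    """A file could not be parsed; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None) -> None:
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateRecordError(ValidationError):
    """A canonical name or (drug, enzyme, role) triple occurs twice."""


class ReferentialIntegrityError(ValidationError):
    """An interaction references a drug absent from the knowledge base."""


class DrugNotFoundError(CypCocktailError, KeyError):
    """A drug name resolved neither as canonical name nor as synonym."""

    def __init__(self, query: str, suggestions: tuple[str, ...] = ()) -> None:
        self.query = query
        self.suggestions = tuple(suggestions)
        hint = f" (did you mean: {', '.join(suggestions)}?)" if suggestions else ""
        super().__init__(f"no drug matching {query!r}{hint}")

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return self.args[0]


class UnknownTermError(CypCocktailError):
    """An interaction term is not covered by the term lexicon."""
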