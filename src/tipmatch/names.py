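"""Parsing, normalization and orthographic mutation of Latin species names.

Comparative datasets and phylogenies write the same binomial in many
surface forms: ``Panthera_leo``, ``Panthera leo``, ``panthera leo``,
``Panthera leo (Linnaeus, 1758)``.  This module provides a structured
:class:`TaxonName`, a case/separator-insensitive comparison key, and the
suffix-substitution machinery used as a fallback when a strict database
lookup fails (e.g. swapping a ``-um`` epithet ending for ``-us``, which
turns up names filed under an alternative Latin gender agreement).

Nothing here attempts fuzzy or edit-distance matching: the only mutations
performed are whole-suffix swaps from an explicit rule table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Union

__all__ = [
    "TaxonName",
    "SubstitutionRule",
    "MalformedNameError",
    "DEFAULT_RULES",
    "parse_name",
    "normalize",
    "format_name",
    "generate_variants",
]


class MalformedNameError(ValueError):
    """Raised for names that cannot be parsed as a binomial.

    Signals that the offending row must be surfaced to the user (counted
    and reported), never silently dropped.
    """


# A Latin-word token: letters only, optionally with internal hyphen
# (e.g. "novae-zelandiae").
_WORD_RE = re.compile(r"^[A-Za-z][A-Za-z-]*$")

# Tokens that mark the start of an authorship string rather than a name part:
# anything with digits, parentheses, commas, ampersands or capitalised
# non-initial words like "(Linnaeus," / "1758)".
_SEPARATORS_RE = re.compile(r"[\s_]+")


@dataclass(frozen=True)
class TaxonName:
    """A parsed binomial or trinomial species name.

    ``raw`` keeps the original input verbatim for reporting; it is
    excluded from equality so that format -> parse round-trips compare
    equal.
    """

    genus: str
    epithet: str
    infraspecific: str | None = None
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.genus or not _WORD_RE.match(self.genus):
            raise MalformedNameError(f"invalid genus token: {self.genus!r}")
        if not self.epithet or not _WORD_RE.match(self.epithet):
            raise MalformedNameError(f"invalid epithet token: {self.epithet!r}")
        object.__setattr__(self, "genus", self.genus[0].upper() + self.genus[1:].lower())
        object.__setattr__(self, "epithet", self.epithet.lower())
        if self.infraspecific is not None:
            object.__setattr__(self, "infraspecific", self.infraspecific.lower())

    @property
    def is_trinomial(self) -> bool:
        return self.infraspecific is not None

    def binomial(self) -> "TaxonName":
        """Drop the infraspecific epithet, if any."""
        if self.infraspecific is None:
            return self
        return TaxonName(self.genus, self.epithet, None, raw=self.raw)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_name(self, " ")


@dataclass(frozen=True)
class SubstitutionRule:
    """A bidirectional epithet-ending swap, e.g. ``um <-> us``.

    Rules act only on the epithet (and infraspecific) suffix; the genus is
    never altered.
    """

    suffix_a: str
    suffix_b: str

    def apply(self, epithet: str) -> str | None:
        """Swap the ending in either direction, or None if neither matches.

        The longer suffix is tried first so that e.g. ``ii <-> i`` maps
        ``grayii`` to ``grayi`` rather than the reverse on the same
        input.  A suffix only matches at a clean boundary (the preceding
        character must differ from the suffix's first character, so
        ``niii`` matches neither ``ii`` nor ``i``), and a swap is only
        accepted if it is reversible — applying the rule to the result
        recovers the input.  Together these keep every rule strictly
        bidirectional.
        """
        for src, dst in self._directions():
            if self._matches(epithet, src):
                candidate = epithet[: -len(src)] + dst
                if self._raw_apply(candidate) == epithet:
                    return candidate
        return None

    def _directions(self) -> tuple[tuple[str, str], tuple[str, str]]:
        first, second = self.suffix_a, self.suffix_b
        if len(second) > len(first):
            first, second = second, first
        return (first, second), (second, first)

    @staticmethod
    def _matches(epithet: str, src: str) -> bool:
        return (
            epithet.endswith(src)
            and len(epithet) > len(src)
            and epithet[-len(src) - 1] != src[0]
        )

    def _raw_apply(self, epithet: str) -> str | None:
        for src, dst in self._directions():
            if self._matches(epithet, src):
                return epithet[: -len(src)] + dst
        return None


#: Default suffix-swap table.  Only um<->us is mandated by the NCBI-style
#: fallback description; the rest cover common Latin gender/declension
#: endings and can be disabled by passing an explicit rule list.
DEFAULT_RULES: tuple[SubstitutionRule, ...] = (
    SubstitutionRule("um", "us"),
    SubstitutionRule("us", "a"),
    SubstitutionRule("um", "a"),
    SubstitutionRule("is", "e"),
    SubstitutionRule("ii", "i"),
    SubstitutionRule("ae", "a"),
)


def _tokens(raw: str) -> list[str]:
    return [t for t in _SEPARATORS_RE.split(raw.strip()) if t]


def parse_name(raw: str) -> TaxonName:
    """Parse a species name from whitespace- or underscore-separated tokens.

    The first token becomes the genus, the second the epithet, and a third
    Latin-word token (if present) the infraspecific epithet.  Trailing
    authorship strings ("(Linnaeus, 1758)") are stripped: token collection
    stops at the first token that is not a plain Latin word.

    Raises
    ------
    MalformedNameError
        For empty input or a uninomial (single token).
    """
    if raw is None or not raw.strip():
        raise MalformedNameError("empty name")
    toks = _tokens(raw)
    words: list[str] = []
    for t in toks:
        if not _WORD_RE.match(t) or (len(words) >= 1 and t[0].isupper()):
            # authorship / annotation starts here (digits, punctuation, or a
            # capitalised word after the genus, e.g. "Panthera leo Linnaeus")
            break
        words.append(t)
        if len(words) == 3:
            break
    if len(words) < 2:
        raise MalformedNameError(
            f"not a binomial (need genus and epithet): {raw!r}"
        )
    infra = words[2] if len(words) == 3 else None
    return TaxonName(words[0], words[1], infra, raw=raw)


def normalize(name: Union[TaxonName, str]) -> str:
    """Return the canonical comparison key for a name.

    Case-folded, with runs of spaces/underscores collapsed to a single
    space.  Unparseable strings fall back to whole-string folding, so
    normalization never raises.
    """
    if isinstance(name, TaxonName):
        parts = [name.genus, name.epithet]
        if name.infraspecific:
            parts.append(name.infraspecific)
        return " ".join(parts).lower()
    return " ".join(_tokens(str(name))).lower()


def format_name(name: TaxonName, separator: str = "_") -> str:
    """Join the name's tokens with ``separator`` (binomial or trinomial)."""
    parts = [name.genus, name.epithet]
    if name.infraspecific:
        parts.append(name.infraspecific)
    return separator.join(parts)


def generate_variants(
    name: TaxonName, rules: Iterable[SubstitutionRule] = DEFAULT_RULES
) -> list[TaxonName]:
    """All names reachable by applying exactly one suffix rule to the epithet.

    The genus is never touched; the input itself is excluded; order follows
    the rule list (deterministic).  An epithet matching no rule yields an
    empty list, as does an empty rule set.
    """
    out: list[TaxonName] = []
    seen = {normalize(name)}
    for rule in rules:
        swapped = rule.apply(name.epithet)
        if swapped is None:
            continue
        variant = TaxonName(name.genus, swapped, name.infraspecific, raw=name.raw)
        key = normalize(variant)
        if key not in seen:
            seen.add(key)
            out.append(variant)
    return out
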