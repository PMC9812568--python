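"""Core sequence-labeling types and BIO-scheme logic.

Tokens are indexed 0-based; spans are half-open ``[start, end)``. BIO tags are
either bare (``B``, ``I``, ``O``) for single-category corpora, or typed
(``B-Disease``, ``I-Disease``, ...). A bare ``B``/``I`` carries the implicit
category ``"ENT"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "BARE_CATEGORY",
    "Corpus",
    "IllegalTransitionError",
    "OverlapError",
    "Sentence",
    "Span",
    "bio_from_spans",
    "make_tag",
    "parse_tag",
    "spans_from_bio",
    "validate_bio",
]

#: implicit category carried by bare B/I tags
BARE_CATEGORY = "ENT"

_TYPED_TAG = re.compile(r"^(B|I)-(\S+)$")


class IllegalTransitionError(ValueError):
    """An ``I`` tag not preceded by a ``B``/``I`` of the same category."""

    def __init__(self, index: int, tag: str):
        self.index = index
        self.tag = tag
        super().__init__(f"illegal BIO transition at index {index}: {tag!r}")


class OverlapError(ValueError):
    """Spans overlap where non-overlapping spans are required."""


def parse_tag(tag: str) -> tuple[str, str | None]:
    """Parse a BIO tag into ``(role, category)``.

    ``role`` is one of ``"B"``, ``"I"``, ``"O"``; category is ``None`` for
    ``O`` and for bare ``B``/``I`` tags.
    """
    if tag == "O":
        return "O", None
    if tag in ("B", "I"):
        return tag, None
    m = _TYPED_TAG.match(tag)
    if m is None:
        raise ValueError(f"not a BIO tag: {tag!r}")
    return m.group(1), m.group(2)


def make_tag(role: str, category: str | None) -> str:
    """Inverse of :func:`parse_tag`."""
    if role == "O":
        return "O"
    if role not in ("B", "I"):
        raise ValueError(f"not a BIO role: {role!r}")
    return role if category is None else f"{role}-{category}"


@dataclass(frozen=True, order=True)
class Span:
    """A labeled entity mention: token range ``[start, end)`` plus category."""

    start: int
    end: int
    category: str = BARE_CATEGORY

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Sentence:
    """A tokenized sentence with optional gold BIO labels."""

    tokens: list[str]
    labels: list[str] | None = None
    id: str = ""

    def __post_init__(self):
        if len(self.tokens) < 1:
            raise ValueError("sentence must contain at least one token")
        for t in self.tokens:
            if not t or any(c.isspace() for c in t):
                raise ValueError(f"bad token {t!r}: empty or contains whitespace")
        if self.labels is not None and len(self.labels) != len(self.tokens):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.tokens)} tokens"
            )

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """A split of labeled sentences plus the category inventory."""

    sentences: list[Sentence]
    split: str = "train"
    categories: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_sentences(cls, sentences: list[Sentence], split: str = "train") -> "Corpus":
        cats = set()
        for s in sentences:
            for tag in s.labels or []:
                role, cat = parse_tag(tag)
                if role != "O":
                    cats.add(BARE_CATEGORY if cat is None else cat)
        return cls(sentences=sentences, split=split, categories=frozenset(cats))

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def __getitem__(self, i: int) -> Sentence:
        return self.sentences[i]


def validate_bio(labels: list[str], repair: bool = False) -> list[str]:
    """Check (or repair) BIO legality of a tag sequence.

    An ``I-X`` is legal only directly after ``B-X`` or ``I-X``. With
    ``repair=True`` each illegal ``I-X`` is rewritten to ``B-X``; legal
    sequences come back unchanged. Repair is idempotent.
    """
    if not labels:
        raise ValueError("empty label sequence")
    out: list[str] = []
    prev_role: str = "O"
    prev_cat: str | None = None
    for i, tag in enumerate(labels):
        role, cat = parse_tag(tag)
        if role == "I" and not (prev_role in ("B", "I") and prev_cat == cat):
            if not repair:
                raise IllegalTransitionError(i, tag)
            role = "B"
            tag = make_tag("B", cat)
        out.append(tag)
        prev_role, prev_cat = role, cat
    return out


def spans_from_bio(labels: list[str]) -> list[Span]:
    """Extract entity spans from a *legal* BIO sequence.

    Maximal ``B``-led runs become spans; bare tags map to the implicit
    category :data:`BARE_CATEGORY`. Caller is responsible for legality
    (run :func:`validate_bio` first).
    """
    spans: list[Span] = []
    start: int | None = None
    cur_cat: str | None = None
    for i, tag in enumerate(labels):
        role, cat = parse_tag(tag)
        if role == "B":
            if start is not None:
                spans.append(Span(start, i, cur_cat or BARE_CATEGORY))
            start, cur_cat = i, cat
        elif role == "I":
            continue
        else:  # O
            if start is not None:
                spans.append(Span(start, i, cur_cat or BARE_CATEGORY))
                start = None
    if start is not None:
        spans.append(Span(start, len(labels), cur_cat or BARE_CATEGORY))
    return spans


def bio_from_spans(spans: list[Span], n: int, bare: bool | None = None) -> list[str]:
    """Render sorted non-overlapping spans as a BIO sequence of length ``n``.

    With ``bare=True`` tags are emitted without a category suffix (single-
    category corpora); the default (``None``) emits bare tags exactly for the
    implicit :data:`BARE_CATEGORY`, making this the inverse of
    :func:`spans_from_bio`. Raises :class:`OverlapError` on overlapping spans.
    """
    labels = ["O"] * n
    prev_end = 0
    for sp in sorted(spans):
        if sp.start < prev_end:
            raise OverlapError(f"span {sp} overlaps previous span ending at {prev_end}")
        if sp.end > n:
            raise ValueError(f"span {sp} exceeds sentence length {n}")
        if bare is None:
            cat = None if sp.category == BARE_CATEGORY else sp.category
        else:
            cat = None if bare else sp.category
        labels[sp.start] = make_tag("B", cat)
        for i in range(sp.start + 1, sp.end):
            labels[i] = make_tag("I", cat)
        prev_end = sp.end
    return labels
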