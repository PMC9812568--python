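"""CoNLL-style corpus reading and writing.

Two-column token/label text, one token per line, blank line between
sentences - the layout the standard BioNER corpora (NCBI-disease, BC2GM,
BC5CDR-chem) ship in. The default dialect is tab-separated; a whitespace-run
separator is accepted on read. Round-trip read-write-read is the identity on
well-formed files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .corpus import Corpus, IllegalTransitionError, Sentence, validate_bio

logger = logging.getLogger(__name__)

__all__ = [
    "ConllDialect",
    "DEFAULT_DIALECT",
    "EmptyFileError",
    "ParseError",
    "load_config",
    "read_conll",
    "write_conll",
]


class ParseError(ValueError):
    """Malformed corpus file; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class EmptyFileError(ValueError):
    """The corpus file contains no sentences."""


@dataclass(frozen=True)
class ConllDialect:
    """Separator and layout conventions of a CoNLL-style file.

    ``separator=None`` splits on any whitespace run when reading (written
    files then use a single tab). ``label_column`` indexes the label field;
    the token is always column 0.
    """

    separator: str | None = "\t"
    label_column: int = 1
    comment_prefix: str | None = None
    encoding: str = "utf-8"


DEFAULT_DIALECT = ConllDialect()


def read_conll(
    path: str | Path,
    dialect: ConllDialect = DEFAULT_DIALECT,
    repair: bool = False,
    split: str = "train",
    labeled: bool = True,
) -> Corpus:
    """Read a blank-line-delimited two-column corpus.

    With ``repair=True`` illegal BIO transitions are rewritten (I after O
    becomes B) with a logged warning; otherwise they raise. ``labeled=False``
    reads token-only files (one column).
    """
    path = Path(path)
    sentences: list[Sentence] = []
    tokens: list[str] = []
    labels: list[str] = []
    sent_start = 1

    def flush(lineno: int) -> None:
        nonlocal tokens, labels, sent_start
        if not tokens:
            return
        labs: list[str] | None = labels if labeled else None
        if labs is not None:
            try:
                repaired = validate_bio(labs, repair=repair)
            except IllegalTransitionError as e:
                raise ParseError(sent_start + e.index, str(e)) from e
            if repaired != labs:
                logger.warning(
                    "%s: repaired illegal BIO labels in sentence starting at line %d",
                    path,
                    sent_start,
                )
            labs = repaired
        sentences.append(Sentence(tokens=tokens, labels=labs, id=f"{split}-{len(sentences)}"))
        tokens, labels = [], []

    lineno = 0
    for lineno, raw in enumerate(path.read_text(encoding=dialect.encoding).splitlines(), start=1):
        line = raw.rstrip()
        if dialect.comment_prefix and line.startswith(dialect.comment_prefix):
            continue
        if not line:
            flush(lineno)
            sent_start = lineno + 1
            continue
        parts = line.split(dialect.separator) if dialect.separator else line.split()
        if labeled:
            if len(parts) <= dialect.label_column:
                raise ParseError(lineno, f"expected a label in column {dialect.label_column}")
            tokens.append(parts[0])
            labels.append(parts[dialect.label_column])
        else:
            tokens.append(parts[0])
    flush(lineno + 1)

    if not sentences:
        raise EmptyFileError(f"no sentences in {path}")
    return Corpus.from_sentences(sentences, split=split)


def write_conll(
    corpus: Corpus,
    path: str | Path,
    dialect: ConllDialect = DEFAULT_DIALECT,
    predictions: list[list[str]] | None = None,
) -> None:
    """Write a corpus (or a corpus plus predicted labels) deterministically."""
    sep = dialect.separator or "\t"
    blocks = []
    if len(corpus) == 0:
        logger.warning("writing empty corpus to %s", path)
    for i, sent in enumerate(corpus):
        labels = predictions[i] if predictions is not None else sent.labels
        if labels is None:
            labels = ["O"] * len(sent)
        blocks.append("\n".join(f"{t}{sep}{l}" for t, l in zip(sent.tokens, labels, strict=True)))
    Path(path).write_text(
        "\n\n".join(blocks) + ("\n" if blocks else ""), encoding=dialect.encoding
    )


def load_config(path: str | Path) -> dict:
    """Flat key-value config file (YAML mapping of scalars)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return data
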