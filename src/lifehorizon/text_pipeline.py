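"""Normalization pipeline for clinical free text (notes and letters).

Clinical notes are noisy: non-standardized abbreviations, spelling errors,
telegram style, and (in letters) greeting/signature boilerplate. The
pipeline runs, in order: boilerplate stripping (letters only) ->
lower-casing and tokenization -> abbreviation expansion -> synonym mapping
-> lexicon-based spelling correction -> optional annotator hook
(e.g. a lemmatizer; the default is pass-through). Every stage preserves
token order and the full pipeline is idempotent on its own output.

Lexicons are TSV files (``key<TAB>value``, lower-case, one entry per
line); small illustrative defaults ship with the package and callers may
supply their own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable

import edlib

from .emr_data import Document, DocType

__all__ = [
    "LexiconSet",
    "TokenizedDocument",
    "load_default_lexicons",
    "strip_boilerplate",
    "normalize_and_tokenize",
    "expand_abbreviations",
    "map_synonyms",
    "correct_spelling",
    "preprocess_document",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)

#: Default patterns for letter boilerplate. A leading block of lines
#: matching a header pattern (greetings, address lines) and a trailing
#: block starting at the first footer match (sign-offs, signatures) are
#: removed from letters.
DEFAULT_HEADER_PATTERNS = (
    r"^\s*(dear|geachte|beste)\b",
    r"^\s*(betreft|re|subject)\s*:",
    r"^\s*\d{4}\s?[a-z]{2}\b",  # Dutch postal code line
)
DEFAULT_FOOTER_PATTERNS = (
    r"^\s*(kind regards|yours sincerely|sincerely|hoogachtend|met vriendelijke groet)\b",
    r"^\s*(dr|drs|prof)\.\s",
)


@dataclass
class LexiconSet:
    """Abbreviation, synonym, and spelling lexicons for the pipeline.

    Maps must be non-cyclic: no expansion/canonical form may itself be a
    key, so that each mapping stage is idempotent.
    """

    abbreviations: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, str] = field(default_factory=dict)
    spelling_lexicon: set[str] = field(default_factory=set)
    header_patterns: tuple[str, ...] = DEFAULT_HEADER_PATTERNS
    footer_patterns: tuple[str, ...] = DEFAULT_FOOTER_PATTERNS

    def __post_init__(self) -> None:
        for name, mapping in (
            ("abbreviations", self.abbreviations),
            ("synonyms", self.synonyms),
        ):
            for key, value in mapping.items():
                if key != key.lower() or value != value.lower():
                    raise ValueError(f"{name} entries must be lower-case: {key!r}")
                for word in value.split():
                    if word in mapping:
                        raise ValueError(
                            f"{name} map is cyclic: expansion {word!r} is itself a key"
                        )


@dataclass
class TokenizedDocument:
    doc_type: DocType
    tokens: list[str]
    source_month: int  # death-anchored month index, 1..61

    def __post_init__(self) -> None:
        if not (1 <= self.source_month <= 61):
            raise ValueError(f"source_month {self.source_month} outside 1..61")


def _read_tsv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        out[key.strip()] = value.strip()
    return out


def load_default_lexicons() -> LexiconSet:
    """Load the small illustrative lexicons shipped with the package."""
    data = resources.files("lifehorizon") / "data"
    with resources.as_file(data) as d:
        abbreviations = _read_tsv(d / "abbreviations.tsv")
        synonyms = _read_tsv(d / "synonyms.tsv")
        words = {
            w.strip()
            for w in (d / "spelling_lexicon.txt").read_text("utf-8").splitlines()
            if w.strip() and not w.startswith("#")
        }
    return LexiconSet(abbreviations=abbreviations, synonyms=synonyms, spelling_lexicon=words)


def strip_boilerplate(text: str, doc_type: DocType, lexicons: LexiconSet | None = None) -> str:
    """Remove header/footer blocks from letters; notes pass through unchanged."""
    if doc_type is not DocType.LETTER or not text:
        return text
    lex = lexicons or LexiconSet()
    headers = [re.compile(p, re.IGNORECASE) for p in lex.header_patterns]
    footers = [re.compile(p, re.IGNORECASE) for p in lex.footer_patterns]
    lines = text.splitlines()
    start = 0
    while start < len(lines) and (
        not lines[start].strip() or any(p.search(lines[start]) for p in headers)
    ):
        start += 1
    end = len(lines)
    for i in range(start, len(lines)):
        if any(p.search(lines[i]) for p in footers):
            end = i
            break
    return "\n".join(lines[start:end]).strip()


def normalize_and_tokenize(text: str) -> list[str]:
    """Lower-case and split into word tokens, dropping punctuation and markup."""
    return _TOKEN_RE.findall(text.lower())


def expand_abbreviations(tokens: list[str], lexicons: LexiconSet) -> list[str]:
    """Replace abbreviation keys by their expansions (multi-word spliced in order)."""
    out: list[str] = []
    for tok in tokens:
        expansion = lexicons.abbreviations.get(tok)
        if expansion is None:
            out.append(tok)
        else:
            out.extend(expansion.split())
    return out


def map_synonyms(tokens: list[str], lexicons: LexiconSet) -> list[str]:
    """Map variant tokens to their canonical concept (idempotent)."""
    return [lexicons.synonyms.get(tok, tok) for tok in tokens]


def _edit_distance(a: str, b: str, limit: int) -> int:
    res = edlib.align(a, b, task="distance", k=limit)
    d = res["editDistance"]
    return d if d >= 0 else limit + 1


def correct_spelling(
    tokens: list[str], lexicons: LexiconSet, max_edit_distance: int = 1
) -> list[str]:
    """Replace out-of-lexicon tokens by the unique nearest lexicon word.

    A token already in the lexicon is never touched. If no lexicon word
    lies within ``max_edit_distance``, or several are tied at the minimal
    distance, the token is left unchanged (conservative tie-break).
    """
    if max_edit_distance < 1:
        raise ValueError("max_edit_distance must be >= 1")
    lexicon = lexicons.spelling_lexicon
    cache: dict[str, str] = {}
    out: list[str] = []
    for tok in tokens:
        if tok in lexicon or not tok.isalpha():
            out.append(tok)
            continue
        if tok not in cache:
            best_d = max_edit_distance + 1
            best: list[str] = []
            for word in lexicon:
                if abs(len(word) - len(tok)) > max_edit_distance:
                    continue
                d = _edit_distance(tok, word, max_edit_distance)
                if d > max_edit_distance:
                    continue
                if d < best_d:
                    best_d, best = d, [word]
                elif d == best_d:
                    best.append(word)
            cache[tok] = best[0] if len(best) == 1 else tok
        out.append(cache[tok])
    return out


AnnotatorHook = Callable[[list[str]], list[str]]


def preprocess_document(
    doc: Document,
    month: int,
    lexicons: LexiconSet,
    max_edit_distance: int = 1,
    annotator: AnnotatorHook | None = None,
) -> TokenizedDocument:
    """Run the full pipeline on one document.

    ``month`` is the death-anchored month index (1 = earliest, 61 = the
    month containing death). ``annotator`` is an optional tokens-in /
    tokens-out hook (e.g. a lemmatizer); the default passes tokens through.
    """
    text = strip_boilerplate(doc.text, doc.doc_type, lexicons)
    tokens = normalize_and_tokenize(text)
    tokens = expand_abbreviations(tokens, lexicons)
    tokens = map_synonyms(tokens, lexicons)
    tokens = correct_spelling(tokens, lexicons, max_edit_distance)
    if annotator is not None:
        tokens = annotator(tokens)
    return TokenizedDocument(doc_type=doc.doc_type, tokens=tokens, source_month=month)
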