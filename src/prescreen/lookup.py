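"""Terminology lookup with synonym closure.

Criteria authoring needs code search over three small vocabularies (ICD-9
diagnoses, laboratory tests, drug codes). A defect this module is designed
against: search results that differ between a brand name and its generic
synonym ("tylenol" finding one record while "acetaminophen" finds several).
The contract here is *synonym closure*: two queries that the vocabulary
itself declares synonymous return the same result set.

Matching is case-folded substring matching over an entry's preferred name
and all its synonyms, after expanding the query through synonym equivalence
classes (terms co-occurring in any entry's term set are equivalent).
Results are ranked exact > prefix > substring, ties broken by code, so the
ordering is total and deterministic.

Vocabularies ship as CSV: ``code,preferred_name,synonyms`` with synonyms
pipe-delimited. A small fixture vocabulary is bundled for tests and demos;
it is illustrative, not a licensed terminology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = ["VocabularyEntry", "load_vocabulary", "bundled_vocabulary", "lookup_codes"]

VOCABULARIES = ("icd9", "lab", "drug")


@dataclass(frozen=True, slots=True)
class VocabularyEntry:
    code: str
    preferred_name: str
    synonyms: frozenset[str]
    vocabulary: str

    def terms(self) -> frozenset[str]:
        return frozenset({_norm(self.preferred_name)} | {_norm(s) for s in self.synonyms})


def _norm(text: str) -> str:
    return " ".join(text.casefold().split())


def load_vocabulary(path: str | Path, vocabulary: str) -> list[VocabularyEntry]:
    if vocabulary not in VOCABULARIES:
        raise ConfigurationError(
            f"unknown vocabulary {vocabulary!r} (expected one of "
            f"{', '.join(VOCABULARIES)})"
        )
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"vocabulary file {path} does not exist")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("code", "preferred_name", "synonyms"):
        if col not in frame.columns:
            raise ConfigurationError(f"{path.name}: missing column {col!r}")
    entries: list[VocabularyEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False)):
        code = row.code.strip()
        name = row.preferred_name.strip()
        if not name:
            raise ConfigurationError(f"{path.name} row {i}: empty preferred_name")
        if code in seen:
            raise ConfigurationError(f"{path.name} row {i}: duplicate code {code!r}")
        seen.add(code)
        synonyms = frozenset(
            s.strip() for s in row.synonyms.split("|") if s.strip()
        )
        entries.append(VocabularyEntry(code, name, synonyms, vocabulary))
    return entries


def bundled_vocabulary(vocabulary: str) -> list[VocabularyEntry]:
    """Load the bundled fixture vocabulary (illustrative, non-clinical)."""
    path = Path(__file__).parent / "data" / "vocab" / f"{vocabulary}.csv"
    return load_vocabulary(path, vocabulary)


def _synonym_classes(entries: list[VocabularyEntry]) -> dict[str, frozenset[str]]:
    """Union-find over normalized terms: terms sharing an entry are synonyms."""
    parent: dict[str, str] = {}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for e in entries:
        terms = sorted(e.terms())
        for t in terms:
            parent.setdefault(t, t)
        for t in terms[1:]:
            parent[find(terms[0])] = find(t)
    classes: dict[str, set[str]] = {}
    for t in parent:
        classes.setdefault(find(t), set()).add(t)
    return {t: frozenset(classes[find(t)]) for t in parent}


def lookup_codes(
    entries: list[VocabularyEntry], query: str
) -> list[VocabularyEntry]:
    """Search a vocabulary; see module docstring for matching and ranking.

    Raises :class:`InputError` for a query that is empty after whitespace
    normalization.
    """
    q = _norm(query)
    if not q:
        raise InputError("empty query")
    classes = _synonym_classes(entries)
    expanded = classes.get(q, frozenset({q}))

    ranked: list[tuple[int, str, VocabularyEntry]] = []
    for e in entries:
        best = None
        for term in e.terms():
            for alias in expanded:
                if alias == term:
                    rank = 0
                elif term.startswith(alias):
                    rank = 1
                elif alias in term:
                    rank = 2
                else:
                    continue
                best = rank if best is None else min(best, rank)
        if best is not None:
            ranked.append((best, e.code, e))
    ranked.sort(key=lambda item: (item[0], item[1]))
    return [e for _, _, e in ranked]
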