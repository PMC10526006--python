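"""Bag-of-words physiological theme assignment for supporting documents.

Every relationship in the knowledge graph is backed by articles; the
document unit here is one (source concept, PMID) pair with a title/abstract
surrogate text.  A theme lexicon maps each physiological theme (endocrine
function, inflammation/cytokine storm, lipid metabolism, sympathetic blood
pressure drive, viral entry, ...) to a set of lowercase tokens.  A document
is assigned single-label to the theme with the highest token-hit count;
documents hitting no lexicon token get the reserved "unknown" label.  The
theme distribution reports counts and percentages of the total.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

UNKNOWN = "unknown"

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on runs of non-alphanumeric characters."""
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


@dataclass(frozen=True)
class ThemeLexicon:
    """Ordered (theme name, token set) pairs; "unknown" is reserved."""

    themes: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.themes]
        if len(set(names)) != len(names):
            raise ValueError("theme names must be unique")
        if UNKNOWN in names:
            raise ValueError(f"{UNKNOWN!r} is reserved for unmatched documents")
        for name, tokens in self.themes:
            if not tokens:
                raise ValueError(f"theme {name!r} has an empty token set")
            if any(t != t.lower() for t in tokens):
                raise ValueError(f"theme {name!r} tokens must be lowercase")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.themes]

    @classmethod
    def from_dict(cls, mapping: dict[str, Iterable[str]]) -> "ThemeLexicon":
        return cls(
            tuple((name, frozenset(tokens)) for name, tokens in mapping.items())
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThemeLexicon":
        """Load a ``{"themes": {name: [token, ...]}}`` JSON file."""
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls.from_dict(raw["themes"])

    def to_json(self, path: str | Path) -> None:
        doc = {"themes": {name: sorted(tokens) for name, tokens in self.themes}}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")


def default_lexicon() -> ThemeLexicon:
    """The shipped six-theme lexicon (illustrative token lists, editable)."""
    return ThemeLexicon.from_json(Path(__file__).parent / "data" / "default_lexicon.json")


@dataclass(frozen=True)
class RelationshipDocument:
    """One supporting article for one source concept."""

    cui: str
    pmid: str
    text: str


def assign_theme(text: str, lexicon: ThemeLexicon) -> tuple[str, bool]:
    """Single-label theme of one document; returns (theme, was_tie).

    The winning theme has the maximum token-hit count (token occurrences are
    counted, so repeated words weigh more).  Zero hits — including empty
    text — yield "unknown".  Ties go to the earliest theme in lexicon order
    and are flagged so callers can log them.
    """
    tokens = tokenize(text)
    best_name, best_hits, tie = UNKNOWN, 0, False
    for name, vocab in lexicon.themes:
        hits = sum(1 for t in tokens if t in vocab)
        if hits > best_hits:
            best_name, best_hits, tie = name, hits, False
        elif hits == best_hits and hits > 0 and name != best_name:
            tie = True
    return best_name, tie


def assign_themes(
    docs: Sequence[RelationshipDocument], lexicon: ThemeLexicon
) -> tuple[list[str], int]:
    """Labels for a document collection plus the number of scoring ties."""
    labels, ties = [], 0
    for doc in docs:
        label, tie = assign_theme(doc.text, lexicon)
        labels.append(label)
        ties += tie
    return labels, ties


def theme_distribution(
    assignments: Sequence[str], lexicon: ThemeLexicon | None = None
) -> pd.DataFrame:
    """Counts and percentages per theme (always including "unknown").

    Rows follow lexicon order when a lexicon is given, else sorted label
    order; percentages sum to 100 up to float rounding.
    """
    if not len(assignments):
        raise ValueError("theme_distribution requires at least one assignment")
    counts = pd.Series(assignments).value_counts()
    order = (
        lexicon.names + [UNKNOWN]
        if lexicon is not None
        else sorted(set(counts.index) | {UNKNOWN})
    )
    rows = [
        {
            "theme": name,
            "count": int(counts.get(name, 0)),
            "percentage": 100.0 * counts.get(name, 0) / len(assignments),
        }
        for name in order
    ]
    return pd.DataFrame(rows, columns=["theme", "count", "percentage"])


def load_corpus(path: str | Path) -> list[RelationshipDocument]:
    """Read a (cui, pmid, text) TSV corpus; '#' lines are comments."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            docs.append(RelationshipDocument(*parts))
    return docs


def write_corpus(docs: Sequence[RelationshipDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#cui\tpmid\ttext\n")
        for doc in docs:
            fh.write(f"{doc.cui}\t{doc.pmid}\t{doc.text}\n")
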