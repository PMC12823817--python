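"""Target-event definition by preferred-term list, and drug-name normalization.

The target adverse event is defined the way a Standardised MedDRA Query
is used in practice: a list of preferred terms, each labeled ``narrow``
(highly specific for the condition) or ``wide`` (sensitive but less
specific), matched exactly on normalized strings against each report's
reaction terms.  The MedDRA dictionary itself is licensed, so term lists
are user-supplied configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .records import AEReport

SCOPES = ("narrow", "wide")
MATCH_NARROW = "narrow-only"
MATCH_BOTH = "narrow+wide"

_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^a-z0-9 ]+")

#: salt/formulation tokens stripped from the tail of drug names by default
DEFAULT_SALT_SUFFIXES = (
    "hcl",
    "hydrochloride",
    "sodium",
    "disodium",
    "potassium",
    "calcium",
    "sulfate",
    "acetate",
    "tartrate",
    "maleate",
    "mesylate",
    "besylate",
    "citrate",
)


def normalize_pt(term: str) -> str:
    """Case-fold and collapse whitespace; the equality used for all PT matching."""
    return _WS.sub(" ", term.strip().casefold())


@dataclass
class PTQuery:
    """A named preferred-term list defining one target adverse event."""

    name: str
    terms: set[tuple[str, str]]  # (normalized pt, scope)
    match_scope: str = MATCH_BOTH

    def active_terms(self) -> set[str]:
        if self.match_scope == MATCH_NARROW:
            return {pt for pt, scope in self.terms if scope == "narrow"}
        return {pt for pt, _ in self.terms}


@dataclass
class DrugSynonymMap:
    """Alias -> canonical active-ingredient map plus strippable salt tokens.

    Canonical names must be fixed points: mapping a canonical name returns
    itself, so normalization is idempotent.
    """

    entries: dict[str, str] = field(default_factory=dict)
    salt_suffixes: tuple[str, ...] = DEFAULT_SALT_SUFFIXES

    def __post_init__(self) -> None:
        self.entries = {normalize_pt(k): normalize_pt(v) for k, v in self.entries.items()}
        bad = [v for v in self.entries.values() if self.entries.get(v, v) != v]
        if bad:
            raise ValueError(f"canonical names are not fixed points of the map: {sorted(set(bad))}")


def load_pt_query(path: str | Path, name: str | None = None, match_scope: str = MATCH_BOTH) -> PTQuery:
    """Load a two-column (term, scope) delimited text file into a :class:`PTQuery`.

    Tab- or comma-delimited; lines starting with ``#`` are comments.
    Duplicate terms are deduplicated; an empty file or an unknown scope
    label is a hard error naming the offending line.
    """
    path = Path(path)
    terms: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'term<delim>scope', got {line!r}")
            term, scope = normalize_pt(parts[0]), parts[1].strip().lower()
            if scope not in SCOPES:
                raise ValueError(f"{path}:{lineno}: unknown scope {scope!r} (expected narrow|wide)")
            terms.add((term, scope))
    if not terms:
        raise ValueError(f"{path}: preferred-term list is empty")
    return PTQuery(name=name or path.stem, terms=terms, match_scope=match_scope)


def normalize_drug(raw_name: str, synonym_map: DrugSynonymMap | None = None) -> str:
    """Reduce a verbatim drug string to a canonical active-ingredient key.

    Case-fold, strip punctuation, drop trailing salt tokens, then apply the
    alias map; an unmapped name comes back in its normalized surface form.
    """
    name = _PUNCT.sub(" ", raw_name.casefold())
    name = _WS.sub(" ", name).strip()
    salts = synonym_map.salt_suffixes if synonym_map else DEFAULT_SALT_SUFFIXES
    tokens = name.split(" ")
    while len(tokens) > 1 and tokens[-1] in salts:
        tokens.pop()
    name = " ".join(tokens)
    if synonym_map:
        name = synonym_map.entries.get(name, name)
    return name


def select_cases(reports: list[AEReport], query: PTQuery) -> set[str]:
    """Primaryids of reports with at least one reaction PT in the query's active scope."""
    active = query.active_terms()
    return {
        r.primaryid
        for r in reports
        if any(normalize_pt(pt) in active for pt in r.reactions)
    }
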