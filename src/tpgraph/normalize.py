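"""Text cleanup and consensus display naming.

Community-contributed reaction tables spell the same compound many ways
("TFA", "trifluoroacetic acid", IUPAC strings with dozens of locants).
For display, one name is chosen per compound by majority vote: the name
mentioned most often across the compound table and every reaction row
wins, with ties broken toward shorter names and finally lexicographically
so selection is deterministic and order-independent.  All collected names
are retained on the record for searching.

Very long winners (>100 characters) or heavily punctuated ones (>20
special characters, where a special character is anything that is not an
ASCII letter, digit or space) are unreadable in a graph display and are
replaced by the compound identifier rendered as ``CID <n>``.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .tables_io import CompoundRecord, ReactionRecord

__all__ = [
    "NameCandidate",
    "CleanReport",
    "clean_text",
    "count_special_chars",
    "consensus_name",
    "display_name",
    "collect_names",
    "MAX_NAME_LENGTH",
    "MAX_SPECIAL_CHARS",
]

#: display-name trimming thresholds
MAX_NAME_LENGTH = 100
MAX_SPECIAL_CHARS = 20

_WS_RUN = re.compile(r"\s+")
_SPECIAL = re.compile(r"[^A-Za-z0-9 ]")


@dataclass(frozen=True)
class NameCandidate:
    """A candidate display name with its mention frequency."""

    name: str
    frequency: int = 1

    @property
    def length(self) -> int:
        return len(self.name)

    @property
    def special_count(self) -> int:
        return count_special_chars(self.name)


@dataclass
class CleanReport:
    """Audit trail of text fixes applied during normalization."""

    rows_touched: int = 0
    fixes: list[tuple] = field(default_factory=list)  # (row id, field, before, after)

    def record(self, row_id, fld: str, before: str, after: str) -> None:
        if before != after:
            self.rows_touched += 1
            self.fixes.append((row_id, fld, before, after))


def clean_text(raw: str) -> str:
    """Normalize a free-text value: NFC, trim, collapse internal whitespace.

    Total and idempotent: ``clean_text(clean_text(s)) == clean_text(s)``.
    """
    return _WS_RUN.sub(" ", unicodedata.normalize("NFC", raw)).strip()


def count_special_chars(name: str) -> int:
    """Count characters that are neither ASCII letters, digits, nor spaces."""
    return len(_SPECIAL.findall(name))


def consensus_name(candidates: Sequence[NameCandidate]) -> str:
    """Majority-vote selection of the display name.

    Sort key: frequency descending, then length ascending, then
    lexicographic — deterministic and independent of input order.
    Always returns the name of one of the candidates.
    """
    if not candidates:
        raise ValueError("consensus_name requires at least one candidate")
    merged: Counter = Counter()
    for c in candidates:
        merged[c.name] += c.frequency
    return min(merged.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))[0]


def display_name(selected: str, cid: int) -> str:
    """Trim unwieldy consensus names to the ``CID <n>`` placeholder.

    Fires when the name exceeds 100 characters or contains more than 20
    special characters; otherwise the selection passes through unchanged.
    """
    if len(selected) > MAX_NAME_LENGTH or count_special_chars(selected) > MAX_SPECIAL_CHARS:
        return f"CID {cid}"
    return selected


def collect_names(
    compounds: Iterable[CompoundRecord],
    reactions: Iterable[ReactionRecord],
    report: CleanReport | None = None,
) -> tuple[list[CompoundRecord], list[ReactionRecord]]:
    """Populate each compound's name multiset and set its display name.

    Per CID the multiset holds the compound table's IUPAC name and title
    (once each, when present) plus every cleaned predecessor/successor
    name occurrence from reaction rows referencing that CID.  Reactions
    referencing CIDs absent from the compound table are returned as
    dangling references (graph validation resolves them).

    Mutates the compound records in place and returns
    ``(compounds, dangling_reactions)``.
    """
    report = report if report is not None else CleanReport()
    by_cid = {c.cid: c for c in compounds}
    comps = list(by_cid.values())
    for c in comps:
        c.names = Counter()
        for fld in ("iupac_name", "title"):
            raw = getattr(c, fld)
            cleaned = clean_text(raw)
            report.record(c.cid, fld, raw, cleaned)
            setattr(c, fld, cleaned)
            if cleaned:
                c.names[cleaned] += 1
    dangling: list[ReactionRecord] = []
    for i, rxn in enumerate(reactions):
        for fld, cid in (
            ("predecessor_name", rxn.predecessor_cid),
            ("successor_name", rxn.successor_cid),
        ):
            raw = getattr(rxn, fld)
            cleaned = clean_text(raw)
            report.record(i, fld, raw, cleaned)
            setattr(rxn, fld, cleaned)
            comp = by_cid.get(cid)
            if comp is None:
                if rxn not in dangling:
                    dangling.append(rxn)
            elif cleaned:
                comp.names[cleaned] += 1
    for c in comps:
        if c.names:
            candidates = [NameCandidate(n, f) for n, f in c.names.items()]
            c.display_name = display_name(consensus_name(candidates), c.cid)
        else:
            c.display_name = f"CID {c.cid}"
    return comps, dangling
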