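"""SMARTS substructure screening over compound structures.

Matching runs on molecules parsed from the SMILES column (the preferred
structure representation in the source tables); compounds whose SMILES
does not parse are skipped with a per-compound report rather than
failing the whole search.  The corpus is small (thousands of compounds),
so a plain per-pattern scan is fast; no fingerprint prescreen is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .graphmodel import TransformationGraph

__all__ = [
    "SubstructureQuery",
    "MatchResult",
    "SearchReport",
    "substructure_search",
    "batch_substructure",
]

RDLogger.DisableLog("rdApp.error")


class SmartsError(ValueError):
    """A SMARTS pattern failed to parse."""


@dataclass(frozen=True)
class SubstructureQuery:
    """Labelled SMARTS patterns; every pattern is validated on creation."""

    patterns: tuple[tuple[str, str], ...]  # (label, SMARTS)

    @classmethod
    def from_smarts(cls, patterns: Sequence[str] | dict[str, str]) -> "SubstructureQuery":
        if isinstance(patterns, dict):
            items = list(patterns.items())
        else:
            items = [(p, p) for p in patterns]
        labels = [lb for lb, _ in items]
        if len(set(labels)) != len(labels):
            raise ValueError("pattern labels must be unique")
        for label, smarts in items:
            if Chem.MolFromSmarts(smarts) is None:
                raise SmartsError(f"invalid SMARTS for {label!r}: {smarts!r}")
        return cls(tuple(items))

    def compiled(self) -> list[tuple[str, "Chem.Mol"]]:
        return [(lb, Chem.MolFromSmarts(sm)) for lb, sm in self.patterns]


@dataclass
class MatchResult:
    cid: int
    matched_labels: list[str]


@dataclass
class SearchReport:
    matches: list[MatchResult]
    unparseable: list[int] = field(default_factory=list)  # CIDs skipped

    def cids(self) -> list[int]:
        return [m.cid for m in self.matches]


def substructure_search(
    graph: TransformationGraph, query: SubstructureQuery
) -> SearchReport:
    """Return every compound matching at least one pattern, annotated
    with all matching labels, ordered by CID."""
    compiled = query.compiled()
    matches: list[MatchResult] = []
    unparseable: list[int] = []
    for cid in sorted(graph.compounds):
        c = graph.compounds[cid]
        if not c.smiles:
            continue
        mol = Chem.MolFromSmiles(c.smiles)
        if mol is None:
            unparseable.append(cid)
            continue
        labels = [lb for lb, patt in compiled if mol.HasSubstructMatch(patt)]
        if labels:
            matches.append(MatchResult(cid, labels))
    return SearchReport(matches, unparseable)


def batch_substructure(
    graph: TransformationGraph, patterns: Iterable[str] | str | Path
) -> tuple[dict[int, SearchReport], dict[int, str]]:
    """Run one search per pattern line.

    ``patterns`` is an iterable of SMARTS strings or a path to a file
    with one SMARTS per line.  Results are keyed by 1-based line number;
    invalid lines go into the error map and do not stop valid ones.
    Each result set equals the corresponding single-pattern search.
    """
    if isinstance(patterns, (str, Path)):
        patterns = Path(patterns).read_text(encoding="utf-8").splitlines()
    results: dict[int, SearchReport] = {}
    errors: dict[int, str] = {}
    for lineno, raw in enumerate(patterns, start=1):
        smarts = raw.strip()
        if not smarts:
            continue
        try:
            q = SubstructureQuery.from_smarts([smarts])
        except SmartsError as exc:
            errors[lineno] = str(exc)
            continue
        results[lineno] = substructure_search(graph, q)
    return results, errors
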