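"""Readers and writers for the transformation-product table schemas.

Two source tables drive everything downstream:

* a **compound table** (one row per chemical entity, keyed by a positive
  integer compound identifier, CID) carrying structure strings (SMILES,
  InChI, InChIKey and its 14-character first block, IKFB), molecular
  formula, monoisotopic mass, predicted XlogP, and the IUPAC name / title;
* a **reaction table** (one row per directed predecessor -> successor
  transformation) carrying reaction SMILES, biosystem, enzyme, a
  descriptive transformation label, mass / XlogP differences, and three
  paired provenance fields (dataset, evidence, source).

Both are plain UTF-8 CSV files with a header row.  Column headers in the
deposited files are matched case-insensitively against documented defaults
and can be overridden with a ``column_map`` ({schema field -> CSV header}).

Exports are written in four layouts: MetFrag suspect-list CSV, patRoon
TP-library CSV, a generic CSV that round-trips every schema field, and an
XLSX mirror of the generic layout.
"""

from __future__ import annotations

import csv
import dataclasses
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CompoundRecord",
    "ReactionRecord",
    "TableReadResult",
    "ExportTable",
    "SchemaError",
    "EXPORT_HEADERS",
    "COMPOUND_COLUMNS",
    "REACTION_COLUMNS",
    "read_compound_table",
    "read_reaction_table",
    "read_contribution_template",
    "write_export",
    "read_export",
]

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: Da tolerance when cross-checking mass_diff against endpoint masses.
MASS_DIFF_TOL = 0.01


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass
class CompoundRecord:
    """One chemical entity with identifiers, structure and descriptors."""

    cid: int
    smiles: str = ""
    inchi: str = ""
    inchikey: str = ""
    ikfb: str = ""
    formula: str = ""
    exact_mass: float | None = None
    xlogp: float | None = None
    iupac_name: str = ""
    title: str = ""
    #: name -> occurrence count, populated by normalize.collect_names
    names: Counter = field(default_factory=Counter)
    #: consensus name after trimming, set by normalize
    display_name: str = ""
    #: unknown source columns, preserved verbatim
    extras: dict = field(default_factory=dict)

    def check(self) -> list[str]:
        """Return invariant violations (empty list = clean record)."""
        problems = []
        if self.cid <= 0:
            problems.append(f"cid {self.cid} not positive")
        if self.inchikey and not INCHIKEY_RE.match(self.inchikey):
            problems.append(f"malformed InChIKey {self.inchikey!r}")
        if self.inchikey and self.ikfb and self.ikfb != self.inchikey[:14]:
            problems.append("ikfb does not match InChIKey first block")
        if self.exact_mass is not None and self.exact_mass <= 0:
            problems.append(f"non-positive exact mass {self.exact_mass}")
        return problems


@dataclass
class ReactionRecord:
    """One directed predecessor -> successor transformation."""

    predecessor_cid: int
    successor_cid: int
    predecessor_name: str = ""
    successor_name: str = ""
    reaction_smiles: str = ""
    desc_reaction_smiles: str = ""
    biosystem: str = ""
    enzyme: str = ""
    transformation: str = ""
    mass_diff: float | None = None
    xlogp_diff: float | None = None
    datasetref: str = ""
    datasetdoi: str = ""
    evidenceref: str = ""
    evidencedoi: str = ""
    sourcecommentfull: str = ""
    sourcecomment: str = ""
    #: SMILES carried by contribution templates (endpoints not yet CID-resolved)
    predecessor_smiles: str = ""
    successor_smiles: str = ""
    #: True when CIDs are placeholders pending resolution (templates)
    unresolved: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def pair(self) -> tuple[int, int]:
        """The directed (predecessor, successor) CID pair."""
        return (self.predecessor_cid, self.successor_cid)

    def mass_diff_consistent(
        self, masses: Mapping[int, float | None], tol: float = MASS_DIFF_TOL
    ) -> bool | None:
        """Check mass_diff ~= successor mass - predecessor mass.

        Returns None when either endpoint mass or mass_diff is unknown
        (nothing to check), True/False otherwise.
        """
        if self.mass_diff is None:
            return None
        mp = masses.get(self.predecessor_cid)
        ms = masses.get(self.successor_cid)
        if mp is None or ms is None:
            return None
        return math.isclose(self.mass_diff, ms - mp, abs_tol=tol)


@dataclass
class SkippedRow:
    line: int  # 1-based data-row number (header excluded)
    reason: str
    raw: dict


@dataclass
class TableReadResult:
    """Parsed records plus the per-row skip report."""

    records: list
    skipped: list[SkippedRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ExportTable:
    format_tag: str
    header: list[str]
    rows: list[list]


# ---------------------------------------------------------------------------
# Default column maps: schema field -> candidate CSV headers (first match
# wins; comparison is case-insensitive).
# ---------------------------------------------------------------------------

COMPOUND_COLUMNS: dict[str, tuple[str, ...]] = {
    "cid": ("cid", "compound_cid", "pubchem_cid"),
    "smiles": ("smiles", "canonicalsmiles", "isomericsmiles"),
    "inchi": ("inchi",),
    "inchikey": ("inchikey",),
    "ikfb": ("ikfb", "inchikey_first_block", "inchikeyfirstblock"),
    "formula": ("molecularformula", "formula", "mf"),
    "exact_mass": ("monoisotopicmass", "exactmass", "monoisotopic_mass"),
    "xlogp": ("xlogp",),
    "iupac_name": ("iupacname", "iupac_name"),
    "title": ("title", "name"),
}

REACTION_COLUMNS: dict[str, tuple[str, ...]] = {
    "predecessor_cid": ("predecessorcid", "predecessor_cid", "parentcid"),
    "successor_cid": ("successorcid", "successor_cid", "tpcid"),
    "predecessor_name": ("predecessor", "predecessorname", "predecessor_name"),
    "successor_name": ("successor", "successorname", "successor_name"),
    "reaction_smiles": ("reactionsmiles",),
    "desc_reaction_smiles": ("descreactionsmiles",),
    "biosystem": ("biosystem",),
    "enzyme": ("enzyme",),
    "transformation": ("transformation",),
    "mass_diff": ("massdiff", "mass_diff"),
    "xlogp_diff": ("xlogpdiff", "xlogp_diff"),
    "datasetref": ("datasetref",),
    "datasetdoi": ("datasetdoi",),
    "evidenceref": ("evidenceref",),
    "evidencedoi": ("evidencedoi",),
    "sourcecommentfull": ("sourcecommentfull",),
    "sourcecomment": ("sourcecomment",),
}

EXPORT_HEADERS: dict[str, list[str]] = {
    "metfrag": [
        "Identifier",
        "Name",
        "InChIKey",
        "InChI",
        "SMILES",
        "MolecularFormula",
        "MonoisotopicMass",
    ],
    "patroon": ["Name", "InChI", "SMILES", "Formula", "ExactMass"],
    "generic_csv": [
        "CID",
        "DisplayName",
        "SMILES",
        "InChI",
        "InChIKey",
        "IKFB",
        "MolecularFormula",
        "MonoisotopicMass",
        "XLogP",
        "IUPACName",
        "Title",
    ],
}
EXPORT_HEADERS["xlsx"] = EXPORT_HEADERS["generic_csv"]


def _resolve_columns(
    header: Sequence[str],
    defaults: Mapping[str, tuple[str, ...]],
    column_map: Mapping[str, str] | None,
) -> dict[str, str]:
    """Map schema fields to actual CSV header names (case-insensitive)."""
    lower = {h.strip().lower(): h for h in header}
    resolved: dict[str, str] = {}
    for fld, candidates in defaults.items():
        if column_map and fld in column_map:
            candidates = (column_map[fld],)
        for cand in candidates:
            if cand.lower() in lower:
                resolved[fld] = lower[cand.lower()]
                break
    return resolved


def _parse_int(value: str | None) -> int | None:
    if value is None:
        return None
    value = value.strip()
    if not value:
        return None
    try:
        return int(float(value)) if "." in value else int(value)
    except ValueError:
        return None


def _parse_float(value: str | None) -> float | None:
    if value is None or not value.strip():
        return None
    try:
        return float(value)
    except ValueError:
        return None


def _read_rows(path: str | Path) -> tuple[list[str], list[dict]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: file has no header row")
        return list(reader.fieldnames), list(reader)


def read_compound_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> TableReadResult:
    """Read the compound-level CSV into :class:`CompoundRecord` objects.

    Rows without a parseable CID are skipped and reported, never silently
    dropped.  Unknown columns are preserved in ``record.extras``.
    """
    header, rows = _read_rows(path)
    cols = _resolve_columns(header, COMPOUND_COLUMNS, column_map)
    if "cid" not in cols:
        raise SchemaError(
            f"{path}: no CID column found; header={header}, "
            f"expected one of {COMPOUND_COLUMNS['cid']} (or a column_map entry)"
        )
    known = set(cols.values())
    records: list[CompoundRecord] = []
    skipped: list[SkippedRow] = []
    for i, row in enumerate(rows, start=1):
        cid = _parse_int(row.get(cols["cid"]))
        if cid is None or cid <= 0:
            skipped.append(SkippedRow(i, "missing or unparseable CID", dict(row)))
            continue

        def get(fld: str) -> str:
            col = cols.get(fld)
            return (row.get(col) or "").strip() if col else ""

        records.append(
            CompoundRecord(
                cid=cid,
                smiles=get("smiles"),
                inchi=get("inchi"),
                inchikey=get("inchikey"),
                ikfb=get("ikfb"),
                formula=get("formula"),
                exact_mass=_parse_float(get("exact_mass")),
                xlogp=_parse_float(get("xlogp")),
                iupac_name=get("iupac_name"),
                title=get("title"),
                extras={k: v for k, v in row.items() if k not in known},
            )
        )
    return TableReadResult(records, skipped)


def read_reaction_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> TableReadResult:
    """Read the reaction-level CSV into :class:`ReactionRecord` objects.

    Duplicate predecessor/successor pairs are retained verbatim — the
    source data keeps parallel evidence for the same transformation, and
    de-duplication is a query-time concern.
    """
    header, rows = _read_rows(path)
    cols = _resolve_columns(header, REACTION_COLUMNS, column_map)
    for endpoint in ("predecessor_cid", "successor_cid"):
        if endpoint not in cols:
            raise SchemaError(
                f"{path}: no {endpoint} column found; header={header}, "
                f"expected one of {REACTION_COLUMNS[endpoint]}"
            )
    known = set(cols.values())
    records: list[ReactionRecord] = []
    skipped: list[SkippedRow] = []
    for i, row in enumerate(rows, start=1):
        pred = _parse_int(row.get(cols["predecessor_cid"]))
        succ = _parse_int(row.get(cols["successor_cid"]))
        if pred is None or pred <= 0 or succ is None or succ <= 0:
            skipped.append(SkippedRow(i, "missing or unparseable endpoint CID", dict(row)))
            continue

        def get(fld: str) -> str:
            col = cols.get(fld)
            return (row.get(col) or "").strip() if col else ""

        records.append(
            ReactionRecord(
                predecessor_cid=pred,
                successor_cid=succ,
                predecessor_name=get("predecessor_name"),
                successor_name=get("successor_name"),
                reaction_smiles=get("reaction_smiles"),
                desc_reaction_smiles=get("desc_reaction_smiles"),
                biosystem=get("biosystem"),
                enzyme=get("enzyme"),
                transformation=get("transformation"),
                mass_diff=_parse_float(get("mass_diff")),
                xlogp_diff=_parse_float(get("xlogp_diff")),
                datasetref=get("datasetref"),
                datasetdoi=get("datasetdoi"),
                evidenceref=get("evidenceref"),
                evidencedoi=get("evidencedoi"),
                sourcecommentfull=get("sourcecommentfull"),
                sourcecomment=get("sourcecomment"),
                extras={k: v for k, v in row.items() if k not in known},
            )
        )
    return TableReadResult(records, skipped)


# Contribution template: predecessor/successor given by name + SMILES, with
# an optional biosystem.  CIDs are unknown at submission time; records come
# back flagged `unresolved` with placeholder CIDs (resolution against an
# external registry is out of scope).  Extra condition columns (e.g. the
# 35-102 field environmental-conditions sheets) pass through unparsed.

_TEMPLATE_COLUMNS: dict[str, tuple[str, ...]] = {
    "predecessor_name": ("predecessor", "predecessorname", "parent", "parent_name"),
    "predecessor_smiles": ("predecessorsmiles", "parentsmiles", "predecessor_smiles"),
    "successor_name": ("successor", "successorname", "tp", "tp_name"),
    "successor_smiles": ("successorsmiles", "tpsmiles", "successor_smiles"),
    "biosystem": ("biosystem", "system", "matrix"),
}

#: placeholder CID for template rows awaiting resolution
UNRESOLVED_CID = 1


def read_contribution_template(path: str | Path) -> TableReadResult:
    """Read a community contribution sheet (CSV or XLSX) of proposed reactions.

    A row is accepted when each endpoint has at least a name or a SMILES;
    otherwise it is rejected with a reason.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        header, rows = _read_xlsx_rows(path)
    else:
        header, rows = _read_rows(path)
    cols = _resolve_columns(header, _TEMPLATE_COLUMNS, None)
    known = set(cols.values())
    records: list[ReactionRecord] = []
    skipped: list[SkippedRow] = []
    for i, row in enumerate(rows, start=1):
        def get(fld: str) -> str:
            col = cols.get(fld)
            return (row.get(col) or "").strip() if col else ""

        pn, ps = get("predecessor_name"), get("predecessor_smiles")
        sn, ss = get("successor_name"), get("successor_smiles")
        if not (pn or ps):
            skipped.append(SkippedRow(i, "predecessor has neither name nor SMILES", dict(row)))
            continue
        if not (sn or ss):
            skipped.append(SkippedRow(i, "successor has neither name nor SMILES", dict(row)))
            continue
        records.append(
            ReactionRecord(
                predecessor_cid=UNRESOLVED_CID,
                successor_cid=UNRESOLVED_CID,
                predecessor_name=pn,
                successor_name=sn,
                predecessor_smiles=ps,
                successor_smiles=ss,
                biosystem=get("biosystem"),
                datasetref="contribution",
                unresolved=True,
                extras={k: v for k, v in row.items() if k not in known},
            )
        )
    return TableReadResult(records, skipped)


def _read_xlsx_rows(path: Path) -> tuple[list[str], list[dict]]:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    ws = wb.active
    rows_iter = ws.iter_rows(values_only=True)
    header = [str(c) if c is not None else "" for c in next(rows_iter)]
    rows = [
        {h: ("" if c is None else str(c)) for h, c in zip(header, r)}
        for r in rows_iter
        if any(c is not None and str(c).strip() for c in r)
    ]
    wb.close()
    return header, rows


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return ""
    return str(value)


def _export_rows(records: Iterable[CompoundRecord], format_tag: str) -> list[list]:
    rows = []
    for r in records:
        name = r.display_name or r.title or r.iupac_name
        if format_tag == "metfrag":
            rows.append([_fmt(r.cid), name, r.inchikey, r.inchi, r.smiles,
                         r.formula, _fmt(r.exact_mass)])
        elif format_tag == "patroon":
            rows.append([name, r.inchi, r.smiles, r.formula, _fmt(r.exact_mass)])
        else:  # generic_csv / xlsx
            rows.append([_fmt(r.cid), name, r.smiles, r.inchi, r.inchikey,
                         r.ikfb, r.formula, _fmt(r.exact_mass), _fmt(r.xlogp),
                         r.iupac_name, r.title])
    return rows


def write_export(
    records: Sequence[CompoundRecord],
    format_tag: str,
    path: str | Path | None = None,
) -> ExportTable:
    """Build (and optionally serialize) a compound export table.

    ``metfrag`` and ``patroon`` follow the canonical suspect-screening
    column lists exactly; ``generic_csv``/``xlsx`` carry every schema
    field.  At most one row per CID is emitted (first occurrence wins).
    """
    if format_tag not in EXPORT_HEADERS:
        raise ValueError(
            f"unknown export format {format_tag!r}; choose from {sorted(EXPORT_HEADERS)}"
        )
    seen: set[int] = set()
    unique: list[CompoundRecord] = []
    for r in records:
        if r.cid not in seen:
            seen.add(r.cid)
            unique.append(r)
    table = ExportTable(format_tag, list(EXPORT_HEADERS[format_tag]),
                        _export_rows(unique, format_tag))
    if path is not None:
        path = Path(path)
        if format_tag == "xlsx":
            _write_xlsx(table, path)
        else:
            with path.open("w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(table.header)
                writer.writerows(table.rows)
    return table


def _write_xlsx(table: ExportTable, path: Path) -> None:
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "compounds"
    ws.append(table.header)
    for row in table.rows:
        ws.append(row)
    wb.save(path)


def read_export(path: str | Path) -> list[CompoundRecord]:
    """Read back a generic_csv export (round-trip counterpart of write_export)."""
    header, rows = _read_rows(path)
    expected = EXPORT_HEADERS["generic_csv"]
    if header != expected:
        raise SchemaError(f"{path}: not a generic_csv export; header={header}")
    records = []
    for row in rows:
        records.append(
            CompoundRecord(
                cid=int(row["CID"]),
                display_name=row["DisplayName"],
                smiles=row["SMILES"],
                inchi=row["InChI"],
                inchikey=row["InChIKey"],
                ikfb=row["IKFB"],
                formula=row["MolecularFormula"],
                exact_mass=_parse_float(row["MonoisotopicMass"]),
                xlogp=_parse_float(row["XLogP"]),
                iupac_name=row["IUPACName"],
                title=row["Title"],
            )
        )
    return records


def write_source_tables(
    compounds: Sequence[CompoundRecord],
    reactions: Sequence[ReactionRecord],
    compounds_path: str | Path,
    reactions_path: str | Path,
) -> None:
    """Serialize records back into the two source CSV schemas.

    Used by the fixture generator and for re-emitting cleaned tables; the
    default header spellings are used.
    """
    comp_cols = [
        ("CID", lambda r: r.cid),
        ("SMILES", lambda r: r.smiles),
        ("InChI", lambda r: r.inchi),
        ("InChIKey", lambda r: r.inchikey),
        ("IKFB", lambda r: r.ikfb),
        ("MolecularFormula", lambda r: r.formula),
        ("MonoisotopicMass", lambda r: _fmt(r.exact_mass)),
        ("XLogP", lambda r: _fmt(r.xlogp)),
        ("IUPACName", lambda r: r.iupac_name),
        ("Title", lambda r: r.title),
    ]
    rxn_fields = [
        ("predecessorcid", "predecessor_cid"),
        ("successorcid", "successor_cid"),
        ("predecessor", "predecessor_name"),
        ("successor", "successor_name"),
        ("ReactionSMILES", "reaction_smiles"),
        ("DescReactionSMILES", "desc_reaction_smiles"),
        ("biosystem", "biosystem"),
        ("enzyme", "enzyme"),
        ("transformation", "transformation"),
        ("MassDiff", "mass_diff"),
        ("XlogPDiff", "xlogp_diff"),
        ("datasetref", "datasetref"),
        ("datasetdoi", "datasetdoi"),
        ("evidenceref", "evidenceref"),
        ("evidencedoi", "evidencedoi"),
        ("sourcecommentfull", "sourcecommentfull"),
        ("sourcecomment", "sourcecomment"),
    ]
    with Path(compounds_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([c for c, _ in comp_cols])
        for r in compounds:
            writer.writerow([getter(r) for _, getter in comp_cols])
    with Path(reactions_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([c for c, _ in rxn_fields])
        for r in reactions:
            writer.writerow([_fmt(getattr(r, f)) for _, f in rxn_fields])
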