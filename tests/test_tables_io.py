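import csv

import pytest

import tpgraph as tp
from tpgraph.tables_io import EXPORT_HEADERS, SchemaError

from conftest import make_compound


def write_csv(path, header, rows):
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
    return path


class TestReadCompoundTable:
    def test_blank_cid_rows_are_skipped_with_report(self, tmp_path):
        path = write_csv(
            tmp_path / "c.csv",
            ["CID", "SMILES", "MonoisotopicMass"],
            [["1", "C", "16.031"], ["2", "CC", "30.047"], ["", "CCC", "44.06"],
             ["4", "CCCC", "58.078"], ["5", "O", "18.011"]],
        )
        result = tp.read_compound_table(path)
        assert len(result.records) == 4
        assert len(result.skipped) == 1
        assert result.skipped[0].line == 3
        assert [r.cid for r in result.records] == [1, 2, 4, 5]

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = write_csv(tmp_path / "c.csv", ["CID", "SMILES"], [])
        result = tp.read_compound_table(path)
        assert result.records == [] and result.skipped == []

    def test_missing_cid_column_is_schema_error(self, tmp_path):
        path = write_csv(tmp_path / "c.csv", ["Identifier", "SMILES"], [["1", "C"]])
        with pytest.raises(SchemaError, match="CID"):
            tp.read_compound_table(path)
        # a column_map bridges nonstandard headers
        result = tp.read_compound_table(path, column_map={"cid": "Identifier"})
        assert [r.cid for r in result.records] == [1]

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            tp.read_compound_table(tmp_path / "nope.csv")

    def test_unknown_columns_preserved_in_extras(self, tmp_path):
        path = write_csv(tmp_path / "c.csv", ["cid", "Color"], [["7", "blue"]])
        (rec,) = tp.read_compound_table(path).records
        assert rec.extras == {"Color": "blue"}

    def test_values_are_whitespace_trimmed(self, tmp_path):
        path = write_csv(tmp_path / "c.csv", ["CID", "Title"], [["7", "  atrazine "]])
        (rec,) = tp.read_compound_table(path).records
        assert rec.title == "atrazine"

    def test_fixture_file_matches_generator_counts(self, fixture_dir, ledger):
        result = tp.read_compound_table(fixture_dir / "compounds.csv")
        assert len(result.records) == ledger["n_compounds"]
        assert not result.skipped
        assert all(not r.check() for r in result.records)


class TestReadReactionTable:
    def test_duplicate_pairs_are_retained_verbatim(self, tmp_path):
        path = write_csv(
            tmp_path / "r.csv",
            ["predecessorcid", "successorcid", "datasetref"],
            [["1", "2", "DS1"], ["1", "2", "DS2"]],
        )
        result = tp.read_reaction_table(path)
        assert len(result.records) == 2
        assert [r.pair for r in result.records] == [(1, 2), (1, 2)]

    def test_missing_endpoint_column_is_schema_error(self, tmp_path):
        path = write_csv(tmp_path / "r.csv", ["predecessorcid", "datasetref"], [])
        with pytest.raises(SchemaError, match="successor_cid"):
            tp.read_reaction_table(path)

    def test_unparseable_endpoint_is_row_level_skip(self, tmp_path):
        path = write_csv(
            tmp_path / "r.csv",
            ["predecessorcid", "successorcid"],
            [["1", "2"], ["x", "3"], ["4", ""]],
        )
        result = tp.read_reaction_table(path)
        assert len(result.records) == 1
        assert [s.line for s in result.skipped] == [2, 3]

    def test_fixture_endpoint_multiset_matches_ledger(self, fixture_dir, ledger):
        result = tp.read_reaction_table(fixture_dir / "reactions.csv")
        assert len(result.records) == ledger["n_reactions"]
        from collections import Counter

        tally = Counter()
        for r in result.records:
            tally[r.predecessor_cid] += 1
            tally[r.successor_cid] += 1
        assert sorted(tally.items()) == [tuple(x) for x in ledger["endpoint_cids"]]


class TestContributionTemplate:
    def test_direct_field_mapping(self, tmp_path):
        path = write_csv(
            tmp_path / "t.csv",
            ["predecessor", "predecessorSMILES", "successor", "successorSMILES", "biosystem"],
            [["atrazine", "CCNc1nc(Cl)nc(NC(C)C)n1", "ammelide", "Nc1nc(O)nc(O)n1", "soil"]],
        )
        result = tp.read_contribution_template(path)
        (rec,) = result.records
        assert rec.biosystem == "soil"
        assert rec.predecessor_name == "atrazine"
        assert rec.successor_smiles == "Nc1nc(O)nc(O)n1"
        assert rec.unresolved

    def test_empty_template(self, tmp_path):
        path = write_csv(tmp_path / "t.csv", ["predecessor", "successor"], [])
        assert tp.read_contribution_template(path).records == []

    def test_row_without_endpoint_identity_is_rejected(self, tmp_path):
        path = write_csv(
            tmp_path / "t.csv",
            ["predecessor", "successor"],
            [["atrazine", ""], ["", "ammelide"], ["a", "b"]],
        )
        result = tp.read_contribution_template(path)
        assert len(result.records) == 1
        assert len(result.skipped) == 2
        assert "successor" in result.skipped[0].reason

    def test_condition_columns_pass_through_unparsed(self, tmp_path):
        header = ["predecessor", "successor", "soil pH", "temperature (C)", "half-life"]
        path = write_csv(
            tmp_path / "bart.csv",
            header,
            [["a", "b", "6.5", "20", "14d"], ["c", "d", "7.0", "25", ""],
             ["e", "f", "", "18", "3d"]],
        )
        result = tp.read_contribution_template(path)
        assert len(result.records) == 3
        assert result.records[0].extras == {
            "soil pH": "6.5", "temperature (C)": "20", "half-life": "14d"
        }

    def test_xlsx_template_reads_like_csv(self, tmp_path):
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.append(["predecessor", "successor", "biosystem"])
        ws.append(["atrazine", "ammelide", "soil"])
        path = tmp_path / "t.xlsx"
        wb.save(path)
        (rec,) = tp.read_contribution_template(path).records
        assert (rec.predecessor_name, rec.successor_name, rec.biosystem) == (
            "atrazine", "ammelide", "soil"
        )


class TestExports:
    @pytest.fixture
    def records(self):
        a = make_compound(1, mass=206.130680, smiles="CC(C)Cc1ccc(cc1)C(C)C(=O)O")
        a.display_name, a.inchikey, a.inchi, a.formula = (
            "ibuprofen", "HEFNNWSXXWATRW-UHFFFAOYSA-N", "InChI=1S/...", "C13H18O2")
        a.ikfb = a.inchikey[:14]
        b = make_compound(2, mass=113.992, smiles="OC(=O)C(F)(F)F")
        b.display_name = "TFA"
        return [a, b]

    def test_metfrag_layout(self, records):
        table = tp.write_export(records, "metfrag")
        assert table.header == ["Identifier", "Name", "InChIKey", "InChI",
                                "SMILES", "MolecularFormula", "MonoisotopicMass"]
        assert len(table.rows) == 2
        assert table.rows[0][0] == "1" and table.rows[0][1] == "ibuprofen"

    def test_patroon_layout(self, records):
        table = tp.write_export(records, "patroon")
        assert table.header == ["Name", "InChI", "SMILES", "Formula", "ExactMass"]
        assert table.rows[1][0] == "TFA"

    def test_empty_selection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        tp.write_export([], "metfrag", path)
        lines = path.read_text().splitlines()
        assert lines == ["Identifier,Name,InChIKey,InChI,SMILES,MolecularFormula,MonoisotopicMass"]

    def test_unknown_format_is_usage_error(self, records):
        with pytest.raises(ValueError, match="unknown export format"):
            tp.write_export(records, "sdf")

    def test_duplicate_cids_exported_once(self, records):
        table = tp.write_export(records + records, "metfrag")
        assert len(table.rows) == 2

    def test_generic_csv_round_trip_is_identity(self, tmp_path, tables):
        compounds, reactions, _ = tables
        compounds, _ = tp.collect_names(list(compounds), list(reactions))
        path = tmp_path / "generic.csv"
        tp.write_export(compounds, "generic_csv", path)
        back = tp.read_export(path)
        assert len(back) == len(compounds)
        for orig, rt in zip(sorted(compounds, key=lambda c: c.cid),
                            sorted(back, key=lambda c: c.cid)):
            for fld in ("cid", "display_name", "smiles", "inchi", "inchikey",
                        "ikfb", "formula", "exact_mass", "xlogp", "iupac_name", "title"):
                assert getattr(orig, fld) == getattr(rt, fld), fld

    def test_xlsx_mirrors_generic_columns(self, tmp_path, records):
        path = tmp_path / "out.xlsx"
        table = tp.write_export(records, "xlsx", path)
        assert table.header == EXPORT_HEADERS["generic_csv"]
        from openpyxl import load_workbook

        ws = load_workbook(path).active
        assert [c.value for c in ws[1]] == EXPORT_HEADERS["generic_csv"]
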