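"""Table readers/writers: year parsing, invariants, round-trip."""

import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbcat import (
    Backbone,
    BackboneEntry,
    DwcIOError,
    read_assessments,
    read_backbone,
    read_occurrences,
    write_checklist,
)
from herbcat._text import CURRENT_YEAR, MIN_COLLECTION_YEAR, parse_year
from herbcat.dwc_io import CHECKLIST_COLUMNS


def oracle_year(s: str) -> int | None:
    """Independent brute-force scan for a standalone 4-digit token."""
    for i in range(len(s) - 3):
        tok = s[i : i + 4]
        if not tok.isdigit():
            continue
        if i > 0 and s[i - 1].isdigit():
            continue
        if i + 4 < len(s) and s[i + 4].isdigit():
            continue
        y = int(tok)
        if MIN_COLLECTION_YEAR <= y <= CURRENT_YEAR:
            return y
    return None


@pytest.mark.parametrize("text", ["1942-03-10", "10/03/1942", "1942"])
def test_parse_year_dialects(text):
    assert parse_year(text) == 1942


@pytest.mark.parametrize(
    "text", ["", "s.d.", "unknown", "03/10", "17491", "1749", "3019", "12345678"]
)
def test_parse_year_rejects_nonyears(text):
    assert parse_year(text) is None


@settings(max_examples=1000, derandomize=True)
@given(st.text(alphabet=string.digits + string.ascii_letters + "-/. ", max_size=20))
def test_parse_year_matches_bruteforce_oracle(text):
    assert parse_year(text) == oracle_year(text)


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def test_read_occurrences_counts_every_row(tmp_path):
    f = tmp_path / "occ.tsv"
    _write(f, [
        "catalogNumber\tscientificName\tEventDate",
        "RB1\tAus bus\t1942-03-10",
        "RB2\tAus cus\tsine data",
        "RB3\tAus dus\t",
    ])
    records, report = read_occurrences(f)
    assert report.n_rows == report.n_records == 3
    assert [r.collection_year for r in records] == [1942, None, None]
    assert report.n_year_parsed == 1
    assert report.n_year_unparseable == 1
    assert report.n_year_absent == 1


def test_read_occurrences_empty_file_header_only(tmp_path):
    f = tmp_path / "occ.tsv"
    _write(f, ["catalogNumber\tscientificName"])
    records, report = read_occurrences(f)
    assert records == []
    assert report.n_rows == report.n_records == 0


def test_missing_mandatory_column_names_it(tmp_path):
    f = tmp_path / "occ.tsv"
    _write(f, ["catalogNumber\tlocality", "RB1\tItatiaia"])
    with pytest.raises(DwcIOError, match="scientificName"):
        read_occurrences(f)


def test_duplicate_catalog_number_is_hard_error(tmp_path):
    f = tmp_path / "occ.tsv"
    _write(f, [
        "catalogNumber\tscientificName",
        "RB1\tAus bus",
        "RB1\tAus cus",
    ])
    with pytest.raises(DwcIOError, match="RB1"):
        read_occurrences(f)


def test_unknown_columns_preserved_as_extras(tmp_path):
    f = tmp_path / "occ.tsv"
    _write(f, [
        "catalogNumber\tscientificName\tweirdColumn",
        "RB1\tAus bus\tpayload",
    ])
    records, _ = read_occurrences(f)
    assert records[0].extras["weirdColumn"] == "payload"


def test_backbone_invariants():
    with pytest.raises(DwcIOError, match="missing"):
        Backbone([BackboneEntry(name="A b", status="synonym", accepted_name="X y")])
    with pytest.raises(DwcIOError, match="non-accepted"):
        Backbone([
            BackboneEntry(name="A b"),
            BackboneEntry(name="C d", status="synonym", accepted_name="A b"),
            BackboneEntry(name="E f", status="synonym", accepted_name="C d"),
        ])
    with pytest.raises(DwcIOError, match="duplicate"):
        Backbone([BackboneEntry(name="A b"), BackboneEntry(name="A b")])


def test_read_backbone_naturalised_is_non_native(tmp_path):
    f = tmp_path / "bb.tsv"
    _write(f, [
        "name\tauthor\tstatus\tacceptedName\tgroup\tfamily\torigin\tendemicToCountry\tlifeForms\tvegetationTypes",
        "Aus bus\tL.\taccepted\tAus bus\tangiosperm\tAusaceae\tnaturalised\tFalse\t\t",
        "Aus cus\tL.\tsynonym\tAus bus\tangiosperm\tAusaceae\tnative\t\t\t",
    ])
    bb = read_backbone(f)
    assert len(bb) == 2
    assert bb.get("Aus bus").origin == "non_native"
    assert bb.accepted_entry("Aus cus").name == "Aus bus"


def test_read_assessments_validates_categories(tmp_path):
    f = tmp_path / "thr.tsv"
    _write(f, ["speciesName\tcategory", "Araucaria angustifolia\tEN"])
    table = read_assessments(f)
    assert table["Araucaria angustifolia"] == "EN"
    assert table.get("Absent species", "NE") == "NE"

    bad = tmp_path / "bad.tsv"
    _write(bad, ["speciesName\tcategory", "Aus bus\tXX"])
    with pytest.raises(DwcIOError, match="XX"):
        read_assessments(bad)


def test_checklist_layout_and_roundtrip(tmp_path, small_dataset):
    paths, _ = small_dataset
    records, _ = read_occurrences(paths.occurrences)
    out = tmp_path / "checklist.tsv"
    write_checklist(records, out)
    header = out.read_text(encoding="utf-8").splitlines()[0].split("\t")
    assert tuple(header[:19]) == CHECKLIST_COLUMNS  # verbatim 19 labels, taxonRank twice
    reread, _ = read_occurrences(out)
    assert reread == records


def test_checklist_preserves_type_status(tmp_path, small_dataset):
    paths, _ = small_dataset
    records, _ = read_occurrences(paths.occurrences)
    records[0].type_status = "holotype"
    out = tmp_path / "checklist.tsv"
    write_checklist(records, out)
    reread, _ = read_occurrences(out)
    assert reread[0].type_status == "holotype"


def test_write_checklist_refuses_empty(tmp_path):
    with pytest.raises(DwcIOError):
        write_checklist([], tmp_path / "empty.tsv")
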