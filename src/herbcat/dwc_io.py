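"""Reading and writing the pipeline's tabular formats.

Occurrence tables, the taxonomic backbone, threat assessments, the
checklist output and the cleaning ledger are all plain delimited text
with UTF-8 encoding. The occurrence layout defaults to the 19-column
Darwin Core export used by the Catálogo de Plantas das Unidades de
Conservação checklists (which, verbatim, lists ``taxonRank`` twice);
a configurable column map lets non-standard dumps (e.g. raw JABOT
exports) be ingested without rewriting headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._text import fold, parse_year

GROUPS = ("angiosperm", "gymnosperm", "lycophyte_fern")
UNKNOWN_GROUP = "unknown"

THREAT_CATEGORIES = ("CR", "EN", "VU", "NT", "LC", "DD", "NE")
#: Categories that make a species eligible for conservation priority.
PRIORITY_CATEGORIES = frozenset({"CR", "EN", "VU", "DD"})

LIFE_FORMS = ("tree", "shrub", "subshrub", "liana", "herb")

#: The 19 verbatim column labels of the published checklist layout.
#: ``taxonRank`` appears twice in the published table; both carry the
#: rank of the identification.
CHECKLIST_COLUMNS = (
    "taxonID",
    "scientificName",
    "kingdom",
    "family",
    "genus",
    "specificEpithet",
    "taxonRank",
    "scientificNameAuthorship",
    "modified",
    "rightsHolder",
    "typeStatus",
    "taxonRank",
    "collectionCode",
    "catalogNumber",
    "locality",
    "recordedBy",
    "EventDate",
    "verbatimLongitude",
    "verbatimLatitude",
)

#: Default verbatim-header -> record-field map. Columns not listed here
#: are preserved untouched in ``OccurrenceRecord.extras``.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "scientificName": "scientific_name",
    "family": "family",
    "genus": "genus",
    "specificEpithet": "specific_epithet",
    "taxonRank": "taxon_rank",
    "scientificNameAuthorship": "scientific_name_authorship",
    "typeStatus": "type_status",
    "collectionCode": "collection_code",
    "catalogNumber": "catalog_number",
    "locality": "locality",
    "municipality": "municipality",
    "stateProvince": "state_province",
    "recordedBy": "recorded_by",
    "recordNumber": "record_number",
    "EventDate": "event_date",
    "eventDate": "event_date",
    "verbatimLongitude": "verbatim_longitude",
    "verbatimLatitude": "verbatim_latitude",
    "group": "group",
    "lifeForm": "life_form",
}


class DwcIOError(ValueError):
    """Malformed or invariant-violating input table."""


@dataclass
class Dialect:
    """How to read a delimited occurrence table."""

    delimiter: str | None = None  # None: infer from extension (.csv -> ',')
    encoding: str = "utf-8"
    column_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLUMN_MAP)
    )

    def resolve_delimiter(self, path: Path) -> str:
        if self.delimiter is not None:
            return self.delimiter
        return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class OccurrenceRecord:
    """One herbarium voucher row (Darwin Core fields plus parsed year)."""

    catalog_number: str
    scientific_name: str
    collection_code: str = ""
    family: str = ""
    genus: str = ""
    specific_epithet: str = ""
    taxon_rank: str = ""
    scientific_name_authorship: str = ""
    recorded_by: str = ""
    record_number: str = ""
    event_date: str = ""
    collection_year: int | None = None
    locality: str = ""
    municipality: str = ""
    state_province: str = ""
    type_status: str = ""
    verbatim_latitude: float | None = None
    verbatim_longitude: float | None = None
    group: str = UNKNOWN_GROUP
    life_form: str = ""
    extras: dict[str, str] = field(default_factory=dict)
    # Filled in by taxonomy.resolve_records / apply_review:
    accepted_name: str | None = None
    accepted_family: str = ""
    match_type: str | None = None

    def binomial(self) -> str:
        """Species-level name (genus + specific epithet), infraspecific
        parts dropped. Falls back to the first two tokens of the
        verbatim scientificName when the atomized fields are empty."""
        if self.genus and self.specific_epithet:
            return f"{self.genus} {self.specific_epithet}"
        tokens = [t for t in self.scientific_name.split() if t not in ("×", "x")]
        return " ".join(tokens[:2])


@dataclass
class ParseReport:
    """Row accounting for one occurrence-table read."""

    n_rows: int = 0
    n_records: int = 0
    n_year_parsed: int = 0
    n_year_absent: int = 0
    n_year_unparseable: int = 0
    n_bad_coordinates: int = 0


@dataclass
class BackboneEntry:
    """One name in the taxonomic backbone (accepted or synonym)."""

    name: str
    author: str = ""
    status: str = "accepted"  # accepted | synonym
    accepted_name: str = ""
    group: str = UNKNOWN_GROUP
    family: str = ""
    origin: str = "native"  # native | non_native
    endemic_to_country: bool | None = None
    life_forms: frozenset[str] = frozenset()
    vegetation_types: frozenset[str] = frozenset()


class Backbone:
    """Accepted-name/synonym lookup emulating a national flora list."""

    def __init__(self, entries: Iterable[BackboneEntry]):
        self.entries: dict[str, BackboneEntry] = {}
        for e in entries:
            if e.name in self.entries:
                raise DwcIOError(f"duplicate backbone name: {e.name!r}")
            self.entries[e.name] = e
        self._validate()

    def _validate(self) -> None:
        for e in self.entries.values():
            if e.status == "accepted":
                if e.accepted_name and e.accepted_name != e.name:
                    raise DwcIOError(
                        f"accepted entry {e.name!r} points at {e.accepted_name!r}"
                    )
                e.accepted_name = e.name
            elif e.status == "synonym":
                target = self.entries.get(e.accepted_name)
                if target is None:
                    raise DwcIOError(
                        f"synonym {e.name!r} points at missing name "
                        f"{e.accepted_name!r}"
                    )
                if target.status != "accepted":
                    raise DwcIOError(
                        f"synonym {e.name!r} points at non-accepted name "
                        f"{e.accepted_name!r}"
                    )
            else:
                raise DwcIOError(f"unknown status {e.status!r} for {e.name!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def get(self, name: str) -> BackboneEntry | None:
        return self.entries.get(name)

    def accepted_entry(self, name: str) -> BackboneEntry | None:
        """The accepted entry behind ``name`` (follows one synonym hop)."""
        e = self.entries.get(name)
        if e is None:
            return None
        return e if e.status == "accepted" else self.entries[e.accepted_name]

    def accepted_names(self) -> list[str]:
        return [n for n, e in self.entries.items() if e.status == "accepted"]


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path, delimiter: str, encoding: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        encoding=encoding,
    )
    # pandas mangles duplicate headers to 'name.1'; the published layout
    # repeats taxonRank, so collapse mangled duplicates back onto the first.
    dup = [c for c in df.columns if re.fullmatch(r".+\.\d+", c) and c.rsplit(".", 1)[0] in df.columns]
    return df.drop(columns=dup)


def _parse_coord(value: str, lo: float, hi: float) -> tuple[float | None, bool]:
    if not value.strip():
        return None, False
    try:
        x = float(value)
    except ValueError:
        return None, True
    if not (lo <= x <= hi):
        return None, True
    return x, False


def read_occurrences(
    path: str | Path, dialect: Dialect | None = None
) -> tuple[list[OccurrenceRecord], ParseReport]:
    """Read an occurrence table into records plus a parse report.

    Every input row yields exactly one record (no silent drops);
    unparseable years are left absent and counted. Raises
    :class:`DwcIOError` when a mandatory column (catalogNumber,
    scientificName) is missing or a catalogNumber repeats within the
    file.
    """
    path = Path(path)
    dialect = dialect or Dialect()
    df = _read_table(path, dialect.resolve_delimiter(path), dialect.encoding)

    colmap = {c: dialect.column_map[c] for c in df.columns if c in dialect.column_map}
    fields_present = set(colmap.values())
    for mandatory, label in (("catalog_number", "catalogNumber"), ("scientific_name", "scientificName")):
        if mandatory not in fields_present:
            raise DwcIOError(f"mandatory column missing: {label}")

    report = ParseReport(n_rows=len(df))
    records: list[OccurrenceRecord] = []
    for row in df.to_dict("records"):
        kwargs: dict[str, str] = {}
        extras: dict[str, str] = {}
        for col, value in row.items():
            fieldname = colmap.get(col)
            if fieldname is None:
                extras[col] = value
            else:
                kwargs[fieldname] = value

        lat_raw = kwargs.pop("verbatim_latitude", "")
        lon_raw = kwargs.pop("verbatim_longitude", "")
        lat, bad_lat = _parse_coord(lat_raw, -90.0, 90.0)
        lon, bad_lon = _parse_coord(lon_raw, -180.0, 180.0)
        report.n_bad_coordinates += int(bad_lat) + int(bad_lon)

        group = fold(kwargs.pop("group", "")).replace(" ", "_")
        rec = OccurrenceRecord(
            **kwargs,
            verbatim_latitude=lat,
            verbatim_longitude=lon,
            group=group if group in GROUPS else UNKNOWN_GROUP,
            extras=extras,
        )
        rec.collection_year = parse_year(rec.event_date)
        if rec.collection_year is not None:
            report.n_year_parsed += 1
        elif rec.event_date.strip():
            report.n_year_unparseable += 1
        else:
            report.n_year_absent += 1
        records.append(rec)
        report.n_records += 1

    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.catalog_number] = counts.get(rec.catalog_number, 0) + 1
    offenders = sorted(cn for cn, n in counts.items() if n > 1 or not cn)
    if offenders:
        raise DwcIOError(f"duplicated or empty catalogNumber values: {offenders}")
    return records, report


def _split_set(value: str) -> frozenset[str]:
    return frozenset(t.strip() for t in value.split(";") if t.strip())


_NON_NATIVE_TOKENS = {"non_native", "non-native", "cultivated", "naturalised", "naturalized", "not_occurring"}


def read_backbone(path: str | Path, delimiter: str = "\t") -> Backbone:
    """Load a backbone table (columns: name, author, status, acceptedName,
    group, family, origin, endemicToCountry, lifeForms, vegetationTypes).

    Origin tokens 'cultivated'/'naturalised'/'not_occurring' normalize to
    non_native. Entry invariants (synonym targets exist and are accepted,
    names unique) are enforced at load time.
    """
    df = _read_table(Path(path), delimiter, "utf-8")
    for col in ("name", "status", "acceptedName"):
        if col not in df.columns:
            raise DwcIOError(f"backbone column missing: {col}")

    entries = []
    for row in df.to_dict("records"):
        origin_raw = fold(row.get("origin", "native")).replace("-", "_").replace(" ", "_")
        origin = "non_native" if origin_raw in _NON_NATIVE_TOKENS else "native"
        endemic_raw = fold(row.get("endemicToCountry", ""))
        endemic = {"true": True, "false": False}.get(endemic_raw)
        entries.append(
            BackboneEntry(
                name=row["name"].strip(),
                author=row.get("author", ""),
                status=fold(row["status"]),
                accepted_name=row["acceptedName"].strip(),
                group=row.get("group", UNKNOWN_GROUP).strip() or UNKNOWN_GROUP,
                family=row.get("family", "").strip(),
                origin=origin,
                endemic_to_country=endemic,
                life_forms=_split_set(row.get("lifeForms", "")),
                vegetation_types=_split_set(row.get("vegetationTypes", "")),
            )
        )
    return Backbone(entries)


def read_assessments(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Load the threat-assessment table (speciesName, category).

    Categories are validated against CR/EN/VU/NT/LC/DD/NE; species absent
    from the table are treated as NE by downstream annotation.
    """
    df = _read_table(Path(path), delimiter, "utf-8")
    for col in ("speciesName", "category"):
        if col not in df.columns:
            raise DwcIOError(f"assessment column missing: {col}")
    out: dict[str, str] = {}
    for row in df.to_dict("records"):
        name = row["speciesName"].strip()
        cat = row["category"].strip().upper()
        if cat not in THREAT_CATEGORIES:
            raise DwcIOError(f"unknown threat category {row['category']!r} for {name!r}")
        if name in out and out[name] != cat:
            raise DwcIOError(f"conflicting categories for {name!r}")
        out[name] = cat
    return out


# ---------------------------------------------------------------------------
# writers


def _fmt_coord(value: float | None) -> str:
    return "" if value is None else repr(value)


def write_checklist(
    records: Iterable[OccurrenceRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write retained records in the 19-column checklist layout.

    The 19 verbatim labels come first (taxonRank twice, as published);
    non-standard fields carried by the records (recordNumber, group,
    lifeForm) follow so that a write/read cycle is the identity.
    """
    records = list(records)
    if not records:
        raise DwcIOError("refusing to write an empty checklist")

    extra_cols = []
    if any(r.record_number for r in records):
        extra_cols.append("recordNumber")
    if any(r.group != UNKNOWN_GROUP for r in records):
        extra_cols.append("group")
    if any(r.life_form for r in records):
        extra_cols.append("lifeForm")

    rows = []
    for r in records:
        row = [
            r.extras.get("taxonID", ""),
            r.scientific_name,
            r.extras.get("kingdom", "Plantae"),
            r.family,
            r.genus,
            r.specific_epithet,
            r.taxon_rank,
            r.scientific_name_authorship,
            r.extras.get("modified", ""),
            r.extras.get("rightsHolder", ""),
            r.type_status,
            r.taxon_rank,
            r.collection_code,
            r.catalog_number,
            r.locality,
            r.recorded_by,
            r.event_date,
            _fmt_coord(r.verbatim_longitude),
            _fmt_coord(r.verbatim_latitude),
        ]
        for col in extra_cols:
            row.append({"recordNumber": r.record_number, "group": r.group, "lifeForm": r.life_form}[col])
        rows.append(row)

    header = list(CHECKLIST_COLUMNS) + extra_cols
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(delimiter.join(header) + "\n")
        for row in rows:
            fh.write(delimiter.join(row) + "\n")


def write_ledger(ledger, path: str | Path, delimiter: str = "\t") -> None:
    """Write a cleaning ledger as one row per (group, stage)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(delimiter.join(["group", "stage", "input", "kept", "removed", "delta", "reason"]) + "\n")
        for s in ledger.stages:
            fh.write(
                delimiter.join(
                    [s.group, s.stage, str(s.n_input), str(s.kept), str(s.removed), str(s.delta), s.reason]
                )
                + "\n"
            )
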