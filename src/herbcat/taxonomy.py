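"""Protocol step 4: resolve verbatim names against the backbone.

Matching is on the binomial only (authorship is preserved but never
keyed on), case- and accent-insensitive, with hybrid markers stripped.
Exact accepted matches beat exact synonym matches beat fuzzy ones; the
fuzzy search sums Levenshtein distances over genus and epithet and
never auto-breaks ties between distinct accepted targets — those go to
the review queue, as do names absent from the backbone, emulating the
manual taxonomist pass.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from ._text import fold_name
from .cleaning import (
    STAGE_REVIEW_ADDITIONS,
    STAGE_REVIEW_REMOVALS,
    CleaningLedger,
    StageCount,
)
from .dwc_io import (
    GROUPS,
    UNKNOWN_GROUP,
    Backbone,
    DwcIOError,
    OccurrenceRecord,
)

MATCH_EXACT_ACCEPTED = "exact_accepted"
MATCH_SYNONYM = "synonym"
MATCH_FUZZY_ACCEPTED = "fuzzy_accepted"
MATCH_FUZZY_SYNONYM = "fuzzy_synonym"
MATCH_NONE = "none"
MATCH_AMBIGUOUS = "ambiguous"


@dataclass
class MatchResult:
    query: str
    match_type: str
    accepted_name: str | None = None
    edit_distance: int = 0
    candidates: list[str] = field(default_factory=list)


def _distance(a: str, b: str, k: int) -> int:
    """Levenshtein distance, -1 if above k (edlib banded alignment)."""
    if a == b:
        return 0
    if abs(len(a) - len(b)) > k:
        return -1
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def _split_binomial(folded: str) -> tuple[str, str]:
    parts = folded.split(" ", 1)
    return (parts[0], parts[1] if len(parts) > 1 else "")


class NameIndex:
    """Folded-binomial index over a backbone, shared across queries."""

    def __init__(self, backbone: Backbone):
        self.backbone = backbone
        self.by_folded: dict[str, str] = {}
        self._split: list[tuple[str, str, str]] = []  # (genus, epithet, name)
        for name in backbone.entries:
            f = fold_name(name)
            self.by_folded.setdefault(f, name)
            g, e = _split_binomial(f)
            self._split.append((g, e, name))

    def exact(self, folded_query: str) -> str | None:
        return self.by_folded.get(folded_query)

    def within(self, folded_query: str, max_distance: int) -> list[tuple[str, int]]:
        """All backbone names with summed genus+epithet distance <=
        max_distance, as (name, distance)."""
        qg, qe = _split_binomial(folded_query)
        hits = []
        for g, e, name in self._split:
            dg = _distance(qg, g, max_distance)
            if dg < 0:
                continue
            de = _distance(qe, e, max_distance - dg)
            if de < 0:
                continue
            hits.append((name, dg + de))
        return hits


def match_name(
    query: str,
    backbone: Backbone | NameIndex,
    max_distance: int = 1,
) -> MatchResult:
    """Match one binomial against the backbone.

    Preference order: exact accepted > exact synonym > fuzzy. Among
    fuzzy hits only the minimal summed distance counts; if the minimal
    hits resolve to more than one accepted name the result is
    ambiguous (candidates listed), never a tie-break.
    """
    index = backbone if isinstance(backbone, NameIndex) else NameIndex(backbone)
    folded = fold_name(query)
    if not folded:
        raise ValueError("empty query name")

    hit = index.exact(folded)
    if hit is not None:
        entry = index.backbone.entries[hit]
        if entry.status == "accepted":
            return MatchResult(query, MATCH_EXACT_ACCEPTED, entry.name, 0)
        return MatchResult(query, MATCH_SYNONYM, entry.accepted_name, 0)

    if max_distance > 0:
        hits = index.within(folded, max_distance)
        if hits:
            best = min(d for _, d in hits)
            nearest = [name for name, d in hits if d == best]
            targets = {index.backbone.entries[n].accepted_name for n in nearest}
            if len(targets) == 1:
                any_accepted = any(
                    index.backbone.entries[n].status == "accepted" for n in nearest
                )
                mtype = MATCH_FUZZY_ACCEPTED if any_accepted else MATCH_FUZZY_SYNONYM
                return MatchResult(query, mtype, targets.pop(), best)
            return MatchResult(query, MATCH_AMBIGUOUS, None, best, sorted(nearest))

    return MatchResult(query, MATCH_NONE, None, max_distance + 1)


def assign_group(record: OccurrenceRecord, backbone: Backbone) -> str:
    """Higher group of the record's accepted name (unknown if unresolved)."""
    if not record.accepted_name:
        return UNKNOWN_GROUP
    entry = backbone.accepted_entry(record.accepted_name)
    if entry is None or entry.group not in GROUPS:
        return record.group if record.group in GROUPS else UNKNOWN_GROUP
    return entry.group


def resolve_records(
    records: list[OccurrenceRecord],
    backbone: Backbone,
    max_distance: int = 1,
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord], Counter]:
    """Resolve each record's binomial to an accepted backbone name.

    Returns (resolved, unresolved_queue, per-matchType counts). Records
    matching nothing, or matching ambiguously, carry no accepted name
    and go to the queue for manual review; resolved + queued = input.
    """
    index = NameIndex(backbone)
    resolved, queued = [], []
    report: Counter = Counter()
    for r in records:
        result = match_name(r.binomial(), index, max_distance)
        report[result.match_type] += 1
        r.match_type = result.match_type
        if result.accepted_name is None:
            r.accepted_name = None
            queued.append(r)
        else:
            r.accepted_name = result.accepted_name
            entry = backbone.accepted_entry(result.accepted_name)
            r.accepted_family = entry.family if entry else r.family
            r.group = assign_group(r, backbone)
            resolved.append(r)
    return resolved, queued, report


@dataclass
class ReviewAction:
    catalog_number: str
    action: str  # accept_as | remove | add
    name: str = ""
    extras: dict[str, str] = field(default_factory=dict)


def read_review(path: str | Path, delimiter: str = "\t") -> list[ReviewAction]:
    """Read a review file: catalogNumber, action, name (+ optional
    trait/record columns such as group, family, origin, category,
    eventDate, recordedBy)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in ("catalogNumber", "action", "name"):
        if col not in df.columns:
            raise DwcIOError(f"review column missing: {col}")
    actions = []
    for row in df.to_dict("records"):
        action = row["action"].strip()
        if action not in ("accept_as", "remove", "add"):
            raise DwcIOError(f"unknown review action {row['action']!r}")
        extras = {
            k: v for k, v in row.items()
            if k not in ("catalogNumber", "action", "name") and str(v).strip()
        }
        actions.append(ReviewAction(row["catalogNumber"].strip(), action, row["name"].strip(), extras))
    return actions


def apply_review(
    records: list[OccurrenceRecord],
    queue: list[OccurrenceRecord],
    actions: list[ReviewAction],
    ledger: CleaningLedger | None = None,
    group: str = "all",
) -> list[OccurrenceRecord]:
    """Apply taxonomist review decisions to the catalogue.

    accept_as sets/overrides a record's accepted name (re-admitting it
    from the queue if needed); remove deletes from the catalogue; add
    appends an externally documented record (e.g. vouchers held in
    other herbaria). Removals/additions are logged to the ledger as
    review stages. Actions naming an unknown catalogNumber (other than
    add) are hard errors.
    """
    by_cn = {r.catalog_number: r for r in records}
    queued_by_cn = {r.catalog_number: r for r in queue}
    out = list(records)
    removals = additions = 0

    for act in actions:
        if act.action == "add":
            rec = OccurrenceRecord(
                catalog_number=act.catalog_number,
                scientific_name=act.name or act.extras.get("scientificName", ""),
                collection_code=act.extras.get("collectionCode", ""),
                family=act.extras.get("family", ""),
                recorded_by=act.extras.get("recordedBy", ""),
                event_date=act.extras.get("eventDate", ""),
                group=act.extras.get("group", UNKNOWN_GROUP),
                extras={k: v for k, v in act.extras.items() if k.startswith("trait:")},
            )
            from ._text import parse_year

            rec.collection_year = parse_year(rec.event_date)
            rec.accepted_name = act.name or rec.binomial()
            rec.accepted_family = act.extras.get("family", "")
            rec.match_type = "review_added"
            out.append(rec)
            by_cn[rec.catalog_number] = rec
            additions += 1
        elif act.action == "accept_as":
            rec = by_cn.get(act.catalog_number) or queued_by_cn.get(act.catalog_number)
            if rec is None:
                raise DwcIOError(f"review accept_as on unknown catalogNumber {act.catalog_number!r}")
            rec.accepted_name = act.name
            rec.match_type = "review_accepted"
            if rec.catalog_number not in by_cn:
                out.append(rec)
                by_cn[rec.catalog_number] = rec
                additions += 1
        elif act.action == "remove":
            rec = by_cn.get(act.catalog_number)
            if rec is None:
                raise DwcIOError(f"review remove on unknown catalogNumber {act.catalog_number!r}")
            out = [r for r in out if r.catalog_number != act.catalog_number]
            del by_cn[act.catalog_number]
            removals += 1

    if ledger is not None:
        n_in = len(records)
        ledger.add(StageCount(group, STAGE_REVIEW_REMOVALS, n_in, n_in - removals,
                              removals, reason="removed by taxonomist review"))
        ledger.add(StageCount(group, STAGE_REVIEW_ADDITIONS, n_in - removals,
                              n_in - removals + additions, 0, delta=additions,
                              reason="added by taxonomist review"))
    return out
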