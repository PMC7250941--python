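"""Protocol steps 1-3: determination filter, locality filter, deduplication.

Each stage records a per-group line in the :class:`CleaningLedger`, the
kept/removed accounting that mirrors the printed cleaning flow diagrams:
``input = kept + removed`` at every stage and the kept count of one
stage feeds the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._text import fold, fold_collector, word_boundary_search
from .dwc_io import DwcIOError, OccurrenceRecord

UNKNOWN_COLLECTOR = "UNKNOWN"

STAGE_DETERMINATION = "determination"
STAGE_LOCALITY = "locality"
STAGE_DUPLICATES = "duplicates"
STAGE_REVIEW_REMOVALS = "review_removals"
STAGE_REVIEW_ADDITIONS = "review_additions"

# Ranks at or below species level (folded, dots stripped).
_SPECIES_LEVEL_RANKS = {
    "species", "sp", "variety", "var", "subspecies", "subsp", "ssp",
    "form", "forma", "f", "subvariety", "subvar", "infraspecificname",
}
_ABOVE_SPECIES_RANKS = {
    "family", "subfamily", "tribe", "genus", "subgenus", "section",
    "order", "class", "kingdom", "phylum", "division",
}


@dataclass
class StageCount:
    group: str
    stage: str
    n_input: int
    kept: int
    removed: int
    delta: int = 0  # signed; used by review additions (removed stays 0)
    reason: str = ""


@dataclass
class CleaningLedger:
    stages: list[StageCount] = field(default_factory=list)

    def add(self, stage: StageCount) -> None:
        if stage.delta == 0 and stage.n_input != stage.kept + stage.removed:
            raise ValueError(
                f"ledger conservation violated at {stage.group}/{stage.stage}: "
                f"{stage.n_input} != {stage.kept} + {stage.removed}"
            )
        if stage.delta != 0 and stage.kept != stage.n_input + stage.delta:
            raise ValueError(
                f"ledger delta inconsistent at {stage.group}/{stage.stage}"
            )
        self.stages.append(stage)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.stages:
            seen.setdefault(s.group, None)
        return list(seen)

    def validate_chain(self) -> None:
        """Check that within each group consecutive stages telescope."""
        for g in self.groups():
            rows = [s for s in self.stages if s.group == g]
            for prev, cur in zip(rows, rows[1:]):
                if cur.n_input != prev.kept:
                    raise ValueError(
                        f"ledger chain broken in group {g!r}: stage "
                        f"{cur.stage} input {cur.n_input} != previous kept {prev.kept}"
                    )

    def final_kept(self, group: str) -> int:
        rows = [s for s in self.stages if s.group == group]
        if not rows:
            raise KeyError(group)
        return rows[-1].kept

    def removed_at(self, stage: str, group: str | None = None) -> int:
        return sum(
            s.removed for s in self.stages
            if s.stage == stage and (group is None or s.group == group)
        )

    @classmethod
    def replay(cls, group: str, n_input: int, removals: list[tuple[str, int]]) -> "CleaningLedger":
        """Build a ledger from a starting count and per-stage removal
        counts, telescoping kept = input - removed stage by stage."""
        ledger = cls()
        current = n_input
        for stage_name, removed in removals:
            ledger.add(StageCount(group, stage_name, current, current - removed, removed))
            current -= removed
        return ledger


@dataclass
class Gazetteer:
    """Locality term lists defining the target protected area.

    ``include_terms`` assert the area (matched on a word boundary to
    beat exclusions); ``exclude_terms`` assert outside-area places.
    Matching is case- and accent-insensitive substring search.
    """

    include_terms: frozenset[str]
    exclude_terms: frozenset[str]
    default_policy: str = "keep_and_queue"  # or "drop"

    def __post_init__(self) -> None:
        self.include_terms = frozenset(fold(t) for t in self.include_terms)
        self.exclude_terms = frozenset(fold(t) for t in self.exclude_terms)
        if self.include_terms & self.exclude_terms:
            raise ValueError("gazetteer include/exclude terms overlap")
        if self.default_policy not in ("keep_and_queue", "drop"):
            raise ValueError(f"unknown default policy {self.default_policy!r}")

    @classmethod
    def from_file(cls, path: str | Path, default_policy: str = "keep_and_queue") -> "Gazetteer":
        include, exclude = set(), set()
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1].strip() not in ("include", "exclude"):
                raise DwcIOError(f"bad gazetteer line {lineno}: {line!r}")
            (include if parts[1].strip() == "include" else exclude).add(parts[0].strip())
        return cls(frozenset(include), frozenset(exclude), default_policy)

    def classify(self, locality: str) -> str:
        """'keep', 'remove' or 'queue' for one verbatim locality."""
        loc = fold(locality)
        include_sub = any(t in loc for t in self.include_terms)
        include_wb = any(word_boundary_search(t, loc) for t in self.include_terms)
        exclude_sub = any(t in loc for t in self.exclude_terms)
        if exclude_sub:
            if include_wb:
                return "keep"
            if include_sub:
                return "queue"  # conflicting evidence -> manual review
            return "remove"
        if include_sub:
            return "keep"
        return "queue" if self.default_policy == "keep_and_queue" else "remove"


def normalize_collector(name: str | None) -> str:
    """Collector key: case-folded, accent-stripped, punctuation removed,
    whitespace collapsed; empty/absent becomes the UNKNOWN token."""
    if not name:
        return UNKNOWN_COLLECTOR
    key = fold_collector(name)
    return key if key else UNKNOWN_COLLECTOR


def is_species_level(record: OccurrenceRecord) -> bool:
    """Species-level determination: a specific epithet plus a rank at or
    below species (an empty rank string defers to the epithet)."""
    if not record.specific_epithet.strip() and len(record.binomial().split()) < 2:
        return False
    rank = fold(record.taxon_rank).replace(".", "")
    if not rank or rank in _SPECIES_LEVEL_RANKS:
        return True
    return False


def filter_determined(
    records: list[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Step 1: keep records determined at species level or below.

    Infraspecific determinations are retained; their species-level name
    is obtained downstream via ``OccurrenceRecord.binomial()``. Records
    with an unrecognizable rank string and no epithet count as
    undetermined.
    """
    kept, removed = [], []
    for r in records:
        (kept if is_species_level(r) else removed).append(r)
    return kept, removed


def filter_locality(
    records: list[OccurrenceRecord], gazetteer: Gazetteer
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Step 2: drop records whose locality places them outside the area.

    Returns (kept, removed, queued_for_review); queued records stay in
    the kept stream but are exported for the manual pass, mirroring the
    protocol's final manual check.
    """
    kept, removed, queued = [], [], []
    for r in records:
        verdict = gazetteer.classify(r.locality)
        if verdict == "remove":
            removed.append(r)
        else:
            kept.append(r)
            if verdict == "queue":
                queued.append(r)
    return kept, removed, queued


def _dedup_key(record: OccurrenceRecord) -> tuple[str, str, int] | None:
    """Complete (collector, number, year) key, or None if any part is
    missing — incomplete keys are never merged."""
    collector = normalize_collector(record.recorded_by)
    number = record.record_number.strip()
    year = record.collection_year
    if collector == UNKNOWN_COLLECTOR or not number or year is None:
        return None
    return (collector, number, year)


def deduplicate(
    records: list[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord], list[tuple[str, str]]]:
    """Step 3: collapse records sharing a complete (collector, number,
    year) key to one representative.

    The representative is the record with the lexicographically smallest
    catalogNumber, making the outcome order-free. Collection codes are
    ignored: duplicates across herbaria merge. Returns
    (unique, removed, pairs) where pairs lists
    (kept catalogNumber, removed catalogNumber).
    """
    groups: dict[tuple[str, str, int], list[OccurrenceRecord]] = {}
    for r in records:
        key = _dedup_key(r)
        if key is not None:
            groups.setdefault(key, []).append(r)

    drop: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda r: r.catalog_number)
        keeper = members[0]
        for twin in members[1:]:
            drop.add(twin.catalog_number)
            pairs.append((keeper.catalog_number, twin.catalog_number))

    unique = [r for r in records if r.catalog_number not in drop]
    removed = [r for r in records if r.catalog_number in drop]
    return unique, removed, pairs


@dataclass
class CleaningResult:
    records: list[OccurrenceRecord]
    ledger: CleaningLedger
    undetermined: list[OccurrenceRecord]
    out_of_area: list[OccurrenceRecord]
    locality_review_queue: list[OccurrenceRecord]
    duplicate_pairs: list[tuple[str, str]]


def run_cleaning(records: list[OccurrenceRecord], gazetteer: Gazetteer) -> CleaningResult:
    """Apply determination -> locality -> duplicates per group, with a
    full ledger."""
    ledger = CleaningLedger()
    out: list[OccurrenceRecord] = []
    undet_all, ooa_all, queue_all, pairs_all = [], [], [], []

    groups: dict[str, list[OccurrenceRecord]] = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)

    for group_name, group_records in groups.items():
        kept, undet = filter_determined(group_records)
        ledger.add(StageCount(group_name, STAGE_DETERMINATION, len(group_records),
                              len(kept), len(undet), reason="not determined to species level"))
        kept2, ooa, queued = filter_locality(kept, gazetteer)
        ledger.add(StageCount(group_name, STAGE_LOCALITY, len(kept), len(kept2),
                              len(ooa), reason="locality outside target area"))
        unique, dup_removed, pairs = deduplicate(kept2)
        ledger.add(StageCount(group_name, STAGE_DUPLICATES, len(kept2), len(unique),
                              len(dup_removed), reason="duplicate collector/number/year"))
        out.extend(unique)
        undet_all.extend(undet)
        ooa_all.extend(ooa)
        queue_all.extend(queued)
        pairs_all.extend(pairs)

    ledger.validate_chain()
    return CleaningResult(out, ledger, undet_all, ooa_all, queue_all, pairs_all)
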