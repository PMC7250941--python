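"""Temporal classification and the conservation-priority rule.

A record is *old* when its collection year is at or before the cutoff
(default 1969) and *recent* after it. A species is flagged priority for
conservation iff it has exactly one retained record, only old records,
and a threat category among CR, EN, VU or DD — i.e. a threatened or
data-deficient species not collected in the park for half a century and
known from a single voucher.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .annotation import SpeciesTraits
from .dwc_io import PRIORITY_CATEGORIES, UNKNOWN_GROUP, OccurrenceRecord

DEFAULT_CUTOFF_YEAR = 1969

AGE_OLD = "old"
AGE_RECENT = "recent"
AGE_UNKNOWN = "unknown"

ONLY_OLD = "only_old"
HAS_RECENT = "has_recent"
TEMPORAL_UNKNOWN = "unknown"


def record_age_class(collection_year: int | None, cutoff_year: int = DEFAULT_CUTOFF_YEAR) -> str:
    """old iff year <= cutoff; recent iff year > cutoff; unknown if absent."""
    if collection_year is None:
        return AGE_UNKNOWN
    return AGE_OLD if collection_year <= cutoff_year else AGE_RECENT


def species_temporal_status(
    records: Iterable[OccurrenceRecord], cutoff_year: int = DEFAULT_CUTOFF_YEAR
) -> str:
    """has_recent if any record is recent; only_old if at least one old
    record and none recent; unknown only when every record is undated."""
    classes = {record_age_class(r.collection_year, cutoff_year) for r in records}
    if not classes:
        raise ValueError("species_temporal_status on empty record set")
    if AGE_RECENT in classes:
        return HAS_RECENT
    if AGE_OLD in classes:
        return ONLY_OLD
    return TEMPORAL_UNKNOWN


def flag_priority(record_count: int, temporal_status: str, threat_category: str) -> bool:
    """True iff single record AND only old records AND CR/EN/VU/DD."""
    return (
        record_count == 1
        and temporal_status == ONLY_OLD
        and threat_category in PRIORITY_CATEGORIES
    )


@dataclass
class SpeciesSummary:
    """One catalogue row per accepted species."""

    species_name: str
    group: str
    family: str
    record_count: int
    temporal_status: str
    traits: SpeciesTraits
    priority: bool = False
    records: list[OccurrenceRecord] = field(default_factory=list, repr=False)

    @property
    def genus(self) -> str:
        return self.species_name.split(" ", 1)[0]


def build_species_summaries(
    records: Iterable[OccurrenceRecord],
    traits_by_species: Mapping[str, SpeciesTraits],
    cutoff_year: int = DEFAULT_CUTOFF_YEAR,
) -> list[SpeciesSummary]:
    """Aggregate resolved, annotated records into per-species summaries,
    sorted by species name. Record counts are over the retained records
    (post-dedup, including review additions)."""
    by_species: dict[str, list[OccurrenceRecord]] = {}
    for r in records:
        if not r.accepted_name:
            raise ValueError(f"unresolved record {r.catalog_number!r} in summary input")
        by_species.setdefault(r.accepted_name, []).append(r)

    summaries = []
    for name in sorted(by_species):
        recs = by_species[name]
        traits = traits_by_species.get(name) or SpeciesTraits(name)
        status = species_temporal_status(recs, cutoff_year)
        groups = {r.group for r in recs if r.group != UNKNOWN_GROUP}
        family = next((r.accepted_family for r in recs if r.accepted_family), recs[0].family)
        summaries.append(
            SpeciesSummary(
                species_name=name,
                group=groups.pop() if len(groups) == 1 else UNKNOWN_GROUP,
                family=family,
                record_count=len(recs),
                temporal_status=status,
                traits=traits,
                priority=flag_priority(len(recs), status, traits.threat_category),
                records=recs,
            )
        )
    return summaries


def priority_table(summaries: Iterable[SpeciesSummary]) -> list[tuple[str, str, str, str]]:
    """(group, family, species, category) rows for the priority list,
    sorted by group then family then species."""
    rows = [
        (s.group, s.family, s.species_name, s.traits.threat_category)
        for s in summaries
        if s.priority
    ]
    return sorted(rows)
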