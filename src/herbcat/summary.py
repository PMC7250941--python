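"""Catalogue headline statistics.

Richness tables (species / genera / families per group), composition
percentages over any trait dimension, collector rankings and the
year-by-year collection profile. Family and genus always come from the
accepted name and its backbone entry, so synonymized records aggregate
onto one species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .cleaning import UNKNOWN_COLLECTOR, normalize_collector
from .conservation import ONLY_OLD, SpeciesSummary
from .dwc_io import PRIORITY_CATEGORIES, OccurrenceRecord

#: speciesSummary accessors for composition dimensions.
_DIMENSIONS = {
    "lifeForm": lambda s: s.traits.life_form,
    "vegetationClass": lambda s: s.traits.vegetation_class,
    "origin": lambda s: s.traits.origin,
    "endemism": lambda s: {True: "endemic", False: "not_endemic", None: "unknown"}[
        s.traits.endemic_to_country
    ],
    "temporalStatus": lambda s: s.temporal_status,
    "threatCategory": lambda s: s.traits.threat_category,
}


@dataclass
class RichnessTable:
    species_per_group: dict[str, int]
    genera_per_group: dict[str, int]
    families_per_group: dict[str, int]
    family_species_counts: dict[tuple[str, str], int]  # (group, family) -> n
    genus_species_counts: dict[tuple[str, str], int]
    totals: tuple[int, int, int] = (0, 0, 0)  # species, genera, families overall

    def top_families(self, k: int = 10, group: str | None = None) -> list[tuple[str, int]]:
        return _top_k(self.family_species_counts, k, group)

    def top_genera(self, k: int = 10, group: str | None = None) -> list[tuple[str, int]]:
        return _top_k(self.genus_species_counts, k, group)


def _top_k(counts: dict[tuple[str, str], int], k: int, group: str | None) -> list[tuple[str, int]]:
    merged: Counter = Counter()
    for (g, taxon), n in counts.items():
        if group is None or g == group:
            merged[taxon] += n
    # descending count, alphabetical within ties
    return sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def richness(summaries: Iterable[SpeciesSummary]) -> RichnessTable:
    """Distinct species / genus / family counts per group and overall."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("richness of an empty catalogue")
    species_g: dict[str, set[str]] = {}
    genera_g: dict[str, set[str]] = {}
    families_g: dict[str, set[str]] = {}
    fam_counts: Counter = Counter()
    gen_counts: Counter = Counter()
    for s in summaries:
        species_g.setdefault(s.group, set()).add(s.species_name)
        genera_g.setdefault(s.group, set()).add(s.genus)
        families_g.setdefault(s.group, set()).add(s.family)
        fam_counts[(s.group, s.family)] += 1
        gen_counts[(s.group, s.genus)] += 1
    all_species = set().union(*species_g.values())
    all_genera = set().union(*genera_g.values())
    all_families = set().union(*families_g.values())
    return RichnessTable(
        {g: len(v) for g, v in species_g.items()},
        {g: len(v) for g, v in genera_g.items()},
        {g: len(v) for g, v in families_g.items()},
        dict(fam_counts),
        dict(gen_counts),
        (len(all_species), len(all_genera), len(all_families)),
    )


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CompositionRow:
    category: str
    count: int
    percent: float        # rounded per ndigits
    percent_exact: float  # unrounded; rows sum to exactly 100


def composition(
    summaries: Iterable[SpeciesSummary],
    dimension: str,
    group: str | None = None,
    ndigits: int = 0,
) -> list[CompositionRow]:
    """Category counts and percentages of the (optionally group-filtered)
    species total along one trait dimension. Categories partition the
    species set, so counts sum to the total and exact shares to 100%."""
    try:
        accessor = _DIMENSIONS[dimension]
    except KeyError:
        raise ValueError(f"unknown dimension {dimension!r}; one of {sorted(_DIMENSIONS)}")
    pool = [s for s in summaries if group is None or s.group == group]
    counts = Counter(accessor(s) for s in pool)
    total = sum(counts.values())
    rows = []
    for cat, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        exact = 100.0 * n / total
        rows.append(CompositionRow(cat, n, round_half_up(exact, ndigits), exact))
    return rows


def collector_stats(records: Iterable[OccurrenceRecord]) -> list[tuple[str, int]]:
    """(normalized collector, record count), descending, ties
    alphabetical; missing collectors pooled under the UNKNOWN row."""
    counts = Counter(normalize_collector(r.recorded_by) for r in records)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class TemporalProfile:
    series: list[tuple[int, int]]  # (year, record count), ascending year
    unknown_count: int

    def peak_year(self) -> int | None:
        """Year with the most records; ties resolve to the earliest."""
        if not self.series:
            return None
        return min(self.series, key=lambda yc: (-yc[1], yc[0]))[0]


def temporal_profile(records: Iterable[OccurrenceRecord]) -> TemporalProfile:
    counts: Counter = Counter()
    unknown = 0
    for r in records:
        if r.collection_year is None:
            unknown += 1
        else:
            counts[r.collection_year] += 1
    return TemporalProfile(sorted(counts.items()), unknown)


def catalogue_headline_counts(
    summaries: list[SpeciesSummary], records: list[OccurrenceRecord]
) -> dict[str, int]:
    """The catalogue's headline numbers, computed from the final records
    and per-species summaries (record totals, richness, origin split,
    threat/endemism/trait counts for angiosperms, priority count)."""
    rich = richness(summaries)
    angio = [s for s in summaries if s.group == "angiosperm"]
    return {
        "total_records": len(records),
        "total_species": rich.totals[0],
        "total_genera": rich.totals[1],
        "total_families": rich.totals[2],
        "native_species": sum(1 for s in summaries if s.traits.origin == "native"),
        "non_native_species": sum(1 for s in summaries if s.traits.origin == "non_native"),
        "angiosperm_species": rich.species_per_group.get("angiosperm", 0),
        "gymnosperm_species": rich.species_per_group.get("gymnosperm", 0),
        "fern_species": rich.species_per_group.get("lycophyte_fern", 0),
        "angiosperm_threatened": sum(
            1 for s in angio if s.traits.threat_category in ("CR", "EN", "VU")
        ),
        "angiosperm_single_record": sum(1 for s in angio if s.record_count == 1),
        "angiosperm_herbs": sum(1 for s in angio if s.traits.life_form == "herb"),
        "angiosperm_forest_restricted": sum(
            1 for s in angio if s.traits.vegetation_class == "forest"
        ),
        "angiosperm_endemic": sum(1 for s in angio if s.traits.endemic_to_country is True),
        "angiosperm_only_old": sum(1 for s in angio if s.temporal_status == ONLY_OLD),
        "angiosperm_priority": sum(1 for s in angio if s.priority),
        "priority_species": sum(1 for s in summaries if s.priority),
        "priority_eligible": sum(
            1 for s in summaries if s.traits.threat_category in PRIORITY_CATEGORIES
        ),
    }
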