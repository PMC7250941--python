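"""End-to-end orchestration: files in, catalogue out.

Chains the protocol stages in their fixed order — determination filter,
locality filter, deduplication, name resolution, taxonomist review,
trait annotation, per-species summaries — carrying the cleaning ledger
through so the whole flow is auditable stage by stage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .annotation import SpeciesTraits, annotate_species
from .cleaning import CleaningLedger, Gazetteer, OccurrenceRecord, run_cleaning
from .conservation import DEFAULT_CUTOFF_YEAR, SpeciesSummary, build_species_summaries
from .dwc_io import (
    Backbone,
    Dialect,
    ParseReport,
    read_assessments,
    read_backbone,
    read_occurrences,
)
from .taxonomy import apply_review, read_review, resolve_records


@dataclass
class PipelineResult:
    records: list[OccurrenceRecord]          # final retained records
    summaries: list[SpeciesSummary]
    ledger: CleaningLedger
    traits: dict[str, SpeciesTraits]
    unresolved: list[OccurrenceRecord]       # still awaiting review
    locality_review_queue: list[OccurrenceRecord]
    resolution_report: Counter
    parse_report: ParseReport = field(default_factory=ParseReport)


def run_pipeline(
    occurrences: str | Path,
    backbone: str | Path | Backbone,
    assessments: str | Path | Mapping[str, str],
    gazetteer: str | Path | Gazetteer,
    review: str | Path | None = None,
    max_distance: int = 1,
    cutoff_year: int = DEFAULT_CUTOFF_YEAR,
    dialect: Dialect | None = None,
    vegetation_map: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run the full protocol over an occurrence table."""
    records, parse_report = read_occurrences(occurrences, dialect)
    if not isinstance(backbone, Backbone):
        backbone = read_backbone(backbone)
    if not isinstance(assessments, Mapping):
        assessments = read_assessments(assessments)
    if not isinstance(gazetteer, Gazetteer):
        gazetteer = Gazetteer.from_file(gazetteer)

    cleaned = run_cleaning(records, gazetteer)
    resolved, unresolved, report = resolve_records(cleaned.records, backbone, max_distance)
    if review is not None:
        actions = read_review(review)
        resolved = apply_review(resolved, unresolved, actions, cleaned.ledger)
        admitted = {r.catalog_number for r in resolved}
        unresolved = [r for r in unresolved if r.catalog_number not in admitted]

    by_species: dict[str, list[OccurrenceRecord]] = {}
    for r in resolved:
        by_species.setdefault(r.accepted_name, []).append(r)
    traits = {
        name: annotate_species(name, backbone, assessments, recs, vegetation_map)
        for name, recs in by_species.items()
    }
    summaries = build_species_summaries(resolved, traits, cutoff_year)
    return PipelineResult(
        records=resolved,
        summaries=summaries,
        ledger=cleaned.ledger,
        traits=traits,
        unresolved=unresolved,
        locality_review_queue=cleaned.locality_review_queue,
        resolution_report=report,
        parse_report=parse_report,
    )
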