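"""Per-species trait and status annotation.

Vegetation types collapse to a binary forest/grassland classification
(plus both / no_info) — finer typing is deliberately out of scope, as
many vouchers lack detailed habitat notes. Life form uses the majority
rule: when the backbone lists several forms, the most frequent form
among the species' own records wins, ties falling back to a fixed
precedence. Origin and endemism come from the backbone (cultivated or
naturalised taxa count as non-native) and the threat category from the
assessment table, defaulting to NE (not evaluated).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from ._text import fold
from .dwc_io import Backbone, DwcIOError, OccurrenceRecord

VEG_FOREST = "forest"
VEG_GRASSLAND = "grassland"
VEG_BOTH = "both"
NO_INFO = "no_info"

#: Tie-break precedence when record evidence cannot decide a life form.
LIFE_FORM_PRECEDENCE = ("tree", "shrub", "subshrub", "liana", "herb")

#: Default vegetation-label map, seeded with the vegetation types named
#: for the park: forest formations on one side, high-altitude grasslands,
#: campos rupestres and inselbergs on the other. Editable via
#: load_vegetation_map.
DEFAULT_VEGETATION_MAP: dict[str, str] = {
    "floresta ombrofila densa": VEG_FOREST,
    "floresta ombrofila mista": VEG_FOREST,
    "floresta estacional semidecidual": VEG_FOREST,
    "floresta altomontana": VEG_FOREST,
    "floresta com araucaria": VEG_FOREST,
    "campo de altitude": VEG_GRASSLAND,
    "campo rupestre": VEG_GRASSLAND,
    "campo limpo": VEG_GRASSLAND,
    "inselberg": VEG_GRASSLAND,
}


@dataclass
class SpeciesTraits:
    species_name: str
    vegetation_class: str = NO_INFO   # forest | grassland | both | no_info
    life_form: str = NO_INFO          # tree | shrub | subshrub | liana | herb | no_info
    origin: str = "native"            # native | non_native
    endemic_to_country: bool | None = None
    threat_category: str = "NE"


def load_vegetation_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV label -> forest|grassland."""
    mapping = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1].strip() not in (VEG_FOREST, VEG_GRASSLAND):
            raise DwcIOError(f"bad vegetation-map line {lineno}: {line!r}")
        mapping[fold(parts[0])] = parts[1].strip()
    return mapping


def classify_vegetation(
    vegetation_types: Iterable[str],
    mapping: Mapping[str, str] | None = None,
    on_unmapped: str = "warn",
) -> str:
    """Collapse backbone vegetation labels to forest/grassland/both.

    Unmapped labels are ignored with a warning (default) or raise,
    per ``on_unmapped`` ('warn' | 'error').
    """
    mapping = DEFAULT_VEGETATION_MAP if mapping is None else mapping
    kinds = set()
    for label in vegetation_types:
        kind = mapping.get(fold(label))
        if kind is None:
            if on_unmapped == "error":
                raise DwcIOError(f"unmapped vegetation label {label!r}")
            warnings.warn(f"ignoring unmapped vegetation label {label!r}", stacklevel=2)
            continue
        kinds.add(kind)
    if not kinds:
        return NO_INFO
    if kinds == {VEG_FOREST}:
        return VEG_FOREST
    if kinds == {VEG_GRASSLAND}:
        return VEG_GRASSLAND
    return VEG_BOTH


def classify_life_form(
    backbone_life_forms: Iterable[str],
    record_life_forms: Iterable[str] = (),
) -> str:
    """Majority-rule life form.

    One backbone form: that form, regardless of record evidence.
    Several: the most frequent among the species' record observations
    (restricted to the backbone set), ties and missing evidence broken
    by tree > shrub > subshrub > liana > herb. No backbone forms: the
    record evidence alone, or no_info.
    """
    backbone_set = {f for f in backbone_life_forms if f in LIFE_FORM_PRECEDENCE}
    evidence = Counter(f for f in record_life_forms if f in LIFE_FORM_PRECEDENCE)
    if len(backbone_set) == 1:
        return next(iter(backbone_set))
    candidates = backbone_set or set(evidence)
    if not candidates:
        return NO_INFO
    restricted = {f: evidence.get(f, 0) for f in candidates}
    best = max(restricted.values())
    tied = [f for f, n in restricted.items() if n == best]
    return min(tied, key=LIFE_FORM_PRECEDENCE.index)


def annotate_species(
    species_name: str,
    backbone: Backbone,
    assessments: Mapping[str, str],
    records: Iterable[OccurrenceRecord] = (),
    vegetation_map: Mapping[str, str] | None = None,
) -> SpeciesTraits:
    """Build the full trait row for one accepted species.

    Species absent from the backbone (possible only for review-added
    taxa) get no_info/unknown traits plus a warning; taxonomist-supplied
    trait overrides may ride on the records' ``extras`` under
    ``trait:origin`` / ``trait:category`` / ``trait:lifeForm``.
    """
    records = list(records)
    overrides: dict[str, str] = {}
    for r in records:
        for k, v in r.extras.items():
            if k.startswith("trait:"):
                overrides[k.removeprefix("trait:")] = v

    entry = backbone.accepted_entry(species_name)
    if entry is None:
        if not overrides:
            warnings.warn(f"species {species_name!r} absent from backbone; traits unknown",
                          stacklevel=2)
        return SpeciesTraits(
            species_name,
            origin=overrides.get("origin", "native"),
            threat_category=overrides.get("category", assessments.get(species_name, "NE")),
            life_form=overrides.get("lifeForm", NO_INFO),
        )

    evidence = [r.life_form for r in records if r.life_form]
    return SpeciesTraits(
        species_name=species_name,
        vegetation_class=classify_vegetation(entry.vegetation_types, vegetation_map),
        life_form=classify_life_form(entry.life_forms, evidence),
        origin=entry.origin,
        endemic_to_country=entry.endemic_to_country,
        threat_category=assessments.get(species_name, "NE"),
    )


def write_species_traits(traits: Iterable[SpeciesTraits], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("speciesName\tvegetationClass\tlifeForm\torigin\tendemicToCountry\tthreatCategory\n")
        for t in traits:
            endemic = "" if t.endemic_to_country is None else str(t.endemic_to_country)
            fh.write(f"{t.species_name}\t{t.vegetation_class}\t{t.life_form}\t"
                     f"{t.origin}\t{endemic}\t{t.threat_category}\n")
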