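"""Synthetic herbarium data with a machine-readable truth manifest.

Generates a backbone, a threat-assessment table and a raw occurrence
file with planted imperfections — genus-level determinations,
out-of-area localities, exact duplicate twins keyed on
(collector, number, year), synonym usage, one-edit misspellings,
missing years and collectors — plus a :class:`SyntheticTruth` manifest
recording exactly what was planted, so every pipeline stage is testable
and parameter-recoverable without any download.

Names are synthesized from pronounceable syllables rather than drawn
from real floras: this keeps edit-distance ground truth unambiguous
(a planted misspelling is guaranteed closer to its source name than to
any other backbone name) and avoids collisions with real taxonomies.
All randomness flows from one seeded generator consumed in a fixed
stage order, so identical seed and config give byte-identical files.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._text import fold_name
from .annotation import LIFE_FORM_PRECEDENCE, NO_INFO, VEG_BOTH, VEG_FOREST, VEG_GRASSLAND
from .cleaning import Gazetteer, normalize_collector
from .conservation import DEFAULT_CUTOFF_YEAR, HAS_RECENT, ONLY_OLD, TEMPORAL_UNKNOWN
from .dwc_io import (
    GROUPS,
    PRIORITY_CATEGORIES,
    Backbone,
    BackboneEntry,
    OccurrenceRecord,
    write_checklist,
)
from .taxonomy import NameIndex

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"

IN_AREA_LOCALITIES = (
    "Parque Nacional do Itatiaia, trilha Véu da Noiva",
    "Parque Nacional do Itatiaia, planalto",
    "Itatiaia, margem do rio Campo Belo",
    "PNI, caminho das Agulhas Negras, Itatiaia",
    "Itatiaia, Lote 31",
)
OUT_OF_AREA_LOCALITIES = (
    "Serra da Bocaina, caminho do rio",
    "Serra dos Órgãos, vertente sul",
    "Itamonte, fazenda fora do parque, Mantiqueira",
)
GAZETTEER_INCLUDE = ("itatiaia", "pni")
GAZETTEER_EXCLUDE = ("bocaina", "órgãos", "fora do parque")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults give ~800 species in three groups (proportioned like a
    large Atlantic Forest park flora: overwhelmingly angiosperms, a
    handful of gymnosperms) and ~5,000 base records with a right-skewed
    records-per-species distribution, 10% duplicate twins, 5% one-edit
    misspellings, 2% out-of-area localities and 5% genus-level
    determinations.
    """

    seed: int = 42
    n_species: dict[str, int] = field(
        default_factory=lambda: {"angiosperm": 680, "gymnosperm": 5, "lycophyte_fern": 115}
    )
    n_families: dict[str, int] = field(
        default_factory=lambda: {"angiosperm": 50, "gymnosperm": 3, "lycophyte_fern": 12}
    )
    n_genera: dict[str, int] = field(
        default_factory=lambda: {"angiosperm": 240, "gymnosperm": 5, "lycophyte_fern": 40}
    )
    synonym_rate: float = 0.3
    synonym_usage_rate: float = 0.25
    mean_records_per_species: float = 6.25
    duplicate_rate: float = 0.10
    misspelling_rate: float = 0.05
    max_planted_distance: int = 1
    out_of_area_rate: float = 0.02
    undetermined_rate: float = 0.05
    missing_year_rate: float = 0.02
    missing_collector_rate: float = 0.02
    old_year_range: tuple[int, int] = (1871, DEFAULT_CUTOFF_YEAR)
    recent_year_range: tuple[int, int] = (DEFAULT_CUTOFF_YEAR + 1, 2018)
    old_record_fraction: float = 0.30
    peak_year: int = 1995
    peak_year_fraction: float = 0.12
    threat_distribution: dict[str, float] = field(
        default_factory=lambda: {"CR": 0.01, "EN": 0.02, "VU": 0.02, "NT": 0.03, "LC": 0.35, "DD": 0.02}
    )
    non_native_rate: float = 0.034
    endemic_rate: float = 0.5
    n_priority_species: int = 16
    n_collectors: int = 40

    def validate(self) -> None:
        rates = {
            "synonym_rate": self.synonym_rate,
            "synonym_usage_rate": self.synonym_usage_rate,
            "duplicate_rate": self.duplicate_rate,
            "misspelling_rate": self.misspelling_rate,
            "out_of_area_rate": self.out_of_area_rate,
            "undetermined_rate": self.undetermined_rate,
            "missing_year_rate": self.missing_year_rate,
            "missing_collector_rate": self.missing_collector_rate,
            "old_record_fraction": self.old_record_fraction,
            "peak_year_fraction": self.peak_year_fraction,
            "non_native_rate": self.non_native_rate,
            "endemic_rate": self.endemic_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        for g in self.n_species:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if self.n_species[g] < self.n_genera.get(g, 0):
                raise ValueError(f"group {g!r}: fewer species than genera")
            if self.n_genera.get(g, 0) < self.n_families.get(g, 0):
                raise ValueError(f"group {g!r}: fewer genera than families")
        if self.n_priority_species > sum(self.n_species.values()):
            raise ValueError("n_priority_species exceeds the number of species")
        if sum(self.threat_distribution.values()) > 1.0 + 1e-9:
            raise ValueError("threat_distribution sums to more than 1")
        if self.mean_records_per_species < 1.0:
            raise ValueError("mean_records_per_species must be >= 1")


@dataclass
class SyntheticTruth:
    """What was planted; the pipeline must recover all of it exactly."""

    species_by_group: dict[str, list[str]]
    synonym_map: dict[str, str]                  # synonym -> accepted
    n_undetermined: int
    n_out_of_area: int
    n_duplicate_twins: int
    n_misspelled: int
    n_final_records: int
    record_counts: dict[str, int]                # species -> retained records
    temporal_status: dict[str, str]
    vegetation_class: dict[str, str]
    life_form: dict[str, str]
    origin: dict[str, str]
    threat_category: dict[str, str]              # NE for unassessed
    priority_species: list[str]
    collector_counts: dict[str, int]             # over retained records
    peak_year: int | None
    richness_by_group: dict[str, tuple[int, int, int]]  # species, genera, families
    record_flags: dict[str, dict[str, bool]]     # catalogNumber -> planted flags


@dataclass
class GeneratedFiles:
    occurrences: Path
    backbone: Path
    assessments: Path
    gazetteer: Path


def default_gazetteer() -> Gazetteer:
    return Gazetteer(frozenset(GAZETTEER_INCLUDE), frozenset(GAZETTEER_EXCLUDE))


def _syllable(rng: np.random.Generator) -> str:
    return _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


def _new_word(rng: np.random.Generator, n_syllables: int, used: set[str]) -> str:
    for _ in range(1000):
        w = _word(rng, n_syllables)
        if w not in used:
            used.add(w)
            return w
    raise RuntimeError("name space exhausted; increase syllable count")


def _perturb_epithet(rng: np.random.Generator, epithet: str) -> str:
    """One random edit (substitute / insert / delete) on the epithet."""
    letters = _CONSONANTS + _VOWELS
    op = rng.integers(3)
    i = int(rng.integers(len(epithet)))
    if op == 0:  # substitute
        repl = letters[rng.integers(len(letters))]
        while repl == epithet[i]:
            repl = letters[rng.integers(len(letters))]
        return epithet[:i] + repl + epithet[i + 1 :]
    if op == 1:  # insert
        return epithet[:i] + letters[rng.integers(len(letters))] + epithet[i:]
    if len(epithet) <= 2:  # deletion would leave too little; substitute instead
        repl = letters[rng.integers(len(letters))]
        while repl == epithet[i]:
            repl = letters[rng.integers(len(letters))]
        return epithet[:i] + repl + epithet[i + 1 :]
    return epithet[:i] + epithet[i + 1 :]


def _format_date(rng: np.random.Generator, year: int) -> str:
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    style = rng.integers(3)
    if style == 0:
        return f"{year:04d}-{month:02d}-{day:02d}"
    if style == 1:
        return f"{day:02d}/{month:02d}/{year:04d}"
    return f"{year:04d}"


def _expected_life_form(backbone_forms: frozenset[str], evidence: Counter) -> str:
    """Inline replica of the majority rule for the truth manifest."""
    forms = {f for f in backbone_forms if f in LIFE_FORM_PRECEDENCE}
    if len(forms) == 1:
        return next(iter(forms))
    candidates = forms or set(evidence)
    if not candidates:
        return NO_INFO
    restricted = {f: evidence.get(f, 0) for f in candidates}
    best = max(restricted.values())
    tied = [f for f, n in restricted.items() if n == best]
    return min(tied, key=LIFE_FORM_PRECEDENCE.index)


def generate(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[GeneratedFiles, SyntheticTruth]:
    """Write backbone / assessments / occurrences / gazetteer files under
    ``out_dir`` and return their paths with the truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- taxon scaffolding -------------------------------------------------
    used_words: set[str] = set()
    entries: list[BackboneEntry] = []
    species_by_group: dict[str, list[str]] = {}
    synonym_map: dict[str, str] = {}
    species_meta: dict[str, BackboneEntry] = {}

    groups = [g for g in GROUPS if config.n_species.get(g, 0) > 0]
    for group in groups:
        n_sp = config.n_species[group]
        n_gen = config.n_genera.get(group, max(1, n_sp // 3))
        n_fam = config.n_families.get(group, max(1, n_gen // 4))
        families = [(_new_word(rng, 3, used_words).capitalize() + "aceae") for _ in range(n_fam)]
        genera = [_new_word(rng, 3, used_words).capitalize() for _ in range(n_gen)]
        # every family gets at least one genus, every genus one species
        genus_family = {
            genera[i]: families[i] if i < n_fam else families[int(rng.integers(n_fam))]
            for i in range(n_gen)
        }
        species_genus = [genera[i] if i < n_gen else genera[int(rng.integers(n_gen))]
                         for i in range(n_sp)]
        names = []
        for genus in species_genus:
            name = f"{genus} {_new_word(rng, int(rng.integers(3, 5)), used_words)}"
            non_native = bool(rng.random() < config.non_native_rate)
            if non_native:
                endemic: bool | None = False
                life_forms: frozenset[str] = (
                    frozenset() if rng.random() < 0.5 else frozenset({"tree"})
                )
                veg: frozenset[str] = frozenset()
            else:
                endemic = bool(rng.random() < config.endemic_rate)
                life_forms = _draw_life_forms(rng, group)
                veg = _draw_vegetation(rng)
            entry = BackboneEntry(
                name=name,
                author=_word(rng, 2).capitalize() + ".",
                status="accepted",
                accepted_name=name,
                group=group,
                family=genus_family[genus],
                origin="non_native" if non_native else "native",
                endemic_to_country=endemic,
                life_forms=life_forms,
                vegetation_types=veg,
            )
            entries.append(entry)
            species_meta[name] = entry
            names.append(name)
            if rng.random() < config.synonym_rate:
                syn = f"{_new_word(rng, 3, used_words).capitalize()} {_new_word(rng, int(rng.integers(3, 5)), used_words)}"
                entries.append(
                    BackboneEntry(
                        name=syn,
                        author=_word(rng, 2).capitalize() + ".",
                        status="synonym",
                        accepted_name=name,
                        group=group,
                        family=genus_family[genus],
                    )
                )
                synonym_map[syn] = name
        species_by_group[group] = names

    all_species = [s for g in groups for s in species_by_group[g]]

    # ---- threat assessments & forced priority species ----------------------
    cats = sorted(config.threat_distribution)
    probs = np.array([config.threat_distribution[c] for c in cats])
    threat: dict[str, str] = {}
    for sp in all_species:
        u = rng.random()
        cum = 0.0
        assigned = "NE"
        for c, p in zip(cats, probs):
            cum += p
            if u < cum:
                assigned = c
                break
        threat[sp] = assigned

    priority_idx = rng.choice(len(all_species), size=config.n_priority_species, replace=False)
    priority_forced = sorted(all_species[int(i)] for i in priority_idx)
    prio_cats = sorted(PRIORITY_CATEGORIES)
    for sp in priority_forced:
        threat[sp] = prio_cats[int(rng.integers(len(prio_cats)))]

    # ---- collectors --------------------------------------------------------
    collectors: list[str] = []
    used_keys: set[str] = set()
    while len(collectors) < config.n_collectors:
        initials = ". ".join(
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))].upper()
            for _ in range(int(rng.integers(1, 3)))
        )
        surname = _new_word(rng, 2, used_words).capitalize()
        name = f"{initials}. {surname}"
        key = normalize_collector(name)
        if key not in used_keys:
            used_keys.add(key)
            collectors.append(name)
    weights = 1.0 / np.arange(1, config.n_collectors + 1)
    weights /= weights.sum()
    collector_counter = {c: 0 for c in collectors}

    # ---- base records ------------------------------------------------------
    records: list[OccurrenceRecord] = []
    flags: dict[str, dict[str, bool]] = {}
    protected: set[int] = set()       # record indices exempt from destructive edits
    priority_set = set(priority_forced)
    catalog_seq = 0

    def next_catalog(code: str) -> str:
        nonlocal catalog_seq
        catalog_seq += 1
        return f"{code}{catalog_seq:08d}"

    p_geom = 1.0 / config.mean_records_per_species
    for group in groups:
        for sp in species_by_group[group]:
            entry = species_meta[sp]
            k = 1 if sp in priority_set else int(rng.geometric(p_geom))
            for j in range(k):
                if sp in priority_set:
                    year = int(rng.integers(config.old_year_range[0], config.old_year_range[1] + 1))
                elif rng.random() < config.old_record_fraction:
                    year = int(rng.integers(config.old_year_range[0], config.old_year_range[1] + 1))
                elif rng.random() < config.peak_year_fraction:
                    year = config.peak_year
                else:
                    year = int(rng.integers(config.recent_year_range[0], config.recent_year_range[1] + 1))
                collector = collectors[int(rng.choice(config.n_collectors, p=weights))]
                collector_counter[collector] += 1
                written = sp
                syns = [s for s, a in synonym_map.items() if a == sp]
                if syns and rng.random() < config.synonym_usage_rate:
                    written = syns[0]
                genus, epithet = written.split(" ", 1)
                life_form = ""
                if entry.life_forms:
                    lf_sorted = sorted(entry.life_forms)
                    life_form = lf_sorted[int(rng.integers(len(lf_sorted)))]
                rec = OccurrenceRecord(
                    catalog_number=next_catalog("RB"),
                    scientific_name=f"{written} {entry.author}",
                    collection_code="RB",
                    family=entry.family,
                    genus=genus,
                    specific_epithet=epithet,
                    taxon_rank="SPECIES",
                    scientific_name_authorship=entry.author,
                    recorded_by=collector,
                    record_number=str(1000 + collector_counter[collector]
                                      + collectors.index(collector) * 100000),
                    event_date=_format_date(rng, year),
                    locality=IN_AREA_LOCALITIES[int(rng.integers(len(IN_AREA_LOCALITIES)))],
                    group=group,
                    life_form=life_form,
                    extras={"taxonID": sp.replace(" ", "_"), "kingdom": "Plantae",
                            "rightsHolder": "JBRJ", "modified": ""},
                )
                rec.collection_year = year
                idx = len(records)
                records.append(rec)
                flags[rec.catalog_number] = {
                    "isDuplicateTwin": False, "isMisspelled": False,
                    "isOutOfArea": False, "isUndetermined": False,
                }
                if j == 0 or sp in priority_set:
                    protected.add(idx)

    n_base = len(records)
    species_of: dict[str, str] = {}  # catalogNumber -> accepted species
    for rec in records:
        written_binomial = rec.binomial()
        species_of[rec.catalog_number] = synonym_map.get(written_binomial, written_binomial)

    # ---- destructive corruptions (fixed order, disjoint sets) --------------
    destructible = [i for i in range(n_base) if i not in protected]
    order = rng.permutation(len(destructible))
    pool = [destructible[int(i)] for i in order]

    n_ooa = int(round(config.out_of_area_rate * n_base))
    n_und = int(round(config.undetermined_rate * n_base))
    if n_ooa + n_und > len(pool):
        raise ValueError("corruption rates too high for the record pool")
    ooa_idx, pool = pool[:n_ooa], pool[n_ooa:]
    und_idx, pool = pool[:n_und], pool[n_und:]

    for i in ooa_idx:
        records[i].locality = OUT_OF_AREA_LOCALITIES[int(rng.integers(len(OUT_OF_AREA_LOCALITIES)))]
        flags[records[i].catalog_number]["isOutOfArea"] = True
    for i in und_idx:
        r = records[i]
        r.specific_epithet = ""
        r.taxon_rank = "GENUS"
        r.scientific_name = r.genus
        flags[r.catalog_number]["isUndetermined"] = True

    # ---- misspellings (on surviving, determined records) -------------------
    backbone = Backbone([dataclasses.replace(e) for e in entries])
    index = NameIndex(backbone)
    corrupted = set(ooa_idx) | set(und_idx)
    candidates = [i for i in range(n_base) if i not in corrupted and i not in protected]
    order = rng.permutation(len(candidates))
    n_mis_target = int(round(config.misspelling_rate * n_base))
    n_mis = 0
    for oi in order:
        if n_mis >= n_mis_target:
            break
        r = records[candidates[int(oi)]]
        source = r.binomial()
        for _ in range(50):
            bad_epithet = _perturb_epithet(rng, r.specific_epithet)
            perturbed = f"{r.genus} {bad_epithet}"
            hits = index.within(fold_name(perturbed), config.max_planted_distance)
            if [h for h, _ in hits] == [source] and index.exact(fold_name(perturbed)) is None:
                r.specific_epithet = bad_epithet
                r.scientific_name = f"{perturbed} {r.scientific_name_authorship}"
                flags[r.catalog_number]["isMisspelled"] = True
                n_mis += 1
                break

    # ---- missing years / collectors ----------------------------------------
    eligible = [i for i in range(n_base) if i not in protected and i not in corrupted]
    order = rng.permutation(len(eligible))
    n_my = int(round(config.missing_year_rate * n_base))
    for oi in order[:n_my]:
        r = records[eligible[int(oi)]]
        r.event_date = "" if rng.random() < 0.5 else "s.d."
        r.collection_year = None
    order = rng.permutation(len(eligible))
    n_mc = int(round(config.missing_collector_rate * n_base))
    for oi in order[:n_mc]:
        records[eligible[int(oi)]].recorded_by = ""

    # ---- duplicate twins ----------------------------------------------------
    twin_sources = [
        i for i in range(n_base)
        if i not in corrupted
        and species_of[records[i].catalog_number] not in priority_set
        and records[i].recorded_by and records[i].collection_year is not None
    ]
    n_twins = int(round(config.duplicate_rate * n_base))
    if n_twins > len(twin_sources):
        raise ValueError("duplicate_rate too high for available complete-key records")
    chosen = rng.choice(len(twin_sources), size=n_twins, replace=False)
    twins: list[OccurrenceRecord] = []
    for ci in sorted(int(c) for c in chosen):
        src = records[twin_sources[ci]]
        code = ("R", "HB")[int(rng.integers(2))]
        twin = dataclasses.replace(
            src,
            catalog_number=next_catalog(code),
            collection_code=code,
            locality=IN_AREA_LOCALITIES[int(rng.integers(len(IN_AREA_LOCALITIES)))],
            extras=dict(src.extras),
        )
        twins.append(twin)
        flags[twin.catalog_number] = {
            "isDuplicateTwin": True, "isMisspelled": flags[src.catalog_number]["isMisspelled"],
            "isOutOfArea": False, "isUndetermined": False,
        }
        species_of[twin.catalog_number] = species_of[src.catalog_number]
    records.extend(twins)

    # shuffle the file order so nothing downstream can rely on grouping
    file_order = rng.permutation(len(records))
    records = [records[int(i)] for i in file_order]

    # ---- truth manifest -----------------------------------------------------
    surviving = [
        r for r in records
        if not flags[r.catalog_number]["isOutOfArea"]
        and not flags[r.catalog_number]["isUndetermined"]
        and not flags[r.catalog_number]["isDuplicateTwin"]
    ]
    record_counts: Counter = Counter(species_of[r.catalog_number] for r in surviving)
    years_by_species: dict[str, list[int | None]] = {}
    lf_evidence: dict[str, Counter] = {}
    collector_counts: Counter = Counter()
    year_hist: Counter = Counter()
    for r in surviving:
        sp = species_of[r.catalog_number]
        years_by_species.setdefault(sp, []).append(r.collection_year)
        lf_evidence.setdefault(sp, Counter())
        if r.life_form:
            lf_evidence[sp][r.life_form] += 1
        collector_counts[normalize_collector(r.recorded_by)] += 1
        if r.collection_year is not None:
            year_hist[r.collection_year] += 1

    cutoff = config.old_year_range[1]
    temporal: dict[str, str] = {}
    for sp, years in years_by_species.items():
        known = [y for y in years if y is not None]
        if not known:
            temporal[sp] = TEMPORAL_UNKNOWN
        elif any(y > cutoff for y in known):
            temporal[sp] = HAS_RECENT
        else:
            temporal[sp] = ONLY_OLD

    veg_truth: dict[str, str] = {}
    lf_truth: dict[str, str] = {}
    origin_truth: dict[str, str] = {}
    for sp in all_species:
        e = species_meta[sp]
        forest = any("floresta" in v for v in e.vegetation_types)
        grass = any(("campo" in v or "inselberg" in v) for v in e.vegetation_types)
        veg_truth[sp] = (
            VEG_BOTH if (forest and grass)
            else VEG_FOREST if forest
            else VEG_GRASSLAND if grass
            else NO_INFO
        )
        lf_truth[sp] = _expected_life_form(e.life_forms, lf_evidence.get(sp, Counter()))
        origin_truth[sp] = e.origin

    priority_truth = sorted(
        sp for sp in all_species
        if record_counts.get(sp, 0) == 1
        and temporal.get(sp) == ONLY_OLD
        and threat[sp] in PRIORITY_CATEGORIES
    )
    peak = min(year_hist.items(), key=lambda yc: (-yc[1], yc[0]))[0] if year_hist else None

    richness_by_group = {}
    for group in groups:
        sps = species_by_group[group]
        richness_by_group[group] = (
            len(sps),
            len({s.split(" ", 1)[0] for s in sps}),
            len({species_meta[s].family for s in sps}),
        )

    truth = SyntheticTruth(
        species_by_group={g: sorted(v) for g, v in species_by_group.items()},
        synonym_map=synonym_map,
        n_undetermined=n_und,
        n_out_of_area=n_ooa,
        n_duplicate_twins=n_twins,
        n_misspelled=n_mis,
        n_final_records=len(surviving),
        record_counts=dict(record_counts),
        temporal_status=temporal,
        vegetation_class=veg_truth,
        life_form=lf_truth,
        origin=origin_truth,
        threat_category=threat,
        priority_species=priority_truth,
        collector_counts=dict(collector_counts),
        peak_year=peak,
        richness_by_group=richness_by_group,
        record_flags=flags,
    )

    # ---- files --------------------------------------------------------------
    paths = GeneratedFiles(
        occurrences=out_dir / "occurrences.tsv",
        backbone=out_dir / "backbone.tsv",
        assessments=out_dir / "assessments.tsv",
        gazetteer=out_dir / "gazetteer.tsv",
    )
    write_checklist(records, paths.occurrences)
    _write_backbone(entries, paths.backbone)
    with open(paths.assessments, "w", encoding="utf-8") as fh:
        fh.write("speciesName\tcategory\n")
        for sp in all_species:
            if threat[sp] != "NE":
                fh.write(f"{sp}\t{threat[sp]}\n")
    with open(paths.gazetteer, "w", encoding="utf-8") as fh:
        for t in GAZETTEER_INCLUDE:
            fh.write(f"{t}\tinclude\n")
        for t in GAZETTEER_EXCLUDE:
            fh.write(f"{t}\texclude\n")
    return paths, truth


def _draw_life_forms(rng: np.random.Generator, group: str) -> frozenset[str]:
    if group == "gymnosperm":
        return frozenset({"tree"})
    if group == "lycophyte_fern":
        return frozenset({"herb"} if rng.random() < 0.9 else {"tree"})
    forms = ["herb", "tree", "shrub", "liana", "subshrub"]
    probs = np.array([0.38, 0.25, 0.17, 0.12, 0.08])
    first = forms[int(rng.choice(len(forms), p=probs))]
    if rng.random() < 0.7:
        return frozenset({first})
    second = forms[int(rng.choice(len(forms), p=probs))]
    return frozenset({first, second})


def _draw_vegetation(rng: np.random.Generator) -> frozenset[str]:
    forest_labels = [
        "floresta ombrofila densa", "floresta ombrofila mista",
        "floresta estacional semidecidual", "floresta altomontana",
    ]
    grass_labels = ["campo de altitude", "campo rupestre", "inselberg"]
    u = rng.random()
    if u < 0.05:
        return frozenset()
    if u < 0.75:
        k = int(rng.integers(1, 3))
        return frozenset(forest_labels[int(i)] for i in rng.choice(4, size=k, replace=False))
    if u < 0.90:
        k = int(rng.integers(1, 3))
        return frozenset(grass_labels[int(i)] for i in rng.choice(3, size=k, replace=False))
    return frozenset({
        forest_labels[int(rng.integers(4))], grass_labels[int(rng.integers(3))]
    })


def _write_backbone(entries: list[BackboneEntry], path: Path) -> None:
    cols = ["name", "author", "status", "acceptedName", "group", "family",
            "origin", "endemicToCountry", "lifeForms", "vegetationTypes"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in entries:
            endemic = "" if e.endemic_to_country is None else str(e.endemic_to_country)
            fh.write("\t".join([
                e.name, e.author, e.status, e.accepted_name, e.group, e.family,
                e.origin, endemic,
                ";".join(sorted(e.life_forms)),
                ";".join(sorted(e.vegetation_types)),
            ]) + "\n")


def verify_recovery(pipeline_result, truth: SyntheticTruth) -> dict[str, bool]:
    """Compare a full pipeline run on generated files against the truth
    manifest. Returns one exact-match boolean per planted statistic."""
    from .summary import collector_stats, richness, temporal_profile

    summaries = pipeline_result.summaries
    ledger = pipeline_result.ledger
    final_records = pipeline_result.records

    species_found = {s.species_name for s in summaries}
    species_planted = {sp for v in truth.species_by_group.values() for sp in v}

    rich = richness(summaries)
    rich_ok = all(
        (
            rich.species_per_group.get(g, 0),
            rich.genera_per_group.get(g, 0),
            rich.families_per_group.get(g, 0),
        ) == truth.richness_by_group[g]
        for g in truth.richness_by_group
    )

    profile = temporal_profile(final_records)
    collectors = dict(collector_stats(final_records))

    checks = {
        "species_set": species_found == species_planted,
        "richness_per_group": rich_ok,
        "determination_removals": ledger.removed_at("determination") == truth.n_undetermined,
        "locality_removals": ledger.removed_at("locality") == truth.n_out_of_area,
        "dedup_removals": ledger.removed_at("duplicates") == truth.n_duplicate_twins,
        "final_record_count": len(final_records) == truth.n_final_records,
        "no_unresolved": len(pipeline_result.unresolved) == 0,
        "record_counts": {s.species_name: s.record_count for s in summaries} == truth.record_counts,
        "temporal_status": {s.species_name: s.temporal_status for s in summaries} == truth.temporal_status,
        "priority_set": sorted(s.species_name for s in summaries if s.priority) == truth.priority_species,
        "collector_counts": collectors == truth.collector_counts,
        "peak_year": profile.peak_year() == truth.peak_year,
    }
    return checks
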