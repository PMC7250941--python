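"""Determination filter, locality gazetteer, dedup key semantics, ledger."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbcat import (
    CleaningLedger,
    Gazetteer,
    OccurrenceRecord,
    StageCount,
    deduplicate,
    filter_determined,
    filter_locality,
    normalize_collector,
    run_cleaning,
)
from herbcat.cleaning import UNKNOWN_COLLECTOR


def rec(cn, name="Aus bus", rank="SPECIES", epithet="bus", genus="Aus",
        collector="A.C. Brade", number="12345", year=1942, locality="Itatiaia, trilha",
        code="RB", group="angiosperm"):
    r = OccurrenceRecord(
        catalog_number=cn, scientific_name=name, genus=genus, specific_epithet=epithet,
        taxon_rank=rank, recorded_by=collector, record_number=number,
        locality=locality, collection_code=code, group=group,
    )
    r.collection_year = year
    return r


# ---- determination ---------------------------------------------------------

def test_species_level_kept_genus_level_removed():
    kept, removed = filter_determined([
        rec("RB1", rank="SPECIES", epithet="angustifolia"),
        rec("RB2", rank="GENUS", epithet="", name="Aus"),
    ])
    assert [r.catalog_number for r in kept] == ["RB1"]
    assert [r.catalog_number for r in removed] == ["RB2"]


def test_infraspecific_kept_and_collapses_to_binomial():
    r = rec("RB1", rank="VARIETY", name="Aus bus var. cus", genus="Aus", epithet="bus")
    kept, removed = filter_determined([r])
    assert kept == [r] and removed == []
    assert r.binomial() == "Aus bus"


def test_unrecognizable_rank_without_epithet_is_undetermined():
    kept, removed = filter_determined([rec("RB1", rank="indet.", epithet="", name="Aus")])
    assert kept == [] and len(removed) == 1


# ---- locality --------------------------------------------------------------

GAZ = Gazetteer(frozenset({"itatiaia"}), frozenset({"bocaina", "itatiaiuçu"}))


def test_include_term_keeps():
    assert GAZ.classify("Parque Nacional do Itatiaia, trilha Véu da Noiva") == "keep"


def test_exclude_term_removes():
    assert GAZ.classify("Serra da Bocaina") == "remove"


def test_accent_and_case_insensitive_matching():
    assert GAZ.classify("SERRA DA BOCAÍNA") == "remove"
    assert GAZ.classify("ITATIAIA, planalto") == "keep"


@pytest.mark.parametrize(
    "locality,verdict",
    [
        # enumeration of include/exclude overlap against the precedence rule
        ("Itatiaia", "keep"),                       # include word-boundary only
        ("Serra da Bocaina", "remove"),             # exclude only
        ("Itatiaia, perto da Bocaina", "keep"),     # boundary include beats exclude
        ("Itatiaiuçu, MG", "queue"),                # substring include vs exclude -> review
        ("Serra do Mar", "queue"),                  # neither -> default keep_and_queue
    ],
)
def test_locality_precedence_cases(locality, verdict):
    gaz = Gazetteer(frozenset({"itatiai", "itatiaia"}), frozenset({"bocaina", "itatiaiuçu"}))
    assert gaz.classify(locality) == verdict


def test_default_policy_drop():
    gaz = Gazetteer(frozenset({"itatiaia"}), frozenset({"bocaina"}), default_policy="drop")
    assert gaz.classify("Serra do Mar") == "remove"


def test_gazetteer_overlap_rejected():
    with pytest.raises(ValueError):
        Gazetteer(frozenset({"itatiaia"}), frozenset({"itatiaia"}))


def test_filter_locality_queue_stays_kept():
    records = [rec("RB1", locality="Itatiaia"), rec("RB2", locality="Serra do Mar"),
               rec("RB3", locality="Serra da Bocaina")]
    kept, removed, queued = filter_locality(records, GAZ)
    assert {r.catalog_number for r in kept} == {"RB1", "RB2"}
    assert [r.catalog_number for r in removed] == ["RB3"]
    assert [r.catalog_number for r in queued] == ["RB2"]


# ---- collector normalization ----------------------------------------------

@pytest.mark.parametrize(
    "raw,key",
    [
        ("A.C. Brade", "ac brade"),
        ("BRADE, A. C.", "brade a c"),
        ("", UNKNOWN_COLLECTOR),
        (None, UNKNOWN_COLLECTOR),
        ("  J.  Câmara ", "j camara"),
    ],
)
def test_normalize_collector(raw, key):
    assert normalize_collector(raw) == key


# ---- deduplication ---------------------------------------------------------

def test_duplicates_merge_across_collections():
    unique, removed, pairs = deduplicate([
        rec("RB9", code="RB"), rec("R1", code="R"),
    ])
    assert len(unique) == 1 and len(removed) == 1
    assert pairs == [("R1", "RB9")]  # smallest catalogNumber kept


def test_different_years_do_not_merge():
    unique, removed, _ = deduplicate([rec("RB1", year=1941), rec("RB2", year=1942)])
    assert len(unique) == 2 and removed == []


@pytest.mark.parametrize("field", ["collector", "number", "year"])
def test_incomplete_keys_never_merge(field):
    kwargs = {"collector": "", "number": "", "year": None}
    a = rec("RB1", **{field: kwargs[field]})
    b = rec("RB2", **{field: kwargs[field]})
    unique, removed, _ = deduplicate([a, b])
    assert len(unique) == 2 and removed == []


def brute_force_dedup(records):
    """Independent oracle: group by complete key, keep min catalogNumber."""
    by_key = {}
    incomplete = []
    for r in records:
        coll = normalize_collector(r.recorded_by)
        if coll == UNKNOWN_COLLECTOR or not r.record_number.strip() or r.collection_year is None:
            incomplete.append(r.catalog_number)
        else:
            by_key.setdefault((coll, r.record_number.strip(), r.collection_year), []).append(
                r.catalog_number
            )
    kept = set(incomplete)
    for cns in by_key.values():
        kept.add(min(cns))
    return kept


def _random_records(n, seed):
    rnd = random.Random(seed)
    collectors = ["A.C. Brade", "P. Porto", "W. Barros", ""]
    out = []
    for i in range(n):
        out.append(
            rec(
                f"RB{i:05d}",
                collector=rnd.choice(collectors),
                number=rnd.choice(["", "1", "2", "3", "44"]),
                year=rnd.choice([None, 1940, 1941, 1942]),
            )
        )
    return out


def test_dedup_matches_bruteforce_oracle_on_1000_records():
    records = _random_records(1000, seed=123)
    unique, removed, _ = deduplicate(records)
    assert len(unique) + len(removed) == len(records)
    assert {r.catalog_number for r in unique} == brute_force_dedup(records)


def test_dedup_idempotent():
    records = _random_records(300, seed=5)
    once, _, _ = deduplicate(records)
    twice, removed2, _ = deduplicate(once)
    assert removed2 == []
    assert {r.catalog_number for r in twice} == {r.catalog_number for r in once}


@settings(max_examples=50, derandomize=True)
@given(st.randoms(use_true_random=False))
def test_dedup_permutation_invariant(rnd):
    records = _random_records(60, seed=9)
    shuffled = records[:]
    rnd.shuffle(shuffled)
    kept_a = {r.catalog_number for r in deduplicate(records)[0]}
    kept_b = {r.catalog_number for r in deduplicate(shuffled)[0]}
    assert kept_a == kept_b


# ---- run_cleaning and the ledger -------------------------------------------

def test_run_cleaning_constructed_fixture():
    records = (
        [rec(f"RB{i}", number=str(i)) for i in range(6)]
        + [rec("RB90", rank="GENUS", epithet="", name="Aus"),
           rec("RB91", rank="FAMILY", epithet="", name="Ausaceae")]
        + [rec("RB92", locality="Serra da Bocaina", number="92")]
        + [rec("RB05", number="5")]  # twin of RB5 (same collector/number/year)
    )
    records[-1].catalog_number = "RB95"
    result = run_cleaning(records, GAZ)
    stages = [(s.stage, s.n_input, s.kept, s.removed) for s in result.ledger.stages]
    assert stages == [
        ("determination", 10, 8, 2),
        ("locality", 8, 7, 1),
        ("duplicates", 7, 6, 1),
    ]
    assert len(result.records) == 6


def test_run_cleaning_empty_input():
    result = run_cleaning([], GAZ)
    assert result.records == [] and result.ledger.stages == []


def test_ledger_conservation_enforced():
    ledger = CleaningLedger()
    with pytest.raises(ValueError, match="conservation"):
        ledger.add(StageCount("angiosperm", "determination", 10, 8, 1))


def test_ledger_chain_telescopes():
    ledger = CleaningLedger.replay(
        "angiosperm", 10888, [("locality", 95), ("duplicates", 734)]
    )
    ledger.validate_chain()
    assert ledger.final_kept("angiosperm") == 10888 - 95 - 734
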