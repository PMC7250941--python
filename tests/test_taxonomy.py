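"""Name resolution: exact, synonym, fuzzy, ambiguity, review actions."""

import itertools

import pytest

from herbcat import (
    CleaningLedger,
    DwcIOError,
    OccurrenceRecord,
    apply_review,
    match_name,
    resolve_records,
)
from herbcat._text import fold_name
from herbcat.taxonomy import (
    MATCH_AMBIGUOUS,
    MATCH_EXACT_ACCEPTED,
    MATCH_FUZZY_ACCEPTED,
    MATCH_NONE,
    MATCH_SYNONYM,
    ReviewAction,
    assign_group,
)


def levenshtein(a: str, b: str) -> int:
    """Reference DP edit distance (independent of edlib)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _rec(cn, name, genus="", epithet="", group="angiosperm"):
    return OccurrenceRecord(
        catalog_number=cn, scientific_name=name, genus=genus,
        specific_epithet=epithet, taxon_rank="SPECIES", group=group,
    )


def test_exact_accepted_match(toy_backbone):
    m = match_name("Aus bus", toy_backbone)
    assert (m.match_type, m.accepted_name, m.edit_distance) == (MATCH_EXACT_ACCEPTED, "Aus bus", 0)


def test_synonym_resolves_to_accepted(toy_backbone):
    m = match_name("Aus cus", toy_backbone)
    assert (m.match_type, m.accepted_name, m.edit_distance) == (MATCH_SYNONYM, "Aus bus", 0)


def test_fuzzy_unique_one_edit(toy_backbone):
    # 'Gymnos sola' is one edit from 'Gymnos solo' and nothing else
    m = match_name("Gymnos sola", toy_backbone, max_distance=1)
    assert (m.match_type, m.accepted_name, m.edit_distance) == (
        MATCH_FUZZY_ACCEPTED, "Gymnos solo", 1,
    )
    # the summed genus+epithet distance agrees with the reference DP oracle
    assert levenshtein("gymnos", "gymnos") + levenshtein("sola", "solo") == 1


def test_equally_near_candidates_are_ambiguous(toy_backbone):
    # 'Dus eno' is one edit from both 'Dus ena' and 'Dus enu'
    m = match_name("Dus eno", toy_backbone, max_distance=1)
    assert m.match_type == MATCH_AMBIGUOUS
    assert m.accepted_name is None
    assert m.candidates == ["Dus ena", "Dus enu"]


def test_no_match_beyond_distance(toy_backbone):
    m = match_name("Zzz qqq", toy_backbone, max_distance=1)
    assert m.match_type == MATCH_NONE and m.accepted_name is None
    assert m.edit_distance > 0


def test_match_is_accent_and_hybrid_insensitive(toy_backbone):
    assert match_name("Áus bús", toy_backbone).accepted_name == "Aus bus"
    assert match_name("Aus × bus", toy_backbone).accepted_name == "Aus bus"


def test_empty_query_is_hard_error(toy_backbone):
    with pytest.raises(ValueError):
        match_name("   ", toy_backbone)


def test_distance_zero_equals_dictionary_lookup(toy_backbone):
    lookup = {}
    for name, entry in toy_backbone.entries.items():
        lookup[fold_name(name)] = entry.accepted_name
    queries = ["Aus bus", "Aus cus", "Aus buz", "Dus ena", "Nope nope", "AUS BUS"]
    for q in queries:
        m = match_name(q, toy_backbone, max_distance=0)
        assert m.accepted_name == lookup.get(fold_name(q))


def test_resolution_is_lossless_and_permutation_invariant(toy_backbone):
    records = [
        _rec("RB1", "Aus bus", "Aus", "bus"),
        _rec("RB2", "Aus cus", "Aus", "cus"),
        _rec("RB3", "Gymnos sola", "Gymnos", "sola"),
        _rec("RB4", "Absent species", "Absent", "species"),
        _rec("RB5", "Dus eno", "Dus", "eno"),
    ]
    for perm in itertools.permutations(records):
        resolved, queued, report = resolve_records(list(perm), toy_backbone)
        assert len(resolved) + len(queued) == len(records)
        assert {r.catalog_number for r in queued} == {"RB4", "RB5"}
        assert {r.accepted_name for r in resolved} == {"Aus bus", "Gymnos solo"}
        assert report[MATCH_NONE] == 1 and report[MATCH_AMBIGUOUS] == 1


def test_accepted_names_are_never_synonyms(toy_backbone):
    records = [_rec("RB1", "Aus cus", "Aus", "cus")]
    resolved, _, _ = resolve_records(records, toy_backbone)
    for r in resolved:
        assert toy_backbone.get(r.accepted_name).status == "accepted"


def test_assign_group(toy_backbone):
    r = _rec("RB1", "Gymnos solo", "Gymnos", "solo", group="angiosperm")
    r.accepted_name = "Gymnos solo"
    assert assign_group(r, toy_backbone) == "gymnosperm"
    r2 = _rec("RB2", "Mystery name")
    assert assign_group(r2, toy_backbone) == "unknown"


# ---- review ----------------------------------------------------------------

def test_review_accept_as_readmits_queued(toy_backbone):
    records = [_rec("RB1", "Aus bus", "Aus", "bus")]
    records[0].accepted_name = "Aus bus"
    queued = [_rec("RB4", "Absent species", "Absent", "species")]
    ledger = CleaningLedger()
    out = apply_review(records, queued,
                       [ReviewAction("RB4", "accept_as", "Absent species")], ledger)
    assert {r.catalog_number for r in out} == {"RB1", "RB4"}
    assert next(r for r in out if r.catalog_number == "RB4").accepted_name == "Absent species"
    additions = [s for s in ledger.stages if s.stage == "review_additions"]
    assert additions[0].delta == 1


def test_review_add_grows_catalogue():
    records = [_rec("RB1", "Aus bus", "Aus", "bus")]
    records[0].accepted_name = "Aus bus"
    out = apply_review(records, [], [
        ReviewAction("HB77", "add", "Other species", {"group": "angiosperm"}),
        ReviewAction("HB78", "add", "Other species2", {"group": "angiosperm"}),
    ])
    assert len(out) == 3
    added = next(r for r in out if r.catalog_number == "HB77")
    assert added.accepted_name == "Other species"


def test_review_remove_and_unknown_catalog_number():
    records = [_rec("RB1", "Aus bus", "Aus", "bus")]
    out = apply_review(records, [], [ReviewAction("RB1", "remove")])
    assert out == []
    with pytest.raises(DwcIOError):
        apply_review(records, [], [ReviewAction("NOPE", "remove")])


def test_empty_review_is_identity():
    records = [_rec("RB1", "Aus bus", "Aus", "bus")]
    assert apply_review(records, [], []) == records
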