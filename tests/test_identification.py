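"""Identification engine: identity statistic, ranking, tiers, species
calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishlabel import (
    BarcodeIdentifier,
    BarcodeRecord,
    Marker,
    MatchHit,
    MatchList,
    Resolution,
    TaxonRecord,
    alignment_stats,
    pairwise_identity,
    rank_matches,
    species_level_call,
    top_tier,
)
from oracles import oracle_alignment_stats

seqs = st.text(alphabet="ACGT", min_size=1, max_size=25)


def _taxon(name: str, family: str = "Testidae") -> TaxonRecord:
    return TaxonRecord(name, family, (name,))


def _record(rid: str, name: str, seq: str, marker=Marker.coi_full) -> BarcodeRecord:
    return BarcodeRecord(rid, _taxon(name), marker, seq)


# ----------------------------------------------------------------- identity


def test_identity_of_identical_sequences_is_100():
    assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0


def test_identity_single_terminal_substitution():
    # 7 matched of 8 aligned columns; skipping the final pair is not an
    # option because the query aligns end to end
    assert pairwise_identity("ACGTACGT", "ACGTACGA") == pytest.approx(87.5)
    assert pairwise_identity("ACGTACGT", "ACGTACGA", "global") == pytest.approx(87.5)


def test_mini_barcode_nested_in_long_reference_is_100(registry):
    rng = np.random.default_rng(7)
    ref = "".join(rng.choice(list("ACGT"), 655))
    query = ref[300:466]  # 166 nt window
    assert pairwise_identity(query, ref, "semi_global") == 100.0


def test_ambiguity_codes_never_count_as_identical():
    assert pairwise_identity("ACGTNCGT", "ACGTNCGT") == pytest.approx(87.5)


def test_identity_rejects_non_nucleotides():
    with pytest.raises(ValueError):
        pairwise_identity("ACGT", "ACXT")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seqs)
def test_identity_reflexive(seq):
    if set(seq) <= set("ACGT"):
        assert pairwise_identity(seq, seq) == 100.0


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seqs, seqs)
def test_global_identity_symmetric(a, b):
    assert pairwise_identity(a, b, "global") == pytest.approx(
        pairwise_identity(b, a, "global")
    )


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seqs, seqs, st.sampled_from(["semi_global", "global"]))
def test_alignment_stats_match_recursive_oracle(a, b, mode):
    assert alignment_stats(a, b, mode) == oracle_alignment_stats(a, b, mode)


def test_global_score_matches_biopython():
    """Independent score route: Biopython's PairwiseAligner with the
    same affine scoring must agree on the optimal global score."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score, aligner.mismatch_score = 1, -1
    aligner.open_gap_score, aligner.extend_gap_score = -5, -2
    rng = np.random.default_rng(11)
    for _ in range(40):
        x = "".join(rng.choice(list("ACGT"), rng.integers(5, 50)))
        y = "".join(rng.choice(list("ACGT"), rng.integers(5, 50)))
        assert alignment_stats(x, y, "global")[0] == aligner.score(y, x)


# ------------------------------------------------------------------ ranking


@pytest.fixture(scope="module")
def toy_library():
    """Three 100-nt species at 1, 10 and 20 substitutions from the
    query used in the ranking test: identities 99, 90, 80 by direct
    substitution counting (the exhaustive-alignment oracle agrees since
    no indels are involved)."""
    rng = np.random.default_rng(5)
    base = rng.choice(4, 100)
    def mutate(arr, k, seed):
        r = np.random.default_rng(seed)
        out = arr.copy()
        pos = r.choice(100, k, replace=False)
        out[pos] = (out[pos] + r.integers(1, 4, k)) % 4
        return out
    to_s = lambda a: "".join("ACGT"[b] for b in a)
    query = to_s(base)
    lib = [
        _record("a1", "Species aa", to_s(mutate(base, 1, 1))),
        _record("b1", "Species bb", to_s(mutate(base, 10, 2))),
        _record("c1", "Species cc", to_s(mutate(base, 20, 3))),
    ]
    return query, lib


def test_rank_matches_orders_by_identity_and_applies_floor(toy_library):
    query, lib = toy_library
    matches = rank_matches(query, lib, floor=90.0)
    names = [h.taxon.scientific_name for h in matches.hits]
    assert names == ["Species aa", "Species bb"]  # 20-mutation species dropped
    assert matches.hits[0].identity == pytest.approx(99.0)
    assert matches.hits[1].identity == pytest.approx(90.0)  # floor is inclusive


def test_rank_matches_exact_query_is_first_at_100(toy_library):
    _, lib = toy_library
    matches = rank_matches(lib[1].sequence, lib)
    assert matches.hits[0].taxon.scientific_name == "Species bb"
    assert matches.hits[0].identity == 100.0


def test_rank_matches_below_floor_everywhere_is_empty(toy_library):
    query, lib = toy_library
    matches = rank_matches(query, lib, floor=99.5)
    assert [h.taxon.scientific_name for h in matches.hits] == []
    assert top_tier(matches).resolution is Resolution.none


def test_higher_floor_truncates_ranking_suffix(toy_library):
    query, lib = toy_library
    low = rank_matches(query, lib, floor=80.0)
    high = rank_matches(query, lib, floor=90.0)
    assert [h.identity for h in low.hits[: len(high.hits)]] == [
        h.identity for h in high.hits
    ]
    assert all(h.identity >= 90.0 for h in high.hits)


def test_marker_classes_are_compared_separately():
    t = _taxon("Species aa")
    coi = BarcodeRecord("c", t, Marker.coi_full, "ACGT" * 30)
    cytb = BarcodeRecord("b", _taxon("Species bb"), Marker.cytb, "ACGT" * 30)
    ident = BarcodeIdentifier().fit([coi, cytb])
    coi_hits = ident.rank("ACGT" * 30, Marker.coi_full)
    assert [h.taxon.scientific_name for h in coi_hits.hits] == ["Species aa"]
    cytb_hits = ident.rank("ACGT" * 30, Marker.cytb)
    assert [h.taxon.scientific_name for h in cytb_hits.hits] == ["Species bb"]


# ------------------------------------------------------------------- tiers


def _matchlist(*pairs):
    hits = tuple(MatchHit(_taxon(n, family="Scombridae"), i, n) for n, i in pairs)
    return MatchList(hits, floor=90.0)


def test_top_tier_excludes_runner_up_epsilon_zero():
    # tied 100s form the tier; the 99.85 hit stays out
    ml = _matchlist(
        ("Thunnus albacares", 100.0),
        ("Thunnus atlanticus", 100.0),
        ("Thunnus obesus", 100.0),
        ("Thunnus maccoyii", 99.85),
    )
    tier = top_tier(ml, 0.0)
    assert {t.scientific_name for t in tier.taxa} == {
        "Thunnus albacares",
        "Thunnus atlanticus",
        "Thunnus obesus",
    }
    assert tier.resolution is Resolution.genus_ambiguous


def test_top_tier_unique_best_is_species_resolution():
    ml = _matchlist(("Thunnus obesus", 100.0), ("Thunnus albacares", 99.69))
    tier = top_tier(ml, 0.0)
    assert {t.scientific_name for t in tier.taxa} == {"Thunnus obesus"}
    assert tier.resolution is Resolution.species


def test_top_tier_single_hit_is_species_resolution():
    tier = top_tier(_matchlist(("Xiphias gladius", 100.0)))
    assert tier.resolution is Resolution.species


def test_top_tier_wider_epsilon_grows_tier():
    ml = _matchlist(("Thunnus obesus", 100.0), ("Thunnus albacares", 99.69))
    assert len(top_tier(ml, 0.5).taxa) == 2


# ------------------------------------------------------------ species calls


def test_species_call_with_clear_margin():
    ml = _matchlist(
        ("Thunnus thynnus", 100.0),
        ("Thunnus orientalis", 99.69),
        ("Thunnus atlanticus", 99.69),
    )
    call = species_level_call(ml, margin_delta=0.3)
    assert call.taxon.scientific_name == "Thunnus thynnus"
    assert call.unique_top_match and call.margin_over_next


def test_species_call_refused_on_ties():
    ml = _matchlist(*[(f"Thunnus sp{i:02d}", 100.0) for i in range(4)])
    call = species_level_call(ml)
    assert call.taxon is None
    assert not call.unique_top_match


def test_species_call_empty_matches():
    assert species_level_call(MatchList((), 90.0)).taxon is None


def test_species_call_monotone_in_margin():
    """Raising the required margin never creates a call that was
    previously absent."""
    ml = _matchlist(("Thunnus thynnus", 100.0), ("Thunnus orientalis", 99.8))
    deltas = [0.0, 0.1, 0.2, 0.3, 0.5, 1.0]
    called = [species_level_call(ml, d).taxon is not None for d in deltas]
    assert called == sorted(called, reverse=True)


def test_species_call_respects_tree_veto():
    ml = _matchlist(("Thunnus thynnus", 100.0), ("Thunnus orientalis", 99.0))
    assert species_level_call(ml, tree_check=False).taxon is None
    assert species_level_call(ml, tree_check=True).taxon is not None


def test_identifier_is_sklearn_compatible():
    ident = BarcodeIdentifier(floor=85.0)
    params = ident.get_params()
    assert params["floor"] == 85.0
    ident.set_params(tier_epsilon=0.2)
    assert ident.tier_epsilon == 0.2
    with pytest.raises(Exception):
        ident.rank("ACGT")  # not fitted
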