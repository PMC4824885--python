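"""Reference data: FASTA I/O, designation table, label normalization,
and the packaged audit table."""

import pytest

from fishlabel import (
    BarcodeRecord,
    Marker,
    QuerySample,
    TaxonRecord,
    TaxonRegistry,
    normalize_label,
    read_fasta,
    top_tier,
    write_fasta,
)
from fishlabel.taxa import IUCNStatus


# --------------------------------------------------------------------- FASTA


TWO_ENTRY = """\
>r1|Thunnus_albacares|coi_full
acgtacgtAACC
>r2|Anguilla_anguilla|coi_mini some free text
GGTTACGT
"""


def test_read_fasta_parses_taxa_and_normalizes_sequences(tmp_path):
    p = tmp_path / "ref.fasta"
    p.write_text(TWO_ENTRY)
    records = read_fasta(p)
    assert len(records) == 2
    assert records[0].taxon.scientific_name == "Thunnus albacares"
    assert records[0].sequence == "ACGTACGTAACC"  # lowercase uppercased
    assert records[1].marker is Marker.coi_mini


def test_read_fasta_maps_u_to_t(tmp_path):
    p = tmp_path / "rna.fasta"
    p.write_text(">r1|Thunnus_albacares|coi_full\nacgu\n")
    assert read_fasta(p)[0].sequence == "ACGT"


@pytest.mark.parametrize(
    "header",
    [">r1|Thunnus_albacares", ">r1|Thunnus_albacares|unknown_marker", ">plain_name"],
)
def test_read_fasta_rejects_malformed_headers(tmp_path, header):
    p = tmp_path / "bad.fasta"
    p.write_text(f"{header}\nACGT\n")
    with pytest.raises(ValueError):
        read_fasta(p)


def test_read_fasta_empty_file_warns(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.warns(UserWarning):
        assert read_fasta(p) == []


def test_fasta_round_trip(tmp_path):
    p = tmp_path / "ref.fasta"
    p.write_text(TWO_ENTRY)
    records = read_fasta(p)
    out = tmp_path / "out.fasta"
    write_fasta(records, out)
    assert read_fasta(out) == records


def test_barcode_record_rejects_bad_sequence():
    t = TaxonRecord("Thunnus albacares", "Scombridae", ("Yellowfin tuna",))
    with pytest.raises(ValueError):
        BarcodeRecord("r1", t, Marker.coi_full, "ACGTXX")
    with pytest.raises(ValueError):
        BarcodeRecord("r1", t, Marker.coi_full, "")


def test_query_sample_requires_exactly_one_evidence_source():
    with pytest.raises(ValueError):
        QuerySample("s1", "London", "Tuna")  # neither
    with pytest.raises(ValueError):
        QuerySample("s1", "London", "")  # empty label


# --------------------------------------------------- designations and labels


def test_kingfish_designation_covers_all_scomberomorus(designations, registry):
    admissible = designations.admissible_species("kingfish", registry)
    assert admissible == registry.in_genus("Scomberomorus")
    assert len(admissible) >= 2


def test_bluefin_designation_is_the_three_bluefin_species(designations, registry):
    admissible = designations.admissible_species("bluefin tuna", registry)
    assert {t.scientific_name for t in admissible} == {
        "Thunnus thynnus",
        "Thunnus orientalis",
        "Thunnus maccoyii",
    }


def test_unknown_commercial_name_is_explicit_not_listed(designations, registry):
    assert designations.lookup("manticore") is None
    assert designations.admissible_species("manticore", registry) is None


def test_duplicate_commercial_name_rejected(designations):
    from fishlabel import DesignationEntry

    with pytest.raises(ValueError, match="duplicate"):
        designations.add(DesignationEntry("tuna", (("genus", "Thunnus"),)))


def test_unknown_pattern_type_rejected(tmp_path):
    from fishlabel import load_designations

    p = tmp_path / "d.tsv"
    p.write_text("commercial_name\tpattern_type\tpatterns\nx\torder\tClupeiformes\n")
    with pytest.raises(ValueError, match="pattern_type"):
        load_designations(p)


@pytest.mark.parametrize(
    "raw, base, claim, tags",
    [
        ("Tuna (Yellowfin)", "tuna", "yellowfin tuna", ()),
        ("Tuna (Albacore)", "tuna", "albacore", ()),
        ("Eel (grilled)", "eel", None, ("grilled",)),
        ("Tuna (Spicy)", "tuna", None, ("spicy",)),
        ("Eel (Freshwater)", "eel", None, ("freshwater",)),
        ("Flying Fish eggs", "flying fish", None, ("eggs",)),
        ("King Fish (Tasmanian)", "kingfish", None, ("tasmanian",)),
        ("Black Cod", "black cod", None, ()),
    ],
)
def test_normalize_label(designations, raw, base, claim, tags):
    lab = normalize_label(raw, designations)
    assert (lab.base_name, lab.species_claim, lab.preparation_tags) == (base, claim, tags)


def test_every_fixture_label_resolves_or_is_explicitly_unlisted(
    audit_fixture, designations
):
    """Designation lookup is total over the audited labels: each base
    name either resolves or returns the explicit not-listed result."""
    for fs in audit_fixture.samples:
        lab = normalize_label(fs.sample.label_raw, designations)
        entry = designations.lookup(lab.base_name)
        if entry is None:
            assert lab.base_name == "black cod"  # the one unlisted market name


# ------------------------------------------------------------ packaged audit


def test_fixture_has_115_samples(audit_fixture):
    assert len(audit_fixture) == 115


def test_fixture_tuna_category_has_48_samples(audit_fixture, designations):
    bases = [
        normalize_label(fs.sample.label_raw, designations).base_name
        for fs in audit_fixture.samples
    ]
    assert bases.count("tuna") == 48


def test_fixture_expects_12_mislabelled(audit_fixture):
    assert sum(audit_fixture.expected_verdicts.values()) == 12


def test_fixture_city_totals(audit_fixture):
    cities = {}
    for fs in audit_fixture.samples:
        cities[fs.sample.city] = cities.get(fs.sample.city, 0) + 1
    assert cities == {
        "Manchester": 37,
        "London": 39,
        "Bristol": 18,
        "Liverpool": 12,
        "Newcastle": 5,
        "Exeter": 4,
    }


def test_fixture_taxa_all_resolve(audit_fixture):
    """No dangling names: every taxon in a match list has a registry
    record with a family and at least one common name."""
    for fs in audit_fixture.samples:
        for hit in fs.sample.match_list.hits:
            rec = audit_fixture.registry.get(hit.taxon.scientific_name)
            assert rec is not None
            assert rec.accepted_common_names


def test_fixture_tiers_reproduce_printed_reporting_names(audit_fixture):
    """The epsilon-0 top tier reproduces the printed identification for
    every row except the one documented typesetting slip (KU168656,
    printed as Bigeye tuna beside a 100% yellowfin match)."""
    from fishlabel import accepted_name_of

    for fs in audit_fixture.samples:
        tier = top_tier(fs.sample.match_list, 0.0)
        name = accepted_name_of(tier)
        if fs.sample.sample_id == "KU168656":
            assert fs.expected_accepted_name == "Bigeye tuna"
            assert name == "Yellowfin tuna"
        else:
            assert name == fs.expected_accepted_name, fs.sample.sample_id


def test_fixture_statuses_match_registry(audit_fixture):
    """Printed Red List statuses agree with the packaged taxon table
    for the reporting species of every row."""
    from fishlabel import accepted_name_of
    from fishlabel.adjudicate import reporting_taxon

    for fs in audit_fixture.samples:
        if fs.sample.sample_id == "KU168656":
            continue
        taxon = reporting_taxon(top_tier(fs.sample.match_list, 0.0))
        assert taxon.iucn_status == fs.expected_iucn_status, fs.sample.sample_id


def test_taxon_record_invariants(registry):
    for t in registry:
        assert t.genus == t.scientific_name.split()[0]
        assert t.accepted_common_names
        assert isinstance(t.iucn_status, IUCNStatus)
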