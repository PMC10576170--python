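"""Backbone loading, local resolution, fallback, and the remote adapters."""

import random
from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tipmatch.names import DEFAULT_RULES, SubstitutionRule, normalize
from tipmatch.synonym_store import (
    BackboneFormatError,
    GbifSource,
    LocalBackboneSource,
    NcbiSource,
    dedupe_identifiers,
    harvest_names,
    load_backbone,
    replay_transport,
    resolve_local,
    resolve_with_fallback,
    write_backbone,
)
from tipmatch.synth import SynthConfig, generate_taxonomy

FIXTURES = Path(__file__).parent / "fixtures"


class TestLoadBackbone:
    def test_fixture_counts_and_reverse_index(self, small_backbone):
        table = load_backbone(small_backbone)
        assert len(table) == 3  # Panthera leo (merged rows), Orthriophis taeniurus, Mus musculus
        # reverse index: every accepted + every distinct synonym
        n_names = len(table.entries) + sum(len(v) for v in table.entries.values())
        assert len(table.reverse) == n_names
        assert set(table.reverse.values()) <= set(table.entries)

    def test_header_only_file_is_empty_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("accepted_name\tsynonym\tstatus\n", encoding="utf-8")
        table = load_backbone(p)
        assert len(table) == 0
        assert not resolve_local(table, "Panthera leo").matched

    def test_felis_leo_reverse_lookup(self, felis_backbone):
        table = load_backbone(felis_backbone)
        assert table.reverse[normalize("Felis_leo")] == "Panthera leo"

    def test_wrong_column_count_names_the_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("A b\tB c\tunknown\textra\tcols\n", encoding="utf-8")
        with pytest.raises(BackboneFormatError, match=r"bad\.tsv:1"):
            load_backbone(p)

    def test_homonym_collision_recorded_and_strict_raises(self, tmp_path):
        p = tmp_path / "homonym.tsv"
        p.write_text(
            "Aus bus\tCus dus\tunknown\nEus fus\tCus dus\tunknown\n",
            encoding="utf-8",
        )
        with pytest.warns(UserWarning, match="homonym"):
            table = load_backbone(p)
        assert table.collisions[normalize("Cus dus")] == ("Aus bus", "Eus fus")
        with pytest.raises(BackboneFormatError, match="collision"):
            load_backbone(p, strict=True)

    def test_duplicate_accepted_rows_merge_with_union(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "Aus bus\tCus dus\tunknown\nAus bus\tCus dus\tunknown\nAus bus\tGus hus\tunknown\n",
            encoding="utf-8",
        )
        table = load_backbone(p)
        assert [s for s, _ in table.entries["Aus bus"]] == ["Cus dus", "Gus hus"]

    def test_serialize_reload_preserves_resolution(self, small_backbone, tmp_path):
        table = load_backbone(small_backbone)
        out = write_backbone(table, tmp_path / "roundtrip.tsv")
        reloaded = load_backbone(out)
        for key in list(table.reverse):
            a = resolve_local(table, key)
            b = resolve_local(reloaded, key)
            assert (a.matched, a.canonical, a.synonyms) == (b.matched, b.canonical, b.synonyms)
        assert write_backbone(reloaded, tmp_path / "again.tsv").read_bytes() == out.read_bytes()


class TestResolveLocal:
    def test_synonym_query_returns_accepted_cloud(self, felis_backbone):
        rec = resolve_local(load_backbone(felis_backbone), "Felis_leo")
        assert rec.matched and rec.canonical == "Panthera leo"
        assert "Panthera leo" in rec.synonyms
        assert normalize("Felis leo") not in {normalize(s) for s in rec.synonyms}

    def test_accepted_self_lookup(self, small_backbone):
        rec = resolve_local(load_backbone(small_backbone), "Panthera_leo")
        assert rec.matched and rec.canonical == "Panthera leo"
        assert sorted(rec.synonyms) == ["Felis leo", "Leo nobilis"]

    def test_absent_key_is_unmatched_not_an_error(self, small_backbone):
        rec = resolve_local(load_backbone(small_backbone), "Nonexistens specius")
        assert not rec.matched and rec.canonical is None and rec.synonyms == []

    def test_homonym_query_flags_ambiguity(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("Aus bus\tCus dus\tunknown\nEus fus\tCus dus\tunknown\n", encoding="utf-8")
        with pytest.warns(UserWarning):
            rec = resolve_local(load_backbone(p), "Cus_dus")
        assert not rec.matched and rec.ambiguous
        assert rec.ambiguous_candidates == ("Aus bus", "Eus fus")

    def test_index_agrees_with_brute_force_scan(self):
        """Oracle equivalence: the reverse index must reproduce a full scan
        of every synonym list for every known name."""
        table, truth = generate_taxonomy(SynthConfig(n_species=60, seed=11))
        clouds = {acc: [acc] + [s for s, _ in syns] for acc, syns in table.entries.items()}
        for name in truth.classes:
            rec = resolve_local(table, name)
            scan_hits = [acc for acc, cloud in clouds.items()
                         if normalize(name) in {normalize(n) for n in cloud}]
            assert rec.matched == (len(scan_hits) == 1)
            if rec.matched:
                assert rec.canonical == scan_hits[0]
                expected = [n for n in clouds[scan_hits[0]]
                            if normalize(n) != normalize(name)]
                assert rec.synonyms == expected


class TestFallback:
    def test_um_us_variant_recovers_the_query(self, tmp_path):
        p = tmp_path / "snake.tsv"
        p.write_text("Orthriophis taeniurus\t\t\n", encoding="utf-8")
        source = LocalBackboneSource.from_path(p)
        rec = resolve_with_fallback(source, "Orthriophis taeniurum")
        assert rec.matched
        assert rec.via_variant == "Orthriophis taeniurus"
        assert rec.query == "Orthriophis taeniurum"

    def test_verbatim_match_has_no_via_variant(self, felis_backbone):
        source = LocalBackboneSource.from_path(felis_backbone)
        rec = resolve_with_fallback(source, "Felis leo")
        assert rec.matched and rec.via_variant is None

    def test_empty_rules_equals_plain_resolve(self, tmp_path):
        p = tmp_path / "snake.tsv"
        p.write_text("Orthriophis taeniurus\t\t\n", encoding="utf-8")
        source = LocalBackboneSource.from_path(p)
        rec = resolve_with_fallback(source, "Orthriophis taeniurum", rules=[])
        assert not rec.matched and rec.via_variant is None

    def test_via_variant_is_a_generated_variant(self, tmp_path):
        p = tmp_path / "snake.tsv"
        p.write_text("Orthriophis taeniurus\t\t\n", encoding="utf-8")
        source = LocalBackboneSource.from_path(p)
        rec = resolve_with_fallback(source, "Orthriophis_taeniurum")
        from tipmatch.names import format_name, generate_variants, parse_name

        variants = {format_name(v, "_") for v in generate_variants(parse_name(rec.query))}
        assert rec.via_variant in variants


class TestDedupeIdentifiers:
    @pytest.mark.parametrize(
        "ids, expected",
        [([7, 3, 7, 7, 1], [7, 3, 1]), ([], []), (["a", "a"], ["a"])],
    )
    def test_first_kept_order_preserved(self, ids, expected):
        assert dedupe_identifiers(ids) == expected

    @given(st.lists(st.integers(0, 20)))
    def test_set_preserved_and_length_is_distinct_count(self, ids):
        out = dedupe_identifiers(ids)
        assert set(out) == set(ids)
        assert len(out) == len(set(ids))


class TestHarvestNames:
    def test_dedup_within_fields(self):
        entry = {"Name": "A b", "OtherNames": {"synonym": ["A c", "A c"]},
                 "OtherNames2": "ignored"}
        assert harvest_names(entry, name_fields=("Name", "OtherNames")) == ["A b", "A c"]

    def test_missing_fields_contribute_nothing(self):
        assert harvest_names({"TaxId": "1", "Rank": "species"}) == []

    def test_synthetic_recorded_response_yields_known_list(self):
        """Replay of a hand-built (synthetic) taxonomy-service record."""
        import json

        payload = json.loads(
            (FIXTURES / "synthetic_ncbi" / "orthriophis_taeniurus.json").read_text()
        )
        names = harvest_names(payload["efetch"][0])
        assert names == [
            "Orthriophis taeniurus",
            "Elaphe taeniura",
            "Orthriophis taeniurus (Cope, 1861)",
        ]


class TestRemoteAdapters:
    def test_gbif_flow_against_replayed_responses(self):
        source = GbifSource(replay_transport(FIXTURES / "synthetic_gbif"))
        rec = source.resolve("Felis leo")
        assert rec.matched and rec.canonical == "Panthera leo"
        assert "Leo nobilis" in rec.synonyms
        assert normalize("Felis leo") not in {normalize(s) for s in rec.synonyms}

    def test_gbif_miss_is_unmatched(self):
        source = GbifSource(replay_transport(FIXTURES / "synthetic_gbif"))
        assert not source.resolve("Nonexistens specius").matched

    def test_ncbi_flow_dedupes_ids_and_harvests(self):
        source = NcbiSource(replay_transport(FIXTURES / "synthetic_ncbi"))
        rec = source.resolve("Orthriophis taeniurus")
        assert rec.matched and rec.canonical == "Orthriophis taeniurus"
        assert rec.synonyms[0] == "Elaphe taeniura"
        assert not rec.ambiguous

    def test_ncbi_fallback_reaches_um_us_variant(self):
        source = NcbiSource(replay_transport(FIXTURES / "synthetic_ncbi"))
        rec = resolve_with_fallback(source, "Orthriophis taeniurum")
        assert rec.matched and rec.via_variant == "Orthriophis taeniurus"

    def test_resolve_is_deterministic(self):
        source = NcbiSource(replay_transport(FIXTURES / "synthetic_ncbi"))
        a = source.resolve("Orthriophis taeniurus")
        b = source.resolve("Orthriophis taeniurus")
        assert (a.canonical, a.synonyms) == (b.canonical, b.synonyms)


class TestRecordInvariants:
    def test_synonyms_never_contain_the_query_key(self, rng):
        table, truth = generate_taxonomy(SynthConfig(n_species=40, seed=5))
        for name in truth.classes:
            rec = resolve_local(table, name)
            assert normalize(name) not in {normalize(s) for s in rec.synonyms}

    def test_unmatched_records_carry_nothing(self):
        from tipmatch.synonym_store import SynonymRecord

        rec = SynonymRecord(query="X y")
        assert rec.canonical is None and rec.current is None and rec.synonyms == []
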