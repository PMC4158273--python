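"""Connectivity search: relations, criteria, blocking, labels, parse-once."""

import pytest

from inchilink import fixtures, inchi_core as ic, keys, search
from conftest import PABA, PABA_NA


def run(reg, term, labels=None, **crit):
    ctx = search.resolve_key_query(reg, term)
    stats = search.SearchStats()
    records = search.execute(
        reg, ctx, search.SearchCriteria(**crit), label_table=labels, stats=stats
    )
    return records, stats


class TestWorkedExample:
    def test_query_on_acid_finds_itself_and_its_salt(
        self, acid_salt_registry, surrogate
    ):
        records, _ = run(acid_salt_registry, keys.key_for(PABA, surrogate), C=4)
        assert [(r.src_compound_id, r.relation) for r in records] == [
            ("ACID", 0),
            ("SALT", 1),
        ]
        salt_hit = records[1]
        assert salt_hit.diff.flags == {"p": 1, "b": 0, "t": 0, "m": 0, "s": 0, "i": 0}

    def test_query_on_salt_finds_itself_and_the_acid_as_component(
        self, acid_salt_registry, surrogate
    ):
        records, _ = run(acid_salt_registry, keys.key_for(PABA_NA, surrogate), C=4)
        pairs = {(r.src_compound_id, r.relation) for r in records}
        # salt matches itself (0) and as sharing its own components (3);
        # the acid matches the salt's benzoate component (2)
        assert ("SALT", 0) in pairs
        assert ("ACID", 2) in pairs
        assert all(rel in (0, 2, 3) for _, rel in pairs)

    def test_default_criteria_find_only_the_exact_connectivity_match(
        self, acid_salt_registry, surrogate
    ):
        records, _ = run(acid_salt_registry, keys.key_for(PABA, surrogate))
        assert [(r.src_compound_id, r.relation) for r in records] == [("ACID", 0)]


class TestResolve:
    def test_key_of_loaded_structure_carries_parsed_query_inchi(
        self, acid_salt_registry, surrogate
    ):
        ctx = search.resolve_key_query(acid_salt_registry, keys.key_for(PABA, surrogate))
        assert ctx.runnable
        assert ic.serialize(ctx.query_inchi) == PABA

    def test_unknown_key_cannot_run(self, acid_salt_registry):
        ctx = search.resolve_key_query(
            acid_salt_registry, "QQQQQQQQQQQQQQ-QQQQQQQQSA-N"
        )
        assert ctx.status == "no query InChI"
        assert search.execute(acid_salt_registry, ctx, search.SearchCriteria()) == []

    def test_key_known_only_from_keys_only_source_cannot_run(
        self, registry, surrogate
    ):
        registry.add_source(2, "keysrc", keys_only=True)
        key = "QQQQQQQQQQQQQQ-QQQQQQQQSA-N"
        registry.load_source(2, [("K", key)])
        ctx = search.resolve_key_query(registry, key)
        assert ctx.status == "no query InChI"

    def test_bare_fikhb_query_runs_without_diff_columns(
        self, acid_salt_registry, surrogate
    ):
        records, _ = run(
            acid_salt_registry, keys.fikhb_of(keys.key_for(PABA, surrogate))
        )
        assert records and all(r.diff is None for r in records)

    def test_cpd_query_matches_key_query_on_same_structure(
        self, acid_salt_registry, surrogate
    ):
        ctx = search.resolve_cpd_query(acid_salt_registry, "ACID", 1)
        assert ctx.query_key == keys.key_for(PABA, surrogate)
        assert ic.serialize(ctx.query_inchi) == PABA

    def test_unknown_src_compound_id(self, acid_salt_registry):
        ctx = search.resolve_cpd_query(acid_salt_registry, "NOPE", 1)
        assert ctx.status == "unknown src_compound_id"

    def test_malformed_key_term_rejected(self, acid_salt_registry):
        with pytest.raises(keys.KeyValidationError):
            search.resolve_key_query(acid_salt_registry, "not-a-key")


class TestCriteria:
    def test_defaults_are_all_zero_and_there_are_eight(self):
        crit = search.SearchCriteria()
        values = [getattr(crit, letter) for letter in "ABCDEFGH"]
        assert values == [0] * search.N_CRITERIA
        assert search.N_CRITERIA == 8

    @pytest.mark.parametrize("bad", [{"B": 2}, {"C": 5}, {"G": -1}, {"D": -1}])
    def test_out_of_range_values_rejected(self, bad):
        with pytest.raises(search.CriteriaError):
            search.SearchCriteria(**bad)

    def test_source_filter_A(self, family_registry):
        reg, manifest = family_registry
        records, _ = run(reg, manifest["probe"]["key"], C=4, A=1)
        assert records and all(r.src_id == 1 for r in records)

    def test_obsolete_scope_G(self, registry, surrogate):
        registry.load_source(1, [("A", PABA), ("S", PABA_NA)])
        registry.load_source(1, [("A", PABA)])  # S becomes obsolete
        key = keys.key_for(PABA, surrogate)
        current_only, _ = run(registry, key, C=4)
        with_obsolete, _ = run(registry, key, C=4, G=1)
        assert {r.src_compound_id for r in current_only} == {"A"}
        assert {(r.src_compound_id, r.current) for r in with_obsolete} == {
            ("A", 1),
            ("S", 0),
        }

    def test_b1_results_subset_of_b0(self, family_registry):
        reg, manifest = family_registry
        wide, _ = run(reg, manifest["probe"]["key"], C=4, B=0)
        narrow, _ = run(reg, manifest["probe"]["key"], C=4, B=1)
        assert fixtures.hit_set(narrow) <= fixtures.hit_set(wide)

    def test_b1_direct_matches_have_no_stereo_or_isotope_diffs(self, family_registry):
        reg, manifest = family_registry
        narrow, _ = run(reg, manifest["probe"]["key"], C=4, B=1)
        direct = [r for r in narrow if r.relation in (0, 2)]
        assert direct
        for r in direct:
            assert all(r.diff.flags[c] == 0 for c in "btmsi")

    def test_b1_with_bare_fikhb_needs_full_key(self, acid_salt_registry, surrogate):
        fikhb = keys.fikhb_of(keys.key_for(PABA, surrogate))
        with pytest.raises(keys.KeyValidationError, match="full key"):
            run(acid_salt_registry, fikhb, B=1)


class TestFreqThreshold:
    def test_default_is_two_hundred(self):
        assert search.freq_threshold(0) == 200

    def test_decade_steps(self):
        assert search.freq_threshold(1) == 2000
        assert search.freq_threshold(2) == 20000

    def test_hard_cap_cannot_be_exceeded(self):
        for d in range(3, 12):
            assert search.freq_threshold(d) == 100000


class TestBlocking:
    def test_short_components_blocked_by_length_criterion(
        self, registry, surrogate
    ):
        """With E raised, the bare-counter-ion sub-query (connectivity
        length 2) is skipped while the skeleton sub-query still runs."""
        ion = fixtures.counter_ion("Na")
        salts = [
            fixtures.make_salt(fixtures.skeleton(i), ion) for i in range(3)
        ]
        registry.load_source(
            1, [(f"S{i}", ic.serialize(s)) for i, s in enumerate(salts)]
        )
        key = keys.key_for_parsed(salts[0], surrogate)
        unblocked, _ = run(registry, key, C=3)
        blocked, stats = run(registry, key, C=3, E=5)
        assert {r.src_compound_id for r in unblocked} == {"S0", "S1", "S2"}
        assert {r.src_compound_id for r in blocked} == {"S0"}
        ion_fikhb = keys.fikhb_of(keys.key_for_parsed(ion, surrogate))
        assert stats.blocked_components == [ion_fikhb]

    def test_e_zero_blocks_nothing(self, registry, surrogate):
        ion = fixtures.counter_ion("Na")
        salt = fixtures.make_salt(fixtures.skeleton(0), ion)
        registry.load_source(1, [("S0", ic.serialize(salt))])
        _, stats = run(registry, keys.key_for_parsed(salt, surrogate), C=4)
        assert stats.blocked_components == []


class TestLabels:
    def test_salt_hits_carry_counter_ion_labels(self, registry, surrogate):
        ion = fixtures.counter_ion("ClH")
        skeleton = fixtures.skeleton(0)
        salt = fixtures.make_salt(skeleton, ion)
        registry.load_source(
            1, [("P", ic.serialize(skeleton)), ("S", ic.serialize(salt))]
        )
        table = {keys.fikhb_of(keys.key_for_parsed(ion, surrogate)): "HCl"}
        records, _ = run(
            registry, keys.key_for_parsed(skeleton, surrogate), labels=table, C=4
        )
        by_id = {r.src_compound_id: r.labels for r in records}
        assert by_id["S"] == ["HCl"]
        assert by_id["P"] == []

    def test_f1_suppresses_labels_entirely(self, registry, surrogate):
        ion = fixtures.counter_ion("ClH")
        salt = fixtures.make_salt(fixtures.skeleton(0), ion)
        registry.load_source(1, [("S", ic.serialize(salt))])
        table = {keys.fikhb_of(keys.key_for_parsed(ion, surrogate)): "HCl"}
        records, _ = run(
            registry, keys.key_for_parsed(salt, surrogate), labels=table, C=0, F=1
        )
        assert records and all(r.labels == [] for r in records)

    def test_annotate_labels_empty_table(self):
        assert search.annotate_labels(["AAAA"], {}) == []


class TestParseOnce:
    def test_each_unique_retrieved_inchi_parsed_at_most_once(self, family_registry):
        reg, manifest = family_registry
        ic.parse_counter.value = 0
        records, stats = run(reg, manifest["probe"]["key"], C=4)
        unique = len({r.standardinchi for r in records})
        assert ic.parse_counter.value <= unique + 1
        assert stats.retrieved_parses <= unique

    def test_hit_inchis_skipped_when_absent(self, registry, surrogate):
        """A structure known only by key never appears in a result set."""
        registry.add_source(2, "keysrc", keys_only=True)
        registry.load_source(1, [("A", PABA)])
        key = keys.key_for(PABA, surrogate)
        fikhb_twin = key[:14] + "-" + "BBBBBBBB" + "SA-N"
        registry.load_source(2, [("K", fikhb_twin)])  # same FIKHB, no InChI
        records, _ = run(registry, key, C=4)
        assert {r.src_compound_id for r in records} == {"A"}
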