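"""Canonical identifier assembly, serialization and parsing."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rinchilib import (
    Direction,
    RDirection,
    ReactionRecord,
    RInChI,
    RInChIValidationError,
    build_rinchi,
    from_groups,
    parse,
    serialize,
    sort_group,
    to_reaction,
)
from rinchilib import fixtures as fx

HEADER = "RInChI=0.02.1S/"


def record_with(reactants, products, agents=(), direction=Direction.FORWARD):
    return ReactionRecord(
        reactants=tuple(fx.mol_record(n) for n in reactants),
        products=tuple(fx.mol_record(n) for n in products),
        agents=tuple(fx.mol_record(n) for n in agents),
        direction=direction,
    )


class TestBuild:
    def test_diels_alder_pinned(self, all_rinchis):
        assert all_rinchis["diels_alder"].serialized() == (
            "RInChI=0.02.1S/C2H4/c1-2/h1-2H2//C4H6/c1-3-4-2/h3-4H,1-2H2"
            "///C6H10/c1-2-4-6-5-3-1/h1-2H,3-6H2/d+"
        )

    def test_direction_follows_group_order(self):
        # reactant side sorts first -> /d+
        r, _ = build_rinchi(record_with(["butadiene", "ethene"], ["cyclohexene"]))
        assert r.direction is RDirection.PLUS
        # the same molecules with roles swapped -> /d-
        s, _ = build_rinchi(record_with(["cyclohexene"], ["butadiene", "ethene"]))
        assert s.direction is RDirection.MINUS
        assert (r.group1, r.group2, r.group3) == (s.group1, s.group2, s.group3)

    def test_equilibrium_keeps_canonical_group_order(self):
        fwd, _ = build_rinchi(record_with(
            ["acetic_acid", "ethanol"], ["ethyl_acetate", "water"],
            direction=Direction.EQUILIBRIUM))
        rev, _ = build_rinchi(record_with(
            ["ethyl_acetate", "water"], ["acetic_acid", "ethanol"],
            direction=Direction.EQUILIBRIUM))
        assert fwd == rev
        assert fwd.direction is RDirection.EQUILIBRIUM

    def test_unspecified_direction_omits_layer(self):
        r, _ = build_rinchi(record_with(["ethanol"], ["ethene", "water"],
                                        direction=Direction.UNSPECIFIED))
        assert r.direction is RDirection.OMITTED
        assert "/d" not in r.serialized()

    def test_identity_reaction_forces_omitted(self, all_rinchis):
        assert all_rinchis["identity"].direction is RDirection.OMITTED

    def test_agents_do_not_touch_reaction_groups(self):
        bare, _ = build_rinchi(record_with(["ethanol"], ["ethene", "water"]))
        with_agent, _ = build_rinchi(
            record_with(["ethanol"], ["ethene", "water"], ["sulfuric_acid"]))
        assert (bare.group1, bare.group2) == (with_agent.group1, with_agent.group2)
        assert with_agent.group3 != ()

    def test_permutation_invariance(self):
        names_r = ["methane", "ethanol", "benzene", "water"]
        names_p = ["ethene", "toluene", "methanol"]
        base = build_rinchi(record_with(names_r, names_p))[0].serialized()
        rng = random.Random(0)
        for _ in range(10):
            pr = rng.sample(names_r, len(names_r))
            pp = rng.sample(names_p, len(names_p))
            assert build_rinchi(record_with(pr, pp))[0].serialized() == base

    def test_duplicates_preserved(self):
        r, _ = build_rinchi(record_with(["water", "water"], ["ethene"]))
        water = fx.mol_record("water").inchi_body
        assert r.serialized().count(water) == 2

    def test_idempotence_through_reconstruction(self, all_rinchis):
        for name in ("diels_alder", "reduction_r", "esterification_eq"):
            r = all_rinchis[name]
            rebuilt, _ = build_rinchi(to_reaction(r))
            assert rebuilt == r

    def test_rauxinfo_alignment(self):
        rec = record_with(["acetic_acid", "ethanol"], ["ethyl_acetate", "water"],
                          ["sulfuric_acid"])
        r, aux = build_rinchi(rec)
        assert len(aux.group1) == len(r.group1)
        assert len(aux.group2) == len(r.group2)
        assert len(aux.group3) == len(r.group3)
        assert aux.serialized().startswith("RAuxInfo=0.02.1/")


class TestSerialize:
    def test_header(self, all_rinchis):
        for r in all_rinchis.values():
            assert r.serialized().startswith(HEADER)

    def test_reactants_only_shows_single_group(self):
        r = from_groups([fx.mol_record("ethanol").inchi_body], [])
        s = serialize(r)
        assert "///" not in s
        assert fx.mol_record("ethanol").inchi_body in s

    def test_empty_middle_group_keeps_separator(self):
        r = from_groups([fx.mol_record("ethanol").inchi_body], [],
                        [fx.mol_record("water").inchi_body])
        s = serialize(r)
        assert "//////" in s
        assert parse(s) == r

    @pytest.mark.parametrize("name", list(fx.REACTIONS))
    def test_parse_serialize_roundtrip(self, name, all_rinchis):
        r = all_rinchis[name]
        assert parse(serialize(r)) == r


class TestParse:
    def test_direction_tokens(self, all_rinchis):
        s = all_rinchis["diels_alder"].serialized()
        assert parse(s).direction is RDirection.PLUS
        assert parse(s[:-3] + "/d-").direction is RDirection.MINUS
        assert parse(s[:-3] + "/d=").direction is RDirection.EQUILIBRIUM

    def test_omitted_direction_is_valid(self, all_rinchis):
        s = all_rinchis["diels_alder"].serialized()[:-3]
        assert parse(s).direction is RDirection.OMITTED

    def test_alternate_header_punctuation(self, all_rinchis):
        s = all_rinchis["diels_alder"].serialized()
        assert parse(s.replace("0.02.1S/", "0.02.1.S/", 1)) == parse(s)

    def test_trailing_slash_accepted(self):
        r = from_groups([fx.mol_record("ethanol").inchi_body], [])
        assert parse(serialize(r) + "/") == r

    def test_bad_header(self):
        with pytest.raises(RInChIValidationError) as exc:
            parse("InChI=1S/CH4/h1H4")
        assert exc.value.rule == "header"

    def test_bad_direction_token(self, all_rinchis):
        s = all_rinchis["diels_alder"].serialized()
        with pytest.raises(RInChIValidationError):
            parse(s[:-1])  # "/d" without its sign

    def test_unsorted_group_rejected(self):
        g = sorted([fx.mol_record("water").inchi_body,
                    fx.mol_record("ethanol").inchi_body])
        bad = HEADER + "//".join(reversed(g))
        with pytest.raises(RInChIValidationError) as exc:
            parse(bad)
        assert exc.value.rule == "group-sort"

    def test_misordered_groups_rejected(self):
        a = fx.mol_record("ethanol").inchi_body
        b = fx.mol_record("water").inchi_body
        lo, hi = sorted([a, b])
        with pytest.raises(RInChIValidationError) as exc:
            parse(HEADER + hi + "///" + lo)
        assert exc.value.rule == "group-order"

    def test_extras_preserved(self, all_rinchis):
        s = all_rinchis["diels_alder"].serialized() + "/x9z"
        r = parse(s)
        assert r.extras == ("/x9z",)
        assert serialize(r) == s


class TestSortGroup:
    def test_bytewise_order(self):
        assert sort_group(["b", "a", "ab"]) == ["a", "ab", "b"]

    def test_duplicates_not_collapsed(self):
        assert sort_group(["x", "x"]) == ["x", "x"]

    def test_enantiomers_tie_on_major_key(self):
        a = fx.mol_record("r_butan_2_ol").inchi_body
        b = fx.mol_record("s_butan_2_ol").inchi_body
        from rinchilib import split_major_minor
        assert split_major_minor(a)[0] == split_major_minor(b)[0]
        # both modes still order the pair deterministically
        assert sort_group([a, b]) == sort_group([b, a])
        assert (sort_group([a, b], "major_then_minor")
                == sort_group([b, a], "major_then_minor"))

    @given(st.lists(st.text(alphabet=st.characters(min_codepoint=33, max_codepoint=126),
                            min_size=1, max_size=20), max_size=8))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_bytewise_matches_byte_sort(self, bodies):
        assert sort_group(bodies) == sorted(bodies, key=lambda s: s.encode())


class TestFlip:
    @pytest.mark.parametrize("name", ["diels_alder", "dehydration", "reduction_r"])
    def test_flip_is_involution_and_swaps_roles(self, name, all_rinchis):
        r = all_rinchis[name]
        f = r.flipped()
        assert f.flipped() == r
        assert r.reactant_bodies() == f.product_bodies()
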