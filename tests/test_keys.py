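"""Hashed molecule and reaction keys."""

import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from rinchilib import (
    RInChI,
    RDirection,
    build_rinchi,
    hash_block,
    inchikey,
    long_key,
    make_keys,
    parse,
    serialize,
    short_key,
)
from rinchilib import fixtures as fx

EMPTY_15 = "UHFFFADPSCTJKWU"  # pinned: hash_block("", 15)


class TestInchikey:
    def test_methane_pinned(self):
        assert inchikey("InChI=1S/CH4/h1H4") == "VNWKTOKETHGBQD-UHFFFAOYSA-N"

    @pytest.mark.parametrize("name", fx.MOLECULE_NAMES)
    def test_byte_match_against_engine(self, name):
        inchi = fx.mol_record(name).inchi
        assert inchikey(inchi) == Chem.InchiToInchiKey(inchi)

    def test_charged_and_multicomponent(self):
        for inchi in (
            "InChI=1S/C2H4O2.Na/c1-2(3)4;/h1H3,(H,3,4);/q;+1/p-1",
            "InChI=1S/2H2O/h2*1H2",
            "InChI=1S/H3N/h1H3/p+1",
        ):
            assert inchikey(inchi) == Chem.InchiToInchiKey(inchi)

    def test_distinct_molecules_distinct_keys(self, all_molecules):
        keys = {inchikey(m.inchi) for m in all_molecules.values()}
        inchis = {m.inchi for m in all_molecules.values()}
        assert len(keys) == len(inchis)

    def test_deterministic(self):
        i = fx.mol_record("benzene").inchi
        assert inchikey(i) == inchikey(i)

    def test_invalid_input(self):
        from rinchilib import RInChIError
        with pytest.raises(RInChIError):
            inchikey("InChI=1/CH4/h1H4")  # non-standard version


class TestHashBlock:
    def test_empty_string_pinned(self):
        assert hash_block("", 15) == EMPTY_15

    @given(st.text(max_size=60), st.integers(min_value=1, max_value=14))
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_truncation_is_prefix(self, text, n):
        assert hash_block(text, n + 1).startswith(hash_block(text, n))

    @given(st.text(max_size=60), st.integers(min_value=1, max_value=15))
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_alphabet_and_length(self, text, n):
        block = hash_block(text, n)
        assert len(block) == n
        assert set(block) <= set(string.ascii_uppercase)

    def test_no_collisions_over_large_corpus(self):
        blocks = {hash_block(f"body-{i}", 15) for i in range(10_000)}
        assert len(blocks) == 10_000


@pytest.fixture(scope="module")
def enantiomer_keys():
    ra, _ = build_rinchi(fx.reaction_record("substitution_r"))
    rb, _ = build_rinchi(fx.reaction_record("substitution_s"))
    return ra, rb


class TestLongKey:
    def test_structure_one_to_two(self, all_rinchis):
        r = all_rinchis["diels_alder"]  # two reactants, one product, no agents
        key = long_key(r, "A")
        assert key.count("--") == 1
        blocks = key.split("-")
        assert blocks[0] == "aSA"
        assert len(blocks[1]) == 5
        # three molecule keys of 27 characters (3 blocks each)
        body = key.split("-", 2)[2]
        mol_keys = [k for k in body.replace("--", "-").split("-")]
        assert len(mol_keys) == 9  # 3 molecules x 3 key blocks

    def test_molecule_order_mirrors_identifier(self, all_rinchis):
        r = all_rinchis["diels_alder"]
        key = long_key(r, "B")
        expected = [inchikey("InChI=1S/" + b) for b in r.group1 + r.group2]
        tail = key.split("-", 2)[2]
        for mk in expected:
            assert mk in tail
        assert tail.index(expected[0]) < tail.index(expected[-1])

    def test_version_b_direction_letter(self, all_rinchis):
        assert long_key(all_rinchis["diels_alder"], "B").split("-")[1][0] == "F"
        assert long_key(all_rinchis["reduction_r"], "B").split("-")[1][0] == "B"
        assert long_key(all_rinchis["esterification_eq"], "B").split("-")[1][0] == "E"
        assert long_key(all_rinchis["identity"], "B").split("-")[1][0] == "U"

    def test_versions_differ_only_in_block2(self, all_rinchis):
        for name in ("diels_alder", "esterification"):
            a = long_key(all_rinchis[name], "A").split("-")
            b = long_key(all_rinchis[name], "B").split("-")
            assert a[0][0] == "a" and b[0][0] == "b"
            assert a[2:] == b[2:]


class TestShortKey:
    def test_fixed_length_independent_of_molecule_count(self):
        body = fx.mol_record("methane").inchi_body
        small = RInChI(group1=(body,), group2=(body,))
        big = RInChI(group1=(body,) * 25, group2=(body,) * 25)
        for v in ("A", "B"):
            assert len(short_key(small, v)) == len(short_key(big, v))

    def test_version_a_block_layout(self, all_rinchis):
        blocks = short_key(all_rinchis["diels_alder"], "A").split("-")
        assert len(blocks) == 5
        assert blocks[0] == "aSA" and len(blocks[1]) == 5
        assert all(len(b) == 15 for b in blocks[2:])

    def test_version_b_block_layout(self, all_rinchis):
        blocks = short_key(all_rinchis["diels_alder"], "B").split("-")
        assert len(blocks) == 8
        assert blocks[0] == "bSA" and len(blocks[1]) == 5
        assert all(len(b) == 10 for b in blocks[2:5])
        assert all(len(b) == 5 for b in blocks[5:])
        # neutral groups flag 'N'
        assert all(b[0] == "N" for b in blocks[5:])

    def test_enantiomers_version_b_differ_only_in_minor_blocks(self, enantiomer_keys):
        ra, rb = enantiomer_keys
        a = short_key(ra, "B").split("-")
        b = short_key(rb, "B").split("-")
        differing = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        assert differing == [5, 6]  # the group1/group2 minor blocks

    def test_enantiomers_version_a_differ_in_both_group_blocks(self, enantiomer_keys):
        ra, rb = enantiomer_keys
        a = short_key(ra, "A").split("-")
        b = short_key(rb, "A").split("-")
        differing = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        assert differing == [2, 3]

    def test_empty_group3_block_identical_across_reactions(self, enantiomer_keys):
        ra, rb = enantiomer_keys
        assert short_key(ra, "A").split("-")[4] == short_key(rb, "A").split("-")[4] == EMPTY_15

    def test_direction_sensitivity(self, all_rinchis):
        r = all_rinchis["diels_alder"]
        f = r.flipped()
        kb_r = short_key(r, "B").split("-")
        kb_f = short_key(f, "B").split("-")
        assert kb_r[1][0] == "F" and kb_f[1][0] == "B"
        assert kb_r[1][1:] == kb_f[1][1:]
        assert kb_r[2:] == kb_f[2:]


class TestKeyBundle:
    def test_keys_pure_function_of_string(self, all_rinchis):
        for r in all_rinchis.values():
            assert make_keys(parse(serialize(r))) == make_keys(r)

    def test_all_blocks_uppercase_letters(self, all_rinchis):
        bundle = make_keys(all_rinchis["esterification"])
        for key in (bundle.long_a, bundle.long_b, bundle.short_a, bundle.short_b):
            body = key[1:]  # leading version letter is lowercase by design
            assert set(body) <= set(string.ascii_uppercase + "-")
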