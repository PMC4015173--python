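"""Corpus-level operations: dedup, partner search, ring/stereo change."""

from fractions import Fraction

import pytest

from rinchilib import Direction, build_rinchi, from_groups, serialize
from rinchilib import fixtures as fx
from rinchilib.analysis import (
    RInChICorpus,
    corpus_stats,
    find_duplicates,
    ring_change,
    rings_report_tsv,
    search_partner,
    stereo_change,
    stereo_report_tsv,
)


def body(name):
    return fx.mol_record(name).inchi_body


def inchi(name):
    return fx.mol_record(name).inchi


@pytest.fixture(scope="module")
def corpus():
    strings = [
        build_rinchi(fx.reaction_record(n))[0].serialized()
        for n in ("dehydration", "diels_alder", "reduction_r", "esterification_eq")
    ]
    # a duplicate of the first entry and a comment-only variant share a string
    strings.append(strings[0])
    return RInChICorpus([(s, f"src:{i}") for i, s in enumerate(strings)])


class TestFindDuplicates:
    def test_k_copies_give_k_minus_1_duplicates(self):
        s = build_rinchi(fx.reaction_record("diels_alder"))[0].serialized()
        rep = find_duplicates(RInChICorpus([s] * 4))
        assert rep.unique_count == 1 and rep.duplicate_count == 3
        assert rep.groups == ((0, 1, 2, 3),)

    def test_comment_only_variants_are_duplicates(self, small_corpus):
        """Records distinguished only by free-text comments collapse to
        the same identifier string."""
        import rinchilib.rxn_io as rio
        text, manifest = small_corpus
        recs = [v for rec in rio.read_rdfile(text) for v in rio.expand_variations(rec)]
        strings = [build_rinchi(r)[0].serialized() for r in recs]
        rep = find_duplicates(RInChICorpus(strings))
        assert rep.duplicate_count == manifest.n_duplicates
        assert sorted(rep.groups) == sorted(manifest.duplicate_groups)

    def test_stereocentre_difference_is_not_a_duplicate(self):
        a = build_rinchi(fx.reaction_record("reduction_r"))[0].serialized()
        b = build_rinchi(fx.reaction_record("reduction_s"))[0].serialized()
        rep = find_duplicates(RInChICorpus([a, b]))
        assert rep.unique_count == 2 and rep.duplicate_count == 0

    def test_invariant_under_input_order(self, corpus):
        rev = RInChICorpus(list(reversed([e.rinchi for e in corpus.entries])))
        a = find_duplicates(corpus)
        b = find_duplicates(rev)
        assert (a.unique_count, a.duplicate_count) == (b.unique_count, b.duplicate_count)

    def test_core_mode_ignores_agents_and_direction(self):
        plain = serialize(from_groups([body("ethanol")], [body("water")]))
        with_agent = serialize(from_groups([body("ethanol")], [body("water")],
                                           [body("toluene")]))
        rep = find_duplicates(RInChICorpus([plain, with_agent]), mode="core")
        assert rep.unique_count == 1


class TestSearchPartner:
    def test_product_role_honours_direction(self, corpus):
        # cyclohexene is the diels_alder product; that identifier is /d+
        hits = search_partner(corpus, inchi("cyclohexene"), role="product")
        assert hits == [1]

    def test_reduction_product_under_reversed_groups(self, corpus):
        # reduction_r serializes with /d-, so group1 holds the product
        hits = search_partner(corpus, inchi("r_butan_2_ol"), role="product")
        assert hits == [2]
        assert search_partner(corpus, inchi("r_butan_2_ol"), role="reactant") == []

    def test_absent_role_is_empty(self, corpus):
        assert search_partner(corpus, inchi("cyclohexene"), role="reactant") == []

    def test_equilibrium_matches_both_sides(self, corpus):
        # ethyl acetate appears only in the equilibrium esterification
        for role in ("reactant", "product"):
            assert search_partner(corpus, inchi("ethyl_acetate"), role=role) == [3]

    def test_agent_role(self, corpus):
        hits = search_partner(corpus, inchi("sulfuric_acid"), role="agent")
        assert set(hits) == {0, 3, 4}

    def test_any_is_union_of_roles(self, corpus):
        for q in ("water", "ethanol", "sulfuric_acid"):
            union = set()
            for role in ("reactant", "product", "agent"):
                union |= set(search_partner(corpus, inchi(q), role=role))
            assert set(search_partner(corpus, inchi(q), role="any")) == union

    def test_invalid_query(self, corpus):
        from rinchilib import RInChIError
        with pytest.raises(RInChIError):
            search_partner(corpus, "not-an-inchi")


class TestRingChange:
    def test_ring_forming_cycloaddition(self):
        s = build_rinchi(fx.reaction_record("diels_alder"))[0]
        rep = ring_change(s)
        assert rep.ring_count_delta == +1
        assert rep.rings_per_molecule_delta == Fraction(1, 1)  # 1/1 - 0/2
        # the acyclic reactant side has no cyclic molecules, so the
        # per-cyclic-molecule ratio is flagged there
        assert rep.empty_denominator

    def test_identity_reaction_no_change(self):
        s = build_rinchi(fx.reaction_record("identity"))[0]
        rep = ring_change(s)
        assert rep.ring_count_delta == 0
        assert rep.direction_unknown  # identity forces the layer off

    def test_ring_opening_flags_empty_denominator(self):
        s = build_rinchi(fx.reaction_record("ring_opening"))[0]
        rep = ring_change(s)
        assert rep.ring_count_delta == -1
        # no cyclic molecule on the product side -> ratio reported as 0
        assert rep.empty_denominator
        assert rep.rings_per_cyclic_molecule_delta == Fraction(-1)

    def test_delta_negates_under_direction_flip(self, all_rinchis):
        for name in ("diels_alder", "ring_opening", "dehydration"):
            r = all_rinchis[name]
            a, b = ring_change(r), ring_change(r.flipped())
            assert a.ring_count_delta == -b.ring_count_delta
            assert a.rings_per_molecule_delta == -b.rings_per_molecule_delta

    def test_multicomponent_body_counts_per_molecule(self):
        # benzene+water fused into one two-component body on the product side
        two_comp = "C6H6.H2O/c1-2-4-6-5-3-1;/h1-6H;1H2"
        s = from_groups([body("methane")], [two_comp])
        rep = ring_change(s)
        assert rep.ring_count_delta == 1
        assert rep.rings_per_molecule_delta == Fraction(1, 2)


class TestStereoChange:
    def test_reduction_creates_one_stereocentre(self):
        s = build_rinchi(fx.reaction_record("reduction_r"))[0]
        rep = stereo_change(s)
        assert rep.stereocentre_delta_per_molecule == Fraction(1)

    def test_enantiomeric_entries_have_equal_counts(self):
        a = stereo_change(build_rinchi(fx.reaction_record("reduction_r"))[0])
        b = stereo_change(build_rinchi(fx.reaction_record("reduction_s"))[0])
        assert (a.stereocentre_delta_per_molecule
                == b.stereocentre_delta_per_molecule)

    def test_racemization_equilibrium_zero_delta(self):
        s = from_groups([body("r_butan_2_ol")], [body("s_butan_2_ol")],
                        direction=Direction.EQUILIBRIUM)
        assert stereo_change(s).stereocentre_delta_per_molecule == 0

    def test_t_only_mode_ignores_double_bonds(self):
        # 2-butene body with a /b layer
        butene = "C4H8/c1-3-4-2/h3-4H,1-2H3/b4-3+"
        s = from_groups([body("butadiene")], [butene])
        assert stereo_change(s).stereocentre_delta_per_molecule == Fraction(1)
        assert stereo_change(s, mode="t_only").stereocentre_delta_per_molecule == 0

    def test_delta_negates_under_direction_flip(self, all_rinchis):
        r = all_rinchis["reduction_r"]
        assert (stereo_change(r).stereocentre_delta_per_molecule
                == -stereo_change(r.flipped()).stereocentre_delta_per_molecule)


class TestCorpusStats:
    def test_injected_duplicates_subtracted(self):
        base = [build_rinchi(fx.reaction_record(n))[0].serialized()
                for n in ("dehydration", "diels_alder", "ring_opening")]
        strings = base + [base[0], base[0], base[2]]
        st = corpus_stats(RInChICorpus(strings))
        assert st.entry_count == 6 and st.unique_reactions == 3

    def test_unique_molecules_is_distinct_body_count(self, corpus):
        st = corpus_stats(corpus)
        bodies = set()
        seen = set()
        for i in range(len(corpus)):
            if corpus.entries[i].rinchi in seen:
                continue
            seen.add(corpus.entries[i].rinchi)
            bodies.update(corpus.parsed(i).all_bodies)
        assert st.unique_molecules == len(bodies)

    def test_compression_ratio_reported(self, corpus):
        st = corpus_stats(corpus, source_bytes=100_000)
        assert st.compression_ratio == pytest.approx(
            len(corpus.to_lines().encode()) / 100_000)

    def test_cross_source_intersection(self):
        a = [build_rinchi(fx.reaction_record(n))[0].serialized()
             for n in ("dehydration", "diels_alder", "reduction_r")]
        b = [build_rinchi(fx.reaction_record(n))[0].serialized()
             for n in ("diels_alder", "reduction_r", "ring_opening")]
        shared = set(a) & set(b)
        assert len(shared) == 2


class TestReports:
    def test_tsv_headers_and_row_count(self, corpus):
        rings = rings_report_tsv(corpus).splitlines()
        stereo = stereo_report_tsv(corpus).splitlines()
        assert rings[0].startswith("entry\tsource_id\tring_count_delta")
        assert stereo[0].startswith("entry\tsource_id\tstereocentre_delta")
        assert len(rings) == len(stereo) == len(corpus) + 1
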