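"""TDRL action, swap invariance, intermediates and minimal windows."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdrlkit import (
    CircularGeneOrder,
    GeneSetMismatchError,
    Tdrl,
    apply_partial,
    apply_tdrl,
    build_duplicated_intermediate,
    is_identity_tdrl,
    minimal_partial,
    swap_labeling,
    whole_from_partial,
)
from tdrlkit.simulate import random_circular_order, random_tdrl


def tdrl(f, s, p):
    return Tdrl(frozenset(f), frozenset(s), p)


IDENTITY8 = CircularGeneOrder(range(1, 9))


def exhaustive_min_window(t, order):
    """Independent oracle: simulate every contiguous window of the origin
    representative (replace W by F'-then-S', compare rotation classes)."""
    rep = order.representative_starting_at(t.origin)
    n = len(rep)
    target = apply_tdrl(t, order)
    for size in range(n + 1):
        for start in range(n - size + 1):
            w = rep[start : start + size]
            repl = (
                rep[:start]
                + tuple(g for g in w if g in t.first)
                + tuple(g for g in w if g in t.second)
                + rep[start + size :]
            )
            if CircularGeneOrder(repl) == target:
                return size
    raise AssertionError("no window reproduces the TDRL output")


class TestApply:
    def test_five_gene_worked_example(self, fig1_order):
        out = apply_tdrl(tdrl({4, 5}, {1, 2, 3}, 1), fig1_order)
        assert out == CircularGeneOrder((4, 5, 1, 2, 3))

    def test_eight_gene_partial_duplication_example(self):
        out = apply_tdrl(tdrl({3, 5}, {1, 2, 4, 6, 7, 8}, 7), IDENTITY8)
        assert out == CircularGeneOrder((1, 2, 4, 6, 3, 5, 7, 8))

    def test_empty_first_copy_is_identity(self, fig1_order):
        t = tdrl((), {1, 2, 3, 4, 5}, 2)
        assert apply_tdrl(t, fig1_order) == fig1_order

    def test_gene_set_mismatch(self, fig1_order):
        with pytest.raises(GeneSetMismatchError):
            apply_tdrl(tdrl({1, 2}, {3, 4}, 1), fig1_order)

    @given(st.permutations(list(range(1, 7))), st.integers(0, 2**31))
    @settings(max_examples=50)
    def test_rotation_consistency(self, rep, seed):
        """The action depends only on the rotation class of the input."""
        o = CircularGeneOrder(rep)
        t = random_tdrl(o, seed, allow_identity=True)
        for p in rep:
            rotated = CircularGeneOrder(o.representative_starting_at(p))
            assert apply_tdrl(t, rotated) == apply_tdrl(t, o)


class TestSwap:
    def test_swap_is_involution_and_equivalent(self, fig1_order):
        t = tdrl({4, 5}, {1, 2, 3}, 1)
        assert swap_labeling(swap_labeling(t)) == t
        assert apply_tdrl(swap_labeling(t), fig1_order) == apply_tdrl(t, fig1_order)

    def test_equivalent_triples_with_different_origins(self, fig1_order):
        a = tdrl({3, 4}, {1, 2, 5}, 5)
        b = tdrl({4, 5}, {1, 2, 3}, 1)
        assert apply_tdrl(a, fig1_order) == apply_tdrl(b, fig1_order)

    @given(st.integers(0, 2**31))
    @settings(max_examples=50)
    def test_swap_invariance_on_random_instances(self, seed):
        o = random_circular_order(7, seed)
        t = random_tdrl(o, seed)
        assert apply_tdrl(t, o) == apply_tdrl(t.swap(), o)


class TestDuplicatedIntermediate:
    def test_kept_reading_of_worked_example(self, fig1_order):
        di = build_duplicated_intermediate(tdrl({4, 5}, {1, 2, 3}, 1), fig1_order)
        assert di.kept_reading == (4, 5, 1, 2, 3)
        assert len(di.occurrences) == 10

    @given(st.integers(0, 2**31))
    @settings(max_examples=30)
    def test_every_gene_twice_kept_once(self, seed):
        o = random_circular_order(6, seed)
        t = random_tdrl(o, seed, allow_identity=True)
        di = build_duplicated_intermediate(t, o)
        genes = [occ.gene for occ in di.occurrences]
        assert sorted(genes) == sorted(list(o.genes) * 2)
        kept = list(di.kept_reading)
        assert sorted(kept) == sorted(o.genes)
        assert sorted(di.lost) == sorted(o.genes)
        assert CircularGeneOrder(kept) == apply_tdrl(t, o)

    def test_full_first_copy_keeps_copy_one(self, fig1_order):
        t = tdrl({1, 2, 3, 4, 5}, (), 1)
        di = build_duplicated_intermediate(t, fig1_order)
        assert all(o.kept == (o.copy == 1) for o in di.occurrences)


class TestMinimalPartial:
    @pytest.mark.parametrize(
        "f,s,p",
        [
            ({4, 6}, {1, 2, 3, 5, 7, 8}, 3),
            ({1, 2, 4, 6, 7, 8}, {3, 5}, 7),
        ],
    )
    def test_worked_window_three_to_six(self, f, s, p):
        part = minimal_partial(tdrl(f, s, p), IDENTITY8)
        assert part.window == (3, 4, 5, 6)
        assert part.kept_first == (4, 6)
        assert part.kept_second == (3, 5)
        assert part.not_duplicated == frozenset({1, 2, 7, 8})

    def test_identity_triple_has_empty_window(self):
        part = minimal_partial(tdrl({1, 2, 3}, {4, 5, 6, 7, 8}, 1), IDENTITY8)
        assert part.window == ()
        assert part.size == 0

    def test_window_never_wraps_the_representative(self):
        t = tdrl({3, 5}, {1, 2, 4, 6, 7, 8}, 7)
        part = minimal_partial(t, IDENTITY8)
        rep = IDENTITY8.representative_starting_at(7)
        i = rep.index(part.window[0])
        assert rep[i : i + part.size] == part.window

    @given(st.integers(0, 2**31), st.integers(4, 8))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_window_oracle(self, seed, n):
        o = random_circular_order(n, seed)
        t = random_tdrl(o, seed)
        part = minimal_partial(t, o)
        assert part.size == exhaustive_min_window(t, o)

    @given(st.integers(0, 2**31))
    @settings(max_examples=40)
    def test_replay_reproduces_the_output(self, seed):
        o = random_circular_order(7, seed)
        t = random_tdrl(o, seed)
        assert apply_partial(minimal_partial(t, o), o) == apply_tdrl(t, o)


class TestWholeFromPartial:
    def test_worked_correspondence(self):
        part = minimal_partial(tdrl({1, 2, 4, 6, 7, 8}, {3, 5}, 7), IDENTITY8)
        whole = whole_from_partial(part, IDENTITY8)
        assert whole == tdrl({3, 5}, {1, 2, 4, 6, 7, 8}, 7)

    @given(st.integers(0, 2**31))
    @settings(max_examples=40)
    def test_same_output_class(self, seed):
        o = random_circular_order(6, seed)
        t = random_tdrl(o, seed)
        part = minimal_partial(t, o)
        whole = whole_from_partial(part, o)
        assert apply_tdrl(whole, o) == apply_tdrl(t, o)

    def test_empty_window_rejected(self):
        part = minimal_partial(tdrl({1, 2}, {3, 4, 5, 6, 7, 8}, 1), IDENTITY8)
        with pytest.raises(ValueError, match="identity map"):
            whole_from_partial(part, IDENTITY8)


class TestIsIdentity:
    def test_empty_first_set(self, fig1_order):
        assert is_identity_tdrl(tdrl((), fig1_order.genes, 3), fig1_order)

    @pytest.mark.parametrize("cut", range(6))
    def test_prefix_cuts_fix_the_order(self, fig1_order, cut):
        rep = fig1_order.representative_starting_at(4)
        t = tdrl(rep[:cut], rep[cut:], 4)
        assert is_identity_tdrl(t, fig1_order)

    def test_proper_rearrangement_is_not_identity(self, fig1_order):
        assert not is_identity_tdrl(tdrl({4, 5}, {1, 2, 3}, 1), fig1_order)
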