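"""Circular order model: parsing, rotations, equality, conserved segments."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdrlkit import (
    CircularGeneOrder,
    GeneOrder,
    InputFormatError,
    GeneSetMismatchError,
    LabelMap,
    circular_equals,
    conserved_segments,
    parse_gene_order_file,
    parse_gene_order_text,
    project_to_shared,
    relabel_by_target,
    shift_k,
)

perms = st.permutations(list(range(1, 8)))


class TestParsing:
    def test_single_record(self, tmp_path):
        f = tmp_path / "toy.fa"
        f.write_text(">toy\n1 2 3 4 5 6 7 8\n")
        records = parse_gene_order_file(f)
        assert len(records) == 1
        name, order = records[0]
        assert name == "toy"
        assert order.n == 8
        assert order.names == tuple(str(i) for i in range(1, 9))

    def test_strand_signs_dropped(self):
        [(_, order)] = parse_gene_order_text(">g\ncox1 -trnL2 +cox2\n")
        assert order.names == ("cox1", "trnL2", "cox2")

    def test_multiple_records_order_preserved(self):
        recs = parse_gene_order_text(">a\n1 2 3\n>b\n3 1 2\n")
        assert [name for name, _ in recs] == ["a", "b"]

    @pytest.mark.parametrize(
        "text,match",
        [
            (">g\na b a\n", "duplicate gene 'a'"),
            (">g\n>h\n1 2\n", "empty record"),
            ("", "no gene-order records"),
            ("1 2 3\n", "before any"),
        ],
    )
    def test_malformed_input(self, text, match):
        with pytest.raises(InputFormatError, match=match):
            parse_gene_order_text(text)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputFormatError, match="not found"):
            parse_gene_order_file(tmp_path / "absent.fa")

    def test_project_to_shared(self):
        a = GeneOrder(["a", "b", "c", "d"])
        b = GeneOrder(["d", "b", "a", "e"])
        pa, pb = project_to_shared(a, b)
        assert pa.names == ("a", "b", "d")
        assert pb.names == ("d", "b", "a")


class TestShift:
    def test_double_shift_example(self):
        assert shift_k((1, 4, 2, 5, 3), 2) == (2, 5, 3, 1, 4)

    def test_single_shift(self):
        assert shift_k((1, 2, 3), 1) == (2, 3, 1)

    @given(perms)
    def test_full_rotation_is_identity(self, rep):
        assert shift_k(rep, len(rep)) == tuple(rep)

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            shift_k((1, 2, 3), 0)


class TestCircularGeneOrder:
    def test_representatives_start_with_requested_gene(self, fig1_order):
        assert fig1_order.representative_starting_at(4) == (4, 2, 5, 3, 1)
        assert fig1_order.representative_starting_at(2) == (2, 5, 3, 1, 4)

    def test_canonical_representative_round_trip(self, fig1_order):
        first = fig1_order.canonical[0]
        assert fig1_order.representative_starting_at(first) == fig1_order.canonical

    def test_unknown_start_gene(self, fig1_order):
        with pytest.raises(KeyError, match="not in this order"):
            fig1_order.representative_starting_at(9)

    def test_rotations_are_equal_classes(self):
        assert circular_equals(
            CircularGeneOrder((1, 4, 2, 5, 3)), CircularGeneOrder((3, 1, 4, 2, 5))
        )

    def test_distinct_classes_differ(self):
        assert not circular_equals(
            CircularGeneOrder((1, 2, 3, 4, 5)), CircularGeneOrder((1, 2, 3, 5, 4))
        )

    @given(perms, st.integers(min_value=1, max_value=7))
    @settings(max_examples=50)
    def test_rotation_closure(self, rep, k):
        o = CircularGeneOrder(rep)
        assert circular_equals(o, CircularGeneOrder(shift_k(rep, k)))
        assert hash(o) == hash(CircularGeneOrder(shift_k(rep, k)))

    @given(perms)
    @settings(max_examples=30)
    def test_every_representative_keeps_the_class(self, rep):
        o = CircularGeneOrder(rep)
        for p in rep:
            r = o.representative_starting_at(p)
            assert r[0] == p
            assert CircularGeneOrder(r) == o

    def test_rejects_duplicates(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            CircularGeneOrder((1, 2, 1))


class TestLabelMap:
    def test_round_trip(self):
        lm = LabelMap(("cox1", "trnL2", "cox2"))
        for g in lm.labels:
            assert lm.to_label(lm.to_int(g)) == g
        assert lm.ints_of(("cox2", "cox1")) == (3, 1)

    def test_unknown_label(self):
        with pytest.raises(KeyError):
            LabelMap(("a", "b")).to_int("c")


class TestRelabel:
    def test_positional_lookup_examples(self):
        assert relabel_by_target(
            (1, 2, 3, 4, 5, 6, 7, 8), (1, 2, 4, 6, 3, 5, 7, 8)
        ) == (1, 2, 5, 3, 6, 4, 7, 8)
        assert relabel_by_target((1, 4, 2, 5, 3), (4, 5, 1, 2, 3)) == (3, 1, 4, 2, 5)

    @given(perms)
    def test_self_relabel_is_identity(self, rep):
        assert relabel_by_target(rep, rep) == tuple(range(1, len(rep) + 1))

    @given(perms)
    @settings(max_examples=30)
    def test_inverse_reconstructs_source(self, rep):
        target = tuple(sorted(rep))
        w = relabel_by_target(rep, target)
        rebuilt = [None] * len(rep)
        for i, p in enumerate(w):
            rebuilt[i] = target[p - 1]
        assert tuple(rebuilt) == tuple(rep)

    def test_mismatched_sets(self):
        with pytest.raises(GeneSetMismatchError, match="only in source"):
            relabel_by_target((1, 2, 3), (1, 2, 4))


class TestConservedSegments:
    def test_identical_orders_give_whole_circle(self, fig1_order):
        [seg] = conserved_segments(fig1_order, fig1_order)
        assert set(seg.genes) == fig1_order.genes
        assert seg.length == 5

    def test_worked_six_gene_example(self):
        a = CircularGeneOrder((1, 2, 3, 4, 5, 6))
        b = CircularGeneOrder((1, 2, 3, 5, 4, 6))
        segs = {s.genes for s in conserved_segments(a, b)}
        assert segs == {(6, 1, 2, 3), (4,), (5,)}

    @given(perms, perms)
    @settings(max_examples=50)
    def test_segments_partition_the_gene_set(self, ra, rb):
        a, b = CircularGeneOrder(ra), CircularGeneOrder(rb)
        segs = conserved_segments(a, b)
        covered = [g for s in segs for g in s.genes]
        assert sorted(covered) == sorted(ra)
        # each segment is a contiguous run of both circular orders
        for s in segs:
            if s.length == a.n:
                continue
            for o in (a, b):
                rep = o.representative_starting_at(s.genes[0])
                assert rep[: s.length] == s.genes

    def test_mismatched_gene_sets(self):
        with pytest.raises(GeneSetMismatchError):
            conserved_segments(
                CircularGeneOrder((1, 2, 3)), CircularGeneOrder((1, 2, 4))
            )
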