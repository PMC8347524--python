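"""Sequence/structure types, dot-bracket parsing, distances, file I/O."""

import numpy as np
import pytest

from rnafoldpath.structure import (
    RnaSequence,
    SecondaryStructure,
    StructureError,
    parse_dotbracket,
    pairs_to_matrix,
    read_structure_file,
    structure_distance,
    write_bpseq,
    write_ct,
    write_dbn,
    write_dotbracket,
)

from conftest import random_sequence, random_structure

THREEWAY_DBN = ".((.((.(((...)))(((....)))))))"
THREEWAY_PAIRS = {
    (2, 30), (3, 29), (5, 28), (6, 27), (8, 16),
    (9, 15), (10, 14), (17, 26), (18, 25), (19, 24),
}


class TestRnaSequence:
    def test_normalization_maps_t_and_lowercase(self):
        assert str(RnaSequence("acgt")) == "ACGU"

    def test_rejects_non_nucleotides(self):
        with pytest.raises(StructureError, match="position 3"):
            RnaSequence("AUXG")

    def test_one_based_indexing(self):
        seq = RnaSequence("GAAAC")
        assert seq[1] == "G" and seq[5] == "C"
        with pytest.raises(IndexError):
            seq[0]


class TestParseDotbracket:
    def test_three_way_junction_pair_list(self):
        struct = parse_dotbracket(THREEWAY_DBN)
        assert set(struct.pairs) == THREEWAY_PAIRS

    def test_all_dots_is_empty(self):
        assert len(parse_dotbracket("...")) == 0

    def test_pseudoknot_layers_parse_with_independent_stacks(self):
        dbn = (
            "((((((((((..((((((......[[.))))))[.....)]"
            "((((((]].....))))))..)))))))))"
        )
        struct = parse_dotbracket(dbn)
        assert len(struct.pseudoknot_pairs()) == 3
        assert all(struct.layer_of(p) == 1 for p in struct.pseudoknot_pairs())
        assert len(struct.nested_pairs()) == 22

    def test_spaces_are_stripped(self):
        assert parse_dotbracket("( ... )").pairs == frozenset({(1, 5)})

    @pytest.mark.parametrize(
        "text,msg",
        [
            ("(..", "never closed"),
            ("..)", "no matching opener"),
            ("([..)", "never closed"),
            (".(x).", "unexpected character"),
        ],
    )
    def test_unbalanced_or_bad_input_raises(self, text, msg):
        with pytest.raises(StructureError, match=msg):
            parse_dotbracket(text)


class TestWriteDotbracket:
    def test_empty_structure(self):
        assert write_dotbracket(SecondaryStructure((), length=4)) == "...."

    def test_single_pair(self):
        assert write_dotbracket(SecondaryStructure([(1, 5)], length=5)) == "(...)"

    def test_roundtrip_of_printed_structure(self):
        assert write_dotbracket(parse_dotbracket(THREEWAY_DBN), 30) == THREEWAY_DBN

    def test_roundtrip_identity_on_random_structures(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            seq = random_sequence(rng, max_len=30)
            mode = "pk_allowed" if rng.random() < 0.3 else "pk_free"
            struct = random_structure(rng, seq, mode)
            if any(struct.layer_of(p) > 3 for p in struct.pairs):
                continue  # deeper pseudoknot nests than the bracket alphabets
            text = write_dotbracket(struct, len(seq))
            assert parse_dotbracket(text).pairs == struct.pairs


class TestContactMatrix:
    def test_empty_structure_all_zero(self):
        assert pairs_to_matrix(SecondaryStructure((), length=6)).sum() == 0

    def test_single_pair_upper_triangular(self):
        mat = pairs_to_matrix(SecondaryStructure([(1, 5)], length=5))
        assert mat[0, 4] == 1 and mat.sum() == 1

    def test_six_native_pairs_give_six_ones(self):
        pairs = [(1, 17), (2, 16), (3, 15), (4, 14), (18, 30), (19, 29)]
        mat = pairs_to_matrix(SecondaryStructure(pairs, length=30))
        assert mat.sum() == 6
        assert np.all(np.tril(mat) == 0)

    def test_nonzero_count_equals_pair_count(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            seq = random_sequence(rng, max_len=25)
            struct = random_structure(rng, seq)
            assert pairs_to_matrix(struct, len(seq)).sum() == len(struct)


class TestStructureDistance:
    def test_identical_structures(self):
        s = parse_dotbracket(THREEWAY_DBN)
        assert structure_distance(s, s) == 0

    def test_native_vs_open_strand_counts_native_pairs(self):
        pairs = [(1, 17), (2, 16), (3, 15), (4, 14), (18, 30), (19, 29)]
        native = SecondaryStructure(pairs, length=30)
        assert structure_distance(native, SecondaryStructure((), length=30)) == 6

    def test_one_pair_swap_costs_two(self):
        a = SecondaryStructure([(1, 5)])
        b = SecondaryStructure([(1, 6)])
        assert structure_distance(a, b) == 2

    def test_mismatched_lengths_raise(self):
        with pytest.raises(StructureError, match="length mismatch"):
            structure_distance(
                SecondaryStructure((), length=5), SecondaryStructure((), length=6)
            )

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            seq = random_sequence(rng, max_len=30)
            a, b, c = (random_structure(rng, seq) for _ in range(3))
            assert structure_distance(a, a) == 0
            assert structure_distance(a, b) == structure_distance(b, a)
            assert structure_distance(a, c) <= (
                structure_distance(a, b) + structure_distance(b, c)
            )

    def test_equals_squared_contact_matrix_difference(self):
        rng = np.random.default_rng(5)
        seq = random_sequence(rng, max_len=30)
        a, b = random_structure(rng, seq), random_structure(rng, seq)
        m = pairs_to_matrix(a, len(seq)).astype(int) - pairs_to_matrix(b, len(seq))
        assert structure_distance(a, b) == int((m**2).sum())


class TestFileIO:
    def test_dbn_roundtrip(self, tmp_path):
        seq = RnaSequence("AAGCGGAACGAAACGUUGCUUUUGCGCCCU")
        struct = parse_dotbracket(THREEWAY_DBN, length=30)
        path = tmp_path / "x.dbn"
        write_dbn(path, "x", seq, struct)
        seq2, struct2 = read_structure_file(path)
        assert str(seq2) == str(seq) and len(seq2) == 30
        assert struct2.pairs == struct.pairs and len(struct2) == 10

    def test_bpseq_roundtrip_and_empty(self, tmp_path):
        seq = RnaSequence("GAAAC")
        path = tmp_path / "x.bpseq"
        write_bpseq(path, seq, SecondaryStructure([(1, 5)], length=5))
        seq2, struct2 = read_structure_file(path)
        assert struct2.pairs == frozenset({(1, 5)})
        path.write_text("1 G 0\n2 A 0\n3 A 0\n4 A 0\n5 C 0\n")
        _, empty = read_structure_file(path)
        assert len(empty) == 0

    def test_ct_roundtrip_and_all_unpaired(self, tmp_path):
        seq = RnaSequence("GGAAACC")
        struct = SecondaryStructure([(1, 7), (2, 6)], length=7)
        path = tmp_path / "x.ct"
        write_ct(path, "x", seq, struct)
        _, struct2 = read_structure_file(path)
        assert struct2.pairs == struct.pairs
        rows = "\n".join(f"{i} A {i-1} {i+1} 0 {i}" for i in range(1, 6))
        path.write_text("5 y\n" + rows + "\n")
        _, empty = read_structure_file(path)
        assert len(empty) == 0

    def test_inconsistent_reciprocal_rows_raise(self, tmp_path):
        path = tmp_path / "bad.bpseq"
        path.write_text("1 G 5\n2 A 0\n3 A 0\n4 A 0\n5 C 4\n")
        with pytest.raises(StructureError, match="reciprocal"):
            read_structure_file(path)


class TestStructureInvariants:
    def test_shared_position_rejected(self):
        with pytest.raises(StructureError, match="position 5"):
            SecondaryStructure([(1, 5), (5, 10)])

    def test_crossing_layer0_pairs_rejected(self):
        with pytest.raises(StructureError, match="cross"):
            SecondaryStructure([(1, 6), (3, 9)])

    def test_crossing_allowed_on_distinct_layers(self):
        s = SecondaryStructure([(1, 6), (3, 9)], layers={(3, 9): 1})
        assert s.pseudoknot_pairs() == frozenset({(3, 9)})
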