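"""Character coding, polarization, transposition and partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaclad.matrix import (
    CharacterDef,
    CharacterMatrix,
    SequenceBlock,
    StateOverflowWarning,
    add_ancestor,
    build_matrix,
    combine_total_evidence,
    decode_state,
    encode_state,
    partition,
    transpose,
)
from rnaclad.simulate import synthetic_scheme, simulate_molecules
from rnaclad.structure import decompose, label_substructures

from conftest import make_matrix


class TestStateAlphabet:
    @pytest.mark.parametrize(
        "value,symbol", [(0, "0"), (9, "9"), (10, "A"), (35, "Z"), (36, "a"), (61, "z")]
    )
    def test_alphanumeric_encoding(self, value, symbol):
        assert encode_state(value) == symbol
        assert decode_state(symbol) == value

    def test_overflow_clamps_with_warning(self):
        with pytest.warns(StateOverflowWarning):
            assert encode_state(75) == "z"

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            encode_state(-1)


class TestBuildMatrix:
    def test_missing_substructure_codes_zero(self):
        scheme = synthetic_scheme(3, 0)
        M = make_seven_block(scheme)
        # molecule m7 lacks P3 entirely
        assert M.values[6, M.char_ids().index("P3.len")] == 0

    def test_identical_molecules_identical_rows(self):
        scheme = synthetic_scheme(2, 2)
        vals = np.array([[4, 3, 2, 3], [4, 3, 2, 3]], np.int16)
        chars = [
            CharacterDef("P1.len", "stabilizing"),
            CharacterDef("L1.len", "destabilizing", metric="loop_nt"),
            CharacterDef("P2.len", "stabilizing"),
            CharacterDef("L2.len", "destabilizing", metric="loop_nt"),
        ]
        M0 = CharacterMatrix(["a", "b"], chars, vals)
        mols, ann = simulate_molecules(M0, scheme)
        labeled = [
            (m.molecule_id, label_substructures(decompose(m), scheme, ann[m.molecule_id]))
            for m in mols
        ]
        M = build_matrix(labeled, scheme)
        assert (M.values[0] == M.values[1]).all()

    def test_seven_molecule_stem_block_shape(self):
        scheme = synthetic_scheme(3, 0)
        M = make_seven_block(scheme)
        assert M.n_taxa == 7
        assert M.char_ids() == ["P1.len", "P2.len", "P3.len"]
        assert M.orientation == "molecules_as_taxa"

    def test_duplicate_taxon_rejected(self):
        scheme = synthetic_scheme(1, 0)
        subs = []
        with pytest.raises(ValueError):
            build_matrix([("a", subs), ("a", subs)], scheme)

    def test_empty_molecule_set_rejected(self):
        with pytest.raises(ValueError):
            build_matrix([], synthetic_scheme(1, 0))


def make_seven_block(scheme):
    """Seven molecules scored for three stems (one lacks P3)."""
    lengths = [
        (5, 4, 3),
        (5, 4, 3),
        (6, 4, 3),
        (5, 3, 2),
        (4, 4, 3),
        (5, 4, 2),
        (5, 4, 0),
    ]
    chars = [CharacterDef(f"P{i}.len", "stabilizing") for i in (1, 2, 3)]
    M0 = CharacterMatrix(
        [f"m{i + 1}" for i in range(7)], chars, np.array(lengths, np.int16)
    )
    mols, ann = simulate_molecules(M0, scheme)
    labeled = [
        (m.molecule_id, label_substructures(decompose(m), scheme, ann[m.molecule_id]))
        for m in mols
    ]
    return build_matrix(labeled, scheme)


class TestAncestor:
    def test_stabilizing_column_max(self):
        M = add_ancestor(make_matrix([[3], [7], [12]]))
        assert M.ancestor[0] == 12
        assert M.ancestor_symbols() == "C"

    def test_destabilizing_column_zero(self):
        M = add_ancestor(make_matrix([[0], [4], [9]], kinds=["destabilizing"]))
        assert M.ancestor[0] == 0

    def test_all_zero_stem_column(self):
        M = add_ancestor(make_matrix([[0], [0], [0]]))
        assert M.ancestor[0] == 0

    def test_reversed_polarity_flips(self):
        M = make_matrix([[1, 0], [5, 4]], kinds=["stabilizing", "destabilizing"])
        rev = add_ancestor(M, polarity="reversed")
        assert rev.ancestor[0] == 1 and rev.ancestor[1] == 4

    @given(st.integers(0, 50), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ancestor_invariant_under_dominated_taxa(self, extra, data):
        vals = data.draw(
            st.lists(st.integers(0, 30), min_size=3, max_size=6).map(
                lambda xs: np.array(xs, np.int16)[:, None]
            )
        )
        M = add_ancestor(make_matrix(vals))
        new_state = data.draw(st.integers(0, int(M.ancestor[0])))
        M2 = add_ancestor(
            make_matrix(np.vstack([vals, [[new_state]]]))
        )
        assert M2.ancestor[0] == M.ancestor[0]


class TestTranspose:
    def test_shape_and_involution(self):
        M = make_matrix([[1, 2, 3], [4, 5, 6]])
        T = transpose(M)
        assert (T.n_taxa, T.n_chars) == (3, 2)
        assert T.orientation == "substructures_as_taxa"
        back = transpose(T)
        assert back.taxa == M.taxa
        assert back.char_ids() == M.char_ids()
        assert (back.values == M.values).all()

    def test_mixed_kind_rejected(self):
        M = make_matrix([[1, 2], [3, 4]], kinds=["stabilizing", "destabilizing"])
        with pytest.raises(ValueError, match="partition"):
            transpose(M)

    def test_stems_block_transposes_to_substructure_taxa(self):
        M = make_seven_block(synthetic_scheme(3, 0))
        T = transpose(M)
        assert T.taxa == ["P1.len", "P2.len", "P3.len"]
        assert T.n_chars == 7


class TestPartition:
    def _matrix(self):
        chars = [
            CharacterDef("P1.len", "stabilizing", "C"),
            CharacterDef("P7.len", "stabilizing", "S"),
            CharacterDef("L1.len", "destabilizing", "C", "loop_nt"),
            CharacterDef("L7.len", "destabilizing", "S", "loop_nt"),
        ]
        meta = {
            "a1": {"superkingdom": "Archaea"},
            "b1": {"superkingdom": "Bacteria"},
            "b2": {"superkingdom": "Bacteria"},
        }
        return CharacterMatrix(
            ["a1", "b1", "b2"],
            chars,
            np.arange(12, dtype=np.int16).reshape(3, 4),
            taxon_meta=meta,
        )

    def test_kind_and_domain_partitions(self):
        M = self._matrix()
        assert partition(M, "stabilizing").char_ids() == ["P1.len", "P7.len"]
        assert partition(M, "destabilizing").char_ids() == ["L1.len", "L7.len"]
        assert partition(M, "domain_S").char_ids() == ["P7.len", "L7.len"]
        assert partition(M, "domain_C").char_ids() == ["P1.len", "L1.len"]

    def test_superkingdom_partition_filters_taxa(self):
        sub = partition(self._matrix(), "superkingdom:Bacteria")
        assert sub.taxa == ["b1", "b2"]
        assert sub.n_chars == 4

    def test_core_preset_requires_labels(self):
        with pytest.raises(ValueError, match="P2"):
            partition(self._matrix(), "core_A")

    def test_core_preset_accepts_composites(self):
        chars = [
            CharacterDef(f"{lab}.len", "stabilizing")
            for lab in ("P1", "P2", "P3", "P4", "P10-11", "P9")
        ]
        M = CharacterMatrix(
            ["x", "y"], chars, np.zeros((2, 6), np.int16)
        )
        sub = partition(M, "core_A")
        assert "P10-11.len" in sub.char_ids()
        assert "P9.len" not in sub.char_ids()

    def test_empty_partition_raises(self):
        M = make_matrix([[1], [2]])
        with pytest.raises(ValueError):
            partition(M, "domain_S")


class TestTotalEvidence:
    def test_concatenation_counts_and_ancestor(self):
        M = add_ancestor(make_matrix([[3, 1], [2, 0]], taxa=["a", "b"]))
        S = SequenceBlock(["b", "a"], ["AC-G", "AUGG"])
        C = combine_total_evidence(M, S)
        assert C.n_chars == 6
        assert [c.ordered for c in C.chars] == [True, True, False, False, False, False]
        # gap in 'b' treated as missing; ancestor missing for sequence columns
        assert C.values[1, 4] == -1
        assert list(C.ancestor[2:]) == [-1] * 4
        # rows realigned to matrix taxon order
        assert C.values[0, 2] == 0  # a: A
        assert C.values[0, 3] == 3  # a: U

    def test_empty_block_is_identity(self):
        M = make_matrix([[1], [2]])
        C = combine_total_evidence(M, SequenceBlock([], []))
        assert C.char_ids() == M.char_ids()
        assert (C.values == M.values).all()

    def test_taxon_mismatch_raises(self):
        M = make_matrix([[1], [2]])
        with pytest.raises(ValueError):
            combine_total_evidence(M, SequenceBlock(["t1", "zz"], ["A", "C"]))


class TestTSV:
    def test_roundtrip(self):
        M = add_ancestor(
            make_matrix([[3, 0], [1, 5]], kinds=["stabilizing", "destabilizing"])
        )
        M.taxon_meta["t1"] = {"superkingdom": "Archaea", "rpr_type": "A"}
        back = CharacterMatrix.from_tsv(M.to_tsv())
        assert back.taxa == M.taxa
        assert (back.values == M.values).all()
        assert (back.ancestor == M.ancestor).all()
        assert [c.kind for c in back.chars] == [c.kind for c in M.chars]
        assert back.taxon_meta["t1"]["superkingdom"] == "Archaea"
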