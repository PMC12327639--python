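"""Structure parsing, contact-graph construction, and label I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactgo import graph_io as gio

# a two-chain-free miniature PDB with an altLoc duplicate CA on residue 2
# and a glycine-like residue 3 lacking a CA record entirely
PDB_ALTLOC = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA ASER A   2       4.000   0.000   0.000  0.60  0.00           C
ATOM      4  CA BSER A   2       4.500   0.000   0.000  0.40  0.00           C
ATOM      5  N   GLY A   3       8.000   0.000   0.000  1.00  0.00           N
ATOM      6  CA  LEU A   4      20.000   0.000   0.000  1.00  0.00           C
END
"""


class TestParseCaCoordinates:
    def test_plain_table_read_back(self, tmp_path):
        f = tmp_path / "coords.txt"
        f.write_text("0 0 0\n5 0 0\n20 0 0\n")
        pts = gio.parse_ca_coordinates(f)
        assert pts.shape == (3, 3)
        np.testing.assert_allclose(pts[1], [5, 0, 0])

    def test_pdb_altloc_keeps_first_and_skips_missing_ca(self, tmp_path):
        f = tmp_path / "toy.pdb"
        f.write_text(PDB_ALTLOC)
        pts = gio.parse_ca_coordinates(f)
        # residues 1, 2 (first altLoc), 4 — residue 3 has no CA
        assert pts.shape == (3, 3)
        np.testing.assert_allclose(pts[1], [4.0, 0.0, 0.0])

    def test_no_atoms_is_empty_structure_error(self, tmp_path):
        f = tmp_path / "empty.pdb"
        f.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(gio.EmptyStructureError):
            gio.parse_ca_coordinates(f)

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(gio.DataError):
            gio.parse_ca_coordinates(tmp_path / "nope.txt")


class TestBuildContactGraph:
    def test_toy_distances(self):
        pts = np.array([[0, 0, 0], [5, 0, 0], [20, 0, 0]], dtype=float)
        A, edges = gio.build_contact_graph(pts, threshold=10.0)
        assert edges == {(0, 1)}
        assert A[0, 1] == A[1, 0] == 1 and A.sum() == 2

    def test_default_threshold_is_10_angstrom(self):
        assert gio.DEFAULT_CONTACT_THRESHOLD == 10.0

    def test_four_close_points_complete_graph(self, rng):
        pts = rng.uniform(0, 3, size=(4, 3))
        _, edges = gio.build_contact_graph(pts, threshold=10.0)
        assert len(edges) == 6  # n(n-1)/2

    def test_nonfinite_coordinate_rejected(self):
        pts = np.array([[0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(gio.DataError):
            gio.build_contact_graph(pts)

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            pts = rng.uniform(0, 15, size=(n, 3))
            A, _ = gio.build_contact_graph(pts, threshold=8.0)
            for i in range(n):
                for j in range(n):
                    expect = int(i != j and np.linalg.norm(pts[i] - pts[j]) <= 8.0)
                    assert A[i, j] == expect
            assert np.array_equal(A, A.T)
            assert np.all(np.diag(A) == 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(4.0, 9.0), st.floats(0.5, 4.0))
    def test_raising_threshold_never_removes_edges(self, seed, t_low, dt):
        pts = np.random.default_rng(seed).uniform(0, 12, size=(8, 3))
        _, low = gio.build_contact_graph(pts, threshold=t_low)
        _, high = gio.build_contact_graph(pts, threshold=t_low + dt)
        assert low <= high

    def test_strict_vs_inclusive_boundary(self):
        pts = np.array([[0, 0, 0], [10, 0, 0]], dtype=float)
        _, inclusive = gio.build_contact_graph(pts, threshold=10.0, inclusive=True)
        _, strict = gio.build_contact_graph(pts, threshold=10.0, inclusive=False)
        assert inclusive == {(0, 1)} and strict == set()


class TestFeatures:
    def test_feature_matrix_read_back(self, tmp_path, rng):
        X = rng.normal(size=(3, 8))
        f = tmp_path / "feat.txt"
        np.savetxt(f, X)
        Y = gio.load_feature_matrix(f, expected_rows=3)
        np.testing.assert_allclose(X, Y, atol=1e-6)

    def test_row_count_mismatch_names_both_counts(self, tmp_path, rng):
        f = tmp_path / "feat.txt"
        np.savetxt(f, rng.normal(size=(4, 5)))
        with pytest.raises(gio.ShapeMismatchError, match="4.*3"):
            gio.load_feature_matrix(f, expected_rows=3)

    def test_one_hot_single_and_distinct(self):
        X = gio.one_hot_features("AC")
        assert X.shape == (2, 20)
        assert X.sum(axis=1).tolist() == [1.0, 1.0]
        assert not np.array_equal(X[0], X[1])

    def test_one_hot_unknown_letter_zero_row(self):
        X = gio.one_hot_features("X")
        assert X.shape == (1, 20) and X.sum() == 0

    def test_one_hot_empty_sequence_rejected(self):
        with pytest.raises(gio.DataError):
            gio.one_hot_features("")


class TestGoLabels:
    def _write(self, tmp_path, rows):
        f = tmp_path / "labels.tsv"
        f.write_text("".join(rows))
        return f

    def test_rare_term_filter(self, tmp_path):
        rows = [
            "P1\tGO:0000001;GO:0000009\n",
            "P2\tGO:0000001\n",
            "P3\tGO:0000002\n",
        ]
        f = self._write(tmp_path, rows)
        kept = gio.read_go_labels(f, "MF", min_term_count=2)
        assert kept["P1"].vocabulary == ("GO:0000001",)
        dropped = gio.read_go_labels(f, "MF", min_term_count=3)
        assert dropped["P1"].vocabulary == ()

    def test_vocabulary_sorted_and_multi_hot(self, tmp_path):
        f = self._write(tmp_path, ["P1\tGO:0000002;GO:0000001\n"])
        labs = gio.read_go_labels(f, "BP", min_term_count=1)
        assert labs["P1"].vocabulary == ("GO:0000001", "GO:0000002")
        assert labs["P1"].labels.tolist() == [1, 1]

    def test_malformed_row_reports_line_number(self, tmp_path):
        f = self._write(tmp_path, ["P1\tGO:0000001\n", "garbage-no-tab\n"])
        with pytest.raises(gio.DataError, match=":2"):
            gio.read_go_labels(f, "CC")

    def test_write_read_round_trip(self, tmp_path):
        f = self._write(tmp_path, ["P1\tGO:0000001;GO:0000003\n", "P2\tGO:0000003\n"])
        labs = gio.read_go_labels(f, "MF")
        out = tmp_path / "again.tsv"
        gio.write_go_labels(out, labs)
        again = gio.read_go_labels(out, "MF")
        for pid in labs:
            assert labs[pid].labels.tolist() == again[pid].labels.tolist()


class TestProteinGraphInvariants:
    def test_edge_count_matches_adjacency(self, tiny_graph):
        assert len(tiny_graph.edges) * 2 == tiny_graph.adjacency.sum()

    def test_asymmetric_adjacency_rejected(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = 1
        with pytest.raises(gio.DataError):
            gio.ProteinGraph("bad", A, np.zeros((3, 2)))

    def test_nonzero_diagonal_rejected(self):
        A = np.eye(3, dtype=int)
        with pytest.raises(gio.DataError):
            gio.ProteinGraph("bad", A, np.zeros((3, 2)))

    def test_feature_row_mismatch_rejected(self):
        with pytest.raises(gio.ShapeMismatchError):
            gio.ProteinGraph("bad", np.zeros((3, 3), dtype=int), np.zeros((4, 2)))


class TestEdgeListIO:
    def test_round_trip(self, tmp_path, tiny_graph):
        f = tmp_path / "edges.txt"
        gio.write_edge_list(f, tiny_graph.edges)
        A, edges = gio.read_edge_list(f, tiny_graph.n_residues)
        assert edges == tiny_graph.edges
        assert np.array_equal(A, tiny_graph.adjacency)

    def test_invalid_edge_rejected(self, tmp_path):
        f = tmp_path / "edges.txt"
        f.write_text("0 7\n")
        with pytest.raises(gio.DataError):
            gio.read_edge_list(f, 3)
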