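"""Edge-list / binary-matrix parsing, writing, and the degree report."""

import logging

import pytest

from bicliq import (
    BipartiteGraph,
    FormatError,
    GeneratorSpec,
    ValidationError,
    degrees,
    format_edge_list,
    random_bipartite,
    read_binary_matrix,
    read_edge_list,
    write_binary_matrix,
    write_edge_list,
)
from bicliq.io import degree_report_lines


def write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReadEdgeList:
    def test_worked_example(self, example_graph):
        assert example_graph.left_labels == ("u1", "u2", "u3", "u4", "u5")
        assert example_graph.right_labels == ("v1", "v2", "v4", "v3")
        assert example_graph.n_edges == 10
        assert example_graph.has_edge(0, 0) and example_graph.has_edge(4, 2)

    def test_minimal_single_edge(self, tmp_path):
        g = read_edge_list(write(tmp_path / "g.el", "1\t1\t1\na\tb\n"))
        assert g.left_labels == ("a",) and g.right_labels == ("b",)
        assert g.edges == ((0, 0),)

    def test_header_mismatch_is_validation_error(self, tmp_path):
        p = write(tmp_path / "g.el", "2\t2\t0\n")
        with pytest.raises(ValidationError, match="declares 2"):
            read_edge_list(p)

    def test_lenient_mode_trusts_content(self, tmp_path):
        p = write(tmp_path / "g.el", "9\t9\t9\na\tb\n")
        g = read_edge_list(p, strict=False)
        assert (g.n_left, g.n_right, g.n_edges) == (1, 1, 1)

    @pytest.mark.parametrize(
        "text, match",
        [
            ("", "missing header"),
            ("1\t1\n", "three tab-separated"),
            ("x\ty\tz\n", "must be integers"),
            ("1\t1\t1\na b c\n", "exactly two"),
            ("1\t1\t1\na\tb\tc\n", "exactly two"),
        ],
    )
    def test_malformed_files(self, tmp_path, text, match):
        p = write(tmp_path / "bad.el", text)
        with pytest.raises(FormatError, match=match):
            read_edge_list(p)

    def test_format_error_names_offending_line(self, tmp_path):
        p = write(tmp_path / "bad.el", "1\t1\t1\na\tb\nbroken line here\n")
        with pytest.raises(FormatError, match="line 3"):
            read_edge_list(p)

    def test_duplicate_edges_collapse_with_warning(self, tmp_path, caplog):
        p = write(tmp_path / "g.el", "1\t1\t1\na\tb\na\tb\n")
        with caplog.at_level(logging.WARNING, logger="bicliq.io"):
            g = read_edge_list(p)
        assert g.n_edges == 1
        assert any("duplicate edge" in r.message for r in caplog.records)

    def test_spaces_around_tokens_are_stripped(self, tmp_path):
        g = read_edge_list(write(tmp_path / "g.el", "1\t1\t1\n a \t b \n"))
        assert g.left_labels == ("a",) and g.right_labels == ("b",)


class TestBinaryMatrix:
    def test_matrix_equals_edge_list_on_example(self, tmp_path, example_graph):
        # same graph, matrix dialect: rows u1..u5, columns in the edge-list's
        # first-appearance order so the parsed structures are identical
        write_binary_matrix(example_graph, tmp_path / "g.mat")
        assert read_binary_matrix(tmp_path / "g.mat") == example_graph

    def test_all_zero_matrix_keeps_isolated_vertices(self, tmp_path):
        p = write(tmp_path / "z.mat", "v1\tv2\nu1\t0\t0\nu2\t0\t0\n")
        g = read_binary_matrix(p)
        assert (g.n_left, g.n_right, g.n_edges) == (2, 2, 0)
        left, right = degrees(g)
        assert set(left.values()) == {0} and set(right.values()) == {0}

    def test_all_ones_matrix_is_complete(self, tmp_path):
        p = write(tmp_path / "k.mat", "v1\tv2\tv3\nu1\t1\t1\t1\nu2\t1\t1\t1\n")
        g = read_binary_matrix(p)
        assert g.n_edges == 6
        assert g.edge_set == {(i, j) for i in range(2) for j in range(3)}

    @pytest.mark.parametrize(
        "text, match",
        [
            ("v1\nu1\t2\n", "0 or 1"),
            ("v1\tv2\nu1\t1\n", "expected 2"),
        ],
    )
    def test_malformed_matrix(self, tmp_path, text, match):
        with pytest.raises(FormatError, match=match):
            read_binary_matrix(write(tmp_path / "bad.mat", text))


class TestFormatEdgeList:
    def test_example_edges_get_correct_header(self, tmp_path, example_path):
        raw = tmp_path / "raw.el"
        body = example_path.read_text().split("\n", 1)[1]
        raw.write_text(body)
        out = tmp_path / "out.el"
        format_edge_list(raw, out)
        assert out.read_text().split("\n")[0] == "5\t4\t10"
        assert read_edge_list(out).n_edges == 10

    def test_single_edge(self, tmp_path):
        out = tmp_path / "out.el"
        format_edge_list(write(tmp_path / "raw", "a\tb\n"), out)
        assert out.read_text() == "1\t1\t1\na\tb\n"

    def test_duplicate_lines_collapse(self, tmp_path):
        out = tmp_path / "out.el"
        format_edge_list(write(tmp_path / "raw", "a\tb\na\tb\n"), out)
        assert out.read_text() == "1\t1\t1\na\tb\n"

    def test_empty_input_is_error(self, tmp_path):
        with pytest.raises(FormatError, match="no edges"):
            format_edge_list(write(tmp_path / "raw", "\n"), tmp_path / "out.el")


class TestDegrees:
    def test_worked_example_degrees(self, example_graph):
        left, right = degrees(example_graph)
        assert left == {"u1": 3, "u2": 3, "u3": 2, "u4": 1, "u5": 1}
        assert right == {"v1": 2, "v2": 2, "v3": 1, "v4": 5}

    def test_report_lines_left_first_in_input_order(self, example_graph):
        lines = degree_report_lines(example_graph)
        assert len(lines) == 9
        assert lines[0] == "u1\t3"
        assert lines[5:] == ["v1\t2", "v2\t2", "v4\t5", "v3\t1"]

    def test_degree_sum_conservation(self):
        for seed in range(20):
            g = random_bipartite(GeneratorSpec(8, 6, 0.3, seed))
            left, right = degrees(g)
            assert sum(left.values()) == sum(right.values()) == g.n_edges


class TestRoundTrips:
    @pytest.mark.parametrize("seed", range(10))
    def test_edge_list_round_trip(self, tmp_path, seed):
        g0 = random_bipartite(GeneratorSpec(7, 5, 0.5, seed))
        # rebuild from labelled edges: appearance-ordered and isolated-free,
        # which is the class of graphs the edge-list dialect can express
        pairs = [(g0.left_labels[l], g0.right_labels[r]) for l, r in g0.edges]
        g = BipartiteGraph.from_label_pairs(pairs)
        write_edge_list(g, tmp_path / "g.el")
        assert read_edge_list(tmp_path / "g.el") == g

    @pytest.mark.parametrize("seed", range(10))
    def test_matrix_round_trip_keeps_isolated(self, tmp_path, seed):
        g = random_bipartite(GeneratorSpec(6, 6, 0.2, seed))
        write_binary_matrix(g, tmp_path / "g.mat")
        assert read_binary_matrix(tmp_path / "g.mat") == g

    def test_cross_dialect_equality(self, tmp_path, example_graph):
        write_edge_list(example_graph, tmp_path / "g.el")
        write_binary_matrix(example_graph, tmp_path / "g.mat")
        assert read_edge_list(tmp_path / "g.el") == read_binary_matrix(tmp_path / "g.mat")

    def test_writer_output_is_bit_exact(self, tmp_path, example_graph, example_path):
        write_edge_list(example_graph, tmp_path / "g.el")
        assert (tmp_path / "g.el").read_bytes() == example_path.read_bytes()

    def test_writer_refuses_isolated_vertices(self, tmp_path):
        g = BipartiteGraph(("a", "b"), ("x",), [(0, 0)])
        with pytest.raises(ValidationError, match="isolated"):
            write_edge_list(g, tmp_path / "g.el")
        write_edge_list(g, tmp_path / "g.el", drop_isolated=True)
        assert (tmp_path / "g.el").read_text() == "1\t1\t1\na\tx\n"


class TestGraphModel:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            BipartiteGraph(("a", "a"), ("x",), [])

    def test_same_label_on_both_sides_is_two_vertices(self):
        g = BipartiteGraph(("a",), ("a",), [(0, 0)])
        assert g.n_left == g.n_right == 1 and g.n_edges == 1

    def test_out_of_range_edge_rejected(self):
        with pytest.raises(ValidationError, match="out of range"):
            BipartiteGraph(("a",), ("x",), [(0, 1)])

    def test_transpose_involution(self, example_graph):
        assert example_graph.transpose().transpose() == example_graph
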