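"""Set-file reading and the matrix/horizontal/vertical export dialects."""

import io
import logging

import pytest
from hypothesis import given, settings, strategies as st

import vennkit as vk
from vennkit import textio
from vennkit.errors import InputError


def _string(writer, part):
    buf = io.StringIO()
    writer(part, buf)
    return buf.getvalue()


class TestReadSetFile:
    def test_whitespace_tokenisation_and_dedupe(self, tmp_path, caplog):
        f = tmp_path / "genes.txt"
        f.write_text("g1 g2\tg3\ng1")
        with caplog.at_level(logging.WARNING, logger="vennkit"):
            gs = vk.read_set_file(f)
        assert gs.elements == frozenset({"g1", "g2", "g3"})
        assert gs.name == "genes"
        assert "duplicate" in caplog.text

    def test_empty_file_warns_not_errors(self, tmp_path, caplog):
        f = tmp_path / "empty.txt"
        f.write_text("")
        with caplog.at_level(logging.WARNING, logger="vennkit"):
            gs = vk.read_set_file(f)
        assert len(gs) == 0
        assert "no identifiers" in caplog.text

    def test_runs_of_whitespace_collapse(self, tmp_path):
        f = tmp_path / "s.txt"
        f.write_text("a\n\n b ")
        assert vk.read_set_file(f, name="S").elements == frozenset({"a", "b"})


class TestMatrix:
    def test_rows_and_cells(self, ab_partition):
        lines = _string(vk.write_matrix, ab_partition).splitlines()
        assert lines == [
            "element\tA\tB",
            "a\t1\t0",
            "b\t1\t1",
            "c\t0\t1",
        ]

    def test_single_set(self):
        part = vk.partition(vk.SetCollection((vk.GeneSet("A", {"x"}),)))
        assert _string(vk.write_matrix, part).splitlines() == [
            "element\tA",
            "x\t1",
        ]

    def test_round_trip_reproduces_partition(self, random_collection):
        for seed in (0, 1, 2):
            part = vk.partition(random_collection(5, seed))
            text = _string(vk.write_matrix, part)
            back = vk.partition(vk.read_matrix(io.StringIO(text)))
            assert back.regions == part.regions
            assert back.set_names == part.set_names


class TestHorizontal:
    def test_two_set_example(self, ab_partition):
        assert _string(vk.write_horizontal, ab_partition).splitlines() == [
            "A: a",
            "B: c",
            "A&B: b",
        ]

    def test_disjoint_emits_empty_intersection_line(self):
        part = vk.partition(
            vk.SetCollection((vk.GeneSet("A", {"a"}), vk.GeneSet("B", {"b"})))
        )
        assert _string(vk.write_horizontal, part).splitlines() == [
            "A: a",
            "B: b",
            "A&B:",
        ]

    @pytest.mark.parametrize("n", [1, 3, 6, 8])
    def test_exhaustive_line_count(self, n, random_collection):
        part = vk.partition(random_collection(n, seed=n))
        lines = _string(vk.write_horizontal, part).splitlines()
        assert len(lines) == 2**n - 1


class TestVertical:
    def test_six_sets_always_64_lines(self, random_collection):
        part = vk.partition(random_collection(6, seed=42))
        assert len(_string(vk.write_vertical, part).splitlines()) == 64

    def test_single_set_two_lines(self):
        part = vk.partition(vk.SetCollection((vk.GeneSet("A", {"x"}),)))
        assert _string(vk.write_vertical, part).splitlines() == [
            "combination\tcount\telements",
            "A\t1\tx",
        ]

    def test_two_set_rows(self, ab_partition):
        lines = _string(vk.write_vertical, ab_partition).splitlines()
        assert len(lines) == 4
        assert lines[3] == "A&B\t1\tb"

    def test_matches_horizontal_content(self, random_collection):
        """Horizontal and vertical carry identical (combination, elements)
        pairs, differing only in arrangement."""
        part = vk.partition(random_collection(6, seed=7))
        horizontal = {}
        for line in _string(vk.write_horizontal, part).splitlines():
            name, _, elems = line.partition(":")
            horizontal[name] = tuple(elems.split())
        vertical = {}
        for line in _string(vk.write_vertical, part).splitlines()[1:]:
            name, count, elems = line.split("\t")
            vertical[name] = tuple(elems.split())
            assert int(count) == len(vertical[name])
        assert horizontal == vertical

    def test_every_union_element_once_across_lines(self, random_collection):
        coll = random_collection(7, seed=3)
        part = vk.partition(coll)
        seen = []
        for line in _string(vk.write_horizontal, part).splitlines():
            seen.extend(line.partition(":")[2].split())
        assert sorted(seen) == sorted(coll.union())


class TestSparseMode:
    def test_nine_plus_sets_emit_only_nonempty(self):
        coll = vk.generate_collection(
            vk.FixtureSpec(12, n_elements=100, seed=1)
        )
        part = vk.partition(coll)
        v_lines = _string(vk.write_vertical, part).splitlines()
        assert v_lines[0] == textio.SPARSE_HEADER
        assert len(v_lines) == len(part.regions) + 2  # comment + header
        h_lines = _string(vk.write_horizontal, part).splitlines()
        assert h_lines[0] == textio.SPARSE_HEADER
        assert len(h_lines) == len(part.regions) + 1


class TestRegionList:
    def test_single_region_lines(self, ab_partition):
        buf = io.StringIO()
        vk.write_region_list(ab_partition, 3, buf)
        assert buf.getvalue() == "b\n"
        buf = io.StringIO()
        vk.write_region_list(ab_partition, 1, buf)
        assert buf.getvalue() == "a\n"

    def test_out_of_range_label(self, ab_partition):
        with pytest.raises(InputError):
            vk.write_region_list(ab_partition, 4, io.StringIO())

    def test_prescribed_region_size(self):
        coll = vk.generate_collection(vk.FixtureSpec(3, {5: 9}, seed=0))
        part = vk.partition(coll)
        buf = io.StringIO()
        vk.write_region_list(part, 5, buf)
        assert len(buf.getvalue().splitlines()) == 9


class TestParseRegionSpec:
    @pytest.mark.parametrize(
        "spec, expected", [("A&B", 3), ("B", 2), ("A", 1)]
    )
    def test_valid(self, spec, expected):
        assert vk.parse_region_spec(spec, ("A", "B")) == expected

    def test_unknown_name(self):
        with pytest.raises(InputError, match="unknown set name"):
            vk.parse_region_spec("C", ("A", "B"))

    def test_empty(self):
        with pytest.raises(InputError):
            vk.parse_region_spec("", ("A", "B"))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(n=st.integers(1, 7), seed=st.integers(0, 1000))
def test_matrix_round_trip_property(n, seed):
    coll = vk.generate_collection(
        vk.FixtureSpec(n_sets=n, n_elements=40, seed=seed)
    )
    part = vk.partition(coll)
    buf = io.StringIO()
    vk.write_matrix(part, buf)
    back = vk.partition(vk.read_matrix(io.StringIO(buf.getvalue())))
    assert back.regions == part.regions
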