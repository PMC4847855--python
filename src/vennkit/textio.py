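"""Reading whitespace-delimited gene lists and writing the export dialects.

Input: one plain-text file per set; any run of whitespace (space, tab,
newline) separates identifiers.  Output: three text dialects —

* **matrix** — binary incidence matrix, one row per element of the union,
  one column per set (the standard input for network construction);
* **horizontal** — one intersection per line, ``Name&Name: e1 e2``;
* **vertical** — header row plus one row per intersection with its name,
  exclusive count and elements.

For up to 8 sets the horizontal/vertical dialects enumerate every one of
the ``2**n - 1`` subset combinations (so a six-set vertical file always has
64 lines, header included).  From 9 to 31 sets exhaustive enumeration is
infeasible and the writers switch to a sparse mode that lists only
non-empty regions behind an explanatory comment line.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Sequence
from typing import TextIO

from .errors import InputError
from .setcore import (
    GeneSet,
    RegionPartition,
    SetCollection,
    combo_name,
    region_elements,
)

logger = logging.getLogger("vennkit")

#: Largest set count for which exports enumerate every combination.
EXHAUSTIVE_LIMIT = 8

SPARSE_HEADER = "# sparse mode: non-empty intersections only"


def read_set_file(path: str | os.PathLike[str], name: str | None = None) -> GeneSet:
    """Read one set from a whitespace-delimited text file.

    Tokens are split on any run of whitespace and silently de-duplicated
    (with a logged warning that includes the duplicate count).  The set
    name defaults to the file basename without its extension.  An empty
    file yields an empty set and a warning, not an error.
    """
    if name is None:
        name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    with open(path, "r", encoding="utf-8") as fh:
        tokens = fh.read().split()
    unique = frozenset(tokens)
    n_dupes = len(tokens) - len(unique)
    if n_dupes:
        logger.warning(
            "set %r: removed %d duplicate identifier occurrence(s)", name, n_dupes
        )
    if not unique:
        logger.warning("set %r: input file contains no identifiers", name)
    return GeneSet(name, unique)


def _as_text_sink(sink: str | os.PathLike[str] | TextIO):
    """Return (file object, needs_close)."""
    if hasattr(sink, "write"):
        return sink, False
    return open(sink, "w", encoding="utf-8", newline="\n"), True


def _writing(sink):
    fh, needs_close = _as_text_sink(sink)

    class _Ctx:
        def __enter__(self):
            return fh

        def __exit__(self, *exc):
            if needs_close:
                fh.close()
            return False

    return _Ctx()


def write_matrix(part: RegionPartition, sink: str | os.PathLike[str] | TextIO) -> None:
    """Write the binary incidence matrix (tab-delimited).

    First row: element-column header then the set names in input order;
    then one row per element of the union, sorted lexicographically, with
    1/0 membership cells.
    """
    membership: dict[str, int] = {}
    for label, members in part.regions.items():
        for element in members:
            membership[element] = label
    with _writing(sink) as fh:
        fh.write("element\t" + "\t".join(part.set_names) + "\n")
        for element in sorted(membership):
            label = membership[element]
            cells = ["1" if label >> i & 1 else "0" for i in range(part.n)]
            fh.write(element + "\t" + "\t".join(cells) + "\n")


def read_matrix(source: str | os.PathLike[str] | TextIO) -> SetCollection:
    """Re-import an incidence matrix as a :class:`SetCollection`.

    The 1-cells of each column become that set's elements; used for
    round-trip verification of the matrix dialect.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise InputError("empty matrix file")
    header = lines[0].split("\t")
    set_names = header[1:]
    members: list[set[str]] = [set() for _ in set_names]
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise InputError(f"matrix row has {len(cells)} cells, expected {len(header)}")
        element = cells[0]
        for i, cell in enumerate(cells[1:]):
            if cell == "1":
                members[i].add(element)
            elif cell != "0":
                raise InputError(f"matrix cell must be 0/1, got {cell!r}")
    return SetCollection(
        tuple(GeneSet(name, frozenset(m)) for name, m in zip(set_names, members))
    )


def _ordered_labels(part: RegionPartition) -> tuple[list[int], bool]:
    """Labels to emit (ascending) and whether sparse mode applies."""
    if part.n <= EXHAUSTIVE_LIMIT:
        return list(range(1, (1 << part.n))), False
    return sorted(part.regions), True


def write_horizontal(part: RegionPartition, sink) -> None:
    """One intersection per line: set names joined by ``&``, a colon, then
    the region's elements separated by single spaces."""
    labels, sparse = _ordered_labels(part)
    with _writing(sink) as fh:
        if sparse:
            fh.write(SPARSE_HEADER + "\n")
        for label in labels:
            members = part.regions.get(label, ())
            line = combo_name(label, part.set_names) + ":"
            if members:
                line += " " + " ".join(members)
            fh.write(line + "\n")


def write_vertical(part: RegionPartition, sink) -> None:
    """Header row plus one row per intersection (name, count, elements).

    In exhaustive mode the file has exactly ``2**n`` lines: the header and
    one row for each of the ``2**n - 1`` combinations in ascending label
    order (64 lines for six sets).
    """
    labels, sparse = _ordered_labels(part)
    with _writing(sink) as fh:
        if sparse:
            fh.write(SPARSE_HEADER + "\n")
        fh.write("combination\tcount\telements\n")
        for label in labels:
            members = part.regions.get(label, ())
            fh.write(
                "\t".join(
                    (
                        combo_name(label, part.set_names),
                        str(len(members)),
                        " ".join(members),
                    )
                )
                + "\n"
            )


def write_region_list(part: RegionPartition, label: int, sink) -> None:
    """Write one region's exclusive elements, one per line (the scripted
    analog of exporting a single shared dataset from the diagram)."""
    members = region_elements(part, label)  # validates the label
    with _writing(sink) as fh:
        for element in members:
            fh.write(element + "\n")


def parse_region_spec(spec: str, set_names: Sequence[str]) -> int:
    """Parse ``"A&B"`` into the region label with exactly those bits set.

    Name matching is exact (case-sensitive); unknown names and empty specs
    are input errors.
    """
    if not spec:
        raise InputError("empty region specification")
    index = {name: i for i, name in enumerate(set_names)}
    label = 0
    for token in spec.split("&"):
        if token not in index:
            raise InputError(
                f"unknown set name {token!r}; known sets: {', '.join(set_names)}"
            )
        label |= 1 << index[token]
    return label
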