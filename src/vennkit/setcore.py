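"""Bit-label classification of set elements into exclusive intersection regions.

Every element ``x`` drawn from the union of ``n`` named sets receives an
integer label ``a_x = sum_i 2**(i-1)`` over the sets that contain it (the
first set in input order owns the least-significant bit).  Elements with
equal labels belong to the same exclusive region of the Venn diagram, so a
single pass over a hash table of elements yields the full partition into at
most ``2**n - 1`` non-empty regions.  ``n`` is capped at 31 so labels fit a
signed 32-bit integer, which also bounds export sizes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from .errors import CapabilityError, InputError

#: Hard upper bound on the number of sets handled in data-processing mode.
MAX_SETS = 31

#: Upper bound on the number of sets that can be drawn as a diagram.
MAX_GRAPH_SETS = 8

#: Instrumentation: number of times :func:`partition` has run (tests use this
#: to confirm a single classification pass serves all requested outputs).
PARTITION_CALLS = 0


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free collection of identifier strings.

    Identifiers are compared byte-exactly and case-sensitively; no
    normalisation is applied beyond the whitespace tokenisation done by the
    readers in :mod:`vennkit.textio`.
    """

    name: str
    elements: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("set name must be non-empty")
        if not isinstance(self.elements, frozenset):
            object.__setattr__(self, "elements", frozenset(self.elements))

    @classmethod
    def from_iterable(cls, name: str, items: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(items))

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, item: str) -> bool:
        return item in self.elements


@dataclass(frozen=True)
class SetCollection:
    """An ordered list of :class:`GeneSet`; order fixes the bit positions.

    The first set corresponds to bit 1 (value ``2**0``), the second to bit 2
    (value ``2**1``) and so on.  Between 1 and 31 sets are allowed.
    """

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        sets = tuple(self.sets)
        object.__setattr__(self, "sets", sets)
        if not 1 <= len(sets) <= MAX_SETS:
            raise CapabilityError(
                f"between 1 and {MAX_SETS} sets are supported, got {len(sets)}"
            )
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate set names: {', '.join(dupes)}")

    @property
    def n(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.elements
        return frozenset(out)


@dataclass(frozen=True)
class RegionPartition:
    """The exclusive-region partition of a collection's union.

    ``regions`` maps each *realised* integer label to the sorted tuple of
    identifiers whose membership pattern is exactly that label; labels whose
    region is empty are simply absent.  Region lists are pairwise disjoint
    and jointly cover the union of the input sets.
    """

    n: int
    set_names: tuple[str, ...]
    regions: Mapping[int, tuple[str, ...]]

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def element_label(membership: Sequence[bool]) -> int:
    """Label an element from its per-set membership flags.

    Returns ``sum(2**(i-1) for i where membership[i-1])``; 0 means the
    element belongs to no set (which cannot occur for elements read from
    set files).
    """
    n = len(membership)
    if not 1 <= n <= MAX_SETS:
        raise CapabilityError(
            f"membership vector must cover 1..{MAX_SETS} sets, got {n}"
        )
    label = 0
    for i, inside in enumerate(membership):
        if inside:
            label |= 1 << i
    return label


def possible_region_count(n: int) -> int:
    """Number of distinct non-trivial regions an ``n``-set diagram resolves."""
    if not 1 <= n <= MAX_SETS:
        raise CapabilityError(f"n must be in [1, {MAX_SETS}], got {n}")
    return (1 << n) - 1


def combo_name(label: int, set_names: Sequence[str], sep: str = "&") -> str:
    """Human-readable name of a region: member set names joined by ``sep``."""
    if not 1 <= label < (1 << len(set_names)):
        raise InputError(
            f"label {label} out of range [1, {(1 << len(set_names)) - 1}]"
        )
    return sep.join(name for i, name in enumerate(set_names) if label >> i & 1)


def partition(collection: SetCollection) -> RegionPartition:
    """Classify every element of the union into its exclusive region.

    Single pass: one hash-table update per (set, element) pair followed by
    one scan of the table, so the running time is linear in the total
    element count and independent of ``2**n``.
    """
    global PARTITION_CALLS
    PARTITION_CALLS += 1

    labels: dict[str, int] = {}
    for i, gene_set in enumerate(collection.sets):
        bit = 1 << i
        for element in gene_set.elements:
            labels[element] = labels.get(element, 0) | bit

    grouped: dict[int, list[str]] = {}
    for element, label in labels.items():
        grouped.setdefault(label, []).append(element)

    regions = {
        label: tuple(sorted(members))
        for label, members in sorted(grouped.items())
    }
    return RegionPartition(
        n=collection.n, set_names=collection.names, regions=regions
    )


def _check_label(part: RegionPartition, label: int) -> None:
    top = (1 << part.n) - 1
    if not 1 <= label <= top:
        raise InputError(f"label {label} out of range [1, {top}]")


def region_elements(part: RegionPartition, label: int) -> tuple[str, ...]:
    """Exclusive elements of one region (empty tuple if none); never
    includes elements of strict superset combinations."""
    _check_label(part, label)
    return part.regions.get(label, ())


def region_counts(
    part: RegionPartition, include_empty: bool = False
) -> dict[int, int]:
    """Exclusive cardinality of each region.

    With ``include_empty`` all ``2**n - 1`` labels appear (zeros allowed);
    otherwise only realised labels.  The counts always sum to the union size.
    """
    if include_empty:
        return {
            label: len(part.regions.get(label, ()))
            for label in range(1, (1 << part.n))
        }
    return {label: len(v) for label, v in part.regions.items()}
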