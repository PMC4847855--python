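"""Synthetic set collections with prescribed overlap structure, plus a
brute-force set-algebra oracle.

The generator fabricates collections whose exclusive-region cardinalities
are known by construction, standing in for real gene lists (RNA-seq derived
or GFF-derived) in tests and examples.  The oracle recomputes the partition
purely with intersection/complement algebra — no bitmasks — and is the
independent cross-check for the hash-table classifier in
:mod:`vennkit.setcore`.
"""

from __future__ import annotations

import random
from collections.abc import Mapping
from dataclasses import dataclass, field

from .errors import CapabilityError, InputError
from .setcore import GeneSet, MAX_SETS, RegionPartition, SetCollection

#: The oracle enumerates all 2**n subsets; keep it test-scale.
ORACLE_MAX_SETS = 12

#: Default membership probability in random-fill mode.
DEFAULT_DENSITY = 0.3


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic collection.

    Either ``region_counts`` prescribes the exclusive size of each region
    exactly, or (when it is ``None``) ``n_elements`` identifiers join each
    set independently with probability ``density`` for naturalistic
    overlap.  Everything is deterministic given ``seed``.
    """

    n_sets: int
    region_counts: Mapping[int, int] | None = None
    n_elements: int = 200
    density: float = DEFAULT_DENSITY
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_sets <= MAX_SETS:
            raise InputError(f"n_sets must be in [1, {MAX_SETS}]")
        if self.region_counts is not None:
            top = (1 << self.n_sets) - 1
            for label, count in self.region_counts.items():
                if not 1 <= label <= top:
                    raise InputError(f"label {label} out of range [1, {top}]")
                if count < 0:
                    raise InputError("region counts must be non-negative")
        if not 0.0 < self.density <= 1.0:
            raise InputError("density must be in (0, 1]")


def all_combinations(n_sets: int, count_per_region: int = 1) -> dict[int, int]:
    """Region-count table populating every one of the ``2**n - 1`` regions."""
    return {label: count_per_region for label in range(1, 1 << n_sets)}


def generate_collection(
    spec: FixtureSpec, set_names: tuple[str, ...] | None = None
) -> SetCollection:
    """Fabricate a collection realising the spec exactly.

    With prescribed counts, region ``L`` of size ``k`` receives ``k``
    fresh identifiers ``g<L>_<i>_<suffix>`` (suffix derived from the seed)
    inserted into exactly the sets of ``L``, so the resulting partition's
    counts equal ``region_counts`` by construction.
    """
    if set_names is None:
        set_names = tuple(f"S{i + 1}" for i in range(spec.n_sets))
    if len(set_names) != spec.n_sets:
        raise InputError("set_names length must equal n_sets")

    rng = random.Random(spec.seed)
    suffix = f"{rng.randrange(16 ** 6):06x}"
    members: list[set[str]] = [set() for _ in range(spec.n_sets)]

    if spec.region_counts is not None:
        for label in sorted(spec.region_counts):
            for i in range(spec.region_counts[label]):
                ident = f"g{label}_{i}_{suffix}"
                for bit in range(spec.n_sets):
                    if label >> bit & 1:
                        members[bit].add(ident)
    else:
        for i in range(spec.n_elements):
            label = 0
            while label == 0:
                label = sum(
                    1 << bit
                    for bit in range(spec.n_sets)
                    if rng.random() < spec.density
                )
            ident = f"g{label}_{i}_{suffix}"
            for bit in range(spec.n_sets):
                if label >> bit & 1:
                    members[bit].add(ident)

    return SetCollection(
        tuple(
            GeneSet(name, frozenset(elems))
            for name, elems in zip(set_names, members)
        )
    )


def oracle_partition(collection: SetCollection) -> RegionPartition:
    """Exclusive-region partition by direct intersection/complement algebra.

    For every non-empty subset S of the sets, the region is
    ``intersection(A_i for i in S) minus union(A_j for j not in S)``.
    Exponential in the set count, hence capped for test-scale use.
    """
    n = collection.n
    if n > ORACLE_MAX_SETS:
        raise CapabilityError(
            f"oracle enumerates 2**n subsets; limited to n <= {ORACLE_MAX_SETS}"
        )
    universes = [s.elements for s in collection.sets]
    regions: dict[int, tuple[str, ...]] = {}
    for label in range(1, 1 << n):
        inside = [universes[i] for i in range(n) if label >> i & 1]
        outside = [universes[i] for i in range(n) if not label >> i & 1]
        region = set(inside[0])
        for u in inside[1:]:
            region &= u
        for u in outside:
            region -= u
        if region:
            regions[label] = tuple(sorted(region))
    return RegionPartition(n=n, set_names=collection.names, regions=regions)
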