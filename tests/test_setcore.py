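"""Bit-label classification and the exclusive-region partition."""

import pytest
from hypothesis import given, settings, strategies as st

import vennkit as vk
from vennkit import setcore
from vennkit.errors import CapabilityError, InputError


@pytest.mark.parametrize(
    "membership, expected",
    [
        ((True, False, True), 5),
        ((False, False, False, False), 0),
        ((True,) * 31, 2**31 - 1),
        ((True,), 1),
        ((False, True), 2),
    ],
)
def test_element_label(membership, expected):
    assert vk.element_label(membership) == expected


def test_element_label_rejects_out_of_range_set_counts():
    with pytest.raises(CapabilityError):
        vk.element_label(())
    with pytest.raises(CapabilityError):
        vk.element_label((True,) * 32)


@pytest.mark.parametrize(
    "n, expected", [(1, 1), (7, 127), (31, 2**31 - 1)]
)
def test_possible_region_count(n, expected):
    assert vk.possible_region_count(n) == expected


def test_possible_region_count_bounds():
    with pytest.raises(CapabilityError):
        vk.possible_region_count(0)
    with pytest.raises(CapabilityError):
        vk.possible_region_count(32)


def test_partition_two_set_example(ab_partition):
    assert dict(ab_partition.regions) == {1: ("a",), 2: ("c",), 3: ("b",)}


def test_partition_single_set():
    coll = vk.SetCollection((vk.GeneSet("A", {"x", "y"}),))
    part = vk.partition(coll)
    assert dict(part.regions) == {1: ("x", "y")}


def test_partition_seven_sets_all_combinations_realised():
    coll = vk.generate_collection(
        vk.FixtureSpec(7, vk.all_combinations(7), seed=11)
    )
    part = vk.partition(coll)
    assert len(part.regions) == 127
    assert all(len(v) == 1 for v in part.regions.values())


def test_duplicate_set_names_rejected():
    with pytest.raises(InputError, match="duplicate"):
        vk.SetCollection((vk.GeneSet("A", {"a"}), vk.GeneSet("A", {"b"})))


def test_collection_capability_bounds():
    with pytest.raises(CapabilityError):
        vk.SetCollection(())
    too_many = tuple(vk.GeneSet(f"S{i}", {f"x{i}"}) for i in range(32))
    with pytest.raises(CapabilityError):
        vk.SetCollection(too_many)


def test_region_elements_exclusive(ab_partition):
    assert vk.region_elements(ab_partition, 3) == ("b",)
    assert vk.region_elements(ab_partition, 1) == ("a",)
    with pytest.raises(InputError):
        vk.region_elements(ab_partition, 4)  # 2**n is out of range
    with pytest.raises(InputError):
        vk.region_elements(ab_partition, 0)


def test_region_counts_modes(ab_partition):
    assert vk.region_counts(ab_partition) == {1: 1, 2: 1, 3: 1}
    disjoint = vk.partition(
        vk.SetCollection((vk.GeneSet("A", {"a"}), vk.GeneSet("B", {"b"})))
    )
    assert vk.region_counts(disjoint, include_empty=True) == {1: 1, 2: 1, 3: 0}
    assert vk.region_counts(disjoint) == {1: 1, 2: 1}


def test_prescribed_counts_recovered_exactly():
    wanted = {1: 4, 3: 2, 5: 7, 7: 1}
    coll = vk.generate_collection(vk.FixtureSpec(3, wanted, seed=5))
    assert vk.region_counts(vk.partition(coll)) == wanted


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    n=st.integers(1, 8),
    seed=st.integers(0, 10_000),
)
def test_conservation_and_marginals(n, seed):
    """Region counts sum to the union size and per-set marginals match."""
    coll = vk.generate_collection(
        vk.FixtureSpec(n_sets=n, n_elements=50, seed=seed)
    )
    part = vk.partition(coll)
    counts = vk.region_counts(part)
    assert sum(counts.values()) == len(coll.union())
    for i, gene_set in enumerate(coll.sets):
        marginal = sum(c for label, c in counts.items() if label >> i & 1)
        assert marginal == len(gene_set)


def test_relabelling_memberships_reproduces_labels(ab_partition):
    """Recomputing each element's label from raw membership yields the
    region that holds it."""
    coll = vk.generate_collection(vk.FixtureSpec(5, seed=2, n_elements=80))
    part = vk.partition(coll)
    for label, members in part.regions.items():
        for element in members:
            recomputed = vk.element_label(
                [element in s for s in coll.sets]
            )
            assert recomputed == label


def test_partition_idempotence_on_single_region():
    """Re-partitioning one region's list as a lone set reproduces it."""
    coll = vk.generate_collection(vk.FixtureSpec(4, seed=9, n_elements=40))
    part = vk.partition(coll)
    for label, members in part.regions.items():
        sub = vk.partition(
            vk.SetCollection((vk.GeneSet("R", frozenset(members)),))
        )
        assert sub.regions == {1: tuple(sorted(members))}


def test_combo_name_bit_order():
    assert vk.combo_name(3, ("A", "B")) == "A&B"
    assert vk.combo_name(2, ("A", "B")) == "B"
    with pytest.raises(InputError):
        vk.combo_name(4, ("A", "B"))


def test_partition_call_counter_increments(ab_collection):
    before = setcore.PARTITION_CALLS
    vk.partition(ab_collection)
    assert setcore.PARTITION_CALLS == before + 1
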