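import pytest

import vennkit as vk


@pytest.fixture
def ab_collection() -> vk.SetCollection:
    """The canonical two-set example: A={a,b}, B={b,c}."""
    return vk.SetCollection(
        (vk.GeneSet("A", {"a", "b"}), vk.GeneSet("B", {"b", "c"}))
    )


@pytest.fixture
def ab_partition(ab_collection) -> vk.RegionPartition:
    return vk.partition(ab_collection)


@pytest.fixture
def random_collection():
    """Factory for seeded random-overlap collections."""

    def make(n_sets: int, seed: int, n_elements: int = 60) -> vk.SetCollection:
        return vk.generate_collection(
            vk.FixtureSpec(n_sets=n_sets, n_elements=n_elements, seed=seed)
        )

    return make
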