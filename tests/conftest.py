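import pytest

from cathkit import fixtures


@pytest.fixture(scope="session")
def helix():
    return fixtures.make_toy_structure("helix", 18, 0.0, seed=1)


@pytest.fixture(scope="session")
def fold_zoo():
    """One noise-free structure per fold kind, same length."""
    return {
        kind: fixtures.make_toy_structure(kind, 18, 0.0, seed=1)
        for kind in fixtures.FOLD_KINDS
    }


@pytest.fixture(scope="session")
def small_hierarchy():
    """Default-shape hierarchy (2 x 2 x 2 x 2 x 3 = 48 domains), seed 7."""
    return fixtures.make_hierarchy(fixtures.FixtureSpec(seed=7))
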