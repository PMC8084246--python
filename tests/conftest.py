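import numpy as np
import pytest

from cdsml import SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_bundle():
    """One bundle at the default study conditions, shared read-only."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast bundle for smoke/pipeline tests."""
    return generate(SyntheticSpec(m=12, n=8, k_true=2, missing_frac=0.15, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def brute_force_matching(left, right, ppi):
    """Independent oracle: exhaustive recursion over all matchings.

    Each left node is either skipped or matched to any still-free right
    node it shares a PPI edge with; the best total weight is returned.
    """
    right = list(right)

    def best(i, used):
        if i == len(left):
            return 0.0
        value = best(i + 1, used)  # leave left[i] unmatched
        for j, q in enumerate(right):
            if j in used or left[i] == q:
                continue
            w = ppi.weight(left[i], q)
            if w is not None:
                value = max(value, w + best(i + 1, used | {j}))
        return value

    return best(0, frozenset())
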