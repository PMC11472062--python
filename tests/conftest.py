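import functools

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dorqseq import (
    ProbeSet,
    TRNAReference,
    design_probe_set,
    generate_reference_set,
)


def naive_levenshtein(a: str, b: str) -> int:
    """Independent recursive edit-distance oracle (memoized plain recursion)."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + cost,
        )

    return rec(len(a), len(b))


@pytest.fixture(scope="session")
def small_refs() -> list[TRNAReference]:
    """Five well-separated synthetic references."""
    return generate_reference_set(5, seed=101)


@pytest.fixture(scope="session")
def small_probe_set(small_refs) -> ProbeSet:
    return design_probe_set(small_refs)


@pytest.fixture(scope="session")
def ten_family_probe_set() -> ProbeSet:
    return design_probe_set(generate_reference_set(10, seed=202))
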