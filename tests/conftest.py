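"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from eba.classify import classify_set
from eba.synthetic import SyntheticConfig, generate

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

# small, fast configuration used by most behavioural tests
SMALL_RANGES = {"alpha": (30, 40), "beta": (35, 45), "gamma": (40, 50)}


def small_config(**overrides) -> SyntheticConfig:
    kwargs = dict(
        n_classes=3,
        dim=16,
        class_length_ranges=SMALL_RANGES,
        n_baits_per_class=4,
        n_queries_per_class=6,
        seed=7,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(small_config())


@pytest.fixture(scope="session")
def default_run():
    """Default-calibration benchmark: generate + classify once per session."""
    data = generate(SyntheticConfig(seed=0))
    records, failures = classify_set(data.queries, data.refset)
    assert not failures
    return data, records


def brute_force_align_score(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Exhaustive maximum over all global alignments with affine gaps.

    A gap of length k costs gap_open + (k - 1) * gap_extend; a gap in one
    sequence directly followed by a gap in the other opens a new gap.
    Feasible for matrices up to about 5x5.
    """
    l1, l2 = S.shape
    best = -np.inf

    def rec(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        if i == l1 and j == l2:
            if score > best:
                best = score
            return
        if i < l1 and j < l2:
            rec(i + 1, j + 1, "D", score + S[i, j])
        if i < l1:
            rec(i + 1, j, "U", score + (gap_extend if prev == "U" else gap_open))
        if j < l2:
            rec(i, j + 1, "L", score + (gap_extend if prev == "L" else gap_open))

    rec(0, 0, "", 0.0)
    return best
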