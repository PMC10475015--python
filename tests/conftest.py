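"""Shared fixtures: small synthetic genomes and reference oracles."""

from __future__ import annotations

import numpy as np
import pytest

from horscope.synthetic import FamilySpec, make_family_set, t2t_like_scenario, generate_genome


def python_levenshtein(a: str, b: str) -> int:
    """Quadratic DP reference, independent of the package kernels."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1] or a[i - 1] == "N"),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[m]


def brute_interval_histogram(seq: str, k: int, max_length: int) -> dict[int, int]:
    """Enumerate every K-window and its next occurrence; independent oracle."""
    last: dict[str, int] = {}
    hist: dict[int, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        if w in last:
            d = i - last[w]
            if d <= max_length:
                hist[d] = hist.get(d, 0) + 1
        last[w] = i
    return hist


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def family_bases():
    """Three 1600 bp monomer families at ~25% mutual divergence."""
    return make_family_set(FamilySpec(seed=7))


@pytest.fixture(scope="session")
def small_scenario():
    """A compact six-array genome with known truth (fast to scan)."""
    spec = t2t_like_scenario(background_length=300_000, seed=11)
    genome, truth, bases = generate_genome(spec)
    return genome, truth, bases
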