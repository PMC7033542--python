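"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use brute force (per-bp marking, pairwise
transitive closure, direct formula transcription) so they stay independent
of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cnvpop.io import CnvCall


def make_call(sample="S1", chrom="chr1", start=100, end=200, cn=1, num_snps=None):
    return CnvCall(sample, chrom, start, end, cn, num_snps)


def bp_union(intervals):
    """Per-bp marking oracle: the set of covered base positions."""
    covered = set()
    for start, end in intervals:
        covered.update(range(start, end + 1))
    return covered


def brute_force_components(calls):
    """Transitive closure over pairwise >=1 bp overlaps, per chromosome.

    Returns a set of frozensets of call keys; independent of the sweep
    merge in cnvpop.cnvr.
    """
    calls = list(calls)
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        a, b = calls[i], calls[j]
        if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
            parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i, c in enumerate(calls):
        groups.setdefault(find(i), set()).add(c.key)
    return {frozenset(g) for g in groups.values()}


def fst_reference(x_freqs, y_freqs, nx, ny):
    """Independent transcription of the four Fst equations.

    x_freqs / y_freqs are full-length vectors over the class alphabet.
    Returns (t, ht, hs, fst) with fst None when Ht == 0.
    """
    x = np.asarray(x_freqs, dtype=float)
    y = np.asarray(y_freqs, dtype=float)
    t = (x * nx + y * ny) / (nx + ny)
    ht = 1.0 - float(np.sum(t**2))
    hs = ((1.0 - float(np.sum(x**2))) * nx + (1.0 - float(np.sum(y**2))) * ny) / (nx + ny)
    if ht <= 1e-12:
        return t, ht, hs, None
    return t, ht, hs, (ht - hs) / ht


def random_frequency_vector(rng, n_classes=6, max_support=6):
    """A random point on the simplex with random support."""
    support = rng.choice(n_classes, size=rng.integers(1, max_support + 1),
                         replace=False)
    vec = np.zeros(n_classes)
    weights = rng.dirichlet(np.ones(len(support)))
    vec[support] = weights
    return vec


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
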