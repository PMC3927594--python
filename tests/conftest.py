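"""Shared fixtures and brute-force oracles.

Oracles enumerate explicitly (structures, alignments, parses) and are
kept independent of the dynamic programs they check.
"""

from __future__ import annotations

import random

import pytest

from rfamforge.rnastruct import HP_MIN, can_pair, structure_energy


def enum_structures(seq: str):
    """All pseudoknot-free structures of seq (hairpins >= HP_MIN), as
    lists of 0-based pairs."""

    def rec(avail: tuple):
        if not avail:
            yield []
            return
        i = avail[0]
        rest = avail[1:]
        yield from rec(rest)
        for j in rest:
            if j - i - 1 >= HP_MIN and can_pair(seq[i], seq[j]):
                inside = tuple(k for k in rest if i < k < j)
                outside = tuple(k for k in rest if k > j)
                for s1 in rec(inside):
                    for s2 in rec(outside):
                        yield [(i, j)] + s1 + s2

    yield from rec(tuple(range(len(seq))))


def brute_force_mfe(seq: str) -> float:
    """Minimum energy over explicitly enumerated structures."""
    best = 0.0
    for pairs in enum_structures(seq):
        e = structure_energy(seq, pairs)
        if e < best:
            best = e
    return best


def random_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic study conditions (3 families x 6 genomes)."""
    from rfamforge.synthetic import make_default_dataset

    return make_default_dataset(seed=18)
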