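"""Shared oracles and fixtures.

The oracles here are deliberately naive and independent of the library's
algorithms: exhaustive index-list search for tokenized-subsequence
matching, brute-force string enumeration for containment counting, and a
textbook dynamic-programming edit distance.
"""

from itertools import product

import numpy as np
import pytest

from subseqsketch import Sequence, TokenizedSequence


def brute_max_prefix(s: str, x: TokenizedSequence) -> int:
    """Maximum m such that the first m tokens of x match at strictly
    increasing start positions of s, by exhaustive search over index lists."""
    t = x.t
    positions = [
        [i for i in range(len(s) - t + 1) if s[i : i + t] == tok]
        for tok in x.tokens
    ]

    def extend(depth: int, min_pos: int) -> int:
        if depth == len(positions):
            return depth
        best = depth
        for p in positions[depth]:
            if p >= min_pos:
                best = max(best, extend(depth + 1, p + 1))
                if best == len(positions):
                    break
        return best

    return extend(0, 0)


def classic_subsequence(x: str, s: str) -> bool:
    """Two-pointer check that x is a (t=1) subsequence of s."""
    it = iter(s)
    return all(c in it for c in x)


def brute_containment_count(n: int, k: int, sigma: int, kmer: str | None = None) -> int:
    """Count length-n strings over {0..sigma-1} containing a fixed length-k
    subsequence, by enumerating all sigma^n strings."""
    alphabet = [chr(ord("a") + i) for i in range(sigma)]
    if kmer is None:
        kmer = alphabet[0] * k
    assert len(kmer) == k
    return sum(
        1
        for chars in product(alphabet, repeat=n)
        if classic_subsequence(kmer, "".join(chars))
    )


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook O(|a||b|) Levenshtein dynamic program."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[len(b)]


def random_string(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_sequences(rng):
    return [Sequence(f"s{i}", random_string(rng, 60)) for i in range(6)]
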