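"""Testing lists and sketch construction.

A *testing list* L is the shared randomness of the scheme: an ordered list
of length-``k*t`` strings, each viewed as ``k`` tokens of size ``t``.  The
sketch of a sequence ``s`` is the integer vector whose i-th entry is the
number of prefix tokens of the i-th testing subsequence that form a
tokenized subsequence of ``s`` — an integer in ``[0, k]``.  Two sketches
are comparable only if they were produced from the identical list, which is
enforced through a content digest.

Testing subsequences are either generated uniformly at random (the
data-oblivious default) or sampled from the input sequences themselves,
which is effective for small collections of closely related genomes.
"""

from __future__ import annotations

import hashlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DNA,
    Alphabet,
    InvalidInputError,
    Sequence,
    TokenizedSequence,
    build_next_occurrence_index,
    max_prefix_tokens,
    tokenize,
)

DEFAULT_K = 15  # entries fit in 4 bits


@dataclass(frozen=True)
class TestingList:
    """Ordered list of testing subsequences sharing one (t, k, alphabet)."""

    entries: tuple[TokenizedSequence, ...]
    t: int
    k: int
    alphabet: Alphabet = DNA
    seed: int | None = None
    provenance: str = "random"  # "random" | "sampled-from-input"

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise InvalidInputError("testing list must contain at least one entry")
        for e in self.entries:
            if e.t != self.t or e.k != self.k:
                raise InvalidInputError(
                    f"entry with t={e.t}, k={e.k} in list with t={self.t}, k={self.k}"
                )

    @property
    def size(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def digest(self) -> str:
        """Content hash identifying this list for sketch compatibility."""
        h = hashlib.sha256()
        h.update(f"t={self.t};k={self.k};sigma={''.join(self.alphabet.symbols)};".encode())
        for e in self.entries:
            h.update(str(e).encode())
            h.update(b"\n")
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class Sketch:
    """Integer sketch vector of one sequence; values[i] in [0, k]."""

    seq_id: str
    values: np.ndarray
    testing_digest: str
    k: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise InvalidInputError("sketch values must be a 1-D vector")
        if v.size and (v.min() < 0 or v.max() > self.k):
            raise InvalidInputError(f"sketch values must lie in [0, {self.k}]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SketchSet:
    """Ordered, uniquely-named collection of sketches from one testing list."""

    testing_digest: str
    t: int
    k: int
    size: int
    sketches: list[Sketch] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [sk.seq_id for sk in self.sketches]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate sequence ids in sketch set")
        for sk in self.sketches:
            if len(sk) != self.size or sk.testing_digest != self.testing_digest:
                raise InvalidInputError("sketch incompatible with this set")

    @property
    def ids(self) -> list[str]:
        return [sk.seq_id for sk in self.sketches]

    def matrix(self) -> np.ndarray:
        """Stack all sketch vectors into an (n_sequences, |L|) array."""
        return np.vstack([sk.values for sk in self.sketches])

    def __len__(self) -> int:
        return len(self.sketches)


def _check_params(t: int, k: int, count: int) -> None:
    if t < 1 or k < 1 or count < 1:
        raise InvalidInputError(
            f"testing-list parameters must be positive, got t={t}, k={k}, count={count}"
        )


def generate_testing_list(
    t: int,
    k: int,
    count: int,
    alphabet: Alphabet = DNA,
    seed: int = 0,
) -> TestingList:
    """Generate ``count`` uniform-random testing subsequences of length k*t.

    Fully reproducible from ``seed``.
    """
    _check_params(t, k, count)
    rng = np.random.default_rng(seed)
    symbols = np.array(list(alphabet.symbols))
    chars = rng.integers(0, alphabet.size, size=(count, k * t))
    entries = tuple(tokenize("".join(symbols[row]), t) for row in chars)
    return TestingList(entries, t, k, alphabet, seed, "random")


def sample_testing_list_from_input(
    seqs: list[Sequence],
    t: int,
    k: int,
    count: int,
    seed: int = 0,
    alphabet: Alphabet = DNA,
    gapped: bool = False,
) -> TestingList:
    """Sample testing subsequences from the input sequences.

    By default each entry is a contiguous window of length ``k*t`` copied
    from a uniformly chosen input sequence (among those long enough) at a
    uniformly chosen start.  With ``gapped=True``, ``k`` non-overlapping
    token start positions are drawn uniformly instead (via the bijection
    between such position lists and k-subsets of ``[0, n-kt+k-1]``), and the
    entry concatenates the k tokens read at those positions.
    """
    _check_params(t, k, count)
    span = k * t
    eligible = [s for s in seqs if len(s) >= span]
    if not eligible:
        raise InvalidInputError(
            f"no input sequence is long enough to sample a length-{span} "
            f"testing subsequence (k*t = {k}*{t})"
        )
    rng = np.random.default_rng(seed)
    entries = []
    for _ in range(count):
        s = eligible[rng.integers(0, len(eligible))].residues
        n = len(s)
        if gapped and n > span:
            picks = np.sort(rng.choice(n - span + k, size=k, replace=False))
            starts = [int(c) + j * (t - 1) for j, c in enumerate(picks)]
            window = "".join(s[p : p + t] for p in starts)
        else:
            start = int(rng.integers(0, n - span + 1))
            window = s[start : start + span]
        entries.append(tokenize(window, t))
    return TestingList(tuple(entries), t, k, alphabet, seed, "sampled-from-input")


def sketch_sequence(
    s: Sequence | str,
    L: TestingList,
    backend: str = "scan",
) -> Sketch:
    """Compute the sketch of one sequence against testing list ``L``.

    ``backend="scan"`` (default) uses greedy leftmost matching with string
    search per token, O(|L| |s|) worst case; ``backend="index"`` builds a
    next-occurrence index on ``s`` first.  Both produce identical values.
    """
    seq_id = s.id if isinstance(s, Sequence) else "seq"
    text = s.residues if isinstance(s, Sequence) else s.upper()
    if backend == "scan":
        values = [max_prefix_tokens(text, e) for e in L.entries]
    elif backend == "index":
        idx = build_next_occurrence_index(text, L.t)
        values = [idx.max_prefix_tokens(e) for e in L.entries]
    else:
        raise InvalidInputError(f"unknown backend {backend!r}")
    return Sketch(seq_id, np.array(values, dtype=np.int64), L.digest(), L.k)


def sketch_collection(
    seqs: list[Sequence],
    L: TestingList,
    threads: int = 1,
    backend: str = "scan",
) -> SketchSet:
    """Sketch every sequence; output order and values are independent of
    the degree of parallelism."""
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidInputError(f"duplicate sequence ids: {', '.join(dupes)}")
    digest = L.digest()
    if threads > 1 and len(seqs) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            sketches = list(pool.map(lambda s: sketch_sequence(s, L, backend), seqs))
    else:
        sketches = [sketch_sequence(s, L, backend) for s in seqs]
    return SketchSet(digest, L.t, L.k, L.size, sketches)
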