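"""Tokenized-subsequence matching primitives.

A string ``x`` of length ``k*t`` is viewed as ``k`` consecutive tokens of
length ``t``.  ``x`` is a *tokenized subsequence* of a host sequence ``s``
if its tokens occur in ``s`` at strictly increasing start positions; token
occurrences may overlap by up to ``t-1`` characters.  At ``t=1`` this is the
classical subsequence relation; at ``t>1`` it is strictly more permissive
than the subsequence relation on characters.

The central quantity for sketching is :func:`max_prefix_tokens`: the largest
``m`` such that the first ``m`` tokens of ``x`` form a tokenized subsequence
of ``s``.  Greedy leftmost matching (always taking the earliest feasible
occurrence of the next token) attains this maximum; the test suite verifies
greedy-vs-exhaustive equality as a property rather than assuming it.

Positions are 0-based half-open internally; messages meant for humans use
1-based coordinates.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


class IncompatibleSketchError(ValueError):
    """Raised when sketches from different testing lists are compared."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of residue symbols.

    Characters outside the alphabet are never matched by any token; they
    may only sit inside the gaps skipped between token occurrences.
    """

    symbols: tuple[str, ...] = ("A", "C", "G", "T")

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise InvalidInputError("alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise InvalidInputError("alphabet symbols must be distinct")
        for c in self.symbols:
            if len(c) != 1:
                raise InvalidInputError("alphabet symbols must be single characters")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, c: str) -> bool:
        return c in self.symbols


DNA = Alphabet(("A", "C", "G", "T"))
PROTEIN = Alphabet(tuple("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class Sequence:
    """A named residue string.  Residues are uppercased on construction."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidInputError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TokenizedSequence:
    """An ordered list of ``k`` tokens, each a string of length ``t``."""

    tokens: tuple[str, ...]
    t: int

    def __post_init__(self) -> None:
        if self.t < 1:
            raise InvalidInputError(f"token size must be >= 1, got {self.t}")
        for tok in self.tokens:
            if len(tok) != self.t:
                raise InvalidInputError(
                    f"token {tok!r} has length {len(tok)}, expected {self.t}"
                )

    @property
    def k(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        return "".join(self.tokens)


def tokenize(x: str, t: int) -> TokenizedSequence:
    """Split ``x`` into consecutive non-overlapping length-``t`` tokens.

    Raises :class:`InvalidInputError` if ``len(x)`` is not a positive
    multiple of ``t``.
    """
    if t < 1:
        raise InvalidInputError(f"token size must be >= 1, got {t}")
    if len(x) == 0 or len(x) % t != 0:
        raise InvalidInputError(
            f"cannot tokenize length-{len(x)} string with token size {t}: "
            "length must be a positive multiple of the token size"
        )
    return TokenizedSequence(tuple(x[i : i + t] for i in range(0, len(x), t)), t)


def _residues(s: "Sequence | str") -> str:
    return s.residues if isinstance(s, Sequence) else s


def max_prefix_tokens(s: "Sequence | str", x: TokenizedSequence) -> int:
    """Length of the longest prefix of ``x``'s tokens that is a tokenized
    subsequence of ``s``.

    Greedy leftmost matching: after matching token ``j`` at position ``i``,
    token ``j+1`` is searched from position ``i+1`` on, so successive token
    occurrences may overlap by up to ``t-1`` characters.
    """
    text = _residues(s)
    find = text.find
    pos = 0
    matched = 0
    for tok in x.tokens:
        i = find(tok, pos)
        if i < 0:
            break
        pos = i + 1
        matched += 1
    return matched


def is_tokenized_subsequence(s: "Sequence | str", x: TokenizedSequence) -> bool:
    """True iff all ``k`` tokens of ``x`` match in order within ``s``."""
    return max_prefix_tokens(s, x) == x.k


@dataclass
class NextOccurrenceIndex:
    """Preprocessed next-occurrence structure over one host sequence.

    For ``t == 1`` a per-character next-pointer automaton (``|s|+1`` rows of
    ``|Sigma|`` pointers); for ``t > 1`` a token -> sorted-start-positions
    table over all (overlapping) length-``t`` windows.  Query cost is O(1)
    per character at ``t=1`` and O(log |s|) per token otherwise.

    Produces results identical to the linear scan; the scan is the default
    backend because in practice it is almost always faster.
    """

    text: str
    t: int
    _automaton: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _table: dict[str, list[int]] = field(default_factory=dict, repr=False)

    @classmethod
    def build(cls, s: "Sequence | str", t: int) -> "NextOccurrenceIndex":
        if t < 1:
            raise InvalidInputError(f"token size must be >= 1, got {t}")
        text = _residues(s)
        idx = cls(text=text, t=t)
        n = len(text)
        if t == 1:
            # automaton[c][i] = least j >= i with text[j] == c, or n (absent)
            nxt: dict[str, list[int]] = {}
            for i in range(n - 1, -1, -1):
                c = text[i]
                if c not in nxt:
                    nxt[c] = [n] * (n + 1)
                nxt[c][i] = i
            for arr in nxt.values():
                for i in range(n - 1, -1, -1):
                    if arr[i] == n:
                        arr[i] = arr[i + 1]
            idx._automaton = nxt
        else:
            table: dict[str, list[int]] = {}
            for i in range(n - t + 1):
                table.setdefault(text[i : i + t], []).append(i)
            idx._table = table
        return idx

    def next(self, token: str, pos: int) -> int | None:
        """Smallest start position ``>= pos`` where ``token`` occurs, else None."""
        if len(token) != self.t:
            raise InvalidInputError(
                f"token {token!r} has length {len(token)}, index built for t={self.t}"
            )
        if self.t == 1:
            arr = self._automaton.get(token)
            if arr is None or pos > len(self.text):
                return None
            pos = max(pos, 0)
            j = arr[pos] if pos < len(self.text) else len(self.text)
            return None if j >= len(self.text) else j
        positions = self._table.get(token)
        if not positions:
            return None
        i = bisect_left(positions, pos)
        return positions[i] if i < len(positions) else None

    def max_prefix_tokens(self, x: TokenizedSequence) -> int:
        if x.t != self.t:
            raise InvalidInputError(
                f"tokenized sequence has t={x.t}, index built for t={self.t}"
            )
        pos = 0
        matched = 0
        for tok in x.tokens:
            i = self.next(tok, pos)
            if i is None:
                break
            pos = i + 1
            matched += 1
        return matched


def build_next_occurrence_index(s: "Sequence | str", t: int) -> NextOccurrenceIndex:
    """Build the opt-in index backend for repeated queries against ``s``."""
    return NextOccurrenceIndex.build(s, t)
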