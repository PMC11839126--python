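"""Parameter selection: subsequence containment combinatorics and token size.

For token size t=1, the number of length-n strings over an alphabet of size
sigma that contain a fixed length-k string as a subsequence is independent
of which length-k string is chosen:

    count(n, k, sigma) = sum_{i=k}^{n} C(i-1, k-1) (sigma-1)^(i-k) sigma^(n-i)

(group the containing strings by the last index i of the leftmost
occurrence; characters before each matched position cannot equal the next
query character, characters after the last are free).  Dividing by sigma^n
gives the containment probability, which also equals the binomial tail
Pr[Binomial(n, 1/sigma) >= k]: greedy left-to-right matching consumes one
query character with probability 1/sigma per scanned position.

These exact quantities drive the choice of k: pick the smallest k whose
containment probability is at most a small threshold, so that few sketch
entries max out.  For t > 1 the analogous count over token alphabets
overestimates badly (overlapping tokens are not independent), so the token
size is chosen from an empirical table indexed by input length instead.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction

from .core import InvalidInputError

#: empirical token-size recommendations at decade input lengths 10^2..10^9
T_RECOMMENDATIONS = {2: 2, 3: 6, 4: 9, 5: 12, 6: 15, 7: 19, 8: 22, 9: 25}


def _check_nk(n: int, k: int, sigma: int) -> None:
    if sigma < 2:
        raise InvalidInputError(f"alphabet size must be >= 2, got {sigma}")
    if k < 1 or n < 1:
        raise InvalidInputError(f"need n >= 1 and k >= 1, got n={n}, k={k}")


def containment_count(n: int, k: int, sigma: int) -> int:
    """Number of length-n strings containing a fixed length-k subsequence.

    Exact big-integer arithmetic; returns 0 when k > n.  The value does not
    depend on which length-k string is fixed.
    """
    _check_nk(n, k, sigma)
    if k > n:
        return 0
    return sum(
        math.comb(i - 1, k - 1) * (sigma - 1) ** (i - k) * sigma ** (n - i)
        for i in range(k, n + 1)
    )


def containment_probability(n: int, k: int, sigma: int, exact: bool = True) -> float:
    """Fraction of length-n strings containing a fixed length-k subsequence.

    ``exact=True`` evaluates the closed-form count over sigma^n as an exact
    rational before converting to float.  ``exact=False`` evaluates the
    equivalent binomial tail Pr[Binomial(n, 1/sigma) >= k] in floating
    point, which is preferable for very large n.
    """
    _check_nk(n, k, sigma)
    if k > n:
        return 0.0
    if exact:
        return float(Fraction(containment_count(n, k, sigma), sigma**n))
    from scipy.stats import binom

    return float(binom.sf(k - 1, n, 1.0 / sigma))


def binomial_tail_probability(n: int, k: int, sigma: int) -> float:
    """Exact-rational Pr[Binomial(n, 1/sigma) >= k], for cross-validation."""
    _check_nk(n, k, sigma)
    if k > n:
        return 0.0
    num = sum(math.comb(n, i) * (sigma - 1) ** (n - i) for i in range(k, n + 1))
    return float(Fraction(num, sigma**n))


def choose_k(n: int, sigma: int, threshold: float = 0.01) -> int:
    """Minimal k >= 1 with containment_probability(n, k, sigma) <= threshold.

    The probability is non-increasing in k, so the first k that clears the
    threshold is minimal.  If even k = n fails (threshold below sigma^-n),
    n is returned with a warning.
    """
    if not (0 < threshold <= 1):
        raise InvalidInputError(f"threshold must be in (0, 1], got {threshold}")
    _check_nk(n, 1, sigma)
    for k in range(1, n + 1):
        if containment_probability(n, k, sigma) <= threshold:
            return k
    warnings.warn(
        f"no k <= n={n} reaches containment probability <= {threshold}; "
        "returning k = n",
        stacklevel=2,
    )
    return n


def recommend_t(n: int) -> int:
    """Empirical token-size recommendation for input length ``n``.

    Exact at decade lengths 10^2..10^9; between decades, the value of the
    nearest decade in log10 (geometric midpoint ties round up); clamped to
    the table ends below 10^2 and above 10^9.
    """
    if n < 1:
        raise InvalidInputError(f"sequence length must be >= 1, got {n}")
    if n <= 100:
        return T_RECOMMENDATIONS[2]
    if n >= 10**9:
        return T_RECOMMENDATIONS[9]
    e = len(str(n)) - 1  # floor(log10 n) for positive ints
    # nearest decade in log10: round up iff n >= 10^(e + 1/2), i.e. n^2 >= 10^(2e+1)
    if n * n >= 10 ** (2 * e + 1):
        e += 1
    return T_RECOMMENDATIONS[min(max(e, 2), 9)]
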