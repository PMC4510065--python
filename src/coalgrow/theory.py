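"""Closed-form expectations under the standard neutral model.

All times are in coalescent units of 4N generations and the mutation rate
enters only through theta = 4Nu:

* E(s_i) = theta / i for i = 1..n-1 (expected frequency spectrum),
* E(S)   = theta * sum_{i=1}^{n-1} 1/i (expected segregating sites),
* E(t_i) = 1 / (i (i-1)) (epoch with i ancestral lineages),
* E(t_MRCA) = (n-1)/n,
* E(s_{i,*}) = theta / n, independent of i, where s_{i,*} counts the size-i
  mutations on a uniformly chosen tip's root path (a size-i mutation is on
  that path with probability i/n).

The i-independence of E(s_{i,*}) is what closes the induction on n: in
E(s_i^(n+1)) = theta/i - E(s_{i,*}) + E(s_{i-1,*}) the two star terms
cancel, and the singleton class is recovered from E(S) by subtraction.
:func:`expected_sfs_by_induction` re-executes that argument numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "TheoryTable",
    "expected_sfs",
    "expected_segregating_sites",
    "expected_interval",
    "expected_tmrca",
    "expected_star_count",
    "star_probability",
    "expected_sfs_by_induction",
    "harmonic_number",
]


def _check_n(n: int) -> None:
    if n < 2:
        raise InvalidParameterError(f"sample size must be >= 2, got {n}")


def _check_theta(theta: float) -> None:
    if theta < 0:
        raise InvalidParameterError(f"theta must be >= 0, got {theta}")


def harmonic_number(m: int) -> float:
    """H_m = sum_{i=1}^{m} 1/i, summed directly in ascending order."""
    return float(sum(1.0 / i for i in range(1, m + 1)))


def expected_sfs(n: int, theta: float) -> np.ndarray:
    """Expected frequency spectrum (theta/1, theta/2, ..., theta/(n-1))."""
    _check_n(n)
    _check_theta(theta)
    return theta / np.arange(1, n, dtype=np.float64)


def expected_segregating_sites(n: int, theta: float) -> float:
    """Expected number of segregating sites, theta * H_{n-1}."""
    _check_n(n)
    _check_theta(theta)
    return theta * harmonic_number(n - 1)


def expected_interval(i: int) -> float:
    """Mean duration 1/(i(i-1)) of the epoch with i ancestral lineages."""
    if i < 2:
        raise InvalidParameterError(f"interval index must be >= 2, got {i}")
    return 1.0 / (i * (i - 1))


def expected_tmrca(n: int) -> float:
    """Expected time to the MRCA, (n-1)/n in units of 4N generations."""
    _check_n(n)
    return (n - 1) / n


def star_probability(i: int, n: int) -> float:
    """Probability i/n that a given size-i mutation is a *-mutation.

    The *-tip is uniform over the n tips and a size-i mutation has exactly
    i descendant tips.
    """
    _check_n(n)
    if not 1 <= i <= n - 1:
        raise InvalidParameterError(f"mutation size must be in 1..{n - 1}, got {i}")
    return i / n


def expected_star_count(n: int, theta: float) -> float:
    """Expected count theta/n of size-i *-mutations -- independent of i."""
    _check_n(n)
    _check_theta(theta)
    return theta / n


def expected_sfs_by_induction(n: int, theta: float) -> np.ndarray:
    """Re-derive the expected spectrum by running the induction numerically.

    Starting from the n=2 base case E(s_1) = E(S) = theta, each step maps the
    size-n spectrum to the size-(n+1) spectrum using only the star-mutation
    bookkeeping: the size-i class loses a fraction i/n of its mass to size
    i+1 and inherits the corresponding outflow of size i-1, and the singleton
    class is set by subtracting the classes i >= 2 from E(S^(n+1)).  The
    result equals theta/i to machine precision -- no cancellation is assumed,
    it is observed.
    """
    _check_n(n)
    _check_theta(theta)
    s = np.array([theta])  # spectrum for sample size 2
    for m in range(2, n):  # grow m -> m+1
        star = s * np.arange(1, m) / m           # E(s_{i,*}) = (i/m) E(s_i)
        out = np.zeros(m)                        # spectrum for size m+1
        out[1:] = np.append(s[1:], 0.0) - np.append(star[1:], 0.0) + star
        out[0] = theta * harmonic_number(m) - out[1:].sum()
        s = out
    return s


@dataclass
class TheoryTable:
    """All closed-form expectations for one (n, theta) pair.

    Time quantities are in coalescent units; :meth:`to_generations` rescales
    them by a user-supplied 4N.
    """

    n: int
    theta: float
    expected_sfs: np.ndarray = field(init=False)
    expected_S: float = field(init=False)
    expected_intervals: np.ndarray = field(init=False)  # E(t_i), i = 2..n
    expected_tmrca: float = field(init=False)
    expected_star: float = field(init=False)

    def __post_init__(self) -> None:
        _check_n(self.n)
        _check_theta(self.theta)
        self.expected_sfs = expected_sfs(self.n, self.theta)
        self.expected_S = expected_segregating_sites(self.n, self.theta)
        self.expected_intervals = np.array(
            [expected_interval(i) for i in range(2, self.n + 1)]
        )
        self.expected_tmrca = expected_tmrca(self.n)
        self.expected_star = expected_star_count(self.n, self.theta)

    def star_probability(self, i: int) -> float:
        return star_probability(i, self.n)

    def to_generations(self, four_N: float) -> dict[str, object]:
        """Time quantities rescaled to generations for a given 4N."""
        return {
            "expected_intervals": self.expected_intervals * four_N,
            "expected_tmrca": self.expected_tmrca * four_N,
        }
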