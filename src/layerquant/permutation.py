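"""Exact paired sign-flip permutation test with midpoint tie ranking.

Two subjects' per-layer relative-intensity series are partitioned into K
contiguous clusters, each layer is dichotomized at a cutoff (default 0.05),
and each cluster is scored by its proportion of supra-cutoff layers.  Under
the null hypothesis of no subject difference, the two subjects' scores in a
cluster are exchangeable, so all 2^K reallocations (sign flips of the paired
differences) are equally likely.  The observed mean difference is ranked
among the statistics of all reallocations sorted ascending, and the
upper-tail p-value uses the midpoint-of-tied-ranks convention::

    p = 1 - (rank_smallest + tie_count/2) / 2^K

where ``rank_smallest`` is the rank of the first element of the observed
value's tie block.  All ranking is done in integer arithmetic (differences
are scaled by the lcm of the cluster sizes), so tie detection is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import ConfigurationError, EnumerationLimitError
from .quant import LayerProfile

#: Default number of clusters.
DEFAULT_K = 20

#: Default dichotomization cutoff for per-layer relative intensity.
DICHOTOMIZE_CUTOFF = 0.05

#: Largest K for which all 2^K reallocations are enumerated exactly.
MAX_EXACT_K = 24


@dataclass(frozen=True)
class PairedClusterSeries:
    """Two subjects' K cluster scores as exact rationals.

    Cluster ``i`` of subject A has ``m_a[i]`` supra-cutoff layers out of
    ``n_a[i]``; its score is the proportion ``m_a[i]/n_a[i]``.  Cluster sizes
    within a subject differ by at most one (near-equal contiguous partition).
    """

    m_a: tuple[int, ...]
    n_a: tuple[int, ...]
    m_b: tuple[int, ...]
    n_b: tuple[int, ...]
    cutoff: float = DICHOTOMIZE_CUTOFF

    def __post_init__(self) -> None:
        m_a, n_a = tuple(self.m_a), tuple(self.n_a)
        m_b, n_b = tuple(self.m_b), tuple(self.n_b)
        if not (len(m_a) == len(n_a) == len(m_b) == len(n_b)) or len(m_a) == 0:
            raise ConfigurationError("both subjects must have the same K >= 1 clusters")
        for m, n in zip(m_a + m_b, n_a + n_b):
            if not 0 <= m <= n:
                raise ConfigurationError("cluster counts must satisfy 0 <= m <= n")
        for sizes in (n_a, n_b):
            if max(sizes) - min(sizes) > 1:
                raise ConfigurationError("cluster sizes within a subject must differ by <= 1")
        object.__setattr__(self, "m_a", m_a)
        object.__setattr__(self, "n_a", n_a)
        object.__setattr__(self, "m_b", m_b)
        object.__setattr__(self, "n_b", n_b)

    @property
    def K(self) -> int:
        return len(self.m_a)

    @property
    def scores_a(self) -> np.ndarray:
        return np.array(self.m_a) / np.array(self.n_a)

    @property
    def scores_b(self) -> np.ndarray:
        return np.array(self.m_b) / np.array(self.n_b)

    def swapped(self) -> "PairedClusterSeries":
        """The same series with the two subjects exchanged."""
        return PairedClusterSeries(self.m_b, self.n_b, self.m_a, self.n_a, self.cutoff)


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the paired sign-flip permutation test.

    ``p`` is the upper-tail midpoint-tie p-value (floored at zero: when the
    observed statistic strictly exceeds every other reallocation the raw
    midpoint formula dips to -1/(2*total)).  ``p_two_sided`` doubles the
    smaller tail, capped at 1.  For Monte-Carlo results ``total`` counts the
    sampled reallocations plus the observed one and ``se`` is the binomial
    standard error of ``p``.
    """

    statistic: Fraction
    rank_smallest: int
    tie_count: int
    total: int
    p: Fraction
    p_two_sided: Fraction
    method: str = "exact"
    se: float | None = None


def midpoint_tie_pvalue(rank_smallest: int, tie_count: int, total: int) -> Fraction:
    """Upper-tail p-value from the midpoint-of-tied-ranks convention.

    Returns ``1 - (rank_smallest + tie_count/2)/total`` as an exact rational;
    rounding happens only at display time.  ``rank_smallest`` is the 1-based
    rank of the first element of the observed tie block among all reallocation
    statistics sorted ascending, ``tie_count`` the block size.  Note the exact
    value is -1/(2*total) in the extreme case ``rank_smallest == total``
    (observed strictly largest); result objects floor the reported p at 0.
    """
    if not 1 <= rank_smallest <= total:
        raise ConfigurationError("need 1 <= rank_smallest <= total")
    if not 1 <= tie_count <= total - rank_smallest + 1:
        raise ConfigurationError("need 1 <= tie_count <= total - rank_smallest + 1")
    return 1 - Fraction(2 * rank_smallest + tie_count, 2 * total)


def cluster_layers(
    profile: LayerProfile, K: int = DEFAULT_K, cutoff: float = DICHOTOMIZE_CUTOFF
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a profile's defined layers into K contiguous clusters.

    Layers with undefined ratios are dropped first; the remaining N layers
    are split in z-order into K blocks with sizes as equal as possible (the
    first ``N mod K`` blocks get one extra layer).  Returns per-cluster
    ``(m, n)``: the count of layers with ``r >= cutoff`` and the cluster size.
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    values = profile.r[profile.defined]
    N = values.size
    if N < K:
        raise ConfigurationError(f"need at least K={K} defined layers, got {N}")
    q, rem = divmod(N, K)
    sizes = np.array([q + 1] * rem + [q] * (K - rem))
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    m = np.array(
        [(values[bounds[i] : bounds[i + 1]] >= cutoff).sum() for i in range(K)]
    )
    return m, sizes


def make_paired_series(
    profile_a: LayerProfile,
    profile_b: LayerProfile,
    K: int = DEFAULT_K,
    cutoff: float = DICHOTOMIZE_CUTOFF,
) -> PairedClusterSeries:
    """Cluster two subjects' profiles into a test-ready paired series."""
    m_a, n_a = cluster_layers(profile_a, K, cutoff)
    m_b, n_b = cluster_layers(profile_b, K, cutoff)
    return PairedClusterSeries(
        tuple(int(x) for x in m_a),
        tuple(int(x) for x in n_a),
        tuple(int(x) for x in m_b),
        tuple(int(x) for x in n_b),
        cutoff,
    )


def _integer_differences(series: PairedClusterSeries) -> tuple[np.ndarray, int]:
    """Scale the paired score differences to exact integers.

    Multiplying every d_i = m_a/n_a - m_b/n_b by L = lcm of all cluster sizes
    turns the statistics into integers, so ranking and tie detection are
    exact; ranks are invariant under the positive scaling.
    """
    L = math.lcm(*series.n_a, *series.n_b)
    d = np.array(
        [
            ma * (L // na) - mb * (L // nb)
            for ma, na, mb, nb in zip(series.m_a, series.n_a, series.m_b, series.n_b)
        ],
        dtype=np.int64,
    )
    return d, L


def _result_from_counts(
    n_less: int, tie: int, total: int, statistic: Fraction, method: str, se: float | None
) -> PermutationResult:
    rank = n_less + 1
    n_greater = total - n_less - tie
    p_upper = max(Fraction(0), midpoint_tie_pvalue(rank, tie, total))
    p_lower = max(Fraction(0), midpoint_tie_pvalue(n_greater + 1, tie, total))
    p_two = min(Fraction(1), 2 * min(p_upper, p_lower))
    return PermutationResult(
        statistic=statistic,
        rank_smallest=rank,
        tie_count=tie,
        total=total,
        p=p_upper,
        p_two_sided=p_two,
        method=method,
        se=se,
    )


def exact_paired_permutation(series: PairedClusterSeries) -> PermutationResult:
    """Enumerate all 2^K sign reallocations and rank the observed statistic.

    The statistic of a sign vector s is mean(s_i * d_i); the observed value
    corresponds to s = +1.  Ranks and tie counts are computed with exact
    integer arithmetic.  K is capped at ``MAX_EXACT_K``; beyond that use
    :func:`monte_carlo_permutation`.
    """
    K = series.K
    if K > MAX_EXACT_K:
        raise EnumerationLimitError(
            f"K={K} exceeds the exact enumeration bound {MAX_EXACT_K}; "
            "use monte_carlo_permutation (CLI: --mc N)"
        )
    d, L = _integer_differences(series)
    sums = np.zeros(1, dtype=np.int64)
    for v in d:
        sums = np.concatenate([sums - v, sums + v])
    t_obs = int(d.sum())
    n_less = int((sums < t_obs).sum())
    tie = int((sums == t_obs).sum())
    statistic = Fraction(t_obs, L * K)
    return _result_from_counts(n_less, tie, 2**K, statistic, "exact", None)


def monte_carlo_permutation(
    series: PairedClusterSeries, n_draws: int = 100_000, seed: int = 0
) -> PermutationResult:
    """Monte-Carlo version of the test for K beyond the enumeration bound.

    Draws ``n_draws`` uniform sign vectors, pools them with the observed
    reallocation, and applies the same midpoint-tie ranking to the pool.
    """
    if n_draws < 1000:
        raise ConfigurationError("n_draws must be >= 1000")
    rng = np.random.default_rng(seed)
    d, L = _integer_differences(series)
    K = series.K
    t_obs = int(d.sum())
    n_less = 0
    tie = 1  # the observed reallocation itself
    chunk = 200_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        signs = rng.integers(0, 2, size=(m, K)).astype(np.int64) * 2 - 1
        sums = signs @ d
        n_less += int((sums < t_obs).sum())
        tie += int((sums == t_obs).sum())
        done += m
    total = n_draws + 1
    statistic = Fraction(t_obs, L * K)
    p_hat = float(max(Fraction(0), midpoint_tie_pvalue(n_less + 1, tie, total)))
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-300) / n_draws)
    return _result_from_counts(n_less, tie, total, statistic, "monte-carlo", se)


def result_report(result: PermutationResult) -> dict:
    """JSON-ready summary of a permutation test result."""
    return {
        "T_obs": float(result.statistic),
        "rank_smallest": result.rank_smallest,
        "tie_count": result.tie_count,
        "total": result.total,
        "p_upper": float(result.p),
        "p_two_sided": float(result.p_two_sided),
        "method": result.method,
        "se": result.se,
    }
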