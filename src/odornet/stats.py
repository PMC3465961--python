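"""Correlation statistics and the constrained randomization null.

Correlation estimates come from scipy (Spearman mid-rank, Kendall tau-b,
Pearson); for small samples (n <= 8) the p-value is replaced by an exact
two-sided permutation enumeration over all n! orderings, which handles ties
correctly. The randomization null draws gene sets of a fixed size from an
ortholog pool with replacement (optionally constraining how many draws come
from a tagged category) and compares the observed network-mean omega against
the empirical distribution of resampled-set means.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .simulate import OrthologPool

EXACT_N_MAX = 8


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    estimate: float
    p_value: float
    n: int


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: correlation undefined")
    return x, y


def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_p_spearman(x, y) -> float:
    """Two-sided exact p over all n! orderings of y.

    Ranks of a permuted vector are the permuted ranks, and the rank standard
    deviations are permutation-invariant, so |rho| ordering reduces to the
    |centered-rank inner product|, evaluated for all permutations at once.
    """
    rx = scipy.stats.rankdata(x) - (len(x) + 1) / 2
    ry = scipy.stats.rankdata(y)
    perms = _all_permutations(len(x))
    stats = np.abs(ry[perms] @ rx)
    observed = np.abs(ry @ rx)
    return float((stats >= observed - 1e-9).mean())


def _exact_p_kendall(x, y) -> float:
    """Two-sided exact p for tau-b over all n! orderings of y.

    The tie corrections in tau-b's denominator depend only on the value
    multisets, hence are permutation-invariant; only the concordance
    numerator sum of sign(dx)*sign(dy) over pairs varies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    iu, ju = np.triu_indices(n, k=1)
    sx = np.sign(x[iu] - x[ju])
    perms = _all_permutations(n)
    yp = y[perms]
    nums = np.abs((np.sign(yp[:, iu] - yp[:, ju]) * sx).sum(axis=1))
    observed = np.abs((np.sign(y[iu] - y[ju]) * sx).sum())
    return float((nums >= observed - 1e-9).mean())


def _spearman_stat(x, y) -> float:
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y, exact: str = "auto") -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties).

    p-value: exact permutation enumeration for n <= 8 (exact="auto" or
    "always"), otherwise the two-sided t approximation.
    """
    x, y = _check_xy(x, y)
    estimate = _spearman_stat(x, y)
    n = len(x)
    if exact == "always" or (exact == "auto" and n <= EXACT_N_MAX):
        p = _exact_p_spearman(x, y)
    else:
        p = float(scipy.stats.spearmanr(x, y).pvalue)
    return CorrelationResult("spearman", estimate, p, n)


def _kendall_stat(x, y) -> float:
    return float(scipy.stats.kendalltau(x, y, variant="b").statistic)


def kendall_tau(x, y, exact: str = "auto") -> CorrelationResult:
    """Kendall's tau-b (tie-corrected).

    p-value: exact permutation enumeration for n <= 8, otherwise the normal
    approximation (which scipy sharpens to an exact tie-free computation
    where applicable).
    """
    x, y = _check_xy(x, y)
    estimate = _kendall_stat(x, y)
    n = len(x)
    if exact == "always" or (exact == "auto" and n <= EXACT_N_MAX):
        p = _exact_p_kendall(x, y)
    else:
        p = float(scipy.stats.kendalltau(x, y, variant="b").pvalue)
    return CorrelationResult("kendall", estimate, p, n)


def pearson_r2(x, y) -> tuple[float, float]:
    """Product-moment correlation r and the coefficient of determination r^2."""
    x, y = _check_xy(x, y)
    r = float(scipy.stats.pearsonr(x, y).statistic)
    return r, r * r


# ---------------------------------------------------------------------------
# randomization null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomizationResult:
    n_reps: int
    set_size: int
    constraint: tuple[str, int] | None
    null_means: np.ndarray
    null_mean_of_means: float
    observed_mean: float
    empirical_p: float
    seed: int

    def __post_init__(self):
        assert len(self.null_means) == self.n_reps


def randomization_null(pool: OrthologPool, observed_mean: float,
                       set_size: int = 16, n_reps: int = 50_000,
                       constraint: tuple[str, int] | None = None,
                       seed: int = 0,
                       within_set_replacement: bool = True) -> RandomizationResult:
    """Empirical null of mean omega over randomly assembled gene sets.

    Each replicate draws set_size entries from the pool with replacement
    (within_set_replacement=False draws each set without internal repeats).
    With constraint=(tag, count), exactly `count` draws per set come from
    tagged entries and the rest from untagged entries. The one-sided
    empirical p for "observed mean below the null" is
    (1 + #{null <= observed}) / (1 + n_reps), never exactly zero.
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    def draw_matrix(values: np.ndarray, k: int) -> np.ndarray:
        if len(values) == 0:
            raise ValueError("constraint unsatisfiable: empty candidate set")
        if within_set_replacement:
            idx = rng.integers(0, len(values), size=(n_reps, k))
        else:
            if k > len(values):
                raise ValueError("set size exceeds pool without replacement")
            idx = np.array([rng.choice(len(values), size=k, replace=False)
                            for _ in range(n_reps)])
        return values[idx]

    if constraint is None:
        sums = draw_matrix(pool.omegas(), set_size).sum(axis=1)
    else:
        tag, required = constraint
        if not 0 <= required <= set_size:
            raise ValueError("required tagged count outside [0, set_size]")
        tagged = pool.omegas(tag)
        untagged = pool.omegas(tag, without=True)
        sums = np.zeros(n_reps)
        if required:
            sums += draw_matrix(tagged, required).sum(axis=1)
        if set_size - required:
            sums += draw_matrix(untagged, set_size - required).sum(axis=1)
    null_means = sums / set_size
    p = (1 + int((null_means <= observed_mean).sum())) / (1 + n_reps)
    return RandomizationResult(
        n_reps=n_reps, set_size=set_size, constraint=constraint,
        null_means=null_means, null_mean_of_means=float(null_means.mean()),
        observed_mean=float(observed_mean), empirical_p=p, seed=seed)


def histogram_bins(values, bin_width: float):
    """Frequency table over equal-width half-open bins [lo, hi).

    Returns a list of (lo, hi, count) covering min..max of the data; counts
    sum to len(values).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to bin")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo0 = math.floor(values.min() / bin_width) * bin_width
    n_bins = max(1, math.floor((values.max() - lo0) / bin_width) + 1)
    edges = lo0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    # np.histogram closes the last bin; shift any max==edge values correctly
    out = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        c = int(((values >= lo) & (values < hi)).sum())
        out.append((float(lo), float(hi), c))
    assert sum(c for _, _, c in out) == values.size
    return out
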