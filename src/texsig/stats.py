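"""Bespoke statistics: ranking distance, its permutation test, the
random-sampling t-test, and the per-unit label-randomization test.

The ranking distance (RD) between two permutations X and Y of 1..n is

    D_n(X, Y) = sum_i | ln( i / f_Y(x_i) ) |,

where f_Y(x_i) is the (1-based) position of the value x_i within Y.  It is
a proper metric on permutations; small values mean consistent orderings.
Consistency is judged against the null of two independent uniform random
permutations: the p-value is the fraction of null distances *strictly
smaller* than the observed one (small observed distance -> small p).

The random-sampling t-test (RST) mimics finite electrode sampling: fixed-
size unit samples are drawn repeatedly, a standard t-test runs per draw,
and the p-values are averaged.  The per-unit randomization test shuffles
CM/SM role labels and compares each unit's observed modulation index with
the null fraction larger than it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .metrics import ResponseMatrix, modulation_indices

__all__ = [
    "ranking_distance",
    "rd_null_samples",
    "rd_permutation_test",
    "RDTestResult",
    "rank_families_by_pmi",
    "random_sampling_ttest",
    "RSTResult",
    "unit_randomization_test",
    "RandomizationTestResult",
]


def _check_permutation(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=int)
    n = len(p)
    counts = np.bincount(p, minlength=n + 1)
    if counts[0] or (counts[1:] != 1).any():
        missing = [v for v in range(1, n + 1) if counts[v] == 0]
        dup = [v for v in range(1, len(counts)) if counts[v] > 1]
        raise ValueError(
            f"{name} is not a permutation of 1..{n}: "
            f"missing {missing}, duplicated {dup}")
    return p


def ranking_distance(X, Y) -> float:
    """RD between two permutations of 1..n (natural logarithm)."""
    X = _check_permutation(X, "X")
    Y = _check_permutation(Y, "Y")
    if len(X) != len(Y):
        raise ValueError(f"length mismatch: {len(X)} vs {len(Y)}")
    n = len(X)
    pos_Y = np.empty(n + 1, dtype=int)
    pos_Y[Y] = np.arange(1, n + 1)         # pos_Y[value] = index in Y
    log_i = np.log(np.arange(1, n + 1))
    # |log(i/f)| as |log i - log f|, summed exactly: the terms of D(X, Y)
    # and D(Y, X) are the same multiset, so exact summation makes the
    # symmetry axiom hold to the last bit
    return math.fsum(np.abs(log_i - log_i[pos_Y[X] - 1]))


def rd_null_samples(n: int, n_samples: int, seed: int = 0,
                    chunk: int = 100_000) -> np.ndarray:
    """Sample RD values between pairs of independent uniform permutations."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    log_i = np.log(np.arange(1, n + 1))
    out = np.empty(n_samples)
    for start in range(0, n_samples, chunk):
        b = min(chunk, n_samples - start)
        X = np.argsort(rng.random((b, n)), axis=1)        # values 0..n-1
        Y = np.argsort(rng.random((b, n)), axis=1)
        pos_Y = np.argsort(Y, axis=1)                     # position of value
        f = np.take_along_axis(pos_Y, X, axis=1)          # 0-based f_Y(x_i)
        out[start:start + b] = np.abs(log_i[None, :] - log_i[f]).sum(axis=1)
    return out


@dataclass
class RDTestResult:
    p_value: float
    std_error: float
    n_samples: int
    observed: float
    n: int


def rd_permutation_test(observed: float, n: int, n_samples: int = 1_000_000,
                        seed: int = 0) -> RDTestResult:
    """Monte-Carlo permutation test of ordering consistency.

    p = fraction of sampled random-permutation-pair distances strictly
    smaller than the observed distance; the binomial Monte-Carlo standard
    error is reported alongside.
    """
    null = rd_null_samples(n, n_samples, seed)
    p = float((null < observed).mean())
    se = float(np.sqrt(max(p * (1.0 - p), 1.0 / n_samples) / n_samples))
    return RDTestResult(p_value=p, std_error=se, n_samples=n_samples,
                        observed=float(observed), n=n)


def rank_families_by_pmi(pmi_per_family: np.ndarray) -> np.ndarray:
    """Family labels (1-based) in decreasing PMI order, ties by family index."""
    v = np.asarray(pmi_per_family, dtype=float)
    if np.isnan(v).any():
        raise ValueError("undefined PMI in input")
    # stable sort on -PMI keeps ascending family index within ties
    order = np.argsort(-v, kind="stable")
    return order + 1


# ---------------------------------------------------------------------------
# Random-sampling t-test
# ---------------------------------------------------------------------------

@dataclass
class RSTResult:
    p_value: float               # mean over repetitions
    p_values: np.ndarray
    n_sample: int
    reps: int
    tail: str
    paired: bool


def random_sampling_ttest(group_a: np.ndarray, group_b="zero",
                          n_sample: int = 100, reps: int = 500,
                          tail: str = "greater", paired: bool = False,
                          seed: int = 0) -> RSTResult:
    """Repeatedly subsample units, t-test each draw, average the p-values.

    ``group_b`` may be an array of values or the string ``"zero"`` for a
    one-sample test against 0.  Samples are drawn without replacement,
    independently per group and repetition; groups smaller than
    ``n_sample`` reduce the sample size to the group size with a warning.
    The default tail is one-sided (a > b).
    """
    a = np.asarray(group_a, dtype=float)
    a = a[~np.isnan(a)]
    one_sample = isinstance(group_b, str) and group_b == "zero"
    if not one_sample:
        b = np.asarray(group_b, dtype=float)
        b = b[~np.isnan(b)]
        if b.size == 0:
            raise ValueError("empty group B")
    if a.size == 0:
        raise ValueError("empty group A")
    n_eff = min(n_sample, a.size) if one_sample else min(n_sample, a.size,
                                                         b.size)
    if n_eff < n_sample:
        import warnings
        warnings.warn(f"sample size reduced to {n_eff}", stacklevel=2)
    if paired and not one_sample and a.size != b.size:
        raise ValueError("paired test needs equal group sizes")
    rng = np.random.default_rng(seed)
    ps = np.empty(reps)
    for r in range(reps):
        ia = rng.choice(a.size, size=n_eff, replace=False)
        if one_sample:
            ps[r] = sps.ttest_1samp(a[ia], 0.0, alternative=tail).pvalue
        elif paired:
            ps[r] = sps.ttest_rel(a[ia], b[ia], alternative=tail).pvalue
        else:
            ib = rng.choice(b.size, size=n_eff, replace=False)
            ps[r] = sps.ttest_ind(a[ia], b[ib], alternative=tail).pvalue
    return RSTResult(p_value=float(ps.mean()), p_values=ps, n_sample=n_eff,
                     reps=reps, tail=tail, paired=paired)


# ---------------------------------------------------------------------------
# Per-unit randomization test
# ---------------------------------------------------------------------------

@dataclass
class RandomizationTestResult:
    p_values: np.ndarray         # per unit; nan where skipped
    significant: np.ndarray      # p < alpha
    n_skipped: int
    n_perm: int
    alpha: float

    @property
    def fraction_significant(self) -> float:
        ok = ~np.isnan(self.p_values)
        if not ok.any():
            return float("nan")
        return float(self.significant[ok].mean())


def unit_randomization_test(R: ResponseMatrix, n_perm: int = 10_000,
                            seed: int = 0, alpha: float = 0.05,
                            method: str = "pair_swap"
                            ) -> RandomizationTestResult:
    """Significance of each unit's positive modulation by label shuffling.

    Null distributions are built by reassigning CM/SM role labels and
    recomputing the unit's modulation index; the p-value is the fraction of
    the null *strictly larger* than the observed index, and a unit is
    significantly positively modulated when that fraction is below
    ``alpha``.

    ``method="pair_swap"`` (default) swaps the two labels within each pair
    independently with probability 1/2, preserving the pair structure.
    Since a swap of pair p negates that pair's index contribution, each
    null draw is a random +-1 signing of the per-pair indices.
    ``method="global"`` permutes all 2 * n_pairs labels and re-pairs the
    columns in order.  Units with no valid pair are skipped and counted.
    """
    if method not in ("pair_swap", "global"):
        raise ValueError(f"unknown method {method!r}")
    observed, n_valid = modulation_indices(R)
    U, P = R.n_units, R.n_pairs
    p_values = np.full(U, np.nan)
    rng = np.random.default_rng(seed)

    a, b = R.cm, R.sm
    tot = a + b
    valid = tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(valid, (a - b) / np.where(valid, tot, 1.0), 0.0)

    if method == "pair_swap":
        for u in range(U):
            if n_valid[u] == 0:
                continue
            signs = rng.integers(0, 2, size=(n_perm, P)) * 2 - 1
            null = (signs @ d[u]) / n_valid[u]
            p_values[u] = float((null > observed[u]).mean())
    else:
        pooled = R.responses
        for u in range(U):
            if n_valid[u] == 0:
                continue
            row = pooled[u]
            null = np.empty(n_perm)
            for k in range(n_perm):
                perm = rng.permutation(2 * P)
                ca, cb = row[perm[:P]], row[perm[P:]]
                t = ca + cb
                v = t > 0
                null[k] = (((ca[v] - cb[v]) / t[v]).mean()
                           if v.any() else 0.0)
            p_values[u] = float((null > observed[u]).mean())

    significant = p_values < alpha
    n_skipped = int(np.isnan(p_values).sum())
    return RandomizationTestResult(p_values=p_values, significant=significant,
                                   n_skipped=n_skipped, n_perm=n_perm,
                                   alpha=alpha)
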