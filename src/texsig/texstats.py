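"""Grouped higher-order texture statistics and the PMI regression.

Seven groups of image statistics, modelled on the parametric texture
description used in texture-selectivity experiments:

1. ``marginal``        pixel skewness and kurtosis
2. ``spectral``        mean energy per (scale, orientation) sub-band
3. ``lin_position``    correlations of linear responses across positions
4. ``lin_scale``       correlations of linear responses across adjacent scales
5. ``en_orientation``  correlations of energy responses across orientations
6. ``en_position``     correlations of energy responses across positions
7. ``en_scale``        correlations of energy responses across adjacent scales

Linear responses come from the even member of a quadrature Gabor pair;
energy is the L2-norm of the even/odd pair (a complex-cell model).  All
scales are filtered on the full-resolution grid with octave-spaced
wavelengths, so cross-scale maps are position-aligned by construction.

Downstream, raw statistics are signed-square-rooted and z-scored, reduced
by per-group PCA to >90% retained variance, and used in an OLS regression
of per-pair population modulation on image statistics whose group
contributions are decomposed exactly by averaging-over-orderings (LMG).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm_api
from scipy.linalg import qr as _pivoted_qr
from scipy.signal import fftconvolve
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from sklearn.decomposition import PCA

from .stimuli import GrayImage, StimulusCorpus

GROUP_NAMES = (
    "marginal",
    "spectral",
    "lin_position",
    "lin_scale",
    "en_orientation",
    "en_position",
    "en_scale",
)

__all__ = [
    "FilterBank",
    "StatGroupVector",
    "TransformRecord",
    "StatDesignMatrix",
    "GROUP_NAMES",
    "compute_texture_stats",
    "stats_matrix",
    "signed_sqrt_zscore",
    "groupwise_pca",
    "fit_pmi_regression",
    "lmg_contributions",
    "group_correlation_cm_sm",
    "PmiStatsRegression",
    "PmiStatsRegressionResults",
]


# ---------------------------------------------------------------------------
# Filter bank
# ---------------------------------------------------------------------------

def _gabor_pair(wavelength: float, theta: float, sigma: float):
    half = int(np.ceil(2.0 * sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    rot = xx * np.cos(theta) + yy * np.sin(theta)
    env = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    arg = 2.0 * np.pi * rot / wavelength
    even = env * np.cos(arg)
    odd = env * np.sin(arg)
    even -= even.mean()          # kill DC leakage in the even member
    even /= np.linalg.norm(even)
    odd /= np.linalg.norm(odd)
    return even, odd


@dataclass
class FilterBank:
    """Quadrature Gabor pairs on an octave-spaced scale x orientation grid."""

    n_scales: int = 4
    n_orientations: int = 4
    base_wavelength: float = 4.0
    sigma_factor: float = 0.45           # envelope sigma = factor * wavelength
    neighborhood_radius: int = 3

    def __post_init__(self) -> None:
        self.wavelengths = [self.base_wavelength * 2 ** s
                            for s in range(self.n_scales)]
        self.thetas = [np.pi * o / self.n_orientations
                       for o in range(self.n_orientations)]
        self.filters = {}
        for s, lam in enumerate(self.wavelengths):
            for o, th in enumerate(self.thetas):
                self.filters[(s, o)] = _gabor_pair(lam, th,
                                                   self.sigma_factor * lam)

    @property
    def max_sigma(self) -> float:
        return self.sigma_factor * self.wavelengths[-1]

    @property
    def max_support(self) -> int:
        """Kernel width of the largest filter (truncated at +-2 sigma)."""
        return 2 * int(np.ceil(2.0 * self.max_sigma)) + 1

    def offsets(self) -> list[tuple[int, int]]:
        """Position-neighborhood offsets, de-duplicated by point symmetry.

        The correlation at offset (dy, dx) equals the one at (-dy, -dx), so
        only the upper half-plane (dy > 0, or dy == 0 and dx > 0) is kept.
        """
        r = self.neighborhood_radius
        out = []
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if (dy, dx) == (0, 0):
                    continue
                if dy > 0 or (dy == 0 and dx > 0):
                    out.append((dy, dx))
        return out

    def group_sizes(self) -> dict[str, int]:
        """Closed-form statistic count per group for this configuration."""
        S, O = self.n_scales, self.n_orientations
        n_off = len(self.offsets())
        return {
            "marginal": 2,
            "spectral": S * O,
            "lin_position": S * O * n_off,
            "lin_scale": (S - 1) * O,
            "en_orientation": S * O * (O - 1) // 2,
            "en_position": S * O * n_off,
            "en_scale": (S - 1) * O,
        }


@dataclass
class StatGroupVector:
    group: str
    values: np.ndarray
    labels: list[str]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUP_NAMES:
            raise ValueError(f"unknown group {self.group!r}")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.labels):
            raise ValueError("values/labels length mismatch")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _shifted_corr(a: np.ndarray, b: np.ndarray, dy: int, dx: int) -> float:
    """Pearson correlation of a with b shifted by (dy, dx), valid overlap."""
    h, w = a.shape
    ys = slice(max(0, dy), min(h, h + dy))
    xs = slice(max(0, dx), min(w, w + dx))
    ys2 = slice(max(0, -dy), min(h, h - dy))
    xs2 = slice(max(0, -dx), min(w, w - dx))
    u = a[ys, xs].ravel()
    v = b[ys2, xs2].ravel()
    return _pearson(u, v)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return 0.0
    return float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))


def compute_texture_stats(img: GrayImage, bank: FilterBank | None = None
                          ) -> list[StatGroupVector]:
    """Compute the seven grouped statistics of one image.

    The image must comfortably contain the largest filter: its smaller
    dimension must be at least four envelope sigmas of the coarsest Gabor.
    Responses are computed by 'same'-mode convolution and a border margin of
    half the largest kernel is trimmed before any correlation.
    """
    bank = bank or FilterBank()
    p = img.pixels
    if min(p.shape) < 4 * bank.max_sigma:
        raise ValueError(
            f"image {p.shape} smaller than 4x the largest filter envelope "
            f"({4 * bank.max_sigma:.0f} px needed)"
        )
    S, O = bank.n_scales, bank.n_orientations
    margin = min(bank.max_support // 2, (min(p.shape) - 4) // 2 - 1)
    trim = (slice(margin, p.shape[0] - margin),
            slice(margin, p.shape[1] - margin))

    lin = {}
    en = {}
    for (s, o), (even, odd) in bank.filters.items():
        re = fftconvolve(p, even, mode="same")
        ro = fftconvolve(p, odd, mode="same")
        lin[(s, o)] = re
        en[(s, o)] = np.sqrt(re ** 2 + ro ** 2)

    groups: list[StatGroupVector] = []

    # 1. marginal -----------------------------------------------------------
    if p.std() == 0:
        groups.append(StatGroupVector("marginal", np.zeros(2),
                                      ["skewness", "kurtosis"],
                                      degenerate=True))
    else:
        groups.append(StatGroupVector(
            "marginal",
            np.array([_skew(p.ravel()), _kurtosis(p.ravel(), fisher=False)]),
            ["skewness", "kurtosis"]))

    # 2. spectral -----------------------------------------------------------
    vals, labels = [], []
    for s in range(S):
        for o in range(O):
            vals.append(en[(s, o)][trim].mean())
            labels.append(f"s{s}o{o}")
    groups.append(StatGroupVector("spectral", np.array(vals), labels))

    # 3/6. position correlations -------------------------------------------
    offs = bank.offsets()
    for name, maps in (("lin_position", lin), ("en_position", en)):
        vals, labels = [], []
        for s in range(S):
            for o in range(O):
                m = maps[(s, o)][trim]
                for dy, dx in offs:
                    vals.append(_shifted_corr(m, m, dy, dx))
                    labels.append(f"s{s}o{o}d{dy},{dx}")
        groups.append(StatGroupVector(name, np.array(vals), labels))

    # 4/7. adjacent-scale correlations -------------------------------------
    for name, maps in (("lin_scale", lin), ("en_scale", en)):
        vals, labels = [], []
        for s in range(S - 1):
            for o in range(O):
                vals.append(_pearson(maps[(s, o)][trim].ravel(),
                                     maps[(s + 1, o)][trim].ravel()))
                labels.append(f"s{s}-{s + 1}o{o}")
        groups.append(StatGroupVector(name, np.array(vals), labels))

    # 5. cross-orientation energy correlations ------------------------------
    vals, labels = [], []
    for s in range(S):
        for o1, o2 in itertools.combinations(range(O), 2):
            vals.append(_pearson(en[(s, o1)][trim].ravel(),
                                 en[(s, o2)][trim].ravel()))
            labels.append(f"s{s}o{o1}-{o2}")
    groups.append(StatGroupVector("en_orientation", np.array(vals), labels))

    order = {g: i for i, g in enumerate(GROUP_NAMES)}
    groups.sort(key=lambda g: order[g.group])
    return groups


def stats_matrix(images: list[GrayImage], bank: FilterBank | None = None
                 ) -> tuple[np.ndarray, dict[str, tuple[int, int]], list[str]]:
    """Stack per-image statistics into (n_images x n_params), with group spans."""
    bank = bank or FilterBank()
    rows = []
    spans: dict[str, tuple[int, int]] = {}
    labels: list[str] = []
    for i, img in enumerate(images):
        groups = compute_texture_stats(img, bank)
        if i == 0:
            start = 0
            for g in groups:
                spans[g.group] = (start, start + len(g.values))
                labels.extend(f"{g.group}:{lab}" for lab in g.labels)
                start += len(g.values)
        rows.append(np.concatenate([g.values for g in groups]))
    return np.vstack(rows), spans, labels


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

@dataclass
class TransformRecord:
    kept: np.ndarray            # indices of retained columns
    dropped: np.ndarray         # indices of constant columns that were removed
    mean: np.ndarray            # post-sqrt column means (kept columns)
    sd: np.ndarray              # post-sqrt column sds (kept columns)

    def apply(self, raw: np.ndarray) -> np.ndarray:
        x = np.sign(raw) * np.sqrt(np.abs(raw))
        return (x[:, self.kept] - self.mean) / self.sd


def signed_sqrt_zscore(raw: np.ndarray) -> tuple[np.ndarray, TransformRecord]:
    """sign(x)*sqrt(|x|) per entry, then z-score each column.

    Constant columns (zero variance after the square root) carry no
    information and are dropped; their indices are kept in the record.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    x = np.sign(raw) * np.sqrt(np.abs(raw))
    sd = x.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    dropped = np.flatnonzero(sd == 0)
    rec = TransformRecord(kept=kept, dropped=dropped,
                          mean=x[:, kept].mean(axis=0), sd=sd[kept])
    z = (x[:, kept] - rec.mean) / rec.sd
    return z, rec


def _remap_spans(spans: dict[str, tuple[int, int]], kept: np.ndarray
                 ) -> dict[str, tuple[int, int]]:
    """Group spans after dropping columns (kept indices are sorted)."""
    out = {}
    pos = 0
    for g, (a, b) in spans.items():
        n = int(((kept >= a) & (kept < b)).sum())
        out[g] = (pos, pos + n)
        pos += n
    return out


@dataclass
class StatDesignMatrix:
    """Concatenated per-group principal-component scores, one row per pair."""

    scores: np.ndarray
    group_spans: dict[str, tuple[int, int]]
    transform: TransformRecord
    variance_retained: dict[str, float]
    components: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.scores.shape[0]

    @property
    def groups(self) -> list[str]:
        return list(self.group_spans)

    def group_columns(self, group: str) -> np.ndarray:
        a, b = self.group_spans[group]
        return self.scores[:, a:b]


def groupwise_pca(z: np.ndarray, group_spans: dict[str, tuple[int, int]],
                  transform: TransformRecord | None = None,
                  var_threshold: float = 0.9,
                  max_components: int | None = None) -> StatDesignMatrix:
    """Per-group PCA keeping the fewest components covering > var_threshold.

    Scores are re-standardized to unit variance so every design column is on
    the same footing in the regression.  ``max_components`` caps the
    per-group count (needed at small sample sizes, where the 90% rule can
    demand more columns than there are rows; the realized variance fraction
    is recorded either way).
    """
    if not 0.0 < var_threshold < 1.0:
        raise ValueError(f"var_threshold must be in (0, 1), got {var_threshold}")
    n = z.shape[0]
    blocks, spans_out, retained, comps = [], {}, {}, {}
    pos = 0
    for g, (a, b) in group_spans.items():
        X = z[:, a:b]
        if X.shape[1] == 0:
            spans_out[g] = (pos, pos)
            retained[g] = 1.0
            continue
        k_max = min(n - 1, X.shape[1])
        if n <= k_max:
            raise ValueError("need more rows than requested components")
        pca = PCA(n_components=k_max, svd_solver="full")
        scores = pca.fit_transform(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, var_threshold) + 1)
        k = min(k, k_max)
        if max_components is not None:
            k = min(k, max_components)
        sub = scores[:, :k]
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        blocks.append(sub / sd)
        spans_out[g] = (pos, pos + k)
        retained[g] = float(cum[k - 1])
        comps[g] = pca.components_[:k]
        pos += k
    return StatDesignMatrix(scores=np.hstack(blocks), group_spans=spans_out,
                            transform=transform, variance_retained=retained,
                            components=comps)


def build_design(images: list[GrayImage], bank: FilterBank | None = None,
                 var_threshold: float = 0.9,
                 max_components: int | None = None) -> StatDesignMatrix:
    """stats -> signed sqrt + z-score -> groupwise PCA, in one call."""
    raw, spans, _ = stats_matrix(images, bank)
    z, rec = signed_sqrt_zscore(raw)
    return groupwise_pca(z, _remap_spans(spans, rec.kept), rec,
                         var_threshold, max_components)


# ---------------------------------------------------------------------------
# Regression and relative importance
# ---------------------------------------------------------------------------

def _subset_r2(X: np.ndarray, y: np.ndarray, cols: np.ndarray) -> float:
    """R-squared of OLS-with-intercept on the selected columns."""
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        return 0.0
    if cols.size == 0:
        return 0.0
    Xc = X[:, cols] - X[:, cols].mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    return 1.0 - float(resid @ resid) / sst


class PmiStatsRegression:
    """OLS of per-pair population modulation on grouped image statistics.

    Parameters
    ----------
    design : StatDesignMatrix
        Groupwise-PCA design (one row per stimulus pair).
    target : array
        Per-pair population modulation index.
    """

    def __init__(self, design: StatDesignMatrix, target: np.ndarray):
        y = np.asarray(target, dtype=float)
        if y.ndim != 1 or len(y) != design.n_rows:
            raise ValueError("target length must match design rows")
        if design.n_rows <= design.scores.shape[1]:
            raise ValueError("need more rows than design columns")
        rank = np.linalg.matrix_rank(design.scores)
        if rank < design.scores.shape[1]:
            # identify offending columns greedily by pivoted QR
            _, _, piv = _pivoted_qr(design.scores, pivoting=True,
                                    mode="economic")
            bad = sorted(piv[rank:].tolist())
            raise ValueError(f"rank-deficient design: dependent columns {bad}")
        self.design = design
        self.target = y

    def fit(self) -> "PmiStatsRegressionResults":
        X = sm_api.add_constant(self.design.scores)
        res = sm_api.OLS(self.target, X).fit()
        return PmiStatsRegressionResults(self, res)


class PmiStatsRegressionResults:
    """Fitted PMI regression: coefficients, R^2, and LMG group contributions."""

    def __init__(self, model: PmiStatsRegression, sm_results):
        self.model = model
        self._sm = sm_results
        self.params = np.asarray(sm_results.params)
        self.rsquared = float(sm_results.rsquared)
        self.fittedvalues = np.asarray(sm_results.fittedvalues)

    def lmg(self) -> dict[str, float]:
        """Percent of full-model R^2 attributed to each group (sums to 100)."""
        return lmg_contributions(self.model.design, self.model.target)

    def summary(self):
        return self._sm.summary()


def fit_pmi_regression(design: StatDesignMatrix, pmi_per_pair: np.ndarray
                       ) -> PmiStatsRegressionResults:
    return PmiStatsRegression(design, pmi_per_pair).fit()


def lmg_contributions(design: StatDesignMatrix, target: np.ndarray,
                      as_percent: bool = True) -> dict[str, float]:
    """Averaging-over-orderings (LMG) decomposition of the full-model R^2.

    The contribution of group g is the average, over all G! orders in which
    the groups can enter the model, of the R^2 increase when g enters.  It
    is computed exactly through the subset identity: the increment of g
    given a preceding subset T appears in |T|!(G-1-|T|)! orderings, so

        lmg(g) = sum_T |T|! (G-1-|T|)! / G! * (R2(T+g) - R2(T)),

    with T ranging over subsets of the other groups.  Cost is 2^G subset
    fits; refused for G > 12.
    """
    y = np.asarray(target, dtype=float)
    groups = [g for g in design.groups
              if design.group_spans[g][1] > design.group_spans[g][0]]
    G = len(groups)
    if G > 12:
        raise ValueError(f"{G} groups: exact enumeration over 2^G subsets refused")
    col_idx = {g: np.arange(*design.group_spans[g]) for g in groups}
    X = design.scores

    r2_cache: dict[frozenset, float] = {}

    def r2_of(subset: frozenset) -> float:
        if subset not in r2_cache:
            cols = (np.concatenate([col_idx[g] for g in subset])
                    if subset else np.array([], dtype=int))
            r2_cache[subset] = _subset_r2(X, y, cols)
        return r2_cache[subset]

    fact = [math.factorial(i) for i in range(G + 1)]
    contrib = {}
    for g in groups:
        others = [h for h in groups if h != g]
        total = 0.0
        for r in range(len(others) + 1):
            w = fact[r] * fact[G - 1 - r] / fact[G]
            for T in itertools.combinations(others, r):
                s = frozenset(T)
                total += w * (r2_of(s | {g}) - r2_of(s))
        contrib[g] = total
    full = r2_of(frozenset(groups))
    if as_percent:
        if full == 0:
            return {g: 0.0 for g in groups}
        return {g: 100.0 * c / full for g, c in contrib.items()}
    return contrib


# ---------------------------------------------------------------------------
# CM-vs-SM per-group statistic correlation
# ---------------------------------------------------------------------------

def group_correlation_cm_sm(corpus: StimulusCorpus,
                            bank: FilterBank | None = None,
                            var_threshold: float = 0.9) -> dict[str, dict]:
    """Per-group correlation of statistics between paired CM and SM images.

    Statistics of all CM and all SM images are pooled, transformed, and
    projected onto principal components fitted on the pooled set; the
    correlation between the paired CM and SM first-component scores is
    reported per group, together with the scatter coordinates.

    On phase-scramble corpora the position groups correlate strongly (those
    correlations are insensitive to phase shuffling) while the cross-scale
    groups do not (each scale's Fourier components are re-phased
    independently).
    """
    if len(corpus) < 10:
        raise ValueError("need at least 10 pairs")
    bank = bank or FilterBank()
    n = len(corpus)
    images = corpus.cm_images() + corpus.sm_images()
    raw, spans, _ = stats_matrix(images, bank)
    z, rec = signed_sqrt_zscore(raw)
    design = groupwise_pca(z, _remap_spans(spans, rec.kept), rec,
                           var_threshold)
    out = {}
    for g in design.groups:
        a, b = design.group_spans[g]
        if b == a:
            out[g] = {"r": float("nan"), "degenerate": True}
            continue
        cm_s = design.scores[:n, a]
        sm_s = design.scores[n:, a]
        degen = cm_s.std() == 0 or sm_s.std() == 0
        r = 0.0 if degen else float(np.corrcoef(cm_s, sm_s)[0, 1])
        out[g] = {"r": r, "degenerate": bool(degen),
                  "cm_scores": cm_s, "sm_scores": sm_s}
    return out
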