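"""Per-unit and population metrics: modulation index, PMI, sparseness.

The modulation index of a unit over a set of CM-SM stimulus pairs is the
mean of (r_cm - r_sm)/(r_cm + r_sm) across pairs, skipping pairs to which
the unit responded with exactly zero on both members; a unit that responds
to no stimulus at all is excluded outright.  The population modulation
index (PMI) is the mean index over non-excluded units.  Sparseness comes in
four flavours: lifetime sparseness S = 1 - (E[r])^2 / E[r^2] across
stimuli, the non-firing fraction, lifetime kurtosis (fourth standardized
moment, not excess), and population sparseness (the lifetime formula taken
across units for a fixed stimulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import StimulusCorpus

__all__ = [
    "ResponseMatrix",
    "ModulationResult",
    "extract_responses",
    "modulation_index",
    "modulation_indices",
    "compute_modulation",
    "pmi",
    "lifetime_sparseness",
    "nonfiring_sparseness",
    "lifetime_kurtosis",
    "population_sparseness",
    "normalize_per_unit",
]


@dataclass
class ResponseMatrix:
    """Nonnegative units x stimuli responses with pair/family metadata.

    Columns are ordered all-CM then all-SM: pair p occupies columns
    (p, n_pairs + p).
    """

    responses: np.ndarray                # (units, 2 * n_pairs)
    family_ids: np.ndarray               # (n_pairs,)
    layer: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.family_ids = np.asarray(self.family_ids, dtype=int)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-D")
        if self.responses.shape[1] != 2 * len(self.family_ids):
            raise ValueError(
                f"{self.responses.shape[1]} columns for "
                f"{len(self.family_ids)} pairs")
        if not np.isfinite(self.responses).all():
            raise ValueError("responses contain non-finite entries")
        if (self.responses < 0).any():
            raise ValueError("responses must be nonnegative")

    @property
    def n_units(self) -> int:
        return self.responses.shape[0]

    @property
    def n_pairs(self) -> int:
        return len(self.family_ids)

    @property
    def cm(self) -> np.ndarray:
        return self.responses[:, :self.n_pairs]

    @property
    def sm(self) -> np.ndarray:
        return self.responses[:, self.n_pairs:]

    def swapped_roles(self) -> "ResponseMatrix":
        return ResponseMatrix(
            responses=np.hstack([self.sm, self.cm]),
            family_ids=self.family_ids, layer=self.layer,
            provenance=dict(self.provenance, roles_swapped=True))


def extract_responses(results, corpus: StimulusCorpus, big_layer: int,
                      layer_label: str | None = None) -> ResponseMatrix:
    """Record flattened big-layer responses to every stimulus in the corpus.

    ``results`` is a trained ``ShmaxResults``; every CM and SM image is
    pushed through the network and the big layer's final maps are flattened
    into one column per stimulus (all CM first, then all SM).
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    images = corpus.cm_images() + corpus.sm_images()
    out = results.forward_batch(images)
    if big_layer >= len(out["big"]):
        raise ValueError(f"big layer {big_layer} has no outputs")
    R = np.column_stack([fm.ravel() for fm in out["big"][big_layer]])
    return ResponseMatrix(
        responses=R, family_ids=corpus.family_ids,
        layer=layer_label or f"BIG{big_layer + 1}",
        provenance={"model": "shmax",
                    "seed": results.info.get("seed")})


def extract_all_big_layers(results, corpus: StimulusCorpus
                           ) -> list[ResponseMatrix]:
    """One ResponseMatrix per big layer, from a single batched forward pass."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    images = corpus.cm_images() + corpus.sm_images()
    out = results.forward_batch(images)
    mats = []
    for b, maps in enumerate(out["big"]):
        R = np.column_stack([fm.ravel() for fm in maps])
        mats.append(ResponseMatrix(
            responses=R, family_ids=corpus.family_ids,
            layer=f"BIG{b + 1}",
            provenance={"model": "shmax", "seed": results.info.get("seed")}))
    return mats


def extract_set_responses(results, corpus: StimulusCorpus) -> dict:
    """Per-set (a, b, c) response matrices for a two-path model."""
    images = corpus.cm_images() + corpus.sm_images()
    out = results.forward_batch(images)
    return {
        name: ResponseMatrix(
            responses=np.column_stack([fm.ravel()
                                       for fm in out["sets"][name]]),
            family_ids=corpus.family_ids, layer=f"set_{name}")
        for name in ("a", "b", "c")
    }


# ---------------------------------------------------------------------------
# Modulation
# ---------------------------------------------------------------------------

def modulation_index(unit_cm: np.ndarray, unit_sm: np.ndarray
                     ) -> tuple[float, int]:
    """Mean of (cm - sm)/(cm + sm) over valid pairs for one unit.

    Returns (index, n_valid_pairs); a unit with no valid pair (it never
    responded) is excluded and returns (nan, 0).
    """
    a = np.asarray(unit_cm, dtype=float)
    b = np.asarray(unit_sm, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    tot = a + b
    valid = tot > 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        return float("nan"), 0
    idx = float(((a[valid] - b[valid]) / tot[valid]).mean())
    return idx, n_valid


def modulation_indices(R: ResponseMatrix,
                       pair_mask: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-unit modulation indices.

    Returns (indices, n_valid); excluded units carry nan.  ``pair_mask``
    optionally restricts to a subset of pairs (e.g. one family).
    """
    a, b = R.cm, R.sm
    if pair_mask is not None:
        a, b = a[:, pair_mask], b[:, pair_mask]
    tot = a + b
    valid = tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        per_pair = np.where(valid, (a - b) / np.where(valid, tot, 1.0), 0.0)
    n_valid = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        idx = per_pair.sum(axis=1) / n_valid
    idx[n_valid == 0] = np.nan
    return idx, n_valid


@dataclass
class ModulationResult:
    indices: np.ndarray          # per-unit index, nan where excluded
    n_valid: np.ndarray          # valid pairs per unit
    family_pmi: dict[int, float]
    overall_pmi: float

    @property
    def n_excluded(self) -> int:
        return int(np.isnan(self.indices).sum())


def compute_modulation(R: ResponseMatrix) -> ModulationResult:
    """Per-unit indices, per-family PMIs, and the overall PMI."""
    idx, n_valid = modulation_indices(R)
    fam_pmi = {}
    for fam in np.unique(R.family_ids):
        fi, _ = modulation_indices(R, pair_mask=R.family_ids == fam)
        fam_pmi[int(fam)] = (float(np.nanmean(fi))
                             if not np.isnan(fi).all() else float("nan"))
    overall = float(np.nanmean(idx)) if not np.isnan(idx).all() else float("nan")
    return ModulationResult(indices=idx, n_valid=n_valid,
                            family_pmi=fam_pmi, overall_pmi=overall)


def pmi(mod: ModulationResult, family: int | None = None) -> float:
    """Population modulation index: mean index over non-excluded units."""
    if family is not None:
        val = mod.family_pmi.get(int(family))
        if val is None:
            raise ValueError(f"no family {family}")
        return val
    if np.isnan(mod.indices).all():
        raise ValueError("all units excluded; PMI undefined")
    return mod.overall_pmi


def per_pair_pmi(R: ResponseMatrix) -> np.ndarray:
    """For each pair, the mean of (cm - sm)/(cm + sm) over responsive units.

    This is the pair-resolved counterpart of the PMI and the regression
    target when fitting modulation with image statistics.
    """
    a, b = R.cm, R.sm
    tot = a + b
    valid = tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        per = np.where(valid, (a - b) / np.where(valid, tot, 1.0), 0.0)
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = per.sum(axis=0) / n
    out[n == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# Sparseness
# ---------------------------------------------------------------------------

def lifetime_sparseness(responses: np.ndarray) -> float:
    """S = 1 - (E[r])^2 / E[r^2] across stimuli; in [0, 1).

    0 for a constant response, 1 - 1/n for a one-hot response over n
    stimuli.  All-zero responses leave S undefined (nan).
    """
    r = np.asarray(responses, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 stimuli")
    m2 = (r ** 2).mean()
    if m2 == 0:
        return float("nan")
    return float(1.0 - r.mean() ** 2 / m2)


def nonfiring_sparseness(responses: np.ndarray,
                         threshold: float = 0.0) -> float:
    """Fraction of stimuli with response <= threshold (default: exact zeros)."""
    r = np.asarray(responses, dtype=float)
    if r.size == 0:
        return float("nan")
    return float((r <= threshold).mean())


def lifetime_kurtosis(responses: np.ndarray) -> float:
    """Fourth standardized moment E[(r - mu)^4] / sigma^4 (not excess)."""
    r = np.asarray(responses, dtype=float)
    mu = r.mean()
    var = ((r - mu) ** 2).mean()
    if var == 0:
        return float("nan")
    return float(((r - mu) ** 4).mean() / var ** 2)


def population_sparseness(R: ResponseMatrix | np.ndarray,
                          stimulus: int | None = None) -> float:
    """Lifetime formula applied across units for one stimulus.

    With no stimulus given, returns the mean over all stimuli (the corpus
    summary).  Scale-invariant in the stimulus column.
    """
    resp = R.responses if isinstance(R, ResponseMatrix) else np.asarray(R)
    if resp.shape[0] < 2:
        raise ValueError("need at least 2 units")
    if stimulus is not None:
        return lifetime_sparseness(resp[:, stimulus])
    vals = np.array([lifetime_sparseness(resp[:, j])
                     for j in range(resp.shape[1])])
    if np.isnan(vals).all():
        return float("nan")
    return float(np.nanmean(vals))


def unit_sparseness_table(R: ResponseMatrix) -> dict[str, np.ndarray]:
    """Per-unit lifetime/non-firing/kurtosis over the full stimulus set."""
    resp = R.responses
    return {
        "lifetime": np.array([lifetime_sparseness(r) for r in resp]),
        "nonfiring": np.array([nonfiring_sparseness(r) for r in resp]),
        "kurtosis": np.array([lifetime_kurtosis(r) for r in resp]),
    }


def normalize_per_unit(R: ResponseMatrix) -> tuple[ResponseMatrix, np.ndarray]:
    """Scale each unit's row to max 1; zero rows pass through, flagged."""
    resp = R.responses.copy()
    mx = resp.max(axis=1)
    zero_rows = mx == 0
    scale = np.where(zero_rows, 1.0, mx)
    resp /= scale[:, None]
    out = ResponseMatrix(responses=resp, family_ids=R.family_ids,
                         layer=R.layer,
                         provenance=dict(R.provenance, normalized=True))
    return out, zero_rows


def sample_stimuli(R: ResponseMatrix, n: int = 2000, seed: int = 0
                   ) -> np.ndarray:
    """Seeded draw of stimulus columns for sparseness estimation.

    Emulates evaluating sparseness on a fixed-size random stimulus sample;
    sampling is without replacement when the corpus is large enough, with
    replacement otherwise.
    """
    rng = np.random.default_rng(seed)
    total = R.responses.shape[1]
    cols = rng.choice(total, size=n, replace=total < n)
    return R.responses[:, cols]
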