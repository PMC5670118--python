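"""Synthetic response matrices with known modulation and sparseness.

Every metric and statistical test in this package is exercised on
generated unit-response data with known ground truth, so nothing needs a
trained network.  Per unit u with true modulation m_u in (-1, 1), CM-role
responses are drawn i.i.d. Gamma with mean scale*(1 + m_u) and SM-role
responses with mean scale*(1 - m_u) (shared shape parameter, default 2 —
a nonnegative, right-skewed response family); zeros are then imposed by
independent thinning at the unit's non-firing probability, which makes the
non-firing fraction exactly the configured probability in expectation.

``gen_tornado`` reproduces the characteristic sparseness-modulation
scatter of trained hierarchical models: units with higher sparseness draw
their modulation from a wider, positively skewed band ("tornado" shape),
units with low sparseness sit in a narrow band around zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import ResponseMatrix

__all__ = ["ResponseGenConfig", "GroundTruth", "gen_response_matrix",
           "gen_tornado"]


@dataclass
class ResponseGenConfig:
    """Knobs of the response generator.

    mod_mean, mod_spread : float
        Mean and s.d. of the per-unit true modulation (clipped to
        (-0.95, 0.95)).
    skew_weight : float in [0, 1]
        Probability that a unit's modulation is drawn from the positive
        half-normal component instead of the symmetric one.
    nonfiring_range : (lo, hi), each in [0, 1]
        Per-unit non-firing probability, uniform in this range.
    tornado_coupling : float >= 0
        How strongly the modulation spread grows with the unit's
        non-firing probability (0 = independent).
    scale, scale_sigma : float
        Log-normal response-scale distribution across units.
    gamma_shape : float
        Shape of the response Gamma family.
    """

    n_units: int = 1000
    n_pairs: int = 40
    mod_mean: float = 0.0
    mod_spread: float = 0.2
    skew_weight: float = 0.0
    nonfiring_range: tuple[float, float] = (0.0, 0.5)
    tornado_coupling: float = 0.0
    scale: float = 1.0
    scale_sigma: float = 0.25
    gamma_shape: float = 2.0
    seed: int = 0
    m_values: np.ndarray | None = field(default=None, repr=False)
    nonfiring_values: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.n_units < 1 or self.n_pairs < 1:
            raise ValueError("n_units and n_pairs must be >= 1")
        lo, hi = self.nonfiring_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"nonfiring_range must be within [0,1], "
                             f"got {self.nonfiring_range}")
        if not 0.0 <= self.skew_weight <= 1.0:
            raise ValueError("skew_weight must be in [0, 1]")
        if self.tornado_coupling < 0:
            raise ValueError("tornado_coupling must be >= 0")
        if self.gamma_shape <= 0 or self.scale <= 0:
            raise ValueError("gamma_shape and scale must be > 0")
        for name in ("m_values", "nonfiring_values"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_units:
                raise ValueError(f"{name} must have length n_units")


@dataclass
class GroundTruth:
    """Per-unit generating parameters, aligned with the response rows."""

    m: np.ndarray                 # true modulation in (-1, 1)
    nonfiring: np.ndarray         # true non-firing probability
    scale: np.ndarray             # generating response scale


def _draw_responses(cfg: ResponseGenConfig, m: np.ndarray, q: np.ndarray,
                    rng: np.random.Generator
                    ) -> tuple[ResponseMatrix, GroundTruth]:
    U, P = cfg.n_units, cfg.n_pairs
    scale = cfg.scale * np.exp(
        cfg.scale_sigma * rng.standard_normal(U) - cfg.scale_sigma ** 2 / 2)
    k = cfg.gamma_shape
    mu_cm = (scale * (1.0 + m))[:, None]
    mu_sm = (scale * (1.0 - m))[:, None]
    cm = rng.gamma(k, mu_cm / k, size=(U, P))
    sm = rng.gamma(k, mu_sm / k, size=(U, P))
    keep_cm = rng.random((U, P)) >= q[:, None]
    keep_sm = rng.random((U, P)) >= q[:, None]
    R = ResponseMatrix(
        responses=np.hstack([cm * keep_cm, sm * keep_sm]),
        family_ids=np.ones(P, dtype=int),
        layer="synthetic",
        provenance={"generator": "gamma-thinning", "seed": cfg.seed,
                    "gamma_shape": k})
    return R, GroundTruth(m=m, nonfiring=q, scale=scale)


def gen_response_matrix(cfg: ResponseGenConfig
                        ) -> tuple[ResponseMatrix, GroundTruth]:
    """Generate (units x stimuli) responses with known ground truth.

    In the no-thinning limit the expected per-pair ratio statistic
    (cm - sm)/(cm + sm) is close to — but not exactly — m_u; recovery
    tests should compare against a Monte-Carlo evaluation of the ratio.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    U = cfg.n_units
    if cfg.m_values is not None:
        m = np.asarray(cfg.m_values, dtype=float)
    else:
        m = cfg.mod_mean + cfg.mod_spread * rng.standard_normal(U)
        if cfg.skew_weight > 0:
            flip = rng.random(U) < cfg.skew_weight
            m[flip] = np.abs(cfg.mod_spread * rng.standard_normal(U)[flip])
    m = np.clip(m, -0.95, 0.95)
    if cfg.nonfiring_values is not None:
        q = np.asarray(cfg.nonfiring_values, dtype=float)
    else:
        lo, hi = cfg.nonfiring_range
        q = rng.uniform(lo, hi, size=U)
    return _draw_responses(cfg, m, q, rng)


def gen_tornado(cfg: ResponseGenConfig) -> tuple[ResponseMatrix, GroundTruth]:
    """Generate the skewed sparseness-modulation coupling.

    Per unit, a non-firing probability q_u is drawn from
    ``nonfiring_range``; the modulation band half-width grows with q_u at
    rate ``tornado_coupling`` on top of ``mod_spread``, and with
    probability ``skew_weight`` the draw is folded to the positive side.
    Coupling 0 makes the spread independent of sparseness.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    U = cfg.n_units
    lo, hi = cfg.nonfiring_range
    q = rng.uniform(lo, hi, size=U)
    spread = cfg.mod_spread + cfg.tornado_coupling * q
    m = cfg.mod_mean + spread * rng.standard_normal(U)
    if cfg.skew_weight > 0:
        flip = rng.random(U) < cfg.skew_weight
        m[flip] = np.abs(m[flip])
    m = np.clip(m, -0.95, 0.95)
    return _draw_responses(cfg, m, q, rng)
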