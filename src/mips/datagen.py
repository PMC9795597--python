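"""Synthetic observational data with known causal structure.

The generator draws ten jointly normal covariates, assigns a binary
treatment from a logistic model on the first seven of them, and produces a
continuous outcome from a linear model with a constant additive treatment
effect. Because both potential outcomes are retained, the true average
treatment effect (ATE) is known — the default configuration has
``ATE = -0.4`` — which makes every downstream estimator testable without any
external data.

Default treatment model (logit scale)::

    logit P(A=1|X) = alpha0 + 0.16 X1 - 0.05 X2 + 0.12 X3 - 0.10 X4
                            - 0.16 X5 - 0.10 X6 + 0.15 X7

with ``alpha0 = 0`` giving ~50% treated and ``alpha0 = -1.1`` giving ~25%.

Default outcome model::

    Y = -3.85 - 0.4 A - 0.8 X1 - 0.36 X2 - 0.73 X3 - 0.2 X4
             + 0.71 X8 - 0.19 X9 + 0.26 X10 + eps,   eps ~ N(0, 1)

Both potential outcomes share one noise draw per subject, so
``Y1 - Y0 = -0.4`` holds exactly row by row; the marginal law of the
observed data is unaffected by this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import ObservedData, PotentialOutcomes

__all__ = [
    "DGPConfig",
    "OutcomeCoefs",
    "TREATMENT_COEFS",
    "identity_corr",
    "exchangeable_corr",
    "ar1_corr",
    "gen_covariates",
    "gen_treatment",
    "gen_outcome",
    "true_ate",
    "simulate",
]

#: Logistic treatment-model slopes on X1..X7 (X8..X10 do not enter).
TREATMENT_COEFS = np.array([0.16, -0.05, 0.12, -0.10, -0.16, -0.10, 0.15])


@dataclass
class OutcomeCoefs:
    """Linear outcome-model coefficients: intercept, treatment effect and a
    slope per covariate column."""

    intercept: float = -3.85
    treatment: float = -0.4
    covariates: np.ndarray = field(
        default_factory=lambda: np.array(
            [-0.8, -0.36, -0.73, -0.2, 0.0, 0.0, 0.0, 0.71, -0.19, 0.26]
        )
    )

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)


def identity_corr(p: int = 10) -> np.ndarray:
    """Independent covariates."""
    return np.eye(p)


def exchangeable_corr(rho: float, p: int = 10) -> np.ndarray:
    """Constant pairwise correlation ``rho``; PD requires
    ``-1/(p-1) < rho < 1``."""
    c = np.full((p, p), float(rho))
    np.fill_diagonal(c, 1.0)
    return c


def ar1_corr(rho: float, p: int = 10) -> np.ndarray:
    """First-order autoregressive correlation ``rho**|i-j|``."""
    idx = np.arange(p)
    return float(rho) ** np.abs(idx[:, None] - idx[None, :])


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("correlation matrix is not positive definite") from None
    return corr


@dataclass
class DGPConfig:
    """Configuration of the data-generating process.

    Parameters
    ----------
    n : int
        Sample size.
    alpha0 : float
        Treatment-model intercept; 0 gives ~50% treated, -1.1 gives ~25%.
    corr : ndarray, optional
        ``p x p`` covariate correlation matrix (unit diagonal, positive
        definite). Defaults to the identity; see :func:`exchangeable_corr`
        and :func:`ar1_corr` for structured alternatives.
    seed : int
        Master seed; fixing it reproduces the dataset bit for bit.
    treat_coefs : ndarray
        Logistic slopes for treatment assignment (default: the seven
        standard slopes above, applied to the first seven covariates).
    outcome_coefs : OutcomeCoefs
        Linear outcome-model coefficients.
    noise_sd : float
        Standard deviation of the outcome noise (default 1).
    """

    n: int
    alpha0: float = 0.0
    corr: np.ndarray | None = None
    seed: int = 0
    treat_coefs: np.ndarray = field(default_factory=lambda: TREATMENT_COEFS.copy())
    outcome_coefs: OutcomeCoefs = field(default_factory=OutcomeCoefs)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.treat_coefs = np.asarray(self.treat_coefs, dtype=float)
        p = len(self.outcome_coefs.covariates)
        if self.corr is None:
            self.corr = identity_corr(p)
        self.corr = _check_corr(self.corr)
        if self.corr.shape[0] != p:
            raise ValueError(
                f"corr is {self.corr.shape[0]}x{self.corr.shape[0]} but the outcome "
                f"model has {p} covariates"
            )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_covariates(cfg: DGPConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` rows of zero-mean, unit-variance multivariate normal
    covariates with correlation ``cfg.corr``."""
    rng = _as_rng(cfg.seed) if rng is None else rng
    p = cfg.corr.shape[0]
    if cfg.n == 0:
        return np.empty((0, p))
    chol = np.linalg.cholesky(cfg.corr)
    return rng.standard_normal((cfg.n, p)) @ chol.T


def gen_treatment(
    x: np.ndarray,
    alpha0: float,
    seed,
    coefs: np.ndarray | None = None,
) -> np.ndarray:
    """Assign treatment ``A_i ~ Bernoulli(expit(alpha0 + c^T X_i))``.

    The slope vector ``c`` (default :data:`TREATMENT_COEFS`) applies to the
    leading columns of ``x``; remaining columns do not affect assignment.
    """
    rng = _as_rng(seed)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    coefs = TREATMENT_COEFS if coefs is None else np.asarray(coefs, dtype=float)
    if x.shape[1] < len(coefs):
        raise ValueError(
            f"covariate matrix has {x.shape[1]} columns; treatment model needs "
            f"{len(coefs)}"
        )
    eta = alpha0 + x[:, : len(coefs)] @ coefs
    return (rng.random(x.shape[0]) < expit(eta)).astype(int)


def gen_outcome(
    x: np.ndarray,
    a: np.ndarray,
    seed,
    coefs: OutcomeCoefs | None = None,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, PotentialOutcomes]:
    """Generate the observed outcome and both potential outcomes.

    A single noise draw per subject enters ``Y1`` and ``Y0``, so the
    individual effect ``Y1_i - Y0_i`` equals the treatment coefficient
    exactly for every subject.
    """
    rng = _as_rng(seed)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    a = np.asarray(a)
    coefs = OutcomeCoefs() if coefs is None else coefs
    if x.shape[0] != a.shape[0]:
        raise ValueError("x and a have different numbers of rows")
    if x.shape[1] < len(coefs.covariates):
        raise ValueError(
            f"covariate matrix has {x.shape[1]} columns; outcome model needs "
            f"{len(coefs.covariates)}"
        )
    eps = noise_sd * rng.standard_normal(x.shape[0])
    base = coefs.intercept + x[:, : len(coefs.covariates)] @ coefs.covariates + eps
    po = PotentialOutcomes(y1=base + coefs.treatment, y0=base)
    return po.observed(a), po


def true_ate(cfg: DGPConfig) -> float:
    """Analytic ATE of the configured process.

    With no treatment-covariate interaction the ATE is the outcome model's
    treatment coefficient (-0.4 under the defaults).
    """
    return float(cfg.outcome_coefs.treatment)


def simulate(
    cfg: DGPConfig, keep_potential: bool = True
) -> tuple[ObservedData, PotentialOutcomes | None]:
    """Run the full generative chain: covariates -> treatment -> outcome.

    Independent child streams are derived from ``cfg.seed`` for each stage,
    so e.g. changing ``alpha0`` does not perturb the covariate draw.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    x = gen_covariates(cfg, rng=np.random.default_rng(children[0]))
    a = gen_treatment(x, cfg.alpha0, np.random.default_rng(children[1]), cfg.treat_coefs)
    y, po = gen_outcome(
        x, a, np.random.default_rng(children[2]), cfg.outcome_coefs, cfg.noise_sd
    )
    data = ObservedData(y=y, a=a, x=x)
    return data, (po if keep_potential else None)
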