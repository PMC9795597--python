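"""Bootstrap standard errors and Wald confidence intervals.

The bootstrap resamples subjects with replacement, re-runs the *entire*
estimation pipeline on each resample — candidate models refitted, network
retrained with a resample-specific seed — and reports the sample standard
deviation of the resampled estimates. Resamples in which the treatment is
single-class (or the estimator fails) are redrawn and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import ObservedData

__all__ = ["BootstrapConfig", "bootstrap_estimates", "bootstrap_se", "wald_ci"]


@dataclass
class BootstrapConfig:
    """Resampling settings.

    ``b`` defaults to 100 (the usual choice for simulation studies; use ~500
    for a single applied analysis). Per-resample seeds are a pure function of
    ``(seed, resample index)``, so any single resample can be reproduced in
    isolation.
    """

    b: int = 100
    seed: int = 0
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if self.b < 2:
            raise ValueError("bootstrap needs at least 2 resamples")
        if self.max_redraws < 0:
            raise ValueError("max_redraws must be non-negative")


def _resample_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def bootstrap_estimates(
    data: ObservedData,
    estimate_fn,
    cfg: BootstrapConfig | None = None,
) -> tuple[np.ndarray, int]:
    """Return the B resampled estimates and the redraw count.

    ``estimate_fn(resampled_data, seed)`` must run the full pipeline and
    return a float; ``seed`` is a derived integer the caller should thread
    into any internal randomness (e.g. network initialization).
    """
    cfg = BootstrapConfig() if cfg is None else cfg
    n = data.n
    estimates = np.empty(cfg.b)
    redraws = 0
    for i in range(cfg.b):
        attempt = 0
        while True:
            rng = _resample_rng(cfg.seed, i * (cfg.max_redraws + 1) + attempt)
            idx = rng.integers(0, n, size=n)
            sub = ObservedData(
                y=data.y[idx], a=data.a[idx], x=data.x[idx], columns=data.columns
            )
            if len(np.unique(sub.a)) < 2:
                redraws += 1
            else:
                seed = int(rng.integers(0, 2**31 - 1))
                try:
                    estimates[i] = estimate_fn(sub, seed)
                    break
                except Exception:
                    redraws += 1
            attempt += 1
            if attempt > cfg.max_redraws:
                raise RuntimeError(
                    f"resample {i}: exceeded {cfg.max_redraws} redraws"
                )
    return estimates, redraws


def bootstrap_se(
    data: ObservedData,
    estimate_fn,
    cfg: BootstrapConfig | None = None,
) -> float:
    """Bootstrap standard error (denominator B - 1) of the full pipeline."""
    estimates, _ = bootstrap_estimates(data, estimate_fn, cfg)
    return float(np.std(estimates, ddof=1))


def wald_ci(
    estimate: float, se: float, level: float = 0.95, z: float | None = None
) -> tuple[float, float]:
    """Wald interval ``estimate +/- z * se``.

    For the 95% level the conventional two-decimal multiplier 1.96 is used
    (matching standard reporting arithmetic); other levels use the exact
    normal quantile. Pass ``z`` to override.
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if z is None:
        z = 1.96 if abs(level - 0.95) < 1e-12 else float(norm.ppf(0.5 + level / 2))
    return (estimate - z * se, estimate + z * se)
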