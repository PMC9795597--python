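"""Monte Carlo evaluation of the estimators.

:func:`run_study` repeats the generate/estimate cycle and summarizes each
configured estimator with the five standard metrics:

* **BIAS%** — 100 * (mean(estimates) - truth) / truth
* **RMSE** — root mean squared error about the truth
* **MC-SE** — Monte Carlo standard error, the sample SD of the estimates
* **BS-SE** — mean bootstrap standard error (when bootstrapping is enabled)
* **CI-Cov%** — percentage of replications whose 95% Wald interval
  (point +/- 1.96 * bootstrap SE) covers the truth

The identity ``RMSE^2 = (abs bias)^2 + MC-SE^2 * (R-1)/R`` links the first
three and holds exactly on every output row. Replication seeds are derived
from the master seed by a counter scheme, so any single replication can be
reproduced on its own and the result does not depend on the worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import DGPConfig, simulate, true_ate
from .estimators import estimate_ate, specs_from_bitmask
from .inference import BootstrapConfig, bootstrap_se
from .scoring import ANNConfig, KernelConfig

__all__ = ["EstimatorConfig", "StudyConfig", "compute_metrics", "run_study"]


@dataclass(frozen=True)
class EstimatorConfig:
    """One estimator to evaluate: a method plus its candidate-model bitmask."""

    method: str
    bitmask: str | None = None
    label: str | None = None

    def resolved_label(self) -> str:
        if self.label:
            return self.label
        from .estimators import _LABELS

        lab = _LABELS[self.method]
        return f"{lab}-{self.bitmask}" if self.bitmask else lab


@dataclass
class StudyConfig:
    """Configuration of a Monte Carlo study."""

    dgp: DGPConfig
    replications: int = 100
    estimators: list[EstimatorConfig] = field(default_factory=list)
    bootstrap: BootstrapConfig | None = None
    kernel: KernelConfig | None = None
    ann: ANNConfig | None = None
    seed: int = 0
    workers: int = 1
    max_failure_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not self.estimators:
            raise ValueError("estimator list must be non-empty")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


def compute_metrics(
    estimates: np.ndarray,
    ses: np.ndarray | None,
    truth: float,
) -> dict:
    """The five-metric summary row for one estimator.

    ``ses`` may be None (bootstrap disabled), in which case BS-SE and
    CI-Cov are reported as NaN. Raises if the truth is zero, since relative
    bias is then undefined.
    """
    estimates = np.asarray(estimates, dtype=float)
    r = estimates.size
    if r < 1:
        raise ValueError("need at least one estimate")
    if truth == 0:
        raise ValueError("relative bias is undefined when the true effect is 0")
    mean = estimates.mean()
    bias_pct = 100.0 * (mean - truth) / truth
    rmse = float(np.sqrt(np.mean((estimates - truth) ** 2)))
    mc_se = float(np.std(estimates, ddof=1)) if r > 1 else 0.0
    if ses is not None:
        ses = np.asarray(ses, dtype=float)
        if ses.shape != estimates.shape:
            raise ValueError("estimates and ses must have equal lengths")
        if np.any(ses < 0):
            raise ValueError("standard errors must be non-negative")
        bs_se = float(ses.mean())
        covered = np.abs(estimates - truth) <= 1.96 * ses
        ci_cov = 100.0 * float(covered.mean())
    else:
        bs_se = float("nan")
        ci_cov = float("nan")
    return {
        "BIAS%": float(bias_pct),
        "RMSE": rmse,
        "MC-SE": mc_se,
        "BS-SE": bs_se,
        "CI-Cov%": ci_cov,
    }


def _rep_seed(master: int, rep: int, stream: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(rep, stream))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _one_replication(cfg: StudyConfig, rep: int) -> dict:
    """Dataset + every configured estimator (and optional bootstrap SE)."""
    dgp = DGPConfig(
        n=cfg.dgp.n,
        alpha0=cfg.dgp.alpha0,
        corr=cfg.dgp.corr,
        seed=_rep_seed(cfg.seed, rep, 0),
        treat_coefs=cfg.dgp.treat_coefs,
        outcome_coefs=cfg.dgp.outcome_coefs,
        noise_sd=cfg.dgp.noise_sd,
    )
    data, _ = simulate(dgp, keep_potential=False)
    out: dict = {}
    for j, est in enumerate(cfg.estimators):
        ps_specs, or_specs = ([], [])
        if est.bitmask:
            ps_specs, or_specs = specs_from_bitmask(est.bitmask)
        ann_seed = _rep_seed(cfg.seed, rep, 10 + j)
        try:
            point = estimate_ate(
                data,
                ps_specs=ps_specs,
                or_specs=or_specs,
                method=est.method,
                kernel=cfg.kernel,
                ann=cfg.ann,
                seed=ann_seed,
            ).estimate
        except Exception as exc:
            out[est.resolved_label()] = (np.nan, np.nan, str(exc))
            continue
        se = np.nan
        if cfg.bootstrap is not None:
            boot = BootstrapConfig(
                b=cfg.bootstrap.b,
                seed=_rep_seed(cfg.seed, rep, 100 + j),
                max_redraws=cfg.bootstrap.max_redraws,
            )

            def fn(d, s, _ps=ps_specs, _or=or_specs, _m=est.method):
                return estimate_ate(
                    d, ps_specs=_ps, or_specs=_or, method=_m,
                    kernel=cfg.kernel, ann=cfg.ann, seed=s,
                ).estimate

            se = bootstrap_se(data, fn, boot)
        out[est.resolved_label()] = (point, se, "")
    return out


def run_study(cfg: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run the Monte Carlo study and return one metrics row per estimator.

    Failed replications are excluded from that estimator's metrics and
    counted in ``n_failed``; the study aborts only if an estimator's failure
    rate exceeds ``cfg.max_failure_rate``.
    """
    reps = range(cfg.replications)
    if cfg.workers > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=cfg.workers)(
            delayed(_one_replication)(cfg, r) for r in reps
        )
    else:
        rows = []
        for r in reps:
            rows.append(_one_replication(cfg, r))
            if progress and (r + 1) % 10 == 0:
                print(f"  replication {r + 1}/{cfg.replications}")

    truth = true_ate(cfg.dgp)
    records = []
    for est in cfg.estimators:
        lab = est.resolved_label()
        points = np.array([row[lab][0] for row in rows])
        ses = np.array([row[lab][1] for row in rows])
        ok = np.isfinite(points)
        n_failed = int((~ok).sum())
        if n_failed > cfg.max_failure_rate * cfg.replications:
            raise RuntimeError(
                f"{lab}: {n_failed}/{cfg.replications} replications failed"
            )
        use_ses = ses[ok] if cfg.bootstrap is not None else None
        metrics = compute_metrics(points[ok], use_ses, truth)
        records.append({"Estimator": lab, **metrics, "n_failed": n_failed})
    return pd.DataFrame.from_records(records)
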