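"""Model / Results interface for ATE estimation.

The entry point for applied use is :class:`ATEModel`: construct it from an
:class:`~mips.data.ObservedData` (or a DataFrame) together with the
candidate model specifications, call :meth:`ATEModel.fit`, and read the
estimate, its bootstrap standard error and the Wald interval off the
returned :class:`ATEResults`.

Example
-------
>>> from mips import ATEModel, DGPConfig, simulate, specs_from_bitmask
>>> data, _ = simulate(DGPConfig(n=500, seed=1))
>>> ps, orm = specs_from_bitmask("1010")
>>> res = ATEModel(data, ps_specs=ps, or_specs=orm, method="ann_mips").fit(seed=1)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .candidates import ModelSpec
from .data import ObservedData
from .estimators import ATEEstimate, estimate_ate
from .inference import BootstrapConfig, bootstrap_estimates, wald_ci
from .scoring import ANNConfig, KernelConfig

__all__ = ["ATEModel", "ATEResults"]


class ATEModel:
    """Average-treatment-effect model for one estimator configuration.

    Parameters
    ----------
    data : ObservedData
        The observational sample.
    ps_specs, or_specs : lists of ModelSpec
        Candidate propensity-score / outcome-regression models.
    method : str
        One of ``ipw``, ``or``, ``aipw``, ``ker_mips``, ``ann_mips``,
        ``ipw_ann``, ``or_ann``.
    kernel, ann : KernelConfig / ANNConfig, optional
        Scorer settings for the multi-index methods.
    """

    def __init__(
        self,
        data: ObservedData,
        ps_specs: list[ModelSpec] | None = None,
        or_specs: list[ModelSpec] | None = None,
        method: str = "ann_mips",
        kernel: KernelConfig | None = None,
        ann: ANNConfig | None = None,
        standardize: bool = True,
        clip_kernel: bool = False,
        label: str | None = None,
    ):
        self.data = data
        self.ps_specs = list(ps_specs or [])
        self.or_specs = list(or_specs or [])
        self.method = method
        self.kernel = kernel
        self.ann = ann
        self.standardize = standardize
        self.clip_kernel = clip_kernel
        self.label = label

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str = "Y",
        treatment: str = "A",
        covariates: list[str] | None = None,
        **kwargs,
    ) -> "ATEModel":
        data = ObservedData.from_dataframe(df, outcome, treatment, covariates)
        return cls(data, **kwargs)

    def _point(self, data: ObservedData, seed: int | None) -> ATEEstimate:
        return estimate_ate(
            data,
            ps_specs=self.ps_specs,
            or_specs=self.or_specs,
            method=self.method,
            kernel=self.kernel,
            ann=self.ann,
            seed=seed,
            standardize=self.standardize,
            clip_kernel=self.clip_kernel,
            label=self.label,
        )

    def fit(
        self,
        bootstrap: BootstrapConfig | int | None = None,
        seed: int | None = None,
        level: float = 0.95,
    ) -> "ATEResults":
        """Estimate the ATE, optionally with bootstrap inference.

        ``bootstrap`` may be a :class:`BootstrapConfig`, an integer number
        of resamples, or None for a point estimate only. ``seed`` drives the
        network initialization (ignored by purely deterministic methods).
        """
        point = self._point(self.data, seed)
        se = ci = None
        boot_estimates = None
        redraws = 0
        if bootstrap is not None:
            if isinstance(bootstrap, int):
                bootstrap = BootstrapConfig(b=bootstrap, seed=seed or 0)
            boot_estimates, redraws = bootstrap_estimates(
                self.data, lambda d, s: self._point(d, s).estimate, bootstrap
            )
            se = float(np.std(boot_estimates, ddof=1))
            ci = wald_ci(point.estimate, se, level)
        return ATEResults(
            model=self,
            estimate=point,
            se=se,
            ci=ci,
            level=level,
            boot_estimates=boot_estimates,
            n_redraws=redraws,
        )


class ATEResults:
    """Fitted results: point estimate, uncertainty and diagnostics."""

    def __init__(
        self,
        model: ATEModel,
        estimate: ATEEstimate,
        se: float | None,
        ci: tuple[float, float] | None,
        level: float,
        boot_estimates: np.ndarray | None = None,
        n_redraws: int = 0,
    ):
        self.model = model
        self._estimate = estimate
        self.se = se
        self.ci = ci
        self.level = level
        self.boot_estimates = boot_estimates
        self.n_redraws = n_redraws

    @property
    def ate(self) -> float:
        return self._estimate.estimate

    # statsmodels-flavored aliases
    @property
    def bse(self) -> float | None:
        return self.se

    @property
    def method_label(self) -> str:
        return self._estimate.label

    @property
    def diagnostics(self) -> dict:
        return self._estimate.diagnostics

    def conf_int(self) -> tuple[float, float] | None:
        return self.ci

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            "Average Treatment Effect Estimation",
            "=" * 46,
            f"{'Estimator:':<22}{self.method_label}",
            f"{'N obs:':<22}{self.model.data.n}",
            f"{'N treated:':<22}{int(self.model.data.a.sum())}",
            f"{'ATE estimate:':<22}{self.ate: .4f}",
        ]
        if self.se is not None:
            lo, hi = self.ci
            lines += [
                f"{'Bootstrap SE:':<22}{self.se: .4f}",
                f"{f'{self.level:.0%} Wald CI:':<22}({lo:.4f}, {hi:.4f})",
                f"{'Resample redraws:':<22}{self.n_redraws}",
            ]
        prop = self._estimate.diagnostics.get("propensity")
        if prop:
            lines.append(
                f"{'Propensity range:':<22}[{prop['min']:.4f}, {prop['max']:.4f}]"
            )
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "estimator": self.method_label,
            "estimate": self.ate,
            "se": self.se,
            "ci": list(self.ci) if self.ci else None,
            "level": self.level,
            "n_redraws": self.n_redraws,
            "diagnostics": self.diagnostics,
        }
        return out

    def plot_propensity(self, ax=None):
        """Histogram of estimated propensities by treatment group
        (multi-index and IPW methods only)."""
        import matplotlib.pyplot as plt

        scores = self.diagnostics.get("scores")
        if scores is None:
            raise ValueError("this estimator does not produce propensity scores")
        if ax is None:
            _, ax = plt.subplots()
        a = self.model.data.a
        bins = np.linspace(0, 1, 31)
        ax.hist(scores[a == 1], bins=bins, alpha=0.6, label="treated")
        ax.hist(scores[a == 0], bins=bins, alpha=0.6, label="control")
        ax.set_xlabel("estimated propensity score")
        ax.set_ylabel("count")
        ax.legend()
        return ax
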