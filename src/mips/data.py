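"""Observed-data container shared by every estimation stage.

An :class:`ObservedData` holds one continuous outcome ``Y``, one binary
treatment indicator ``A`` and an ``n x p`` covariate matrix ``X`` — the unit
of analysis for every estimator in this package. Validation happens at
construction so downstream code can assume a clean, rectangular, missing-free
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ObservedData", "PotentialOutcomes"]


@dataclass
class ObservedData:
    """Outcome, binary treatment and covariates for ``n`` subjects.

    Parameters
    ----------
    y : array-like, shape (n,)
        Continuous outcome.
    a : array-like, shape (n,)
        Treatment indicator, coded 0 (control) / 1 (treated).
    x : array-like, shape (n, p)
        Pre-treatment covariate matrix.
    columns : list of str, optional
        Covariate names; defaults to ``X1..Xp``.
    """

    y: np.ndarray
    a: np.ndarray
    x: np.ndarray
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.a = np.asarray(self.a)
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.x.shape[0] != self.y.shape[0] and self.x.shape[1] == self.y.shape[0]:
            self.x = self.x.T
        n = self.y.shape[0]
        if self.a.shape[0] != n or self.x.shape[0] != n:
            raise ValueError(
                f"length mismatch: y has {n} rows, a has {self.a.shape[0]}, "
                f"x has {self.x.shape[0]}"
            )
        a_vals = np.unique(self.a)
        if not np.all(np.isin(a_vals, (0, 1))):
            bad = [v for v in a_vals if v not in (0, 1)]
            raise ValueError(f"treatment must be coded 0/1; found {bad}")
        self.a = self.a.astype(int)
        for name, arr in (("y", self.y), ("x", self.x)):
            if not np.all(np.isfinite(arr)):
                rows = np.unique(np.argwhere(~np.isfinite(np.atleast_2d(arr.T).T))[:, 0])
                raise ValueError(f"missing/non-finite values in {name} at rows {rows.tolist()}")
        if not self.columns:
            self.columns = [f"X{j + 1}" for j in range(self.x.shape[1])]
        if len(self.columns) != self.x.shape[1]:
            raise ValueError("number of covariate names does not match x")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Return a single covariate column by name."""
        try:
            j = self.columns.index(name)
        except ValueError:
            raise KeyError(f"unknown covariate {name!r}; have {self.columns}") from None
        return self.x[:, j]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str = "Y",
        treatment: str = "A",
        covariates: list[str] | None = None,
    ) -> "ObservedData":
        """Build from a DataFrame; all non-outcome/treatment columns are
        covariates unless ``covariates`` is given."""
        if covariates is None:
            covariates = [c for c in df.columns if c not in (outcome, treatment)]
        missing = [c for c in (outcome, treatment, *covariates) if c not in df.columns]
        if missing:
            raise KeyError(f"columns not in dataframe: {missing}")
        sub = df[[outcome, treatment, *covariates]]
        na_rows = sub.index[sub.isna().any(axis=1)].tolist()
        if na_rows:
            raise ValueError(f"missing values in rows {na_rows}")
        return cls(
            y=sub[outcome].to_numpy(float),
            a=sub[treatment].to_numpy(),
            x=sub[covariates].to_numpy(float),
            columns=list(covariates),
        )

    def to_dataframe(self, outcome: str = "Y", treatment: str = "A") -> pd.DataFrame:
        out = {outcome: self.y, treatment: self.a}
        for j, c in enumerate(self.columns):
            out[c] = self.x[:, j]
        return pd.DataFrame(out)


@dataclass
class PotentialOutcomes:
    """Counterfactual outcome pair retained by the generator for evaluation.

    The consistency identity ``Y = A*Y1 + (1-A)*Y0`` ties these to the
    observed data; it is checked at construction when the observed triple is
    supplied.
    """

    y1: np.ndarray
    y0: np.ndarray

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=float)
        self.y0 = np.asarray(self.y0, dtype=float)
        if self.y1.shape != self.y0.shape:
            raise ValueError("y1 and y0 must have the same length")

    def observed(self, a: np.ndarray) -> np.ndarray:
        """Observed outcome implied by treatment assignment ``a``."""
        a = np.asarray(a)
        return np.where(a == 1, self.y1, self.y0)

    @property
    def ate(self) -> float:
        """Sample average treatment effect ``mean(Y1 - Y0)``."""
        return float(np.mean(self.y1 - self.y0)) if self.y1.size else float("nan")
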