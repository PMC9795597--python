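"""Parametric candidate models and the index columns they induce.

A candidate propensity-score (PS) model is a logistic regression of the
treatment on transformed covariates; a candidate outcome-regression (OR)
model is a linear regression of the outcome on transformed covariates plus
the treatment. Each fitted candidate contributes one *index* — the fitted
linear combination ``slopes^T t(X)`` with intercept and treatment
coefficient dropped — and the collection of indices is the regressor set on
which the multi-index propensity score is built. A candidate need not be
correct: the multiply robust construction only requires that *some*
candidate's index spans the truth.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .data import ObservedData

__all__ = [
    "ModelSpec",
    "FittedIndex",
    "IndexMatrix",
    "fit_ps_model",
    "fit_or_model",
    "build_index_matrix",
]

_TERM_RE = re.compile(r"^([A-Za-z_]\w*)(?:\^(\d+))?$")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a role, a list of covariate transforms, a label.

    Terms are strings like ``"X1"`` or ``"X3^2"`` (column name with an
    optional integer power). PS specs never include the treatment; OR specs
    include it by default.
    """

    role: str  # "ps" | "or"
    terms: tuple[str, ...]
    label: str
    include_treatment: bool = True

    def __init__(self, role, terms, label, include_treatment=True):
        role = str(role).lower()
        if role not in ("ps", "or"):
            raise ValueError(f"role must be 'ps' or 'or', got {role!r}")
        terms = tuple(terms)
        # an OR spec may be intercept+treatment only; PS needs covariates
        if not terms and not (role == "or" and include_treatment):
            raise ValueError("term list must be non-empty")
        for t in terms:
            if not _TERM_RE.match(t):
                raise ValueError(f"malformed term {t!r}; expected e.g. 'X1' or 'X1^2'")
        if role == "ps":
            include_treatment = False
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "label", str(label))
        object.__setattr__(self, "include_treatment", bool(include_treatment))

    def transform(self, data: ObservedData) -> np.ndarray:
        """Evaluate the covariate transforms on observed data, one column
        per term (no intercept, no treatment)."""
        cols = []
        for t in self.terms:
            m = _TERM_RE.match(t)
            col = data.column(m.group(1))
            power = int(m.group(2)) if m.group(2) else 1
            cols.append(col**power)
        return np.column_stack(cols) if cols else np.empty((data.n, 0))


@dataclass
class FittedIndex:
    """A fitted candidate model reduced to its index ingredients."""

    spec: ModelSpec
    intercept: float
    slopes: np.ndarray
    treat_coef: float | None = None
    converged: bool = True
    n_iter: int = 0
    message: str = ""

    def index(self, data: ObservedData) -> np.ndarray:
        """The raw (unstandardized) index ``slopes^T t(X)``."""
        return self.spec.transform(data) @ self.slopes

    def predict_ps(self, data: ObservedData) -> np.ndarray:
        """Fitted treatment probabilities (PS specs only)."""
        if self.spec.role != "ps":
            raise ValueError("predict_ps requires a PS fit")
        from scipy.special import expit

        return expit(self.intercept + self.index(data))

    def predict_outcome(self, data: ObservedData, a) -> np.ndarray:
        """Fitted outcome mean with treatment forced to ``a`` (OR specs)."""
        if self.spec.role != "or":
            raise ValueError("predict_outcome requires an OR fit")
        mu = self.intercept + self.index(data)
        if self.treat_coef is not None:
            mu = mu + self.treat_coef * np.broadcast_to(a, (data.n,))
        return mu


def _check_rank(design: np.ndarray, names: list[str], label: str) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        kept: list[int] = []
        for j in range(design.shape[1]):
            trial = design[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(
            f"design matrix for {label!r} is rank deficient; collinear terms: {bad}"
        )


def fit_ps_model(
    data: ObservedData,
    spec: ModelSpec,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> FittedIndex:
    """Fit a candidate logistic PS model by maximum likelihood.

    Newton/IRLS via statsmodels; convergence requires the score vector's
    max-norm to fall below ``tol``. Quasi-separated or degenerate fits are
    returned with ``converged=False`` rather than raising, so a simulation
    replication can count and skip them.
    """
    if spec.role != "ps":
        raise ValueError(f"spec {spec.label!r} does not have role 'ps'")
    design = spec.transform(data)
    names = list(spec.terms)
    full = np.column_stack([np.ones(data.n), design])
    _check_rank(full, ["const", *names], spec.label)
    if len(np.unique(data.a)) < 2:
        return FittedIndex(
            spec=spec,
            intercept=np.nan,
            slopes=np.full(design.shape[1], np.nan),
            converged=False,
            message="treatment is constant; likelihood is degenerate",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(data.a, full).fit(
                method="newton", maxiter=maxiter, tol=1e-12, disp=0
            )
        except Exception as exc:  # perfect separation, singular Hessian, ...
            return FittedIndex(
                spec=spec,
                intercept=np.nan,
                slopes=np.full(design.shape[1], np.nan),
                converged=False,
                message=f"logistic fit failed: {exc}",
            )
    params = np.asarray(res.params, dtype=float)
    score = np.asarray(res.model.score(params))
    fitted = np.asarray(res.predict())
    # complete separation: fitted probabilities collapse onto the labels
    # while the likelihood is unbounded (coefficients drift outward)
    separated = bool(np.max(np.abs(fitted - data.a)) < 1e-3)
    diverged = np.linalg.norm(params) > 1e3 or separated
    converged = bool(np.max(np.abs(score)) <= tol and np.all(np.isfinite(params)))
    if diverged:
        converged = False
    return FittedIndex(
        spec=spec,
        intercept=float(params[0]),
        slopes=params[1:],
        converged=converged,
        n_iter=int(getattr(res.mle_retvals, "get", lambda *a: 0)("iterations", 0)),
        message="" if converged else "separation suspected (diverging coefficients)"
        if diverged
        else "score did not reach tolerance",
    )


def fit_or_model(
    data: ObservedData,
    spec: ModelSpec,
    by_group: bool = False,
) -> FittedIndex | tuple[FittedIndex, FittedIndex]:
    """Fit a candidate linear OR model by ordinary least squares.

    By default the treatment enters as a regressor (one joint fit, one index
    column). With ``by_group=True`` the model is fitted separately on the
    treated and control subsets — the standard way of accommodating
    treatment-covariate interactions — yielding a pair of fitted indices.
    """
    if spec.role != "or":
        raise ValueError(f"spec {spec.label!r} does not have role 'or'")
    if by_group:
        sub_spec = ModelSpec(
            role="or", terms=spec.terms, label=spec.label, include_treatment=False
        )
        fits = []
        for grp, tag in ((1, "t"), (0, "c")):
            mask = data.a == grp
            sub = ObservedData(
                y=data.y[mask], a=data.a[mask], x=data.x[mask], columns=data.columns
            )
            fit = fit_or_model(sub, sub_spec)
            fit.spec = ModelSpec(
                role="or",
                terms=spec.terms,
                label=f"{spec.label}[{tag}]",
                include_treatment=False,
            )
            fits.append(fit)
        return fits[0], fits[1]

    design = spec.transform(data)
    names = list(spec.terms)
    cols = [np.ones(data.n), design]
    if spec.include_treatment:
        cols.insert(1, data.a.astype(float))
        names = ["A", *names]
    full = np.column_stack(cols)
    n_params = full.shape[1]
    if data.n <= n_params:
        raise ValueError(
            f"{spec.label!r}: n={data.n} observations cannot identify "
            f"{n_params} parameters"
        )
    _check_rank(full, ["const", *names], spec.label)
    res = sm.OLS(data.y, full).fit()
    params = np.asarray(res.params, dtype=float)
    k = 2 if spec.include_treatment else 1
    return FittedIndex(
        spec=spec,
        intercept=float(params[0]),
        slopes=params[k:],
        treat_coef=float(params[1]) if spec.include_treatment else None,
        converged=True,
    )


@dataclass
class IndexMatrix:
    """The ``n x d`` matrix of fitted indices used as MiPS regressors.

    When standardized, the per-column center/scale is recorded so the same
    affine map can be applied to new rows.
    """

    s: np.ndarray
    labels: list[str]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    degenerate: list[str] = field(default_factory=list)
    fits: list[FittedIndex] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.s.shape[0]

    @property
    def d(self) -> int:
        return self.s.shape[1]

    def transform_new(self, data: ObservedData) -> np.ndarray:
        """Index columns for new rows, on the training standardization."""
        raw = np.column_stack([f.index(data) for f in self.fits])
        if self.center is not None:
            raw = (raw - self.center) / self.scale
        return raw


def build_index_matrix(
    data: ObservedData,
    ps_fits: list[FittedIndex],
    or_fits: list[FittedIndex],
    standardize: bool = True,
) -> IndexMatrix:
    """Stack fitted PS and OR indices into the MiPS regressor matrix.

    Columns follow the order PS fits then OR fits. A zero-variance index
    (all-zero slopes, or a constant transform) is replaced by zeros and
    flagged with a warning; duplicate or collinear indices are deliberately
    kept, since robustness to redundant candidates is part of the method's
    contract.
    """
    fits = [*ps_fits, *or_fits]
    if not fits:
        raise ValueError("need at least one fitted candidate model (K + L >= 1)")
    not_conv = [f.spec.label for f in fits if not f.converged]
    if not_conv:
        raise ValueError(f"cannot build indices from non-converged fits: {not_conv}")
    cols = np.column_stack([f.index(data) for f in fits])
    labels = [f.spec.label for f in fits]
    degenerate = []
    sd = cols.std(axis=0, ddof=1) if data.n > 1 else np.zeros(cols.shape[1])
    for j in range(cols.shape[1]):
        if sd[j] == 0 or not np.isfinite(sd[j]):
            degenerate.append(labels[j])
            cols[:, j] = 0.0
            sd[j] = 1.0
    if degenerate:
        warnings.warn(
            f"zero-variance index column(s) {degenerate}; replaced by zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    center = scale = None
    if standardize:
        center = cols.mean(axis=0)
        scale = sd.copy()
        cols = (cols - center) / scale
        for j, lab in enumerate(labels):
            if lab in degenerate:
                cols[:, j] = 0.0
    return IndexMatrix(
        s=cols,
        labels=labels,
        center=center,
        scale=scale,
        degenerate=degenerate,
        fits=fits,
    )
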