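"""Point estimators of the average treatment effect.

All weighting-based estimators share one algebraic core, the Hajek
(self-normalized) inverse-probability-weighted contrast

    Delta_hat = sum_i A_i w_i Y_i / sum_i A_i w_i
              - sum_i (1-A_i) v_i Y_i / sum_i (1-A_i) v_i,

with ``w_i = 1/pi_i`` and ``v_i = 1/(1-pi_i)``. What distinguishes IPW,
the kernel multi-index estimator and the neural-network multi-index
estimator is only where ``pi`` comes from. The outcome-regression (OR)
estimator and the augmented IPW (AIPW) comparator are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .candidates import (
    FittedIndex,
    ModelSpec,
    build_index_matrix,
    fit_or_model,
    fit_ps_model,
)
from .data import ObservedData
from .scoring import ANNConfig, KernelConfig, PropensityVector, nw_mips, predict_mips, train_ann

__all__ = [
    "ATEEstimate",
    "hajek_ipw",
    "or_estimate",
    "aipw_estimate",
    "estimate_ate",
    "simulation_model_sets",
    "specs_from_bitmask",
    "ANN_CLIP",
]

#: Guard clip applied to network propensities before weighting.
ANN_CLIP = 1e-6


@dataclass
class ATEEstimate:
    """A point estimate with its provenance and diagnostics."""

    estimate: float
    label: str
    se: float | None = None
    ci: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci is not None:
            if self.se is None:
                raise ValueError("a CI requires an SE")
            lo, hi = self.ci
            if not (lo <= self.estimate <= hi):
                raise ValueError("estimate must lie inside its CI")


def hajek_ipw(y, a, pi) -> float:
    """Self-normalized IPW contrast of weighted group means.

    ``pi`` may be a :class:`~mips.scoring.PropensityVector` or an array.
    A propensity of exactly 0 on a treated unit or 1 on a control makes the
    required weight infinite and raises; negative or >1 kernel scores are
    allowed through with a warning, since their effect on the estimate is
    part of the kernel estimator's documented pathology.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    scores = pi.scores if isinstance(pi, PropensityVector) else np.asarray(pi, dtype=float)
    if not (y.shape == a.shape == scores.shape):
        raise ValueError("y, a and pi must have equal lengths")
    treated = a == 1
    control = ~treated
    if not treated.any() or not control.any():
        raise ValueError("both treatment groups must be non-empty")
    if np.any(scores[treated] == 0):
        raise ValueError("propensity 0 on a treated unit: weight undefined")
    if np.any(scores[control] == 1):
        raise ValueError("propensity 1 on a control unit: weight undefined")
    n_neg = int(np.sum((scores < 0) | (scores > 1)))
    if n_neg:
        warnings.warn(
            f"{n_neg} propensity score(s) outside [0, 1] used as weights",
            RuntimeWarning,
            stacklevel=2,
        )
    w1 = 1.0 / scores[treated]
    w0 = 1.0 / (1.0 - scores[control])
    s1 = w1.sum()
    s0 = w0.sum()
    if s1 <= 0 or s0 <= 0:
        raise ValueError("weight sums must be positive in both groups")
    return float((w1 @ y[treated]) / s1 - (w0 @ y[control]) / s0)


def or_estimate(data: ObservedData, or_fit) -> float:
    """Outcome-regression estimator: mean of mu1(X_i) - mu0(X_i) over all i.

    For a joint linear fit without interactions this is exactly the fitted
    treatment coefficient. ``or_fit`` may also be the (treated, control)
    pair produced by group-separate fitting, in which case the row-wise
    prediction contrast is averaged.
    """
    if isinstance(or_fit, tuple):
        fit_t, fit_c = or_fit
        mu1 = fit_t.predict_outcome(data, 1)
        mu0 = fit_c.predict_outcome(data, 0)
        return float(np.mean(mu1 - mu0))
    if not or_fit.converged:
        raise ValueError("OR fit did not converge")
    mu1 = or_fit.predict_outcome(data, 1)
    mu0 = or_fit.predict_outcome(data, 0)
    return float(np.mean(mu1 - mu0))


def aipw_estimate(
    data: ObservedData, ps_fit: FittedIndex, or_fit: FittedIndex
) -> float:
    """Augmented IPW (textbook, unnormalized form).

    mean over i of
    ``A Y/pi - (A - pi) mu1/pi`` minus ``(1-A) Y/(1-pi) + (A - pi) mu0/(1-pi)``.
    Doubly robust: consistent if either the PS or the OR candidate is right.
    """
    for fit, what in ((ps_fit, "PS"), (or_fit, "OR")):
        if not fit.converged:
            raise ValueError(f"{what} fit did not converge")
    pi = ps_fit.predict_ps(data)
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("fitted propensities must lie strictly in (0, 1)")
    mu1 = or_fit.predict_outcome(data, 1)
    mu0 = or_fit.predict_outcome(data, 0)
    a = data.a
    y = data.y
    term1 = a * y / pi - (a - pi) * mu1 / pi
    term0 = (1 - a) * y / (1 - pi) + (a - pi) * mu0 / (1 - pi)
    return float(np.mean(term1 - term0))


# --------------------------------------------------------------------------
# Candidate-set presets mirroring the simulation design
# --------------------------------------------------------------------------

_PS_LINEAR = tuple(f"X{j}" for j in range(1, 8))
_PS_SQUARED = tuple(f"X{j}^2" for j in range(1, 8))
_OR_COLS = (1, 2, 3, 4, 8, 9, 10)
_OR_LINEAR = tuple(f"X{j}" for j in _OR_COLS)
_OR_SQUARED = tuple(f"X{j}^2" for j in _OR_COLS)


def simulation_model_sets() -> dict[str, ModelSpec]:
    """The candidate models of the benchmark simulation design.

    ``PS1``/``OR1`` match the data-generating process (correct); ``PS2``/
    ``OR2`` use squared covariates (incorrect functional form). ``PS3``,
    ``PS4``, ``OR3`` and ``OR4`` are the deliberately misspecified
    three-covariate extras used in the redundant-model scenarios.
    """
    return {
        "PS1": ModelSpec("ps", _PS_LINEAR, "PS1"),
        "PS2": ModelSpec("ps", _PS_SQUARED, "PS2"),
        "OR1": ModelSpec("or", _OR_LINEAR, "OR1"),
        "OR2": ModelSpec("or", _OR_SQUARED, "OR2"),
        "PS3": ModelSpec("ps", ("X1", "X2", "X3"), "PS3"),
        "PS4": ModelSpec("ps", ("X1^2", "X2^2", "X3^2"), "PS4"),
        "OR3": ModelSpec("or", ("X1", "X2", "X3"), "OR3"),
        "OR4": ModelSpec("or", ("X1^2", "X2^2", "X3^2"), "OR4"),
    }


def specs_from_bitmask(bitmask: str) -> tuple[list[ModelSpec], list[ModelSpec]]:
    """Translate a ``"0000"``-style bitmask into candidate model lists.

    The four digits flag inclusion of PS1, PS2, OR1, OR2 in that order.
    Suffixes ``-2PS``, ``-2OR`` and ``-2PS2OR`` append the extra incorrect
    candidates (PS3/PS4 and/or OR3/OR4).
    """
    sets = simulation_model_sets()
    base, _, suffix = bitmask.partition("-")
    if len(base) != 4 or any(c not in "01" for c in base):
        raise ValueError(f"bitmask must be four 0/1 digits, got {bitmask!r}")
    if base == "0000":
        raise ValueError("bitmask '0000' selects no candidate models")
    ps = [sets[k] for k, c in zip(("PS1", "PS2"), base[:2]) if c == "1"]
    orm = [sets[k] for k, c in zip(("OR1", "OR2"), base[2:]) if c == "1"]
    if suffix:
        if suffix not in ("2PS", "2OR", "2PS2OR"):
            raise ValueError(f"unknown bitmask suffix {suffix!r}")
        if "2PS" in suffix:
            ps += [sets["PS3"], sets["PS4"]]
        if suffix.endswith("2OR"):
            orm += [sets["OR3"], sets["OR4"]]
    return ps, orm


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

_METHODS = ("ipw", "or", "aipw", "ker_mips", "ann_mips", "ipw_ann", "or_ann")

_LABELS = {
    "ipw": "IPW",
    "or": "OR",
    "aipw": "AIPW",
    "ker_mips": "Ker.MiPS",
    "ann_mips": "ANN.MiPS",
    "ipw_ann": "IPW.ANN",
    "or_ann": "OR.ANN",
}


def _ann_cfg(ann: ANNConfig | None, seed: int | None, output: str = "sigmoid") -> ANNConfig:
    cfg = ANNConfig() if ann is None else ann
    return ANNConfig(
        hidden_units=cfg.hidden_units,
        learning_rate=cfg.learning_rate,
        momentum=cfg.momentum,
        epochs=cfg.epochs,
        loss=cfg.loss,
        init_scale=cfg.init_scale,
        seed=cfg.seed if seed is None else seed,
        output_activation=output,
    )


def _raw_covariate_matrix(data: ObservedData, standardize: bool = True) -> np.ndarray:
    x = data.x
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return x


def estimate_ate(
    data: ObservedData,
    ps_specs: list[ModelSpec] | None = None,
    or_specs: list[ModelSpec] | None = None,
    method: str = "ann_mips",
    kernel: KernelConfig | None = None,
    ann: ANNConfig | None = None,
    seed: int | None = None,
    standardize: bool = True,
    clip_kernel: bool = False,
    label: str | None = None,
) -> ATEEstimate:
    """Run the full pipeline for one estimator configuration.

    For the multi-index methods this fits every candidate, stacks the
    indices, scores them by kernel or network regression, and applies the
    Hajek contrast. Network scores are clipped into
    ``[ANN_CLIP, 1 - ANN_CLIP]``; kernel scores are left unclipped by
    default, preserving the estimator's documented behavior near 0/1.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    ps_specs = list(ps_specs or [])
    or_specs = list(or_specs or [])
    diagnostics: dict = {}

    if method == "ipw":
        if not ps_specs:
            raise ValueError("IPW requires a PS model specification")
        fit = fit_ps_model(data, ps_specs[0])
        if not fit.converged:
            raise ValueError(f"PS fit failed: {fit.message}")
        pi = fit.predict_ps(data)
        pv = PropensityVector(scores=pi, method="parametric")
        est = hajek_ipw(data.y, data.a, pv)
        diagnostics["propensity"] = pv.summary()
        diagnostics["scores"] = pv.scores
    elif method == "or":
        if not or_specs:
            raise ValueError("OR requires an OR model specification")
        fit = fit_or_model(data, or_specs[0])
        est = or_estimate(data, fit)
    elif method == "aipw":
        if not ps_specs or not or_specs:
            raise ValueError("AIPW requires one PS and one OR specification")
        ps_fit = fit_ps_model(data, ps_specs[0])
        or_fit = fit_or_model(data, or_specs[0])
        if not ps_fit.converged:
            raise ValueError(f"PS fit failed: {ps_fit.message}")
        est = aipw_estimate(data, ps_fit, or_fit)
    elif method == "ipw_ann":
        # network propensity on raw covariates, no index stage
        s = _raw_covariate_matrix(data)
        model = train_ann(s, data.a, _ann_cfg(ann, seed))
        pv = predict_mips(model, s)
        pv.scores = np.clip(pv.scores, ANN_CLIP, 1 - ANN_CLIP)
        pv.clipped = True
        est = hajek_ipw(data.y, data.a, pv)
        diagnostics["propensity"] = pv.summary()
    elif method == "or_ann":
        # network outcome regression on (X, A) with linear output
        s = _raw_covariate_matrix(data)
        design = np.column_stack([s, data.a.astype(float)])
        model = train_ann(design, data.y, _ann_cfg(ann, seed, output="linear"))
        mu1 = model.forward(np.column_stack([s, np.ones(data.n)]))
        mu0 = model.forward(np.column_stack([s, np.zeros(data.n)]))
        est = float(np.mean(mu1 - mu0))
    else:  # ker_mips / ann_mips
        if not ps_specs and not or_specs:
            raise ValueError("MiPS methods need at least one candidate model")
        ps_fits = [fit_ps_model(data, sp) for sp in ps_specs]
        or_fits = [fit_or_model(data, sp) for sp in or_specs]
        failed = [f.spec.label for f in ps_fits if not f.converged]
        if failed:
            raise ValueError(f"candidate PS fit(s) failed: {failed}")
        index = build_index_matrix(data, ps_fits, or_fits, standardize=standardize)
        if method == "ker_mips":
            pv = nw_mips(index, data.a, kernel)
            if clip_kernel:
                pv.scores = np.clip(pv.scores, ANN_CLIP, 1 - ANN_CLIP)
                pv.clipped = True
        else:
            model = train_ann(index, data.a, _ann_cfg(ann, seed))
            pv = predict_mips(model, index)
            pv.scores = np.clip(pv.scores, ANN_CLIP, 1 - ANN_CLIP)
            pv.clipped = True
            diagnostics["final_loss"] = float(model.loss_trace[-1])
        est = hajek_ipw(data.y, data.a, pv)
        diagnostics["propensity"] = pv.summary()
        diagnostics["scores"] = pv.scores
        diagnostics["index_labels"] = index.labels
        if index.degenerate:
            diagnostics["degenerate_indices"] = index.degenerate

    if label is None:
        label = _LABELS[method]
        if method in ("ker_mips", "ann_mips"):
            sets = {sp.label for sp in ps_specs} | {sp.label for sp in or_specs}
            base = "".join(
                "1" if k in sets else "0" for k in ("PS1", "PS2", "OR1", "OR2")
            )
            suffix = ""
            if {"PS3", "PS4"} <= sets:
                suffix += "-2PS"
            if {"OR3", "OR4"} <= sets:
                suffix += "-2OR" if not suffix else "2OR"
            label = f"{label}-{base}{suffix}"
    return ATEEstimate(estimate=est, label=label, diagnostics=diagnostics)
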