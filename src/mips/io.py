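"""Dataset and configuration I/O.

Datasets travel as headed CSV with columns ``Y, A, X1..Xp`` (plus optional
``Y1, Y0`` counterfactual columns from the generator). Configurations are
YAML documents validated against a closed schema: unknown keys are rejected
and out-of-range values are reported in aggregate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ObservedData
from .datagen import DGPConfig, ar1_corr, exchangeable_corr, identity_corr
from .inference import BootstrapConfig
from .scoring import ANNConfig, KernelConfig
from .study import EstimatorConfig, StudyConfig

__all__ = ["read_dataset", "write_dataset", "parse_corr", "validate_config", "load_config"]


def read_dataset(
    path,
    outcome: str = "Y",
    treatment: str = "A",
    covariates: list[str] | None = None,
) -> ObservedData:
    """Read a headed CSV into an :class:`ObservedData`.

    Rows with missing values and non-binary treatment codes are rejected
    with the offending rows/columns named.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if covariates is None:
        covariates = [
            c for c in df.columns if c not in (outcome, treatment, "Y1", "Y0")
        ]
    bad_a = df.index[~df[treatment].isin((0, 1))].tolist()
    if bad_a:
        raise ValueError(
            f"{path}: column {treatment!r} must be 0/1; bad rows {bad_a}"
        )
    for c in (outcome, *covariates):
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"{path}: column {c!r} is not numeric")
    return ObservedData.from_dataframe(df, outcome, treatment, covariates)


def write_dataset(data: ObservedData, path, potential=None) -> None:
    """Write ``Y, A, X1..Xp[, Y1, Y0]`` as CSV."""
    df = data.to_dataframe()
    if potential is not None:
        df["Y1"] = potential.y1
        df["Y0"] = potential.y0
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def parse_corr(value, p: int = 10) -> np.ndarray:
    """Parse a correlation preset: ``identity``, ``exchangeable:RHO`` or
    ``ar1:RHO``."""
    if value is None or value == "identity":
        return identity_corr(p)
    if isinstance(value, str) and ":" in value:
        kind, _, rho = value.partition(":")
        rho = float(rho)
        if kind in ("exchangeable", "exch"):
            return exchangeable_corr(rho, p)
        if kind == "ar1":
            return ar1_corr(rho, p)
    raise ValueError(
        f"unknown correlation preset {value!r}; use identity, exchangeable:RHO or ar1:RHO"
    )


# --------------------------------------------------------------------------
# Config validation
# --------------------------------------------------------------------------

_SCHEMA = {
    "dgp": {"n": None, "alpha0": None, "corr": None, "seed": None, "noise_sd": None},
    "scoring": {
        "method": None,
        "kernel": {"bandwidth_rule": None, "undersmooth": None, "leave_one_out": None},
        "ann": {
            "epochs": None,
            "learning_rate": None,
            "momentum": None,
            "hidden_units": None,
            "init_scale": None,
            "loss": None,
            "seed": None,
        },
    },
    "bootstrap": {"b": None, "seed": None, "max_redraws": None},
    "study": {"replications": None, "estimators": None, "workers": None, "seed": None},
}


def _collect_unknown(doc: dict, schema: dict, prefix: str, errors: list[str]) -> None:
    for key, val in doc.items():
        if key not in schema:
            errors.append(f"unknown key {prefix}{key}")
        elif isinstance(schema[key], dict) and isinstance(val, dict):
            _collect_unknown(val, schema[key], f"{prefix}{key}.", errors)


def validate_config(document: dict) -> StudyConfig:
    """Validate a study config document and materialize defaults.

    Every unknown key is rejected; range violations are aggregated into a
    single error report.
    """
    if not isinstance(document, dict):
        raise ValueError("config document must be a mapping")
    errors: list[str] = []
    _collect_unknown(document, _SCHEMA, "", errors)

    dgp_doc = dict(document.get("dgp", {}))
    scoring = dict(document.get("scoring", {}))
    ann_doc = dict(scoring.get("ann", {}))
    kern_doc = dict(scoring.get("kernel", {}))
    boot_doc = document.get("bootstrap")
    study_doc = dict(document.get("study", {}))

    lr = ann_doc.get("learning_rate", 0.001)
    if not (0 < lr < 1):
        errors.append(f"scoring.ann.learning_rate {lr} out of range (0, 1)")
    epochs = ann_doc.get("epochs", 2000)
    if epochs < 1:
        errors.append("scoring.ann.epochs must be >= 1")
    b = (boot_doc or {}).get("b", 100)
    if b < 2:
        errors.append("bootstrap.b must be >= 2")

    estimators = []
    for ent in study_doc.get("estimators", []):
        if isinstance(ent, str):
            method, _, bitmask = ent.partition(":")
            ent = {"method": method, "bitmask": bitmask or None}
        method = ent.get("method")
        bitmask = ent.get("bitmask")
        if bitmask is not None:
            from .estimators import specs_from_bitmask

            try:
                specs_from_bitmask(bitmask)
            except ValueError as exc:
                errors.append(str(exc))
        estimators.append(
            EstimatorConfig(method=method, bitmask=bitmask, label=ent.get("label"))
        )
    if not estimators:
        errors.append("study.estimators must be non-empty")

    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    dgp = DGPConfig(
        n=int(dgp_doc.get("n", 1000)),
        alpha0=float(dgp_doc.get("alpha0", 0.0)),
        corr=parse_corr(dgp_doc.get("corr", "identity")),
        seed=int(dgp_doc.get("seed", 0)),
        noise_sd=float(dgp_doc.get("noise_sd", 1.0)),
    )
    ann = ANNConfig(
        hidden_units=tuple(ann_doc.get("hidden_units", (4, 4))),
        learning_rate=float(lr),
        momentum=float(ann_doc.get("momentum", 0.5)),
        epochs=int(epochs),
        loss=str(ann_doc.get("loss", "sse")),
        init_scale=float(ann_doc.get("init_scale", 0.3)),
        seed=int(ann_doc.get("seed", 0)),
    )
    kernel = KernelConfig(
        bandwidth_rule=str(kern_doc.get("bandwidth_rule", "scott")),
        undersmooth=float(kern_doc.get("undersmooth", 1.0)),
        leave_one_out=bool(kern_doc.get("leave_one_out", False)),
    )
    bootstrap = None
    if boot_doc is not None:
        bootstrap = BootstrapConfig(
            b=int(b),
            seed=int(boot_doc.get("seed", 0)),
            max_redraws=int(boot_doc.get("max_redraws", 1000)),
        )
    return StudyConfig(
        dgp=dgp,
        replications=int(study_doc.get("replications", 100)),
        estimators=estimators,
        bootstrap=bootstrap,
        kernel=kernel,
        ann=ann,
        seed=int(study_doc.get("seed", 0)),
        workers=int(study_doc.get("workers", 1)),
    )


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return validate_config(doc)
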