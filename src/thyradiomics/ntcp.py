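"""Published-form NTCP dose-response models for radiation-induced hypothyroidism.

Three parameterized families cover the external models the pipeline is
benchmarked against:

* ``logistic`` — p = 1 / (1 + exp(-(b0 + sum_i b_i x_i))) over named
  clinical covariates (typically mean thyroid dose D_mean in Gy and thyroid
  volume V_thyroid in mL);
* ``lkb`` — Lyman-Kutcher-Burman, p = Phi((gEUD - TD50) / (m TD50)); with
  only summary doses available the gEUD reduces to D_mean (uniform-organ,
  volume exponent n = 1);
* ``mixture`` — a weighted sum of logistic components, covering
  mixture-type published models.

Coefficients are configuration, not facts asserted by this package: the
bundled registry carries citation DOIs and illustrative values to be
checked against the cited sources before any clinical use.  Tests exercise
the functional forms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "NTCPParams",
    "ntcp_logistic",
    "ntcp_lkb",
    "ntcp_mixture",
    "ntcp_predict",
    "load_registry",
    "compare_against_pipeline",
]


@dataclass
class NTCPParams:
    """One parameterized NTCP model.

    ``form`` selects the family.  For logistic: ``intercept`` and
    ``coefficients`` (covariate name -> beta).  For LKB: ``td50`` (Gy),
    ``m`` (slope), ``n`` (volume exponent, kept for completeness), and
    ``dose_covariate`` naming the summary dose used as gEUD.  For mixture:
    ``components`` (list of {weight, intercept, coefficients}).
    """

    form: str
    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)
    td50: float = 60.0
    m: float = 0.27
    n: float = 1.0
    dose_covariate: str = "D_mean"
    components: list[dict] = field(default_factory=list)
    citation: str = ""

    def __post_init__(self) -> None:
        if self.form not in ("logistic", "lkb", "mixture"):
            raise ValueError(f"unknown NTCP form {self.form!r}")
        if self.form == "lkb":
            if self.td50 <= 0 or self.m <= 0 or not 0 <= self.n <= 1:
                raise ValueError("LKB requires TD50 > 0, m > 0, 0 <= n <= 1")


def _covariates(record) -> dict:
    if isinstance(record, pd.Series):
        return record.to_dict()
    if isinstance(record, dict):
        return record
    return vars(record)


def ntcp_logistic(record, params: NTCPParams) -> float:
    """Logistic dose-response probability for one patient record."""
    cov = _covariates(record)
    lin = params.intercept + sum(
        beta * float(cov[name]) for name, beta in params.coefficients.items()
    )
    return float(1.0 / (1.0 + np.exp(-lin)))


def ntcp_lkb(record, params: NTCPParams) -> float:
    """LKB probability; gEUD taken as the configured summary dose."""
    cov = _covariates(record)
    geud = float(cov[params.dose_covariate])
    t = (geud - params.td50) / (params.m * params.td50)
    return float(norm.cdf(t))


def ntcp_mixture(record, params: NTCPParams) -> float:
    """Weighted mixture of logistic components."""
    cov = _covariates(record)
    total, wsum = 0.0, 0.0
    for comp in params.components:
        lin = comp.get("intercept", 0.0) + sum(
            beta * float(cov[name]) for name, beta in comp.get("coefficients", {}).items()
        )
        w = comp.get("weight", 1.0)
        total += w / (1.0 + np.exp(-lin))
        wsum += w
    return float(total / wsum) if wsum else 0.5


_FORMS = {"logistic": ntcp_logistic, "lkb": ntcp_lkb, "mixture": ntcp_mixture}


def ntcp_predict(records: pd.DataFrame, params: NTCPParams, threshold: float = 0.5):
    """Vectorized probabilities and binary calls for a clinical table."""
    fn = _FORMS[params.form]
    p = np.array([fn(row, params) for _, row in records.iterrows()])
    return p, (p >= threshold).astype(int)


def load_registry(path=None) -> dict[str, NTCPParams]:
    """Load the citation-tagged model registry (bundled YAML by default)."""
    if path is None:
        text = resources.files("thyradiomics.data").joinpath("ntcp_models.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for name, cfg in raw["models"].items():
        out[name] = NTCPParams(
            form=cfg["form"],
            intercept=cfg.get("intercept", 0.0),
            coefficients=cfg.get("coefficients", {}) or {},
            td50=cfg.get("td50", 60.0),
            m=cfg.get("m", 0.27),
            n=cfg.get("n", 1.0),
            dose_covariate=cfg.get("dose_covariate", "D_mean"),
            components=cfg.get("components", []) or [],
            citation=cfg.get("citation", ""),
        )
    return out


def compare_against_pipeline(
    ntcp_models: dict[str, NTCPParams],
    pipeline_predictions: dict[str, np.ndarray],
    records: pd.DataFrame,
    labels,
) -> pd.DataFrame:
    """Side-by-side validation metrics: external models vs pipeline models.

    ``pipeline_predictions`` maps a model name to binary calls on the same
    validation rows; external models are evaluated from the clinical table
    at the 0.5 probability threshold.  One row per model with sensitivity,
    specificity, accuracy and F-score.
    """
    y = np.asarray(labels).astype(int)
    rows = []
    for name, params in ntcp_models.items():
        _, pred = ntcp_predict(records, params)
        rows.append((name, "external", *_binary_metrics(pred, y)))
    for name, pred in pipeline_predictions.items():
        rows.append((name, "pipeline", *_binary_metrics(np.asarray(pred).astype(int), y)))
    return pd.DataFrame(
        rows, columns=["model", "kind", "sensitivity", "specificity", "accuracy", "f_score"]
    ).set_index("model")


def _binary_metrics(pred: np.ndarray, y: np.ndarray):
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return sens, spec, acc, f1
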