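"""Classifier training, selection and evaluation for the hypothyroidism endpoint.

Models are trained on three feature pools (clinical/dosimetric, radiomic,
and their union) for each data-split variant.  Input features per model
are chosen by greedy sequential forward selection (2 to 5 features)
maximizing stratified 5-fold cross-validated AUC on the training rows;
the internal cross-validation guards the greedy criterion against
overfitting the training AUC.  Validation rows influence nothing fitted:
they are only scored.

Evaluation reports AUC with its DeLong standard error plus
confusion-matrix metrics (sensitivity, specificity, accuracy, F1) at a
0.5 probability threshold.  Best models per feature pool (highest
validation F-score) are combined into AND / OR / PROBA ensembles, the
PROBA decision threshold coming from Youden's J on the *training* ROC.
Correlated AUCs are compared with DeLong's paired test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import clone
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .filtration import run_filtration
from .preproc import make_split, minmax_scale, preprocess_variant
from .synth import CLINICAL_FEATURES

__all__ = [
    "ModelSpec",
    "EvaluationReport",
    "EnsembleRule",
    "FittedModel",
    "default_model_specs",
    "build_estimator",
    "sequential_forward_select",
    "train",
    "evaluate",
    "youden_threshold",
    "ensemble_predict",
    "delong_test",
    "delong_auc_variance",
    "run_variant",
    "VariantResult",
    "encode_clinical",
]

#: architectures that support inverse-frequency class weighting
BALANCED_CAPABLE = {"logistic", "svc", "decision_tree", "random_forest"}

FEATURE_SETS = ("clinical", "radiomic", "radiomic+clinical")


@dataclass
class ModelSpec:
    architecture: str
    hyperparams: dict = field(default_factory=dict)
    class_weight: str = "equal"  # 'equal' | 'balanced'
    name: str | None = None

    def __post_init__(self) -> None:
        if self.class_weight not in ("equal", "balanced"):
            raise ValueError("class_weight must be 'equal' or 'balanced'")
        if self.class_weight == "balanced" and self.architecture not in BALANCED_CAPABLE:
            raise ValueError(
                f"{self.architecture} does not support balanced class weights"
            )
        if self.name is None:
            suffix = "_bal" if self.class_weight == "balanced" else ""
            self.name = self.architecture + suffix


def default_model_specs() -> list[ModelSpec]:
    """The ten-architecture zoo, plus balanced-weight variants where supported.

    Hyperparameters come from the bundled ``data/model_grids.yaml`` so the
    defaults are inspectable and overridable as configuration.
    """
    import yaml
    from importlib import resources

    raw = yaml.safe_load(
        resources.files("thyradiomics.data").joinpath("model_grids.yaml").read_text()
    )
    hyper = {
        name: {
            k: tuple(v) if isinstance(v, list) else v for k, v in (params or {}).items()
        }
        for name, params in raw["architectures"].items()
    }
    specs = [ModelSpec(a, hyperparams=hyper[a]) for a in hyper]
    specs += [
        ModelSpec(a, hyperparams=hyper[a], class_weight="balanced")
        for a in sorted(raw["balanced_capable"])
    ]
    return specs


def build_estimator(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a spec (unfitted)."""
    cw = "balanced" if spec.class_weight == "balanced" else None
    base = {
        "logistic": lambda: LogisticRegression(max_iter=5000, class_weight=cw),
        "mlp": lambda: MLPClassifier(hidden_layer_sizes=(4,), max_iter=3000, random_state=seed),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "svc": lambda: SVC(probability=True, class_weight=cw, random_state=seed),
        "decision_tree": lambda: DecisionTreeClassifier(class_weight=cw, random_state=seed),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, class_weight=cw, random_state=seed
        ),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "gaussian_process": lambda: GaussianProcessClassifier(random_state=seed),
        "naive_bayes": lambda: GaussianNB(),
        "qda": lambda: QuadraticDiscriminantAnalysis(),
    }
    if spec.architecture not in base:
        raise ValueError(f"unknown architecture {spec.architecture!r}")
    est = base[spec.architecture]()
    if spec.hyperparams:
        est.set_params(**spec.hyperparams)
    return est


# ---------------------------------------------------------------------------
# Sequential forward selection


def _cv_auc(est, x: np.ndarray, y: np.ndarray, seed: int, n_splits: int = 5) -> float:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(x, y):
        model = clone(est)
        model.fit(x[tr], y[tr])
        p = model.predict_proba(x[te])[:, 1]
        if len(np.unique(y[te])) < 2:
            continue
        aucs.append(roc_auc_score(y[te], p))
    return float(np.mean(aucs)) if aucs else 0.5


def sequential_forward_select(
    spec: ModelSpec,
    table: pd.DataFrame,
    labels,
    k_min: int = 2,
    k_max: int = 5,
    seed: int = 0,
    return_trace: bool = False,
):
    """Greedy forward selection maximizing cross-validated training AUC.

    Adds one feature at a time (ties broken by feature name) up to
    ``k_max`` and returns the best-scoring prefix whose size lies in
    ``[k_min, k_max]``.  Deterministic for a fixed seed and table.
    """
    y = np.asarray(labels).astype(int)
    pool = sorted(table.columns)
    k_max = min(k_max, len(pool))
    k_min = min(k_min, k_max)
    est = build_estimator(spec, seed)

    chosen: list[str] = []
    trace = []  # (chosen after step, score)
    while len(chosen) < k_max:
        best_feat, best_score = None, -np.inf
        for feat in pool:
            if feat in chosen:
                continue
            cand = chosen + [feat]
            score = _cv_auc(est, table[cand].to_numpy(dtype=float), y, seed)
            if score > best_score + 1e-12:
                best_feat, best_score = feat, score
        chosen.append(best_feat)
        trace.append((tuple(chosen), best_score))
    sizes = [s for s in range(k_min, k_max + 1)]
    best_size = max(sizes, key=lambda s: trace[s - 1][1])
    subset = list(trace[best_size - 1][0])
    if return_trace:
        return subset, trace
    return subset


def train(spec: ModelSpec, table: pd.DataFrame, labels, seed: int = 0):
    """Fit the estimator on training rows only."""
    est = build_estimator(spec, seed)
    est.fit(table.to_numpy(dtype=float), np.asarray(labels).astype(int))
    return est


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvaluationReport:
    auc: float
    auc_se: float
    sensitivity: float
    specificity: float
    accuracy: float
    f_score: float
    threshold: float
    selected_features: list[str] = field(default_factory=list)
    model_name: str = ""
    feature_set: str = ""


def _metrics_at_threshold(scores: np.ndarray, y: np.ndarray, threshold: float):
    pred = (scores >= threshold).astype(int)
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


def evaluate(scores, labels, threshold: float = 0.5) -> EvaluationReport:
    """Score continuous predictions: rank AUC with DeLong SE plus
    confusion-matrix metrics at ``threshold``."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y, s))
    se = float(np.sqrt(delong_auc_variance(s, y)))
    sens, spec, acc, f1 = _metrics_at_threshold(s, y, threshold)
    return EvaluationReport(auc, se, sens, spec, acc, f1, threshold)


def evaluate_model(model, table: pd.DataFrame, labels, threshold: float = 0.5) -> EvaluationReport:
    return evaluate(model.predict_proba(table.to_numpy(dtype=float))[:, 1], labels, threshold)


def youden_threshold(scores, labels) -> float:
    """Probability cut maximizing Youden's J = sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, dtype=float))
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


# ---------------------------------------------------------------------------
# Ensembles


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: object
    features: list[str]
    threshold: float = 0.5
    report: EvaluationReport | None = None

    def proba(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(table[self.features].to_numpy(dtype=float))[:, 1]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.proba(table) >= self.threshold).astype(int)


@dataclass
class EnsembleRule:
    mode: str  # 'AND' | 'OR' | 'PROBA'
    proba_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("AND", "OR", "PROBA"):
            raise ValueError("mode must be AND, OR or PROBA")


def ensemble_predict(rule: EnsembleRule, members: list[FittedModel], table: pd.DataFrame) -> np.ndarray:
    """Combine member predictions.

    AND/OR operate on the members' binary calls; PROBA averages their
    probabilities (threshold applied by the caller or via the rule)."""
    if rule.mode == "PROBA":
        mean_p = np.mean([m.proba(table) for m in members], axis=0)
        return (mean_p >= rule.proba_threshold).astype(int)
    bins = np.array([m.predict(table) for m in members])
    if rule.mode == "AND":
        return bins.all(axis=0).astype(int)
    return bins.any(axis=0).astype(int)


# ---------------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def _delong_placements(scores: np.ndarray, y: np.ndarray):
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both classes for AUC")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    v10 = (all_r[:m] - pos_r) / n  # per-positive placement
    v01 = 1.0 - (all_r[m:] - neg_r) / m  # per-negative placement
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc_variance(scores, labels) -> float:
    """DeLong variance of a single AUC (placement-value estimator)."""
    y = np.asarray(labels).astype(int)
    _, v10, v01 = _delong_placements(np.asarray(scores, dtype=float), y)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong comparison of two correlated AUCs.

    Returns (AUC_a - AUC_b, SE of the difference, two-sided normal p).
    """
    y = np.asarray(labels).astype(int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    auc_a, v10a, v01a = _delong_placements(a, y)
    auc_b, v10b, v01b = _delong_placements(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    dauc = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return float(dauc), 0.0, 1.0 if dauc == 0 else 0.0
    se = float(np.sqrt(var))
    z = dauc / se
    p = float(2 * norm.sf(abs(z)))
    return float(dauc), se, p


# ---------------------------------------------------------------------------
# Variant orchestration


def encode_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """Numeric clinical/dosimetric design matrix (sex: F=1, stage: III-IV=1)."""
    out = pd.DataFrame(index=records.index)
    for col in CLINICAL_FEATURES:
        if col == "sex":
            out[col] = (records[col] == "F").astype(float)
        elif col == "stage":
            out[col] = (records[col] == "III-IV").astype(float)
        else:
            out[col] = records[col].astype(float)
    return out


@dataclass
class VariantResult:
    variant: str
    split: object
    reports: dict  # (feature_set, model name) -> EvaluationReport
    best: dict  # feature_set -> FittedModel
    ensemble_reports: dict  # mode -> EvaluationReport
    delong: pd.DataFrame
    filtration: object
    selected_radiomic: list[str]


def run_variant(
    variant: str,
    records: pd.DataFrame,
    radiomic: pd.DataFrame,
    stability: pd.DataFrame | None = None,
    specs: list[ModelSpec] | None = None,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    seed: int = 0,
    k_min: int = 2,
    k_max: int = 5,
    split=None,
) -> VariantResult:
    """Execute one full analysis variant on a cohort.

    ``records`` is the clinical table indexed by patient id (with
    ``center`` and ``riht``); ``radiomic`` the raw feature table on the
    same index.  Preprocessing, filtration and selection are fitted on the
    training partition only.  Returns per-model validation reports, the
    best model per feature pool (highest validation F-score), AND/OR/PROBA
    ensembles of the best clinical and radiomic models, and the DeLong
    comparison of every radiomic-bearing model against the clinical one.
    """
    specs = specs if specs is not None else default_model_specs()
    if split is None:
        split = make_split(records, variant, seed=seed)
    tr, va = split.train_ids, split.val_ids
    y_tr = records.loc[tr, "riht"].to_numpy(dtype=int)
    y_va = records.loc[va, "riht"].to_numpy(dtype=int)

    rad_tr, rad_va, _ = preprocess_variant(
        radiomic.loc[tr],
        radiomic.loc[va],
        variant,
        train_batches=records.loc[tr, "center"],
        val_batches=records.loc[va, "center"],
    )
    filt, screen = run_filtration(rad_tr, y_tr, stability=stability)
    selected_radiomic = filt.selected

    clin = encode_clinical(records)
    clin_tr, p_clin = minmax_scale(clin.loc[tr])
    clin_va, _ = minmax_scale(clin.loc[va], p_clin)

    pools_tr = {
        "clinical": clin_tr,
        "radiomic": rad_tr[selected_radiomic],
        "radiomic+clinical": pd.concat([rad_tr[selected_radiomic], clin_tr], axis=1),
    }
    pools_va = {
        "clinical": clin_va,
        "radiomic": rad_va[selected_radiomic],
        "radiomic+clinical": pd.concat([rad_va[selected_radiomic], clin_va], axis=1),
    }

    reports: dict = {}
    fitted: dict = {}
    for fs in feature_sets:
        x_tr, x_va = pools_tr[fs], pools_va[fs]
        if x_tr.shape[1] == 0:
            continue
        for spec in specs:
            subset = sequential_forward_select(
                spec, x_tr, y_tr, k_min=k_min, k_max=k_max, seed=seed
            )
            model = train(spec, x_tr[subset], y_tr, seed=seed)
            fm = FittedModel(spec, model, subset)
            rep = evaluate(fm.proba(x_va), y_va)
            rep.selected_features = subset
            rep.model_name = spec.name
            rep.feature_set = fs
            fm.report = rep
            reports[(fs, spec.name)] = rep
            fitted[(fs, spec.name)] = fm

    best: dict = {}
    for fs in feature_sets:
        cands = [(name, reports[(s, name)]) for (s, name) in reports if s == fs]
        if not cands:
            continue
        best_name = max(sorted(cands), key=lambda kv: kv[1].f_score)[0]
        best[fs] = fitted[(fs, best_name)]

    ensemble_reports: dict = {}
    ens_scores: dict = {}
    if "clinical" in best and "radiomic" in best:
        members = [best["clinical"], best["radiomic"]]
        mem_tables_va = {
            "clinical": pools_va["clinical"],
            "radiomic": pools_va["radiomic"],
        }

        def member_proba(table_map):
            return [
                best["clinical"].proba(table_map["clinical"]),
                best["radiomic"].proba(table_map["radiomic"]),
            ]

        p_tr = np.mean(
            [
                best["clinical"].proba(pools_tr["clinical"]),
                best["radiomic"].proba(pools_tr["radiomic"]),
            ],
            axis=0,
        )
        proba_thr = youden_threshold(p_tr, y_tr)
        p_va = np.mean(member_proba(mem_tables_va), axis=0)
        for mode in ("AND", "OR"):
            bins = np.array(
                [
                    best["clinical"].predict(pools_va["clinical"]),
                    best["radiomic"].predict(pools_va["radiomic"]),
                ]
            )
            pred = bins.all(axis=0) if mode == "AND" else bins.any(axis=0)
            rep = evaluate(pred.astype(float), y_va, threshold=0.5)
            rep.model_name = mode
            ensemble_reports[mode] = rep
        rep = evaluate(p_va, y_va, threshold=proba_thr)
        rep.model_name = "PROBA"
        ensemble_reports["PROBA"] = rep
        ens_scores["PROBA"] = p_va

    delong_rows = []
    if "clinical" in best:
        clin_scores = best["clinical"].proba(pools_va["clinical"])
        compare = []
        if "radiomic" in best:
            compare.append(("radiomic", best["radiomic"].proba(pools_va["radiomic"])))
        if "radiomic+clinical" in best:
            compare.append(
                (
                    "radiomic+clinical",
                    best["radiomic+clinical"].proba(pools_va["radiomic+clinical"]),
                )
            )
        if "PROBA" in ens_scores:
            compare.append(("PROBA", ens_scores["PROBA"]))
        for name, scores in compare:
            dauc, se, p = delong_test(scores, clin_scores, y_va)
            delong_rows.append(
                {"model": name, "delta_auc_vs_clinical": dauc, "se": se, "p": p}
            )
    delong_table = pd.DataFrame(delong_rows)

    return VariantResult(
        variant=variant,
        split=split,
        reports=reports,
        best=best,
        ensemble_reports=ensemble_reports,
        delong=delong_table,
        filtration=filt,
        selected_radiomic=selected_radiomic,
    )
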