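"""Cross-site classification experiments with and without the healthy core.

Three designs probe classifier generalizability between two sites:

* Experiment I  — train, validate and test within one site.
* Experiment II — train/validate on one site, test on the other site.
* Experiment III — as II, but the HC pools are replaced by healthy-core
  members; leakage-free by default (training uses only the training
  site's core HCs, testing only the test site's core HCs).

Four binary classifiers (L1-regularized logistic regression, RBF-kernel
SVM, random forest, XGBoost) are tuned by sequential model-based
optimization maximizing validation AUC, each experiment repeated under
several seeded random splits with averaged metrics, and t-SNE embeddings
provide a visual diagnostic of HC/core/patient structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .core import CoreSelection
from .datamodel import ConfigurationError, DataError, FeatureTable, concat_tables
from .io import split_by
from .optimize import Dimension, maximize

logger = logging.getLogger(__name__)

MODEL_IDS = ("l1_logreg", "svm", "random_forest", "xgboost")

SEARCH_SPACES: dict[str, list[Dimension]] = {
    "l1_logreg": [Dimension("C", 1e-3, 1e3, log=True)],
    "svm": [
        Dimension("C", 1e-2, 1e3, log=True),
        Dimension("gamma", 1e-4, 10.0, log=True),
    ],
    "random_forest": [
        Dimension("n_estimators", 50, 300, integer=True),
        Dimension("max_depth", 2, 10, integer=True),
        Dimension("max_features", 0.1, 1.0),
    ],
    "xgboost": [
        Dimension("n_estimators", 50, 300, integer=True),
        Dimension("max_depth", 2, 8, integer=True),
        Dimension("learning_rate", 0.01, 0.3, log=True),
        Dimension("subsample", 0.5, 1.0),
    ],
}


def _make_model(model_id: str, params: Mapping, seed: int, pos_weight: float = 1.0):
    # HC/patient groups are strongly imbalanced; class weighting keeps the
    # 0.5 probability threshold meaningful for the confusion metrics
    if model_id == "l1_logreg":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=params["C"],
            max_iter=2000, random_state=seed, class_weight="balanced",
        )
    if model_id == "svm":
        return SVC(
            C=params["C"], gamma=params["gamma"], kernel="rbf",
            random_state=seed, class_weight="balanced",
        )
    if model_id == "random_forest":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"], max_depth=params["max_depth"],
            max_features=params["max_features"], random_state=seed, n_jobs=1,
            class_weight="balanced",
        )
    if model_id == "xgboost":
        return XGBClassifier(
            n_estimators=params["n_estimators"], max_depth=params["max_depth"],
            learning_rate=params["learning_rate"], subsample=params["subsample"],
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss",
            scale_pos_weight=pos_weight,
        )
    raise ConfigurationError(f"unknown model {model_id!r}")


def _raw_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


class CalibratedModel:
    """A fitted classifier plus a validation-fitted probability map.

    Raw scores (decision function or raw probability) are mapped through
    a one-dimensional logistic calibration fitted on the validation
    split with balanced class weights, so the 0.5 probability threshold
    sits at the balanced operating point regardless of class prevalence
    — essential when train and test cohorts have different HC/patient
    ratios.
    """

    def __init__(self, base, calibrator: LogisticRegression):
        self.base = base
        self.calibrator = calibrator

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = _raw_scores(self.base, X)[:, None]
        return self.calibrator.predict_proba(s)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_classifier(
    model_id: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    tuning_budget: int = 30,
    seed: int = 0,
):
    """Tune, fit and calibrate one classifier, maximizing validation AUC.

    Returns ``(calibrated model, best hyperparameters, validation AUC)``.
    Deterministic given the seed.
    """
    y_train, y_val = np.asarray(y_train), np.asarray(y_val)
    for name, y in (("train", y_train), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise DataError(f"{name} split contains a single class")

    pos_weight = float((y_train == 0).sum() / max((y_train == 1).sum(), 1))

    def objective(params: Mapping) -> float:
        model = _make_model(model_id, params, seed, pos_weight)
        model.fit(X_train, y_train)
        return roc_auc_score(y_val, _raw_scores(model, X_val))

    result = maximize(objective, SEARCH_SPACES[model_id], budget=tuning_budget, seed=seed)
    model = _make_model(model_id, result.best_params, seed, pos_weight)
    model.fit(X_train, y_train)
    calibrator = LogisticRegression(class_weight="balanced", max_iter=1000)
    calibrator.fit(_raw_scores(model, X_val)[:, None], y_val)
    return CalibratedModel(model, calibrator), result.best_params, result.best_score


@dataclass
class MetricsRow:
    """Evaluation metrics of one model on one split, with confusion counts."""

    model: str
    repeat_index: int
    role: str  # validation | test
    auc: float | None
    accuracy: float
    specificity: float
    sensitivity: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc_flag: str | None = None  # set when AUC could not be computed

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate(
    model, X_test: np.ndarray, y_test: np.ndarray,
    model_id: str = "", repeat_index: int = 0, role: str = "test",
) -> MetricsRow:
    """Threshold-free AUC plus threshold-0.5 confusion metrics."""
    y_test = np.asarray(y_test)
    proba = model.predict_proba(X_test)[:, 1]
    pred = (proba >= 0.5).astype(int)
    tp = int(((pred == 1) & (y_test == 1)).sum())
    fp = int(((pred == 1) & (y_test == 0)).sum())
    tn = int(((pred == 0) & (y_test == 0)).sum())
    fn = int(((pred == 0) & (y_test == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y_test)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    if len(np.unique(y_test)) < 2:
        auc, flag = None, "single-class test set"
    else:
        auc, flag = float(roc_auc_score(y_test, proba)), None
    return MetricsRow(
        model=model_id, repeat_index=repeat_index, role=role, auc=auc,
        accuracy=acc, specificity=spec, sensitivity=sens, f1=f1,
        tp=tp, fp=fp, tn=tn, fn=fn, auc_flag=flag,
    )


@dataclass
class ExperimentSpec:
    """One of the three cross-site evaluation designs."""

    id: str  # I | II | III
    train_site: str
    test_site: str
    patient_group: str  # EM | CM
    use_core: bool = False
    n_repeats: int = 5
    train_frac: float = 0.6
    val_frac: float = 0.2
    tuning_budget: int = 30
    models: Sequence[str] = MODEL_IDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.id not in ("I", "II", "III"):
            raise ConfigurationError("experiment id must be I, II or III")
        if self.id == "I" and self.train_site != self.test_site:
            raise ConfigurationError("Experiment I is within-site")
        if self.id in ("II", "III") and self.train_site == self.test_site:
            raise ConfigurationError("Experiments II/III are cross-site")
        if self.id == "III" and not self.use_core:
            raise ConfigurationError("Experiment III requires use_core=True")
        if self.id != "III" and self.use_core:
            raise ConfigurationError("use_core is only valid for Experiment III")
        if self.patient_group not in ("EM", "CM"):
            raise ConfigurationError("patient_group must be EM or CM")
        unknown = set(self.models) - set(MODEL_IDS)
        if unknown:
            raise ConfigurationError(f"unknown models {sorted(unknown)}")


@dataclass
class ExperimentResult:
    """Per-repeat metric rows plus across-repeat means, per model."""

    spec: ExperimentSpec
    rows: pd.DataFrame

    def mean_by_model(self, role: str = "test") -> pd.DataFrame:
        sub = self.rows[self.rows["role"] == role]
        return sub.groupby("model")[
            ["auc", "accuracy", "specificity", "sensitivity", "f1"]
        ].mean()

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _binary_table(table: FeatureTable, patient_group: str) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with HC = 0 and the patient group = 1."""
    keep = [i for i, s in enumerate(table.subjects) if s.group in ("HC", patient_group)]
    sub = table.take(keep)
    y = np.array([0 if s.group == "HC" else 1 for s in sub.subjects])
    return sub.values, y


def _standardize_with(train: np.ndarray, *others: np.ndarray):
    mu, sd = train.mean(axis=0), train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((Z - mu) / sd for Z in (train, *others))


def _core_hc_table(table: FeatureTable, core: CoreSelection, site: str) -> FeatureTable:
    if site not in core.retained:
        raise DataError(f"core selection has no retained set for site {site!r}")
    ids = set(core.retained[site])
    keep = [i for i, s in enumerate(table.subjects) if s.subject_id in ids]
    if not keep:
        raise DataError(f"no core subjects of site {site!r} present in the table")
    return table.take(keep)


def run_experiment(
    tables: Mapping[str, FeatureTable],
    spec: ExperimentSpec,
    core: CoreSelection | None = None,
) -> ExperimentResult:
    """Run one experiment design over ``n_repeats`` seeded re-splits."""
    if spec.id == "III" and core is None:
        raise ConfigurationError("Experiment III needs a CoreSelection")
    train_table = tables[spec.train_site]
    test_table = tables[spec.test_site]

    rows: list[dict] = []
    for rep in range(spec.n_repeats):
        rep_seed = int(
            np.random.SeedSequence([spec.seed, rep]).generate_state(1)[0] % (2**31)
        )
        if spec.id == "I":
            X, y = _binary_table(train_table, spec.patient_group)
            X_tr, X_tmp, y_tr, y_tmp = train_test_split(
                X, y, train_size=spec.train_frac, stratify=y, random_state=rep_seed
            )
            rel_val = spec.val_frac / (1.0 - spec.train_frac)
            X_val, X_te, y_val, y_te = train_test_split(
                X_tmp, y_tmp, train_size=rel_val, stratify=y_tmp,
                random_state=rep_seed + 1,
            )
        else:
            if spec.id == "III":
                # The core spans both sites and is what bridges them: the
                # HC training pool is the full core minus the test-site
                # members reserved for testing, so no subject appears on
                # both sides of the split.
                hc_train_site = _core_hc_table(
                    split_by(train_table, "group")["HC"], core, spec.train_site
                )
                hc_test_site = _core_hc_table(
                    split_by(test_table, "group")["HC"], core, spec.test_site
                )
                n_reserve = max(2, hc_test_site.n_subjects // 2)
                reserve_rng = np.random.default_rng(rep_seed)
                order = reserve_rng.permutation(hc_test_site.n_subjects)
                hc_test = hc_test_site.take(order[:n_reserve])
                hc_bridge = hc_test_site.take(order[n_reserve:])
                patients_train = split_by(train_table, "group")[spec.patient_group]
                patients_test = split_by(test_table, "group")[spec.patient_group]
                train_parts = [hc_train_site, patients_train]
                if hc_bridge.n_subjects:
                    train_parts.insert(1, hc_bridge)
                train_pool = concat_tables(train_parts)
                test_pool = concat_tables([hc_test, patients_test])
                X, y = _binary_table(train_pool, spec.patient_group)
                X_te, y_te = _binary_table(test_pool, spec.patient_group)
            else:
                X, y = _binary_table(train_table, spec.patient_group)
                X_te, y_te = _binary_table(test_table, spec.patient_group)
            tr_frac = spec.train_frac / (spec.train_frac + spec.val_frac)
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y, train_size=tr_frac, stratify=y, random_state=rep_seed
            )
        X_tr, X_val, X_te = _standardize_with(X_tr, X_val, X_te)

        for k, model_id in enumerate(spec.models):
            model_seed = int(
                np.random.SeedSequence([spec.seed, rep, k]).generate_state(1)[0]
                % (2**31)
            )
            model, params, val_auc = fit_classifier(
                model_id, X_tr, y_tr, X_val, y_val,
                tuning_budget=spec.tuning_budget, seed=model_seed,
            )
            val_row = evaluate(model, X_val, y_val, model_id, rep, role="validation")
            test_row = evaluate(model, X_te, y_te, model_id, rep, role="test")
            for r in (val_row, test_row):
                d = r.as_dict()
                d["experiment"] = spec.id
                d["best_params"] = repr(params)
                rows.append(d)

    frame = pd.DataFrame(rows)
    return ExperimentResult(spec=spec, rows=frame)


def round_half_up(value: float, ndigits: int = 4) -> float:
    """Decimal round-half-up, the convention used in reported tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(
    results: Mapping[str, ExperimentResult | pd.DataFrame],
    metric: str = "auc",
    role: str = "test",
    ndigits: int = 4,
) -> pd.DataFrame:
    """Models x experiments table of mean test metrics with an Average row.

    The Average row is the arithmetic mean of the per-model values,
    rounded half-up to ``ndigits`` — the convention of the reported
    tables (e.g. four AUCs 0.7360, 0.6700, 0.7700, 0.8370 average to
    0.7533 at four decimals).
    """
    columns: dict[str, pd.Series] = {}
    for name, res in results.items():
        if isinstance(res, ExperimentResult):
            per_model = res.mean_by_model(role)[metric]
        else:
            sub = res[res["role"] == role] if "role" in res.columns else res
            per_model = sub.groupby("model")[metric].mean()
        columns[name] = per_model
    if not columns:
        return pd.DataFrame()
    table = pd.DataFrame(columns)
    table = table.map(lambda v: round_half_up(v, ndigits) if pd.notna(v) else v)
    averages = {
        name: round_half_up(float(np.mean(col.dropna().to_numpy())), ndigits)
        for name, col in table.items()
    }
    table.loc["Average"] = pd.Series(averages)
    return table


def summary_markdown(table: pd.DataFrame, title: str = "") -> str:
    lines = []
    if title:
        lines += [f"### {title}", ""]
    lines.append(table.to_markdown(floatfmt=".4f"))
    return "\n".join(lines)


def embed_diagnostic(
    tables: Sequence[FeatureTable],
    labels: Sequence[str] | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """2-D t-SNE embedding (PCA initialization) of pooled tables.

    Returns one row per subject with columns ``subject_id, label, x, y``.
    Perplexity is lowered automatically (with a warning) when the pooled
    sample is too small for the requested value.
    """
    pooled = concat_tables(list(tables))
    if pooled.n_subjects < 5:
        raise DataError("need at least 5 points for an embedding")
    if labels is None:
        labels = [f"{s.site_id}:{s.group}" for s in pooled.subjects]
    labels = list(labels)
    if len(labels) != pooled.n_subjects:
        raise DataError("labels length does not match pooled subjects")
    max_perp = (pooled.n_subjects - 1) / 3.0
    if perplexity > max_perp:
        logger.warning("perplexity lowered from %.1f to %.1f", perplexity, max_perp)
        perplexity = max(1.0, max_perp)
    X = pooled.values
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    coords = TSNE(
        n_components=2, init="pca", random_state=seed, perplexity=perplexity,
    ).fit_transform(X)
    return pd.DataFrame(
        {
            "subject_id": pooled.subject_ids,
            "label": labels,
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )
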