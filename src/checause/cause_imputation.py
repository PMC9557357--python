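"""Impute the cause group of visits beyond the three most recent.

Surveys of this design record the reason for seeking care only for the
three most recent inpatient and three most recent outpatient visits.  For
older visits only the annual counts are known.  This module trains a
random-forest classifier on visits with an observed cause and predicts the
cause group of the unobserved ones, separately per country and care level.

Features are respondent covariates (age, sex, urban residence, education,
wealth quintile), annual visit counts, and the composition of the
respondent's *other* observed-cause visits (leave-one-out counts per cause
group) — the strongest predictor when a respondent's care is concentrated
in one disease area.

Cross-validation is grouped by respondent so that a respondent's visits
never straddle the train/test split.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold

from checause.errors import CheCauseError, PipelineOrderError
from checause.survey_io import CARE_LEVELS, CAUSE_ORDER

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationSettings:
    """Random-forest hyperparameters (none are survey-published; all exposed)."""

    n_trees: int = 500
    min_samples_leaf: int = 5
    max_features: str | float = "sqrt"
    min_training_rows: int = 20
    k_folds: int = 5
    seed: int = 0


_COVARIATE_FEATURES = [
    "age",
    "female",
    "urban",
    "education",
    "wealth_q",
    "n_visits_outpatient",
    "n_visits_inpatient",
]


def build_features(
    visits: pd.DataFrame,
    respondents: pd.DataFrame,
    context: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the feature matrix for cause classification.

    For each visit row: respondent covariates, visit counts, care level
    indicator, and leave-one-out counts of the respondent's other observed
    causes.  ``context`` supplies the observed-cause visits those counts
    are taken from (defaults to ``visits`` itself); a row with an observed
    cause is excluded from its own count.
    """
    if context is None:
        context = visits
    resp_cols = ["respondent_id"] + _COVARIATE_FEATURES
    feat = visits[["visit_id", "respondent_id", "care_level", "cause_group"]].merge(
        respondents[resp_cols], on="respondent_id", how="left", validate="m:1"
    )
    missing = feat[_COVARIATE_FEATURES].isna().any()
    if missing.any():
        bad = missing.index[missing][0]
        raise CheCauseError(f"imputation-input error: missing feature '{bad}'")
    feat["inpatient"] = (feat["care_level"] == "inpatient").astype(int)

    # per-respondent counts of observed causes, then leave-one-out
    observed = context.dropna(subset=["cause_group"])
    counts = (
        observed.groupby(["respondent_id", "cause_group"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(CAUSE_ORDER), fill_value=0)
    )
    for g in CAUSE_ORDER:
        col = counts[g] if g in counts else pd.Series(dtype=int)
        feat[f"other_{g}"] = feat["respondent_id"].map(col).fillna(0).astype(int)
        own = (feat["cause_group"] == g).fillna(False).astype(int)
        feat[f"other_{g}"] = feat[f"other_{g}"] - own

    return feat


FEATURE_COLUMNS = _COVARIATE_FEATURES + ["inpatient"] + [
    f"other_{g}" for g in CAUSE_ORDER
]


@dataclass
class CauseModel:
    """A fitted cause classifier for one (country, care level) cell."""

    estimator: RandomForestClassifier | None
    features: list[str]
    classes: list[str]
    constant_class: str | None = None
    accuracy_overall: float = float("nan")
    accuracy_by_class: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability matrix over the seven groups in canonical order."""
        out = np.zeros((len(X), len(CAUSE_ORDER)))
        if self.constant_class is not None:
            out[:, CAUSE_ORDER.index(self.constant_class)] = 1.0
            return out
        raw = self.estimator.predict_proba(X[self.features])
        for j, cls in enumerate(self.estimator.classes_):
            out[:, CAUSE_ORDER.index(cls)] = raw[:, j]
        return out


def _data_hash(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def fit_cause_classifier(
    visits_observed: pd.DataFrame,
    respondents: pd.DataFrame,
    settings: ImputationSettings = ImputationSettings(),
    context: pd.DataFrame | None = None,
) -> CauseModel:
    """Fit a random forest on visits with observed cause (one data cell).

    Callers normally use :func:`fit_cause_models`, which slices by country
    and care level first.  ``context`` optionally widens the observed-cause
    pool used for the cause-composition features (e.g. both care levels).
    Single-class training data yields a constant predictor with a warning;
    fewer than ``min_training_rows`` rows is an error.
    """
    train = visits_observed.dropna(subset=["cause_group"])
    if len(train) < settings.min_training_rows:
        raise CheCauseError(
            f"too few training rows for cause model "
            f"({len(train)} < {settings.min_training_rows})"
        )
    feat = build_features(train, respondents, context)
    y = feat["cause_group"].astype(str).to_numpy()
    classes = sorted(set(y), key=CAUSE_ORDER.index)
    meta = {
        "seed": settings.seed,
        "n_trees": settings.n_trees,
        "n_train": len(train),
        "data_hash": _data_hash(train[["visit_id", "cause_group"]]),
    }
    if len(classes) == 1:
        warnings.warn(
            f"single-class training data ({classes[0]}); returning constant predictor",
            stacklevel=2,
        )
        return CauseModel(
            estimator=None,
            features=FEATURE_COLUMNS,
            classes=classes,
            constant_class=classes[0],
            accuracy_overall=1.0,
            accuracy_by_class={classes[0]: 1.0},
            meta=meta,
        )
    rf = RandomForestClassifier(
        n_estimators=settings.n_trees,
        min_samples_leaf=settings.min_samples_leaf,
        max_features=settings.max_features,
        random_state=settings.seed,
        n_jobs=1,
    )
    rf.fit(feat[FEATURE_COLUMNS], y)
    model = CauseModel(
        estimator=rf, features=FEATURE_COLUMNS, classes=classes, meta=meta
    )
    try:
        overall, by_class = holdout_accuracy(
            model, train, respondents, k_folds=settings.k_folds,
            settings=settings, context=context,
        )
        model.accuracy_overall = overall
        model.accuracy_by_class = by_class
    except CheCauseError:
        log.info("skipping holdout accuracy: too few respondent groups")
    return model


def holdout_accuracy(
    model: CauseModel,
    visits_observed: pd.DataFrame,
    respondents: pd.DataFrame,
    k_folds: int = 5,
    settings: ImputationSettings = ImputationSettings(),
    context: pd.DataFrame | None = None,
) -> tuple[float, dict]:
    """Grouped k-fold cross-validated accuracy (groups = respondents).

    Refits a fresh forest per fold with the model's hyperparameters; a
    respondent's visits never appear in both train and test of a fold.
    """
    if k_folds < 2:
        raise CheCauseError("k_folds must be >= 2")
    train = visits_observed.dropna(subset=["cause_group"])
    groups = train["respondent_id"].to_numpy()
    n_groups = len(np.unique(groups))
    if n_groups < k_folds:
        raise CheCauseError(
            f"fewer respondent groups ({n_groups}) than folds ({k_folds})"
        )
    feat = build_features(train, respondents, context)
    X = feat[FEATURE_COLUMNS].to_numpy()
    y = feat["cause_group"].astype(str).to_numpy()
    if model.constant_class is not None:
        pred = np.full(len(y), model.constant_class)
    else:
        pred = np.empty(len(y), dtype=object)
        gkf = GroupKFold(n_splits=k_folds)
        for tr, te in gkf.split(X, y, groups):
            if len(set(y[tr])) == 1:
                pred[te] = y[tr][0]
                continue
            rf = RandomForestClassifier(
                n_estimators=settings.n_trees,
                min_samples_leaf=settings.min_samples_leaf,
                max_features=settings.max_features,
                random_state=settings.seed,
                n_jobs=1,
            )
            rf.fit(X[tr], y[tr])
            proba = rf.predict_proba(X[te])
            # modal class with canonical-order tie-break
            full = np.zeros((len(te), len(CAUSE_ORDER)))
            for j, cls in enumerate(rf.classes_):
                full[:, CAUSE_ORDER.index(cls)] = proba[:, j]
            pred[te] = np.array(CAUSE_ORDER)[full.argmax(axis=1)]
    overall = float((pred == y).mean())
    by_class = {
        cls: float((pred[y == cls] == cls).mean()) for cls in np.unique(y)
    }
    return overall, by_class


def predict_cause(
    model: CauseModel,
    visits_unobserved: pd.DataFrame,
    respondents: pd.DataFrame,
    visits_observed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Predict cause groups for visits lacking an observed cause.

    Leave-one-out cause-composition features are computed from
    ``visits_observed`` (the same respondent's recorded visits).  Returns a
    table of visit id, predicted group (modal class, ties broken in
    canonical group order) and the full probability vector.  Deterministic
    given the model.
    """
    cols = ["visit_id", "predicted_cause"] + [f"p_{g}" for g in CAUSE_ORDER]
    if len(visits_unobserved) == 0:
        return pd.DataFrame(columns=cols)
    feat = build_features(visits_unobserved, respondents, context=visits_observed)
    proba = model.predict_proba(feat)
    labels = np.array(CAUSE_ORDER)[proba.argmax(axis=1)]
    out = pd.DataFrame({"visit_id": feat["visit_id"].to_numpy(),
                        "predicted_cause": labels})
    for j, g in enumerate(CAUSE_ORDER):
        out[f"p_{g}"] = proba[:, j]
    return out.reset_index(drop=True)


def fit_cause_models(
    visits_observed: pd.DataFrame,
    respondents: pd.DataFrame,
    settings: ImputationSettings = ImputationSettings(),
) -> dict[tuple[str, str], CauseModel]:
    """Fit one cause model per (country, care level) cell.

    The cause-composition features always draw on the respondent's observed
    visits from *both* care levels, matching what is available at
    prediction time.
    """
    models: dict[tuple[str, str], CauseModel] = {}
    observed = visits_observed.dropna(subset=["cause_group"])
    for (country, lvl), sub in observed.groupby(
        ["country", "care_level"], observed=True
    ):
        ctx = observed[observed["country"] == country]
        models[(country, lvl)] = fit_cause_classifier(
            sub, respondents, settings, context=ctx
        )
    return models


def impute_causes(
    visits: pd.DataFrame,
    respondents: pd.DataFrame,
    settings: ImputationSettings = ImputationSettings(),
    models: dict[tuple[str, str], CauseModel] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], CauseModel]]:
    """Fill a ``final_cause`` column: observed cause where present, else predicted.

    Returns the visit table with ``final_cause`` and ``cause_imputed``
    columns plus the fitted models.
    """
    out = visits.copy()
    out["final_cause"] = out["cause_group"]
    out["cause_imputed"] = out["cause_group"].isna()
    observed = out[out["cause_group"].notna()]
    if models is None:
        models = fit_cause_models(observed, respondents, settings)
    todo = out[out["cause_group"].isna()]
    if len(todo) == 0:
        return out, models
    for (country, lvl), sub in todo.groupby(["country", "care_level"],
                                            observed=True):
        key = (country, lvl)
        if key not in models:
            # no observed-cause visits in this cell at all; fall back to the
            # other care level's model for the country if available
            alt = [(c, l) for (c, l) in models if c == country]
            if not alt:
                raise PipelineOrderError(
                    f"no cause model trainable for {key}"
                )
            key = alt[0]
        obs_cell = observed[observed["respondent_id"].isin(sub["respondent_id"])]
        pred = predict_cause(models[key], sub, respondents, obs_cell)
        out.loc[out["visit_id"].isin(pred["visit_id"]), "final_cause"] = (
            out.loc[out["visit_id"].isin(pred["visit_id"]), "visit_id"]
            .map(pred.set_index("visit_id")["predicted_cause"])
        )
    if out["final_cause"].isna().any():
        raise PipelineOrderError("some visits still lack a cause after imputation")
    return out, models


def save_model_report(
    models: dict[tuple[str, str], CauseModel], path: str | Path
) -> None:
    """Write a per-cell accuracy report (CSV) and metadata (JSON)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for (country, lvl), m in models.items():
        rows.append(
            {
                "country": country,
                "care_level": lvl,
                "accuracy_overall": m.accuracy_overall,
                **{f"accuracy_{k}": v for k, v in m.accuracy_by_class.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = {
        f"{c}|{l}": m.meta for (c, l), m in models.items()
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
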