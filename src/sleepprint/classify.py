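"""Leakage-regime classification of band-power epochs.

Three train/test split regimes probe what a gradient-boosted tree model
actually learns from 180-dimensional band-power epochs labeled with ISI
severity:

* ``intra_individual`` — epochs from both nights pooled, stratified random
  80/20 split: train and test share subjects *and* nights, so the model may
  exploit individual fingerprints freely.
* ``night_to_night`` — train on all Night-1 epochs, test on all Night-2
  epochs: same subjects, different night.  The split is deterministic, so
  metric SDs over repetitions are exactly zero.
* ``subject_wise`` — 80/20 split of subject ids, epochs follow their
  subject: train and test subjects are disjoint, the only regime that
  measures generalization to new people.

If individual fingerprints dominate and severity carries no spectral
signal, accuracy is near-perfect in the first regime, intermediate in the
second, and at chance in the third.

Feature attribution uses the tree-path (SHAP-value) decomposition built
into XGBoost (``pred_contribs``): per-row contributions plus the base value
sum exactly to the model margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .spectra import BandScheme, band_of_column, feature_matrix

REGIMES = ("intra_individual", "night_to_night", "subject_wise")


@dataclass(frozen=True)
class SplitRegime:
    """One train/test design."""

    name: str
    test_fraction: float = 0.2
    repetitions: int = 100
    stage: str = "NREM"  # analysis subset: "NREM" or "REM"

    def validate(self) -> None:
        if self.name not in REGIMES:
            raise ValueError(f"unknown regime {self.name!r}; one of {REGIMES}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test fraction must be in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass(frozen=True)
class ClassifierConfig:
    """Gradient-boosted tree hyperparameters.

    Boosting rounds (not pinned by convention) default to 300 with early
    stopping on a 10% validation carve-out of the training rows.  The
    optional 10-fold CV refinement searches a small grid (trees x depth) on
    training folds only.
    """

    learning_rate: float = 0.3
    gamma: float = 0.0
    max_depth: int = 10
    reg_alpha: float = 0.0
    n_estimators: int = 300
    early_stopping_rounds: int = 20
    tree_method: str = "auto"
    cv_folds: int = 10
    use_cv_refinement: bool = False
    cv_grid_estimators: tuple[int, ...] = (100, 300)
    cv_grid_depth: tuple[int, ...] = (6, 10)
    n_jobs: int = 1

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.max_depth < 1:
            raise ValueError("illegal hyperparameter value")
        if self.gamma < 0 or self.reg_alpha < 0 or self.n_estimators < 1:
            raise ValueError("illegal hyperparameter value")


# ----------------------------------------------------------------------
# splits
# ----------------------------------------------------------------------
def make_splits(table: pd.DataFrame, regime: SplitRegime,
                rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Row-index train/test pairs, one per repetition.

    ``intra_individual`` stratifies the random 80/20 split by
    (subject x ISI class) so both nights stay represented; ``night_to_night``
    is the deterministic Night-1 -> Night-2 split; ``subject_wise`` splits
    subject ids 80/20 and epochs follow their subject.
    """
    regime.validate()
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    splits = []
    for _ in range(regime.repetitions):
        if regime.name == "intra_individual":
            test_sel = np.zeros(len(table), dtype=bool)
            for _, idx in table.groupby(["subject", "isi_group"]).indices.items():
                idx = np.asarray(idx)
                perm = rng.permutation(len(idx))
                n_test = int(round(regime.test_fraction * len(idx)))
                test_sel[idx[perm[:n_test]]] = True
            train = np.flatnonzero(~test_sel)
            test = np.flatnonzero(test_sel)
        elif regime.name == "night_to_night":
            nights = sorted(table["night"].unique())
            if len(nights) < 2:
                raise ValueError("night_to_night requires two nights")
            train = np.flatnonzero(table["night"].to_numpy() == nights[0])
            test = np.flatnonzero(table["night"].to_numpy() == nights[1])
        else:  # subject_wise
            subjects = np.asarray(sorted(table["subject"].unique()))
            if len(subjects) < 5:
                raise ValueError(
                    "subject_wise needs >= 5 subjects to hold out 20%"
                )
            n_test = max(1, int(round(regime.test_fraction * len(subjects))))
            perm = rng.permutation(len(subjects))
            test_subjects = set(subjects[perm[:n_test]])
            in_test = table["subject"].isin(test_subjects).to_numpy()
            train = np.flatnonzero(~in_test)
            test = np.flatnonzero(in_test)
        splits.append((train, test))
    return splits


# ----------------------------------------------------------------------
# model fit / predict
# ----------------------------------------------------------------------
def fit_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
    config: ClassifierConfig | None = None, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, xgb.XGBClassifier | None]:
    """Fit the boosted-tree classifier and predict test classes.

    Labels are arbitrary hashables; prediction is the argmax class
    probability with ties broken by the fixed sorted class order.  Returns
    ``(predicted labels, class probabilities, fitted model)``; a degenerate
    single-class training set yields constant predictions and no model.
    """
    config = config if config is not None else ClassifierConfig()
    config.validate()
    classes = np.asarray(sorted(set(y_train)))
    if len(classes) < 2:
        warnings.warn("single-class training data: constant prediction")
        proba = np.ones((len(X_test), 1))
        return np.full(len(X_test), classes[0]), proba, None
    class_index = {c: i for i, c in enumerate(classes)}
    y_enc = np.array([class_index[c] for c in y_train])

    params = dict(
        learning_rate=config.learning_rate, gamma=config.gamma,
        max_depth=config.max_depth, reg_alpha=config.reg_alpha,
        n_estimators=config.n_estimators, tree_method=config.tree_method,
        n_jobs=config.n_jobs, random_state=seed, verbosity=0,
        eval_metric="mlogloss" if len(classes) > 2 else "logloss",
    )
    if config.use_cv_refinement:
        params.update(_cv_refine(X_train, y_enc, params, config, seed))

    rng = np.random.default_rng(seed)
    n = len(X_train)
    val_n = max(1, int(round(0.1 * n)))
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:val_n], perm[val_n:]
    model = xgb.XGBClassifier(
        **params, early_stopping_rounds=config.early_stopping_rounds
    )
    if len(set(y_enc[fit_idx])) < len(classes):
        # carve-out lost a class entirely; fall back to no early stopping
        model = xgb.XGBClassifier(**params)
        model.fit(X_train, y_enc)
    else:
        model.fit(
            X_train[fit_idx], y_enc[fit_idx],
            eval_set=[(X_train[val_idx], y_enc[val_idx])], verbose=False,
        )
    proba = model.predict_proba(X_test)
    pred = classes[np.argmax(proba, axis=1)]  # argmax takes first max: fixed order
    return pred, proba, model


def _cv_refine(X: np.ndarray, y: np.ndarray, params: dict,
               config: ClassifierConfig, seed: int) -> dict:
    """Small grid search by k-fold CV log-loss on the training rows only."""
    from sklearn.model_selection import StratifiedKFold
    from sklearn.metrics import log_loss

    best, best_loss = {}, np.inf
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=seed)
    for n_est in config.cv_grid_estimators:
        for depth in config.cv_grid_depth:
            trial = dict(params, n_estimators=n_est, max_depth=depth)
            losses = []
            for tr, va in skf.split(X, y):
                m = xgb.XGBClassifier(**trial)
                m.fit(X[tr], y[tr])
                losses.append(
                    log_loss(y[va], m.predict_proba(X[va]),
                             labels=np.unique(y))
                )
            loss = float(np.mean(losses))
            if loss < best_loss:
                best_loss = loss
                best = {"n_estimators": n_est, "max_depth": depth}
    return best


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------
@dataclass
class ClassificationReport:
    """Mean +- SD (percent) of accuracy and macro P/R/F1 over repetitions."""

    regime: str
    stage: str
    metrics: dict[str, tuple[float, float]]  # name -> (mean %, sd %)
    confusion: pd.DataFrame  # summed over repetitions (rows = truth)
    chance_level: float  # percent
    n_repetitions: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"regime": self.regime, "stage": self.stage, "metric": k,
             "mean_pct": m, "sd_pct": s}
            for k, (m, s) in self.metrics.items()
        ]
        return pd.DataFrame(rows)


def score_single(pred: np.ndarray, truth: np.ndarray,
                 classes: np.ndarray | None = None) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1 (fractions, not percent).

    Classes absent from ``truth`` are excluded from the macro averages.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    if classes is None:
        classes = np.unique(np.concatenate([truth, pred]))
    present = [c for c in classes if (truth == c).any()]
    if len(present) < len(classes):
        warnings.warn("classes absent from truth excluded from macro averages")
    prec, rec, f1 = [], [], []
    for c in present:
        tp = float(((pred == c) & (truth == c)).sum())
        fp = float(((pred == c) & (truth != c)).sum())
        fn = float(((pred != c) & (truth == c)).sum())
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    return {
        "accuracy": float((pred == truth).mean()),
        "precision": float(np.mean(prec)),
        "recall": float(np.mean(rec)),
        "f1": float(np.mean(f1)),
    }


def confusion_matrix(pred: np.ndarray, truth: np.ndarray,
                     classes: np.ndarray) -> np.ndarray:
    out = np.zeros((len(classes), len(classes)), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(truth, pred):
        out[idx[t], idx[p]] += 1
    return out


# ----------------------------------------------------------------------
# attribution
# ----------------------------------------------------------------------
@dataclass
class AttributionSummary:
    """Mean |tree-path contribution| per feature, with band-level top-10 shares."""

    mean_abs: pd.Series  # indexed by feature name, descending
    top10: list[str]
    band_shares_top10: dict[str, float]  # fraction of top-10 slots per band family

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.mean_abs.index,
             "mean_abs_contribution": self.mean_abs.to_numpy(),
             "rank": np.arange(1, len(self.mean_abs) + 1)}
        )


def attribute_features(
    model: xgb.XGBClassifier, X: np.ndarray, feature_names: list[str],
    max_rows: int = 1000, rng: np.random.Generator | None = None,
    scheme: BandScheme | None = None,
) -> AttributionSummary:
    """SHAP-style additive attribution from the fitted tree ensemble.

    Uses XGBoost's exact tree-path contributions: for every row, per-feature
    contributions plus the base value reproduce the model margin.  Rows are
    subsampled to ``max_rows``; importance is the mean absolute contribution
    over rows and classes.
    """
    if model is None or not isinstance(model, xgb.XGBClassifier):
        raise TypeError("attribution requires a fitted tree-ensemble model")
    scheme = scheme if scheme is not None else BandScheme()
    if rng is not None and len(X) > max_rows:
        X = X[rng.choice(len(X), size=max_rows, replace=False)]
    else:
        X = X[:max_rows]
    contribs = shap_contributions(model, X)
    mean_abs = np.abs(contribs).mean(axis=tuple(range(contribs.ndim - 1)))
    ser = pd.Series(mean_abs[:-1], index=feature_names)  # last col = base value
    ser = ser.sort_values(ascending=False)
    top10 = list(ser.index[:10])
    fams = [scheme.band_group(band_of_column(c, scheme)) for c in top10]
    shares = {
        fam: fams.count(fam) / len(fams) for fam in sorted(set(fams))
    }
    return AttributionSummary(ser, top10, shares)


def shap_contributions(model: xgb.XGBClassifier, X: np.ndarray) -> np.ndarray:
    """Raw tree-path contributions, shape (rows[, classes], features + 1)."""
    booster = model.get_booster()
    dmat = xgb.DMatrix(X)
    return booster.predict(dmat, pred_contribs=True)


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------
def run_regime(
    table: pd.DataFrame, regime: SplitRegime,
    config: ClassifierConfig | None = None, label: str = "isi_group",
    seed: int = 0, collect_attribution: bool = False,
    attribution_rows: int = 1000,
) -> tuple[ClassificationReport, AttributionSummary | None]:
    """Run one split regime end to end over its repetitions.

    The table is restricted to the regime's stage subset; per-repetition
    seeds are derived from ``seed`` by counter.  When
    ``collect_attribution`` is set, tree-path attributions from each
    repetition's test rows are averaged into one summary.
    """
    config = config if config is not None else ClassifierConfig()
    sub = table[table["stage"] == regime.stage].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no rows in stage subset {regime.stage!r}")
    X, feat_names = feature_matrix(sub)
    y = sub[label].to_numpy()
    classes = np.asarray(sorted(set(y)))
    rng = np.random.default_rng(seed)
    splits = make_splits(sub, regime, rng)

    metrics_per_rep: list[dict[str, float]] = []
    conf_total = np.zeros((len(classes), len(classes)), dtype=int)
    attr_accum: pd.Series | None = None
    for rep, (train, test) in enumerate(splits):
        # the night-to-night design is fully deterministic: identical split
        # and identical model every repetition, hence zero metric SD
        rep_seed = seed if regime.name == "night_to_night" else seed + rep
        if regime.name == "subject_wise":
            assert not (
                set(sub["subject"].iloc[train]) & set(sub["subject"].iloc[test])
            ), "subject leakage in subject_wise split"
        pred, _, model = fit_predict(
            X[train], y[train], X[test], config, seed=rep_seed
        )
        metrics_per_rep.append(score_single(pred, y[test], classes))
        conf_total += confusion_matrix(pred, y[test], classes)
        if collect_attribution and model is not None:
            summ = attribute_features(
                model, X[test], feat_names, max_rows=attribution_rows,
                rng=np.random.default_rng(rep_seed),
            )
            attr_accum = (
                summ.mean_abs if attr_accum is None
                else attr_accum.add(summ.mean_abs, fill_value=0.0)
            )

    names = ("accuracy", "precision", "recall", "f1")
    metrics = {}
    for name in names:
        vals = 100.0 * np.array([m[name] for m in metrics_per_rep])
        metrics[name] = (float(vals.mean()), float(vals.std()))
    report = ClassificationReport(
        regime=regime.name, stage=regime.stage, metrics=metrics,
        confusion=pd.DataFrame(conf_total, index=classes, columns=classes),
        chance_level=100.0 / len(classes), n_repetitions=regime.repetitions,
    )
    attribution = None
    if attr_accum is not None:
        ser = (attr_accum / regime.repetitions).sort_values(ascending=False)
        scheme = BandScheme()
        top10 = list(ser.index[:10])
        fams = [scheme.band_group(band_of_column(c, scheme)) for c in top10]
        attribution = AttributionSummary(
            ser, top10,
            {fam: fams.count(fam) / len(fams) for fam in sorted(set(fams))},
        )
    return report, attribution
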