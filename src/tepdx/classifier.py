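"""RBF-SVM classifier over the selected gene panel, plus the CA125 combination.

Hyperparameters (cost, sigma) are tuned by seeded random search under
stratified cross-validation; probabilities come from Platt scaling fitted on
out-of-fold decision values; the operating cut-off is 0.5. A logistic
stacking model combines the panel probability with log10 serum CA125 and
falls back to the panel alone whenever CA125 is missing.

Trained models are frozen, self-contained objects (panel ids, training
standardization constants, support vectors, kernel and Platt parameters) and
serialize to versioned JSON, so prediction never touches training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "Hyperparams",
    "TrainedModel",
    "CombinedModel",
    "tune_svm",
    "train_svm",
    "predict",
    "fit_combiner",
    "predict_combined",
    "ca125_rule",
    "model_to_json",
    "model_from_json",
]

CA125_CUTOFF = 35.0  # mU/L, conventional clinical positivity threshold


@dataclass(frozen=True)
class Hyperparams:
    cost: float
    sigma: float  # RBF width in the k(x,y)=exp(-sigma*||x-y||^2) convention

    def __post_init__(self):
        if self.cost <= 0 or self.sigma <= 0:
            raise ValueError("cost and sigma must be positive")


@dataclass
class TrainedModel:
    panel: list  # ordered gene ids
    mean: np.ndarray  # per-gene training means
    sd: np.ndarray  # per-gene training sds
    support_vectors: np.ndarray  # standardized
    dual_coef: np.ndarray
    intercept: float
    hyperparams: Hyperparams
    platt_a: float
    platt_b: float
    threshold: float = 0.5

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=-1)
        K = np.exp(-self.hyperparams.sigma * d2)
        return K @ self.dual_coef + self.intercept


@dataclass
class CombinedModel:
    coef_logit_tep: float
    coef_log_ca125: float
    intercept: float


def _binary_y(y) -> np.ndarray:
    """0/1 encoding with OC as the positive class when present."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got {list(classes)}")
    if "OC" in classes:
        return (y == "OC").astype(int)
    if set(classes) == {0, 1}:
        return y.astype(int)
    return (y == classes[-1]).astype(int)


def _align_panel(X_new: pd.DataFrame, panel: list) -> np.ndarray:
    missing = [g for g in panel if g not in X_new.columns]
    if missing:
        raise KeyError(f"panel genes missing from input: {missing}")
    return X_new.loc[:, panel].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# tuning and training
# ---------------------------------------------------------------------------


def tune_svm(
    X: pd.DataFrame,
    y,
    n_draws: int = 5000,
    folds: int = 10,
    seed: int = 0,
) -> Hyperparams:
    """Random search for (cost, sigma) maximizing stratified CV accuracy.

    Draws are log-uniform over the conventional libsvm grids, cost in
    [2^-5, 2^15] and sigma in [2^-15, 2^3]; ties go to the first draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    yb = _binary_y(y)
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    log_cost = rng.uniform(-5, 15, n_draws)
    log_sigma = rng.uniform(-15, 3, n_draws)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = [(tr, te) for tr, te in cv.split(Xv, yb)]
    scaled = []
    for tr, te in splits:
        mean = Xv[tr].mean(axis=0)
        sd = Xv[tr].std(axis=0)
        sd[sd == 0] = 1.0
        scaled.append(((Xv[tr] - mean) / sd, (Xv[te] - mean) / sd, yb[tr], yb[te]))
    best_acc, best = -np.inf, None
    for c, s in zip(2.0 ** log_cost, 2.0 ** log_sigma):
        accs = []
        for Xtr, Xte, ytr, yte in scaled:
            clf = SVC(C=c, gamma=s, kernel="rbf")
            clf.fit(Xtr, ytr)
            accs.append(np.mean(clf.predict(Xte) == yte))
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict: ties keep the earlier draw
            best_acc, best = acc, Hyperparams(cost=float(c), sigma=float(s))
    return best


def train_svm(X: pd.DataFrame, y, hp: Hyperparams, seed: int = 0, platt_folds: int = 5) -> TrainedModel:
    """Fit the RBF SVM on standardized panel expression with Platt scaling.

    Platt's sigmoid is fitted on out-of-fold decision values (stratified
    ``platt_folds``-fold refits) to avoid the optimism of resubstitution
    decision values.
    """
    yb = _binary_y(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("training labels contain a single class")
    Xv = X.to_numpy(dtype=float)
    mean = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance panel gene; cannot standardize")
    Xs = (Xv - mean) / sd

    svc = SVC(C=hp.cost, gamma=hp.sigma, kernel="rbf")
    svc.fit(Xs, yb)

    # out-of-fold decision values for the Platt fit
    dec_oof = np.zeros(len(yb))
    cv = StratifiedKFold(n_splits=platt_folds, shuffle=True, random_state=seed)
    for tr, te in cv.split(Xs, yb):
        f = SVC(C=hp.cost, gamma=hp.sigma, kernel="rbf")
        f.fit(Xs[tr], yb[tr])
        dec_oof[te] = f.decision_function(Xs[te])
    platt = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    platt.fit(dec_oof[:, None], yb)

    return TrainedModel(
        panel=list(X.columns),
        mean=mean,
        sd=sd,
        support_vectors=Xs[svc.support_],
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        hyperparams=hp,
        platt_a=float(platt.coef_[0, 0]),
        platt_b=float(platt.intercept_[0]),
    )


def predict(model: TrainedModel, X_new: pd.DataFrame):
    """Panel probabilities and OC calls for new samples (id-keyed alignment).

    A sample is called OC when its probability is >= the model threshold
    (ties at exactly 0.5 count as positive).
    """
    Xv = _align_panel(X_new, model.panel)
    Xs = (Xv - model.mean) / model.sd
    dec = model.decision_function(Xs)
    probs = expit(model.platt_a * dec + model.platt_b)
    probs = pd.Series(probs, index=X_new.index, name="prob_oc")
    calls = pd.Series(np.where(probs >= model.threshold, "OC", "control"), index=X_new.index)
    return probs, calls


# ---------------------------------------------------------------------------
# CA125 and the combination model
# ---------------------------------------------------------------------------


def ca125_rule(ca125) -> pd.Series:
    """Clinical CA125 call: positive iff >= 35 mU/L; missing stays missing."""
    s = pd.Series(ca125, dtype=float)
    if (s.dropna() < 0).any():
        raise ValueError("negative CA125 values")
    out = pd.Series(pd.NA, index=s.index, dtype="object")
    out[s >= CA125_CUTOFF] = "OC"
    out[s < CA125_CUTOFF] = "control"
    return out


def _stack_features(tep_probs: np.ndarray, ca125: np.ndarray) -> np.ndarray:
    p = np.clip(tep_probs, 1e-12, 1 - 1e-12)
    return np.column_stack([logit(p), np.log10(ca125 + 1.0)])


def fit_combiner(tep_probs, ca125, y) -> CombinedModel:
    """Logistic stacking of the panel probability and log10 CA125.

    Fit on training-cohort outputs only, using complete cases; samples with
    missing CA125 contribute nothing to the fit and fall back to the panel
    probability at prediction time.
    """
    tep = np.asarray(tep_probs, dtype=float)
    ca = np.asarray(ca125, dtype=float)
    yb = _binary_y(y)
    ok = ~np.isnan(ca)
    if not ok.any():
        raise ValueError("cannot fit the combination model: all CA125 values missing")
    Z = _stack_features(tep[ok], ca[ok])
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(Z, yb[ok])
    return CombinedModel(
        coef_logit_tep=float(lr.coef_[0, 0]),
        coef_log_ca125=float(lr.coef_[0, 1]),
        intercept=float(lr.intercept_[0]),
    )


def predict_combined(cm: CombinedModel, tep_probs, ca125) -> pd.Series:
    """Combined probability; equals the panel probability where CA125 is missing."""
    tep = pd.Series(tep_probs, dtype=float)
    ca = pd.Series(ca125, dtype=float).reindex(tep.index)
    out = tep.copy()
    ok = ca.notna().to_numpy()
    if ok.any():
        Z = _stack_features(tep.to_numpy()[ok], ca.to_numpy()[ok])
        z = cm.intercept + Z @ np.array([cm.coef_logit_tep, cm.coef_log_ca125])
        out.iloc[np.flatnonzero(ok)] = expit(z)
    return out.rename("prob_oc_combined")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def model_to_json(model: TrainedModel) -> str:
    payload = {
        "format_version": _FORMAT_VERSION,
        "panel": model.panel,
        "mean": model.mean.tolist(),
        "sd": model.sd.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "cost": model.hyperparams.cost,
        "sigma": model.hyperparams.sigma,
        "platt_a": model.platt_a,
        "platt_b": model.platt_b,
        "threshold": model.threshold,
    }
    return json.dumps(payload)


def model_from_json(text: str) -> TrainedModel:
    d = json.loads(text)
    if d.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {d.get('format_version')}")
    return TrainedModel(
        panel=list(d["panel"]),
        mean=np.asarray(d["mean"], dtype=float),
        sd=np.asarray(d["sd"], dtype=float),
        support_vectors=np.asarray(d["support_vectors"], dtype=float),
        dual_coef=np.asarray(d["dual_coef"], dtype=float),
        intercept=float(d["intercept"]),
        hyperparams=Hyperparams(cost=float(d["cost"]), sigma=float(d["sigma"])),
        platt_a=float(d["platt_a"]),
        platt_b=float(d["platt_b"]),
        threshold=float(d["threshold"]),
    )
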