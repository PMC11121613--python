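"""Two-class OPLS-DA with cross-validated Q², permutation check and VIP.

Orthogonal projections to latent structures (O-PLS) splits the
X-variation into one component predictive of the class vector y and
a configurable number of components orthogonal to it.  For a single
response the algorithm is deterministic and non-iterative:

    w  ∝  X'y                         (predictive weight, ||w|| = 1)
    repeat for each orthogonal component:
        t    = X w
        p    = X't / t't
        w_o  = p - (w'p) w,  normalized
        t_o  = X w_o
        p_o  = X't_o / t_o't_o
        X   <- X - t_o p_o'           (remove y-orthogonal variation)
    t = X w;  p = X't / t't;  c = y't / t't

Inputs are log2-transformed (optional) and column-mean-centered; y is
coded -1/+1 and centered.  No variance scaling is applied by default,
i.e. centering only.  Model quality is reported as R²Y (in-sample) and
Q² = 1 - PRESS/TSS from stratified k-fold cross-validation (falling
back to leave-one-out when the fold count exceeds the sample count);
Q² > 0.5 is the conventional validity rule.  Per-feature importance is
the standard PLS VIP over the predictive component(s), normalised so
that the mean squared VIP is 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import child_rng

logger = logging.getLogger(__name__)

Q2_VALIDITY_THRESHOLD = 0.5


@dataclass
class OplsModel:
    """Fitted two-class OPLS-DA model (one predictive component)."""

    weights: np.ndarray          # predictive weight vector w, unit norm
    loadings: np.ndarray         # predictive loading vector p
    scores: np.ndarray           # predictive scores t (n samples)
    coef_c: float                # inner regression coefficient c
    ortho_weights: np.ndarray    # (p, k) orthogonal weights
    ortho_loadings: np.ndarray   # (p, k) orthogonal loadings
    ortho_scores: np.ndarray     # (n, k) orthogonal scores
    r2y: float
    r2x_pred: float
    r2x_ortho: np.ndarray        # per orthogonal component
    x_mean: np.ndarray
    y_mean: float
    classes: tuple[str, str]
    feature_names: list[str]
    log2: bool
    dropped_features: list[str] = field(default_factory=list)
    q2: float | None = None
    vip: pd.Series | None = None

    @property
    def n_ortho(self) -> int:
        return self.ortho_scores.shape[1]


def _prepare_xy(X, y, log2: bool):
    """Coerce inputs, log2-transform, drop constant columns, center."""
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
    y = np.asarray(y)
    if Xv.shape[0] != y.shape[0]:
        raise ValueError("X and y have different sample counts")
    classes = sorted(pd.unique(y).tolist(), key=str)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 samples")
    yv = np.where(y == classes[1], 1.0, -1.0)
    if log2:
        if np.any(Xv <= 0):
            raise ValueError("log2 transform requires strictly positive X")
        Xv = np.log2(Xv)
    keep = Xv.std(axis=0) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("dropping %d constant feature(s)", len(dropped))
        Xv = Xv[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    x_mean = Xv.mean(axis=0)
    y_mean = yv.mean()
    return Xv - x_mean, yv - y_mean, x_mean, y_mean, tuple(map(str, classes)), names, dropped


def fit_opls(X, y, n_ortho: int = 1, log2: bool = True) -> OplsModel:
    """Fit a two-class OPLS-DA model.

    Parameters
    ----------
    X:
        samples x features matrix (DataFrame or array), raw scale.
    y:
        length-n class label vector with exactly two levels (>= 2
        samples each).  Labels are sorted; the second one is coded +1
        and oriented to positive mean predictive score.
    n_ortho:
        number of orthogonal components (0 reduces the model to
        one-component PLS1).
    log2:
        log2-transform X before centering (the convention for
        metabolite intensity matrices).
    """
    Xc, yc, x_mean, y_mean, classes, names, dropped = _prepare_xy(X, y, log2)
    n, p = Xc.shape
    if n_ortho < 0 or n_ortho > n - 2:
        raise ValueError("n_ortho must be between 0 and n_samples - 2")
    ssx_total = float((Xc**2).sum())
    ssy_total = float((yc**2).sum())

    w = Xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("X carries no covariance with y")
    w = w / norm

    Xd = Xc.copy()
    W_o = np.zeros((p, n_ortho))
    P_o = np.zeros((p, n_ortho))
    T_o = np.zeros((n, n_ortho))
    r2x_ortho = np.zeros(n_ortho)
    for k in range(n_ortho):
        t = Xd @ w
        pv = Xd.T @ t / (t @ t)
        w_o = pv - (w @ pv) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            logger.warning("orthogonal component %d is null; truncating", k + 1)
            W_o, P_o, T_o, r2x_ortho = W_o[:, :k], P_o[:, :k], T_o[:, :k], r2x_ortho[:k]
            break
        w_o = w_o / nrm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[:, k], P_o[:, k], T_o[:, k] = w_o, p_o, t_o
        r2x_ortho[k] = float((np.outer(t_o, p_o) ** 2).sum()) / ssx_total

    t = Xd @ w
    pv = Xd.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))

    # orient: second listed class gets positive mean predictive score
    if t[yc > 0].mean() < 0:
        w, t, pv, c = -w, -t, -pv, -c

    r2y = 1.0 - float(((yc - c * t) ** 2).sum()) / ssy_total
    r2x_pred = float((np.outer(t, pv) ** 2).sum()) / ssx_total
    return OplsModel(
        weights=w,
        loadings=pv,
        scores=t,
        coef_c=c,
        ortho_weights=W_o,
        ortho_loadings=P_o,
        ortho_scores=T_o,
        r2y=r2y,
        r2x_pred=r2x_pred,
        r2x_ortho=r2x_ortho,
        x_mean=x_mean,
        y_mean=y_mean,
        classes=classes,
        feature_names=names,
        log2=log2,
        dropped_features=dropped,
    )


def predict_scores(model: OplsModel, X_new) -> np.ndarray:
    """Predictive scores of new samples (orthogonal filtering applied)."""
    if isinstance(X_new, pd.DataFrame):
        X_new = X_new[model.feature_names].to_numpy(dtype=float)
    else:
        X_new = np.asarray(X_new, dtype=float)
    if model.log2:
        X_new = np.log2(X_new)
    Xc = X_new - model.x_mean
    for k in range(model.n_ortho):
        t_o = Xc @ model.ortho_weights[:, k]
        Xc = Xc - np.outer(t_o, model.ortho_loadings[:, k])
    return Xc @ model.weights


def predict_y(model: OplsModel, X_new) -> np.ndarray:
    """Predicted (continuous) class code of new samples."""
    return predict_scores(model, X_new) * model.coef_c + model.y_mean


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle within class, deal samples round-robin across folds.

    A running offset carries the dealing across classes so that all
    folds fill before any fold receives a second sample (folds equal to
    the sample count therefore yields leave-one-out).
    """
    assignments = np.zeros(len(y), dtype=int)
    offset = 0
    for cls in pd.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        assignments[idx] = (offset + np.arange(len(idx))) % folds
        offset += len(idx)
    return [np.flatnonzero(assignments == f) for f in range(folds)]


def cross_validated_q2(
    X,
    y,
    n_ortho: int = 1,
    folds: int = 7,
    log2: bool = True,
    seed: int = 0,
) -> float:
    """Q² = 1 - PRESS/TSS over held-out class predictions.

    Folds are stratified by class; when ``folds`` exceeds the sample
    count the split degenerates to leave-one-out (logged).  TSS uses
    the overall class-code mean, PRESS the per-fold refit predictions.
    Deterministic given ``seed``.
    """
    if isinstance(X, pd.DataFrame):
        Xv = X.to_numpy(dtype=float)
        Xdf = X
    else:
        Xv = np.asarray(X, dtype=float)
        Xdf = None
    y = np.asarray(y)
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        logger.info("folds=%d > n=%d; falling back to leave-one-out", folds, n)
        folds = n
    classes = sorted(pd.unique(y).tolist(), key=str)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    ycode = np.where(y == classes[1], 1.0, -1.0)
    rng = child_rng(seed, "opls:cv")
    fold_idx = [f for f in _stratified_folds(y, folds, rng) if len(f)]
    press = 0.0
    for test in fold_idx:
        train = np.setdiff1d(np.arange(n), test)
        y_train = y[train]
        if len(pd.unique(y_train)) < 2:
            raise ValueError("a training fold lost one class; use fewer folds")
        k = min(n_ortho, len(train) - 2)
        Xtr = Xdf.iloc[train] if Xdf is not None else Xv[train]
        Xte = Xdf.iloc[test] if Xdf is not None else Xv[test]
        model = fit_opls(Xtr, y_train, n_ortho=k, log2=log2)
        if Xdf is not None:
            Xte = Xte[model.feature_names]
        y_hat = predict_y(model, Xte)
        press += float(((ycode[test] - y_hat) ** 2).sum())
    tss = float(((ycode - ycode.mean()) ** 2).sum())
    return 1.0 - press / tss


def permutation_q2(
    X, y, n_ortho: int = 1, folds: int = 7, log2: bool = True,
    n_permutations: int = 100, seed: int = 0,
) -> np.ndarray:
    """Null distribution of Q² under random relabelling of y."""
    rng = child_rng(seed, "opls:permutation")
    y = np.asarray(y)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = y[rng.permutation(len(y))]
        try:
            out[i] = cross_validated_q2(
                X, y_perm, n_ortho=n_ortho, folds=folds, log2=log2, seed=seed + i + 1
            )
        except ValueError:
            out[i] = np.nan
    return out


def compute_vip(model: OplsModel) -> pd.Series:
    """Variable importance in projection over the predictive component.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with unit-norm
    weights; with a single predictive component this reduces to
    sqrt(p) * |w_j|, and the squared VIPs always sum to the feature
    count.
    """
    if model.weights is None:
        raise ValueError("model is not fitted")
    p = len(model.weights)
    vip = np.sqrt(p) * np.abs(model.weights)
    series = pd.Series(vip, index=model.feature_names, name="vip")
    model.vip = series
    return series


def validate_model(q2: float, threshold: float = Q2_VALIDITY_THRESHOLD) -> bool:
    """A discriminant model is accepted iff Q² strictly exceeds the threshold."""
    return q2 > threshold


def model_summary(model: OplsModel) -> pd.DataFrame:
    """One-row-per-component summary (report surface)."""
    rows = [
        {
            "component": "predictive",
            "r2x": model.r2x_pred,
            "r2y": model.r2y,
            "q2": model.q2 if model.q2 is not None else np.nan,
        }
    ]
    for k in range(model.n_ortho):
        rows.append(
            {"component": f"orthogonal_{k + 1}", "r2x": model.r2x_ortho[k],
             "r2y": np.nan, "q2": np.nan}
        )
    return pd.DataFrame(rows)
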