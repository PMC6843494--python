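"""OPLS / OPLS-DA with cross-validation, jack-knife confidence intervals,
VIP and p(corr).

The discriminant model regresses a centred 0/1 class vector on a
UV-scaled metabolite matrix.  Variation in X that is orthogonal to y is
removed component by component before a single predictive component is
extracted, so between-group differences concentrate in one score vector
t while within-group (orthogonal) structure is modelled separately:

    w   ∝ X'y                      (predictive weights, unit norm)
    p   = X't / (t't)              (loadings for the current X)
    w_o ∝ p − (w'p) w              (orthogonal weights, unit norm)
    t_o = X w_o ;  p_o = X't_o / (t_o't_o) ;  X ← X − t_o p_o'

With zero orthogonal components the model coincides with one-component
PLS1.  Diagnostics follow chemometrics conventions: R²X (fraction of X
sum-of-squares modelled by predictive + orthogonal components), R²Y(cum)
(explained y variance), Q²(cum) = 1 − PRESS/SS from k-fold
cross-validation, p(corr) (correlation of each scaled variable with t)
and VIP normalised so that the mean squared VIP is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .normalize import apply_scaling, uv_scale

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass
class OplsModel:
    n_orthogonal: int
    mean_x: np.ndarray
    sd_x: np.ndarray
    mean_y: float
    w: np.ndarray            # predictive weights, unit norm
    t: np.ndarray            # predictive scores (training)
    p: np.ndarray            # predictive loadings
    w_o: np.ndarray          # n_variables × n_orthogonal
    t_o: np.ndarray          # n_samples × n_orthogonal
    p_o: np.ndarray          # n_variables × n_orthogonal
    b: float                 # regression of centred y on t
    r2x: float
    r2y_cum: float
    pcorr: np.ndarray
    vip: np.ndarray
    q2_cum: float | None = None
    ss_x_pred: float = 0.0       # X sum-of-squares captured by the predictive comp
    ss_x_orth: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ss_y_pred: float = 0.0       # y sum-of-squares explained by the predictive comp


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ModelError("X and y have different numbers of samples")
    if np.unique(y).size < 2:
        raise ModelError("y contains a single class; OPLS-DA needs both groups")
    return X, y


def fit_opls(X: np.ndarray, y: np.ndarray, n_orthogonal: int = 1) -> OplsModel:
    """Fit an OPLS(-DA) model with one predictive component.

    X is UV-scaled and y centred internally.  ``n_orthogonal`` y-orthogonal
    components are removed sequentially before the predictive component is
    computed on the filtered matrix.
    """
    X, y = _validate_xy(X, y)
    n, k = X.shape
    if n_orthogonal >= min(n, k):
        raise ModelError(f"n_orthogonal={n_orthogonal} too large for an {n}×{k} matrix")
    Z, mean_x, sd_x = uv_scale(X)
    mean_y = float(y.mean())
    yc = y - mean_y

    ss_x_total = float((Z ** 2).sum())
    ss_y_total = float((yc ** 2).sum())

    Xf = Z.copy()
    w_o = np.zeros((k, n_orthogonal))
    t_o = np.zeros((n, n_orthogonal))
    p_o = np.zeros((k, n_orthogonal))
    ss_x_orth = np.zeros(n_orthogonal)
    for a in range(n_orthogonal):
        w = Xf.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ModelError("X'y vanished; no predictive direction")
        w /= nw
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        wo = p - (w @ p) * w
        nwo = np.linalg.norm(wo)
        if nwo <= 1e-12:
            raise ModelError(f"orthogonal component {a + 1}: no orthogonal variation left")
        wo /= nwo
        to = Xf @ wo
        po = Xf.T @ to / (to @ to)
        Xf = Xf - np.outer(to, po)
        w_o[:, a], t_o[:, a], p_o[:, a] = wo, to, po
        ss_x_orth[a] = float((to @ to) * (po @ po))

    w = Xf.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ModelError("X'y vanished; no predictive direction")
    w /= nw
    t = Xf @ w
    p = Xf.T @ t / (t @ t)
    b = float((t @ yc) / (t @ t))

    ss_x_pred = float((t @ t) * (p @ p))
    yhat_c = b * t
    ss_y_pred = float((yhat_c ** 2).sum())
    r2y = 1.0 - float(((yc - yhat_c) ** 2).sum()) / ss_y_total
    r2x = (ss_x_pred + ss_x_orth.sum()) / ss_x_total

    # p(corr): correlation of each scaled variable (pre-deflation) with t
    tc = t - t.mean()
    Zc = Z - Z.mean(axis=0)
    denom = np.sqrt((Zc ** 2).sum(axis=0) * (tc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        pcorr = (Zc.T @ tc) / denom
    pcorr = np.clip(np.nan_to_num(pcorr), -1.0, 1.0)

    model = OplsModel(
        n_orthogonal=n_orthogonal, mean_x=mean_x, sd_x=sd_x, mean_y=mean_y,
        w=w, t=t, p=p, w_o=w_o, t_o=t_o, p_o=p_o, b=b,
        r2x=r2x, r2y_cum=r2y, pcorr=pcorr, vip=np.zeros(k),
        ss_x_pred=ss_x_pred, ss_x_orth=ss_x_orth, ss_y_pred=ss_y_pred,
    )
    model.vip = vip(model)
    return model


def vip(model: OplsModel) -> np.ndarray:
    """Total VIP over predictive and orthogonal components.

    The predictive component's squared weights are weighted by the y
    sum-of-squares it explains, each orthogonal component's by the X
    sum-of-squares it captures; the result is normalised so that
    Σ VIP² = n_variables (mean squared VIP = 1), making the conventional
    0.8 significance threshold applicable.
    """
    k = model.w.shape[0]
    weights = model.ss_y_pred * model.w ** 2
    total = model.ss_y_pred
    for a in range(model.n_orthogonal):
        weights = weights + model.ss_x_orth[a] * model.w_o[:, a] ** 2
        total += model.ss_x_orth[a]
    if total == 0:
        return np.ones(k)
    return np.sqrt(k * weights / total)


def predict(model: OplsModel, Xnew: np.ndarray) -> np.ndarray:
    """Predict y for new samples.

    Applies the stored scaling, strips orthogonal variation with the
    stored w_o/p_o, and returns ŷ = b·t + mean(y).
    """
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[None, :]
    if Xnew.shape[1] != model.mean_x.shape[0]:
        raise ModelError(
            f"variable mismatch: model has {model.mean_x.shape[0]} variables, "
            f"new data has {Xnew.shape[1]}"
        )
    Z = apply_scaling(Xnew, model.mean_x, model.sd_x)
    for a in range(model.n_orthogonal):
        to = Z @ model.w_o[:, a]
        Z = Z - np.outer(to, model.p_o[:, a])
    t = Z @ model.w
    return model.b * t + model.mean_y


@dataclass
class CrossValidation:
    n_folds: int
    folds: np.ndarray            # fold index per sample
    cv_predicted_y: np.ndarray   # out-of-fold prediction per sample
    press: float
    q2: float
    fold_models: list[OplsModel]


def assign_folds(y: np.ndarray, sample_ids: list[str] | None, n_folds: int) -> np.ndarray:
    """Deterministic folds: samples sorted by (class, sample_id), dealt
    round-robin so every fold sees both classes where possible."""
    n = y.shape[0]
    if sample_ids is None:
        sample_ids = [f"{i:06d}" for i in range(n)]
    order = sorted(range(n), key=lambda i: (y[i], sample_ids[i]))
    folds = np.empty(n, dtype=int)
    for pos, i in enumerate(order):
        folds[i] = pos % n_folds
    return folds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 7,
    n_orthogonal: int = 1,
    sample_ids: list[str] | None = None,
) -> CrossValidation:
    """k-fold cross-validation of the OPLS model (default seven-fold).

    Each fold's samples are predicted by a model refit (including scaling)
    on the remaining samples; Q² = 1 − PRESS / Σ(y−ȳ)².
    """
    X, y = _validate_xy(X, y)
    if n_folds < 2:
        raise ModelError("n_folds must be at least 2")
    n = y.shape[0]
    smallest = int(min(np.sum(y == c) for c in np.unique(y)))
    if n_folds > n:
        logger.warning("reducing n_folds from %d to n=%d", n_folds, n)
        n_folds = n
    if smallest < n_folds < n:
        logger.warning("smallest class has %d < %d samples; some folds may miss a class",
                       smallest, n_folds)
    folds = assign_folds(y, sample_ids, n_folds)
    yhat = np.empty(n)
    fold_models: list[OplsModel] = []
    for g in range(n_folds):
        test = folds == g
        model = fit_opls(X[~test], y[~test], n_orthogonal)
        fold_models.append(model)
        yhat[test] = predict(model, X[test])
    press = float(((y - yhat) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / ss
    return CrossValidation(n_folds, folds, yhat, press, q2, fold_models)


def fit_opls_cv(X, y, n_folds: int = 7, n_orthogonal: int = 1,
                sample_ids: list[str] | None = None) -> tuple[OplsModel, CrossValidation]:
    """Fit the full model and attach Q²(cum) from cross-validation."""
    model = fit_opls(X, y, n_orthogonal)
    cv = cross_validate(X, y, n_folds, n_orthogonal, sample_ids)
    model.q2_cum = cv.q2
    return model, cv


def predicted_y_test(cv: CrossValidation, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test on cross-validated predicted y
    between the two classes; returns (t, p)."""
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ModelError("predicted-y test needs exactly two classes")
    a = cv.cv_predicted_y[y == classes[1]]
    b = cv.cv_predicted_y[y == classes[0]]
    if min(a.size, b.size) < 2:
        raise ModelError("each class needs at least 2 samples")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class JackknifeResult:
    statistic: np.ndarray     # full-model per-variable statistic
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    significant: np.ndarray   # CI excludes 0


def jackknife_ci(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 7,
    n_orthogonal: int = 1,
    alpha: float = 0.05,
    statistic: str = "pcorr",
    sample_ids: list[str] | None = None,
) -> JackknifeResult:
    """Jack-knife confidence intervals over cross-validation sub-models.

    Each of the G = n_folds rounds refits the model without one fold and
    records the per-variable statistic (p(corr) by default, scaled
    regression coefficients b·w via ``statistic='coef'``), with its sign
    aligned to the full model's predictive score direction.  Then

        SE_j = sqrt( (G−1)/G · Σ_g (s_gj − s̄_j)² )
        CI_j = s_j(full) ± t_{1−alpha/2, G−1} · SE_j

    and a variable is significant when its CI excludes zero.
    """
    X, y = _validate_xy(X, y)
    if statistic not in ("pcorr", "coef"):
        raise ValueError(f"statistic must be 'pcorr' or 'coef', got {statistic!r}")
    full = fit_opls(X, y, n_orthogonal)
    cv = cross_validate(X, y, n_folds, n_orthogonal, sample_ids)
    G = cv.n_folds
    if G < 3:
        raise ModelError("jack-knife needs at least 3 cross-validation rounds")

    def stat_of(m: OplsModel) -> np.ndarray:
        return m.pcorr if statistic == "pcorr" else m.b * m.w

    full_stat = stat_of(full)
    S = np.empty((G, X.shape[1]))
    for g, m in enumerate(cv.fold_models):
        # NIPALS/OPLS sign is indeterminate per refit: align by the score
        # direction on the shared training samples
        train = cv.folds != g
        sign = np.sign(float(m.t @ full.t[train])) or 1.0
        S[g] = sign * stat_of(m)
    se = np.sqrt((G - 1) / G * ((S - S.mean(axis=0)) ** 2).sum(axis=0))
    tcrit = sps.t.ppf(1 - alpha / 2, G - 1)
    lower = full_stat - tcrit * se
    upper = full_stat + tcrit * se
    significant = (lower > 0) | (upper < 0)
    return JackknifeResult(full_stat, se, lower, upper, significant)
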