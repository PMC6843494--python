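"""NIPALS principal component analysis with projection, Hotelling T² and
the multivariate-design representative-sample selector.

NIPALS extracts components sequentially, which matches how chemometrics
software reports per-component R²X and keeps the algorithm well defined
for the low-rank, few-sample matrices typical of designed metabolomics
studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .normalize import apply_scaling, uv_scale

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PcaModel:
    n_components: int
    mean: np.ndarray            # per-variable centring
    sd: np.ndarray              # per-variable scaling (ones if scaling='none')
    scores: np.ndarray          # n_samples × n_components
    loadings: np.ndarray        # n_variables × n_components, unit-norm columns
    r2x_per_component: np.ndarray


def _nipals_component(X: np.ndarray, tol: float = 1e-10, max_iter: int = 500,
                      index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One NIPALS PCA component; deterministic start at the column of
    largest variance."""
    start = int(np.argmax(X.var(axis=0)))
    t = X[:, start].copy()
    if not np.any(t):
        raise ConvergenceError(f"component {index}: residual matrix is zero")
    for _ in range(max_iter):
        p = X.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t_new = X @ p
        if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
            return t_new, p
        t = t_new
    raise ConvergenceError(f"component {index}: NIPALS did not converge in {max_iter} iterations")


def fit_pca(X: np.ndarray, n_components: int, scaling: str = "uv",
            center: bool = True) -> PcaModel:
    """Fit a NIPALS PCA.

    ``scaling='uv'`` centres and scales each column to unit variance;
    ``scaling='none'`` centres only (set ``center=False`` for a fully raw
    cross-product model, as used for combined loading profiles).
    Loading signs follow the convention that each column's
    largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n_components > min(n, k):
        raise ValueError(f"n_components={n_components} exceeds min(dims)={min(n, k)}")
    if scaling == "uv":
        Z, mean, sd = uv_scale(X)
    elif scaling == "none":
        mean = X.mean(axis=0) if center else np.zeros(k)
        sd = np.ones(k)
        Z = X - mean
    else:
        raise ValueError(f"scaling must be 'uv' or 'none', got {scaling!r}")

    ss_total = float((Z ** 2).sum())
    R = Z.copy()
    scores = np.zeros((n, n_components))
    loadings = np.zeros((k, n_components))
    r2x = np.zeros(n_components)
    for a in range(n_components):
        t, p = _nipals_component(R, index=a)
        j = int(np.argmax(np.abs(p)))
        if p[j] < 0:
            p, t = -p, -t
        scores[:, a] = t
        loadings[:, a] = p
        r2x[a] = float(t @ t) / ss_total if ss_total > 0 else 0.0
        R = R - np.outer(t, p)
    return PcaModel(n_components, mean, sd, scores, loadings, r2x)


def project(model: PcaModel, Xnew: np.ndarray) -> np.ndarray:
    """Score new samples in an existing PCA model.

    Applies the model's stored centring/scaling, then multiplies by the
    loadings.  Projecting the training data reproduces the training scores.
    """
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[None, :]
    if Xnew.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"variable mismatch: model has {model.mean.shape[0]} variables, "
            f"new data has {Xnew.shape[1]}"
        )
    Z = apply_scaling(Xnew, model.mean, model.sd)
    return Z @ model.loadings


def hotelling_t2(model: PcaModel, scores: np.ndarray,
                 alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Hotelling T² of score vectors and its (1−alpha) control limit.

    T²_i = Σ_a t_ia² / s_a² with s_a² the training score variance; the
    limit uses the F distribution with (A, n−A) degrees of freedom:
    A(n−1)/(n−A) · F_{1−alpha}.
    """
    if model.n_components < 1:
        raise ValueError("model must have at least one component")
    n, A = model.scores.shape
    if n <= A:
        raise ValueError("need more training samples than components for a T² limit")
    s2 = model.scores.var(axis=0, ddof=1)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    t2 = ((scores ** 2) / s2[None, :]).sum(axis=1)
    limit = A * (n - 1) / (n - A) * stats.f.ppf(1 - alpha, A, n - A)
    return t2, float(limit)


def select_representative(scores: np.ndarray, sample_ids: list[str],
                          per_quadrant: int = 2, center: int = 2) -> list[str]:
    """Multivariate-design selection spanning a 2-component score plane.

    Per quadrant, picks first the sample farthest from the origin, then
    repeatedly the sample maximizing the minimum distance to the picks
    already made in that quadrant and to the origin (the centre is covered
    by the dedicated centre picks, so quadrant picks span the periphery);
    the ``center`` picks are the remaining samples closest to the origin.
    Boundary scores (exactly 0) count as positive; ties break by sample-id
    order.  Empty or underfilled quadrants yield fewer samples with a
    logged warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] < 2:
        raise ValueError("representative selection needs 2-component scores")
    scores = scores[:, :2]
    order = np.argsort(np.asarray(sample_ids, dtype=object))  # tie-break by id
    dist = np.linalg.norm(scores, axis=1)

    quadrant = np.where(scores[:, 0] >= 0, 0, 1) + 2 * np.where(scores[:, 1] >= 0, 0, 1)
    selected: list[int] = []
    for q in range(4):
        members = [i for i in order if quadrant[i] == q]
        if len(members) < per_quadrant:
            logger.warning(
                "quadrant %d has %d samples; requested %d", q, len(members), per_quadrant
            )
        picks: list[int] = []
        while members and len(picks) < per_quadrant:
            if not picks:
                best = max(members, key=lambda i: dist[i])
            else:
                best = max(
                    members,
                    key=lambda i: min(
                        [np.linalg.norm(scores[i] - scores[j]) for j in picks] + [dist[i]]
                    ),
                )
            picks.append(best)
            members.remove(best)
        selected.extend(picks)

    remaining = [i for i in order if i not in selected]
    remaining.sort(key=lambda i: dist[i])
    selected.extend(remaining[:center])
    return [sample_ids[i] for i in selected]
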