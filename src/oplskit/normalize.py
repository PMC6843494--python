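"""Internal-standard normalization and unit-variance scaling.

Normalization follows the spiked-standard strategy common for GC-MS peak
tables: a one-component PCA of the internal-standard matrix yields a
per-sample score t1 that acts as a common intensity factor (injection
volume, extraction efficiency, detector drift), and every peak area in a
sample is divided by that sample's score.

The standards PCA is scale-only (each standard divided by its SD) and NOT
mean-centred: with centring, t1 scores can be zero or negative and division
is undefined, whereas the uncentred score is a weighted mean intensity and
stays positive for positive data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import InternalStandardTable, PeakTable, ValidationError


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationResult:
    normalized: PeakTable
    t1_scores: np.ndarray   # per-sample positive factors, aligned with sample_ids
    loadings: np.ndarray    # per-standard weights (unit norm)


def is_normalize(table: PeakTable, standards: InternalStandardTable) -> NormalizationResult:
    """Divide each sample's peak areas by its internal-standard t1 score.

    The score is the first principal component of the standards matrix,
    scaled to unit variance per standard without mean-centring; its sign is
    fixed so the mean score is positive.  Missing cells stay missing.
    """
    if standards.sample_ids != table.sample_ids:
        raise NormalizationError("standards sample_ids do not align with the peak table")
    X = standards.areas
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant standard still carries scale
    Y = X / sd
    # first singular pair of the uncentred matrix = scale-only PCA component
    _, s, vt = np.linalg.svd(Y, full_matrices=False)
    v = vt[0]
    t1 = Y @ v
    if t1.mean() < 0:
        t1, v = -t1, -v
    if np.any(t1 <= 0):
        i = int(np.argmin(t1))
        raise NormalizationError(
            f"non-positive t1 score for sample {table.sample_ids[i]!r}; "
            "standards are inconsistent with a common intensity factor"
        )
    out = table.copy()
    out.areas = out.areas / t1[:, None]
    out.areas[out.missing_mask] = np.nan
    return NormalizationResult(out, t1, v)


def uv_scale(
    X: np.ndarray, missing_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre each column to mean 0 and scale to SD 1 (population SD).

    Means and SDs are computed over non-missing entries; missing entries
    are imputed as 0 after scaling, i.e. at the column mean.  Raises on a
    zero-variance column, naming it by index.
    """
    X = np.asarray(X, dtype=float)
    if missing_mask is None:
        missing_mask = ~np.isfinite(X)
    W = np.ma.masked_array(X, mask=missing_mask)
    mean = np.asarray(W.mean(axis=0))
    sd = np.asarray(W.std(axis=0, ddof=0))
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise ValidationError(f"zero-variance column at index {int(bad[0])}")
    Z = (X - mean) / sd
    Z[missing_mask] = 0.0
    return Z, mean, sd


def apply_scaling(X: np.ndarray, mean: np.ndarray, sd: np.ndarray,
                  missing_mask: np.ndarray | None = None) -> np.ndarray:
    """Apply stored column means/SDs to new data (missing → column mean)."""
    X = np.asarray(X, dtype=float)
    if missing_mask is None:
        missing_mask = ~np.isfinite(X)
    Z = (X - mean) / sd
    Z[missing_mask] = 0.0
    return Z
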