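"""Multi-batch / multi-study synthesis.

Per-batch OPLS-DA p(corr) profiles are combined into one loading profile
via an unscaled, uncentred PCA of the batch × metabolite matrix; per-study
effect directions are called from jack-knife CIs and VIP, and agreement
between studies is summarised as direction concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import DOWN, MISSING, NONE, UP, DirectionTable, IdentifierError
from .opls import JackknifeResult


@dataclass
class CombinedProfile:
    metabolite_ids: list[str]
    pcorr_matrix: np.ndarray   # batches × metabolites, NaN where missing
    p1: np.ndarray             # combined loading profile, unit norm


@dataclass
class ConcordanceSummary:
    n_evaluated: int
    n_congruent_any_validation: int
    fraction: float
    per_pair: dict[str, tuple[int, int]]   # comparison study -> (congruent, evaluated)


def combine_pcorr(profiles: Sequence[Mapping[str, float]]) -> CombinedProfile:
    """Combine per-batch p(corr) vectors into one loading profile.

    Builds the batch × metabolite matrix over the union of metabolites
    (entries missing in a batch are mean-imputed per metabolite across the
    batches that measured it), then takes the first loading vector of a
    PCA with no scaling and no centring.  The sign of p1 is fixed so its
    correlation with the first batch's profile is positive.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 batch profiles")
    mets = sorted(set().union(*[set(p) for p in profiles]))
    shared = set(profiles[0])
    for p in profiles[1:]:
        shared &= set(p)
    if len(shared) < 2:
        raise ValueError("batches share fewer than 2 metabolites")
    M = np.full((len(profiles), len(mets)), np.nan)
    for i, p in enumerate(profiles):
        for m, v in p.items():
            M[i, mets.index(m)] = v
    X = M.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_at = np.isnan(X)
    X[nan_at] = np.broadcast_to(col_mean, X.shape)[nan_at]

    # raw cross-product PCA: first right singular vector of the uncentred matrix
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    p1 = vt[0]
    ref = np.array([profiles[0].get(m, np.nan) for m in mets])
    ok = ~np.isnan(ref)
    if float(p1[ok] @ ref[ok]) < 0:
        p1 = -p1
    return CombinedProfile(mets, M, p1)


def call_directions(
    jk: JackknifeResult,
    vip: np.ndarray,
    metabolite_ids: Sequence[str],
    vip_threshold: float = 0.8,
) -> dict[str, str]:
    """Per-metabolite direction calls from jack-knife CIs and VIP.

    UP if the CI is entirely positive and VIP ≥ threshold, DOWN if
    entirely negative and VIP ≥ threshold, NONE otherwise.
    """
    vip = np.asarray(vip, dtype=float)
    if len(metabolite_ids) != jk.statistic.shape[0] or vip.shape[0] != jk.statistic.shape[0]:
        raise ValueError("metabolite sets of jack-knife result and VIP do not match")
    calls = {}
    for i, m in enumerate(metabolite_ids):
        if vip[i] >= vip_threshold and jk.lower[i] > 0:
            calls[m] = UP
        elif vip[i] >= vip_threshold and jk.upper[i] < 0:
            calls[m] = DOWN
        else:
            calls[m] = NONE
    return calls


def directions_to_table(
    per_study: Mapping[str, Mapping[str, str]], studies: Sequence[str] | None = None
) -> DirectionTable:
    """Assemble per-study call dictionaries into a DirectionTable
    (metabolites absent from a study become MISSING)."""
    studies = list(studies) if studies is not None else list(per_study)
    mets = sorted(set().union(*[set(per_study[s]) for s in studies]))
    calls = np.array(
        [[per_study[s].get(m, MISSING) for s in studies] for m in mets], dtype=object
    )
    return DirectionTable(mets, studies, calls)


def concordance(
    dirs: DirectionTable,
    reference_study: str,
    comparison_studies: Sequence[str],
) -> ConcordanceSummary:
    """Direction concordance of a reference study with ≥1 comparison study.

    A metabolite is evaluated if its reference call is not MISSING, and
    congruent if the reference symbol (UP/DOWN/NONE — "no change" counts
    as a result in its own right) equals the call in at least one
    comparison study; MISSING never matches.
    """
    ref = dirs.column(reference_study)
    comps = {s: dirs.column(s) for s in comparison_studies}
    n_eval = 0
    n_cong = 0
    per_pair = {s: [0, 0] for s in comparison_studies}
    for m, call in ref.items():
        if call == MISSING:
            continue
        n_eval += 1
        hit = False
        for s, col in comps.items():
            other = col.get(m, MISSING)
            if other != MISSING:
                per_pair[s][1] += 1
                if other == call:
                    per_pair[s][0] += 1
                    hit = True
        if hit:
            n_cong += 1
    if n_eval == 0:
        raise ValueError("no evaluable metabolites in the reference study")
    return ConcordanceSummary(
        n_evaluated=n_eval,
        n_congruent_any_validation=n_cong,
        fraction=n_cong / n_eval,
        per_pair={s: (c, n) for s, (c, n) in per_pair.items()},
    )


def pairwise_agreement(
    dirs: DirectionTable, study_a: str, study_b: str, changed_only: bool = True
) -> float:
    """Fraction of metabolites with equal calls in two studies.

    With ``changed_only`` the comparison is restricted to metabolites
    called UP or DOWN in both studies; otherwise any pair of non-MISSING
    calls is eligible.
    """
    a = dirs.column(study_a)
    b = dirs.column(study_b)
    if changed_only:
        eligible = [m for m in a if a[m] in (UP, DOWN) and b.get(m) in (UP, DOWN)]
    else:
        eligible = [m for m in a if a[m] != MISSING and b.get(m, MISSING) != MISSING]
    if not eligible:
        raise ValueError("no eligible metabolites for pairwise agreement")
    return sum(1 for m in eligible if a[m] == b[m]) / len(eligible)
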