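"""End-to-end pipeline: normalize → scale → OPLS-DA → cross-validate →
jack-knife → VIP → t-tests → direction calls, with config validation,
logging and a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    InternalStandardTable,
    PeakTable,
    SampleMeta,
    group_vector,
    read_peak_table,
    read_sample_meta,
    read_standards,
)
from .meta import call_directions
from .normalize import is_normalize, uv_scale
from .opls import fit_opls_cv, jackknife_ci, predicted_y_test
from .stats import metabolite_ttests

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "peak_table", "standards", "metadata", "output_dir", "timepoint",
    "n_folds", "n_orthogonal", "alpha", "vip_threshold", "seed",
    "normalize", "exclude_samples",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    peak_table: str | None = None
    standards: str | None = None
    metadata: str | None = None
    output_dir: str | None = None
    timepoint: str = "T18"
    n_folds: int = 7
    n_orthogonal: int = 1
    alpha: float = 0.05
    vip_threshold: float = 0.8
    seed: int = 0
    normalize: bool = True
    exclude_samples: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_orthogonal < 0:
            raise ValueError("n_orthogonal must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.vip_threshold < 0:
            raise ValueError("vip_threshold must be >= 0")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    model_summary: dict
    metabolite_table: pd.DataFrame   # pcorr, VIP, jack-knife CI, significance, t-test
    cv_predicted_y: pd.DataFrame
    direction_calls: dict[str, str]
    manifest: dict


def run_pipeline(
    config: PipelineConfig,
    table: PeakTable | None = None,
    meta: Sequence[SampleMeta] | None = None,
    standards: InternalStandardTable | None = None,
) -> PipelineResult:
    """Run the full discriminant analysis on one cohort.

    Inputs may be passed in memory or read from the configured paths.
    The pipeline is a pure function of (inputs, config): identical inputs
    and config give identical outputs.
    """
    config.validate()
    if table is None:
        if config.peak_table is None:
            raise PipelineError("stage input: no peak table given (path or object)")
        table = read_peak_table(config.peak_table)
        meta = read_sample_meta(config.metadata)
        standards = read_standards(config.standards) if config.standards else None
    assert meta is not None

    if config.exclude_samples:
        keep = [s for s in table.sample_ids if s not in set(config.exclude_samples)]
        n_removed = table.n_samples - len(keep)
        logger.info("stage exclude: removed %d sample(s): %s",
                    n_removed, sorted(set(config.exclude_samples)))
        table = table.subset_samples(keep)
        if standards is not None:
            idx = [standards.sample_ids.index(s) for s in keep]
            standards = InternalStandardTable(
                keep, standards.standard_ids, standards.areas[idx])

    if config.normalize and standards is not None:
        try:
            table = is_normalize(table, standards).normalized
        except Exception as e:
            raise PipelineError(f"stage normalize: {e}") from e
        logger.info("stage normalize: %d samples × %d standards",
                    table.n_samples, len(standards.standard_ids))

    lookup = {m.sample_id: m for m in meta}
    tp_samples = [s for s in table.sample_ids if lookup[s].timepoint == config.timepoint]
    table_tp = table.subset_samples(tp_samples)
    y = group_vector(table_tp, meta)
    logger.info("stage model: %d samples × %d metabolites at %s",
                table_tp.n_samples, table_tp.n_metabolites, config.timepoint)

    X = table_tp.areas.copy()
    X[table_tp.missing_mask] = np.nan
    try:
        model, cv = fit_opls_cv(X, y, config.n_folds, config.n_orthogonal,
                                sample_ids=table_tp.sample_ids)
        jk = jackknife_ci(X, y, config.n_folds, config.n_orthogonal,
                          alpha=config.alpha, sample_ids=table_tp.sample_ids)
        t_stat, p_pred = predicted_y_test(cv, y)
    except Exception as e:
        raise PipelineError(f"stage opls: {e}") from e

    try:
        ttests = metabolite_ttests(table_tp, meta, config.timepoint)
    except Exception as e:
        raise PipelineError(f"stage ttest: {e}") from e

    calls = call_directions(jk, model.vip, table_tp.metabolite_ids,
                            config.vip_threshold)

    met_table = pd.DataFrame({
        "metabolite": table_tp.metabolite_ids,
        "pcorr": model.pcorr,
        "vip": model.vip,
        "jk_lower": jk.lower,
        "jk_upper": jk.upper,
        "jk_significant": jk.significant,
        "direction": [calls[m] for m in table_tp.metabolite_ids],
    }).merge(ttests[["metabolite", "t", "p", "testable"]], on="metabolite")

    summary = {
        "n_samples": int(table_tp.n_samples),
        "n_metabolites": int(table_tp.n_metabolites),
        "n_orthogonal": config.n_orthogonal,
        "r2x": model.r2x,
        "r2y_cum": model.r2y_cum,
        "q2_cum": cv.q2,
        "predicted_y_p": p_pred,
    }
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "n_samples_modelled": int(table_tp.n_samples),
    }
    result = PipelineResult(
        model_summary=summary,
        metabolite_table=met_table,
        cv_predicted_y=pd.DataFrame({
            "sample_id": table_tp.sample_ids, "y": y, "cv_predicted_y": cv.cv_predicted_y,
        }),
        direction_calls=calls,
        manifest=manifest,
    )
    if config.output_dir:
        _write_bundle(result, Path(config.output_dir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        p = outdir / "model_summary.json"
        p.write_text(json.dumps(result.model_summary, indent=2) + "\n")
        written.append(p)
        p = outdir / "metabolite_table.tsv"
        result.metabolite_table.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / "cv_predicted_y.tsv"
        result.cv_predicted_y.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / "run_manifest.json"
        p.write_text(json.dumps(result.manifest, indent=2) + "\n")
        written.append(p)
    except Exception as e:
        for p in written:   # remove partial outputs on failure
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage write: {e}") from e
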