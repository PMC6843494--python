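"""Domain containers and I/O for metabolite peak tables.

The central object is the :class:`PeakTable`: a samples × metabolites matrix
of positive GC-MS peak areas with an explicit missingness mask.  Companion
tables carry per-sample metadata (:class:`SampleMeta`), internal-standard
areas (:class:`InternalStandardTable`) and per-study effect-direction calls
(:class:`DirectionTable`).  Readers/writers use plain CSV/TSV with a header
row of metabolite names and one row per sample; empty cells mark missing
values.

All matrices are oriented samples-in-rows throughout the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UP = "UP"
DOWN = "DOWN"
NONE = "NONE"
MISSING = "MISSING"

#: on-disk symbols for DirectionTable cells
_DIR_TO_SYMBOL = {UP: "+", DOWN: "-", NONE: "N", MISSING: "."}
_SYMBOL_TO_DIR = {v: k for k, v in _DIR_TO_SYMBOL.items()}
# fixture files keep the arrows as printed
_SYMBOL_TO_DIR.update({"↑": UP, "↓": DOWN})


class IdentifierError(ValueError):
    """Duplicate or unknown sample/metabolite identifier."""


class ValidationError(ValueError):
    """A table cell violates an invariant (e.g. non-positive peak area)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise IdentifierError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class PeakTable:
    """Samples × metabolites matrix of positive peak areas.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (row labels).
    metabolite_ids : list of str
        Unique metabolite names (column labels).
    areas : ndarray, shape (n_samples, n_metabolites)
        Peak areas in arbitrary detector units.  Entries under a true
        ``missing_mask`` are undefined and ignored downstream.
    missing_mask : ndarray of bool, same shape
    """

    sample_ids: list[str]
    metabolite_ids: list[str]
    areas: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.areas)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.areas.shape != (len(self.sample_ids), len(self.metabolite_ids)):
            raise ValidationError(
                f"areas shape {self.areas.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.metabolite_ids)} metabolites"
            )
        if self.missing_mask.shape != self.areas.shape:
            raise ValidationError("missing_mask shape does not match areas")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.metabolite_ids, "metabolite")
        bad = (~self.missing_mask) & ~(self.areas > 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-positive peak area at sample {self.sample_ids[i]!r}, "
                f"metabolite {self.metabolite_ids[j]!r}: {self.areas[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def copy(self) -> "PeakTable":
        return PeakTable(
            list(self.sample_ids),
            list(self.metabolite_ids),
            self.areas.copy(),
            self.missing_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view with NaN at missing cells."""
        vals = self.areas.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.metabolite_ids)

    def subset_samples(self, keep: Sequence[str]) -> "PeakTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return PeakTable(
            [self.sample_ids[i] for i in idx],
            list(self.metabolite_ids),
            self.areas[idx],
            self.missing_mask[idx],
        )


@dataclass
class SampleMeta:
    """Per-sample metadata: group (placebo=0, active=1), time point, batch."""

    sample_id: str
    group: int
    timepoint: str = "T18"
    batch_id: str = "batch1"
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise ValidationError(f"group must be 0 (placebo) or 1 (active), got {self.group}")


def group_vector(table: PeakTable, meta: Sequence[SampleMeta]) -> np.ndarray:
    """0/1 class vector aligned with the table's sample order."""
    lookup = {m.sample_id: m for m in meta}
    missing = [s for s in table.sample_ids if s not in lookup]
    if missing:
        raise IdentifierError(f"no metadata for samples: {missing[:3]}")
    return np.array([lookup[s].group for s in table.sample_ids], dtype=float)


@dataclass
class InternalStandardTable:
    """Samples × internal-standards matrix of positive spiked-compound areas."""

    sample_ids: list[str]
    standard_ids: list[str]
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.standard_ids, "standard")
        if self.areas.shape != (len(self.sample_ids), len(self.standard_ids)):
            raise ValidationError("standards areas shape mismatch")
        if not (self.areas > 0).all():
            raise ValidationError("internal-standard areas must all be positive")


@dataclass
class DirectionTable:
    """Per-metabolite, per-study effect-direction calls.

    ``calls`` entries are one of UP/DOWN/NONE/MISSING; MISSING is reserved
    for metabolites not detected in a study and is distinct from NONE
    ("no change").
    """

    metabolite_ids: list[str]
    studies: list[str]
    calls: np.ndarray  # dtype object/str, shape (n_metabolites, n_studies)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        _check_unique(self.metabolite_ids, "metabolite")
        _check_unique(self.studies, "study")
        if self.calls.shape != (len(self.metabolite_ids), len(self.studies)):
            raise ValidationError("calls shape mismatch")
        bad = {c for c in self.calls.ravel()} - {UP, DOWN, NONE, MISSING}
        if bad:
            raise ValidationError(f"unknown direction symbols: {sorted(bad)}")

    def column(self, study: str) -> dict[str, str]:
        if study not in self.studies:
            raise IdentifierError(f"unknown study label: {study!r}")
        j = self.studies.index(study)
        return {m: self.calls[i, j] for i, m in enumerate(self.metabolite_ids)}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DELIM = {"csv": ",", "tsv": "\t"}


def _dialect_for(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in _DELIM:
            raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
        return dialect
    return "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"


def read_peak_table(path: str | Path, dialect: str | None = None) -> PeakTable:
    """Read a peak table: header of metabolite names, one row per sample.

    The first column holds the sample id; empty cells mark missing values.
    Raises :class:`IdentifierError` on duplicate ids and
    :class:`ValidationError` on non-positive numeric areas (naming the cell).
    """
    d = _dialect_for(path, dialect)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=_DELIM[d]))
    if not rows:
        raise ValidationError(f"empty peak table file: {path}")
    header = rows[0]
    metabolite_ids = header[1:]
    sample_ids, area_rows, mask_rows = [], [], []
    for row in rows[1:]:
        if not row:
            continue
        sample_ids.append(row[0])
        cells = row[1:] + [""] * (len(metabolite_ids) - len(row) + 1)
        vals, mask = [], []
        for cell in cells[: len(metabolite_ids)]:
            if cell.strip() == "":
                vals.append(np.nan)
                mask.append(True)
            else:
                vals.append(float(cell))
                mask.append(False)
        area_rows.append(vals)
        mask_rows.append(mask)
    return PeakTable(sample_ids, metabolite_ids, np.array(area_rows, dtype=float),
                     np.array(mask_rows, dtype=bool))


def write_peak_table(table: PeakTable, path: str | Path, dialect: str | None = None) -> None:
    """Write a peak table; missing cells become empty strings.

    Areas are written with ``repr`` so a read/write round trip is
    bit-identical.
    """
    d = _dialect_for(path, dialect)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=_DELIM[d])
        w.writerow(["sample_id"] + table.metabolite_ids)
        for i, sid in enumerate(table.sample_ids):
            row = [sid] + [
                "" if table.missing_mask[i, j] else repr(float(table.areas[i, j]))
                for j in range(table.n_metabolites)
            ]
            w.writerow(row)


def read_sample_meta(path: str | Path, dialect: str | None = None) -> list[SampleMeta]:
    d = _dialect_for(path, dialect)
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=_DELIM[d]):
            known = {"sample_id", "group", "timepoint", "batch_id"}
            cov = {k: float(v) for k, v in row.items() if k not in known and v not in (None, "")}
            out.append(SampleMeta(
                sample_id=row["sample_id"],
                group=int(row["group"]),
                timepoint=row.get("timepoint", "T18") or "T18",
                batch_id=row.get("batch_id", "batch1") or "batch1",
                covariates=cov,
            ))
    return out


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path,
                      dialect: str | None = None) -> None:
    d = _dialect_for(path, dialect)
    cov_keys = sorted({k for m in meta for k in m.covariates})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=_DELIM[d])
        w.writerow(["sample_id", "group", "timepoint", "batch_id"] + cov_keys)
        for m in meta:
            w.writerow([m.sample_id, m.group, m.timepoint, m.batch_id]
                       + [m.covariates.get(k, "") for k in cov_keys])


def read_standards(path: str | Path, dialect: str | None = None) -> InternalStandardTable:
    pt = read_peak_table(path, dialect)
    if pt.missing_mask.any():
        raise ValidationError("internal-standard table must have no missing cells")
    return InternalStandardTable(pt.sample_ids, pt.metabolite_ids, pt.areas)


def write_standards(std: InternalStandardTable, path: str | Path,
                    dialect: str | None = None) -> None:
    write_peak_table(
        PeakTable(std.sample_ids, std.standard_ids, std.areas,
                  np.zeros_like(std.areas, dtype=bool)),
        path, dialect,
    )


def read_direction_table(path: str | Path, dialect: str | None = None) -> DirectionTable:
    """Read a direction table serialized with symbols {+,-,N,.} (arrows accepted)."""
    d = _dialect_for(path, dialect)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=_DELIM[d]))
    studies = rows[0][1:]
    mets, calls = [], []
    for row in rows[1:]:
        if not row:
            continue
        mets.append(row[0])
        try:
            calls.append([_SYMBOL_TO_DIR[c.strip()] for c in row[1:]])
        except KeyError as e:
            raise ValidationError(f"unknown direction symbol {e} for {row[0]!r}") from e
    return DirectionTable(mets, studies, np.array(calls, dtype=object))


def write_direction_table(dirs: DirectionTable, path: str | Path,
                          dialect: str | None = None) -> None:
    d = _dialect_for(path, dialect)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=_DELIM[d])
        w.writerow(["metabolite"] + dirs.studies)
        for i, m in enumerate(dirs.metabolite_ids):
            w.writerow([m] + [_DIR_TO_SYMBOL[c] for c in dirs.calls[i]])


# ---------------------------------------------------------------------------
# packaged fixtures (verbatim transcriptions of the published summary tables)
# ---------------------------------------------------------------------------

_FIXTURES = {"table1", "table2", "table3", "table4", "table5"}


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("oplskit").joinpath("data", f"{name}.tsv")))


def load_fixture(name: str):
    """Load a packaged transcription of a published summary table.

    * ``table1`` — baseline 2×2 contingency rows (DataFrame with counts,
      group totals and the printed p-value as a string; blank/"n/a" kept).
    * ``table2`` — main-study decreased metabolites: (name, p_value, vip)
      with ``p_value`` NaN where printed "NS".
    * ``table3``/``table4`` — validation-study per-batch significant
      compounds with direction, p and VIP.
    * ``table5`` — a :class:`DirectionTable` over studies
      (main, validation1, validation2).
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURES)}")
    path = _fixture_path(name)
    if name == "table5":
        return read_direction_table(path, "tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if name == "table1":
        for col in ("active_n", "active_total", "placebo_n", "placebo_total"):
            df[col] = df[col].astype(int)
        return df
    df["vip"] = df["vip"].astype(float)
    df["p_printed"] = df["p_value"]
    df["p_value"] = pd.to_numeric(df["p_value"].replace("NS", ""), errors="coerce")
    return df
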