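"""Censored pesticide-residue concentration datasets.

Residue monitoring labs report three kinds of result for a compound in a
sample: a quantified concentration (at or above the limit of quantification,
LOQ), a detection that could not be quantified (between the limit of
detection, LOD, and the LOQ), or a non-detect (below the LOD).  The last two
are censored observations — the concentration is known only to lie in an
interval — and carry real statistical information that the distribution
fitting downstream must use.  This module provides the validated in-memory
representation of such datasets, CSV round-tripping, and the descriptive
summaries (geometric means of quantified values, detection frequencies) used
by the deterministic hazard screen.

Concentrations are fixed in ng active ingredient per gram of matrix
(equivalently parts per billion); any unit conversion happens upstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

UNITS = "ng a.i./g"

MATRICES = ("soil", "pollen", "nectar")

STATUS_QUANTIFIED = "quantified"
STATUS_NONDETECT = "nondetect"
STATUS_BELOW_LOQ = "below_loq"
STATUSES = (STATUS_QUANTIFIED, STATUS_NONDETECT, STATUS_BELOW_LOQ)

CSV_COLUMNS = ("sample_id", "analyte", "matrix", "status", "value", "lod", "loq")


class ResidueFormatError(ValueError):
    """Raised when a residue table is structurally malformed (e.g. missing columns)."""


class ResidueValidationError(ValueError):
    """Raised when one or more rows violate the observation invariants.

    Carries ``errors``, a list of ``(row_index, message)`` pairs so a user can
    locate every offending row in one pass.
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.errors)
        super().__init__(f"invalid residue rows: {lines}")


class NoQuantifiableResidues(ValueError):
    """Raised when an operation needs quantified values but the group has none.

    Mirrors the "NQ" (not quantifiable) outcome for compounds detected only
    below the LOQ.
    """


@dataclass(frozen=True)
class ResidueObservation:
    """One composite sample's result for one analyte in one matrix.

    ``value`` is present only for ``status='quantified'``.  A non-detect is
    left-censored on (0, lod); a below-LOQ detection is interval-censored on
    [lod, loq).
    """

    sample_id: str
    analyte: str
    matrix: str
    status: str
    lod: float
    loq: float
    value: float | None = None

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if not (0 < self.lod <= self.loq):
            raise ValueError(f"need 0 < lod <= loq, got lod={self.lod}, loq={self.loq}")
        if self.status == STATUS_QUANTIFIED:
            if self.value is None:
                raise ValueError("quantified observation requires a value")
            if not self.value > 0:
                raise ValueError(f"quantified value must be positive, got {self.value}")
            if self.value < self.loq:
                # Labs differ in reporting dialects; accept but flag.
                warnings.warn(
                    f"quantified value {self.value} below LOQ {self.loq} "
                    f"for {self.analyte}/{self.sample_id}",
                    stacklevel=3,
                )
        elif self.value is not None:
            raise ValueError(f"status {self.status!r} must not carry a value")


@dataclass(frozen=True)
class ResidueDataset:
    """An ordered collection of residue observations sharing one unit scale."""

    observations: tuple[ResidueObservation, ...]
    units: str = UNITS

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[ResidueObservation]:
        return iter(self.observations)

    @classmethod
    def from_observations(cls, obs: Iterable[ResidueObservation]) -> "ResidueDataset":
        return cls(observations=tuple(obs))

    def subset(self, analyte: str | None = None, matrix: str | None = None) -> "ResidueDataset":
        keep = [
            o
            for o in self.observations
            if (analyte is None or o.analyte == analyte)
            and (matrix is None or o.matrix == matrix)
        ]
        return ResidueDataset(observations=tuple(keep), units=self.units)

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (analyte, matrix) pairs in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for o in self.observations:
            seen.setdefault((o.analyte, o.matrix), None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": o.sample_id,
                "analyte": o.analyte,
                "matrix": o.matrix,
                "status": o.status,
                "value": o.value,
                "lod": o.lod,
                "loq": o.loq,
            }
            for o in self.observations
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def _parse_float(raw: object, col: str) -> float:
    try:
        return float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise ValueError(f"column {col!r}: not a number: {raw!r}") from exc


def read_residue_table(path) -> ResidueDataset:
    """Read a residue CSV (UTF-8, decimal point, header required).

    Columns: sample_id, analyte, matrix, status, value, lod, loq.  The value
    cell is empty for censored rows.  Rows violating the observation
    invariants are collected and reported together with their row indices.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise ResidueFormatError(f"empty residue table: {path}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ResidueFormatError(f"residue table {path} missing columns: {missing}")

    obs: list[ResidueObservation] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            raw_value = str(getattr(row, "value")).strip()
            status = str(getattr(row, "status")).strip()
            if raw_value and status != STATUS_QUANTIFIED:
                raise ValueError(f"status {status!r} must not carry a value")
            value = _parse_float(raw_value, "value") if raw_value else None
            obs.append(
                ResidueObservation(
                    sample_id=str(getattr(row, "sample_id")).strip(),
                    analyte=str(getattr(row, "analyte")).strip(),
                    matrix=str(getattr(row, "matrix")).strip(),
                    status=status,
                    value=value,
                    lod=_parse_float(getattr(row, "lod"), "lod"),
                    loq=_parse_float(getattr(row, "loq"), "loq"),
                )
            )
        except ValueError as exc:
            errors.append((i, str(exc)))
    if errors:
        raise ResidueValidationError(errors)
    return ResidueDataset.from_observations(obs)


def write_residue_table(ds: ResidueDataset, path) -> None:
    """Write the CSV dialect read by :func:`read_residue_table` (round-trips)."""
    df = ds.to_frame()
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.12g")


def geometric_mean_quantified(ds: ResidueDataset, analyte: str, matrix: str) -> float:
    """Geometric mean of quantified concentrations for one analyte x matrix group.

    Censored rows (non-detects, below-LOQ) are excluded by definition: this is
    the summary feeding the deterministic hazard-quotient screen, which treats
    unquantifiable residues as contributing no dose.
    """
    values = [
        o.value
        for o in ds
        if o.analyte == analyte and o.matrix == matrix and o.status == STATUS_QUANTIFIED
    ]
    if not values:
        raise NoQuantifiableResidues(
            f"no quantifiable residues for {analyte} in {matrix}"
        )
    return float(math.exp(np.mean(np.log(values))))


def detection_summary(ds: ResidueDataset) -> pd.DataFrame:
    """Per-group detection frequencies.

    frac_detected counts quantified plus below-LOQ rows (anything at or above
    the LOD); frac_quantified counts quantified rows only, so
    frac_quantified <= frac_detected <= 1.
    """
    if len(ds) == 0:
        return pd.DataFrame(
            columns=["analyte", "matrix", "n", "frac_detected", "frac_quantified"]
        )
    df = ds.to_frame()
    grouped = df.groupby(["analyte", "matrix"], sort=False)
    out = grouped.agg(
        n=("status", "size"),
        n_quantified=("status", lambda s: int((s == STATUS_QUANTIFIED).sum())),
        n_below_loq=("status", lambda s: int((s == STATUS_BELOW_LOQ).sum())),
    ).reset_index()
    out["frac_detected"] = (out["n_quantified"] + out["n_below_loq"]) / out["n"]
    out["frac_quantified"] = out["n_quantified"] / out["n"]
    return out[["analyte", "matrix", "n", "frac_detected", "frac_quantified"]]
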