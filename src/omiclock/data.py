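"""Omics data containers, file I/O, preprocessing and age bucketing.

Matrices are stored samples-by-features. Two modalities are expected in
practice — RNA-seq expression (TPM, log2(TPM+1)-transformed before
modelling) and DNA-methylation beta values in [0, 1] — but nothing here is
specific to two; any number of modalities is supported. Missingness is
handled at the modality level (a sample simply lacks a row in a modality),
never by feature-level imputation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from omiclock.errors import (
    DomainError,
    FormatError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_BUCKET_COUNT = 10
DEFAULT_BUCKET_WIDTH = 10.0


@dataclass(frozen=True)
class OmicsMatrix:
    """One modality's samples x features real matrix with string ids.

    Parameters
    ----------
    modality_name : str
        E.g. ``"rna"`` or ``"methylation"``.
    sample_ids, feature_ids : sequence of str
        Unique, order-preserving identifiers for rows and columns.
    values : ndarray of shape (n_samples, n_features)
    """

    modality_name: str
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got ndim={values.ndim}")
        if values.shape[0] != len(self.sample_ids):
            raise ValidationError(
                f"{values.shape[0]} rows but {len(self.sample_ids)} sample ids"
            )
        if values.shape[1] != len(self.feature_ids):
            raise ValidationError(
                f"{values.shape[1]} columns but {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.feature_ids, "feature id")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )


@dataclass(frozen=True)
class CohortTable:
    """Per-sample metadata: chronological age, age bucket, optional survival.

    ``survival_time`` and ``event`` are either both present (aligned float /
    0-1 integer arrays with NaN allowed pairwise) or both ``None``.
    ``covariates`` holds any further per-sample columns.
    """

    sample_ids: tuple[str, ...]
    chronological_age: np.ndarray
    age_bucket: np.ndarray | None = None
    survival_time: np.ndarray | None = None
    event: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique(self.sample_ids, "sample id")
        age = np.asarray(self.chronological_age, dtype=float)
        object.__setattr__(self, "chronological_age", age)
        n = len(self.sample_ids)
        if age.shape != (n,):
            raise ValidationError(f"ages shape {age.shape} != ({n},)")
        if np.any(age < 0) or np.any(~np.isfinite(age)):
            raise DomainError("chronological ages must be finite and >= 0")
        if (self.survival_time is None) != (self.event is None):
            raise ValidationError("survival_time and event must be given together")
        if self.survival_time is not None:
            t = np.asarray(self.survival_time, dtype=float)
            e = np.asarray(self.event, dtype=float)
            if t.shape != (n,) or e.shape != (n,):
                raise ValidationError("survival columns must match cohort length")
            both = np.isfinite(t) & np.isfinite(e)
            if np.any(np.isfinite(t) != np.isfinite(e)):
                raise ValidationError("survival_time present iff event present")
            if np.any(t[both] <= 0):
                raise DomainError("survival times must be > 0")
            if not np.all(np.isin(e[both], (0.0, 1.0))):
                raise ValidationError("event indicator must be 0 or 1")
            object.__setattr__(self, "survival_time", t)
            object.__setattr__(self, "event", e)
        if self.age_bucket is not None:
            b = np.asarray(self.age_bucket, dtype=int)
            if b.shape != (n,):
                raise ValidationError("age_bucket must match cohort length")
            object.__setattr__(self, "age_bucket", b)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"sample {exc.args[0]!r} not in cohort") from exc

    def subset(self, index: np.ndarray) -> "CohortTable":
        index = np.asarray(index)
        return CohortTable(
            sample_ids=tuple(self.sample_ids[i] for i in index),
            chronological_age=self.chronological_age[index],
            age_bucket=None if self.age_bucket is None else self.age_bucket[index],
            survival_time=None if self.survival_time is None else self.survival_time[index],
            event=None if self.event is None else self.event[index],
            covariates=None if self.covariates is None else self.covariates.iloc[index],
        )


@dataclass(frozen=True)
class MultiOmicsDataset:
    """Aligned modality matrices + cohort + per-sample modality presence.

    Every matrix is re-indexed to the cohort's sample order; rows for absent
    samples are zero-filled and masked out via ``presence_mask`` (modality
    name -> boolean vector over cohort samples). Models must consult the
    mask, never the fill value.
    """

    matrices: Mapping[str, OmicsMatrix]
    cohort: CohortTable
    presence_mask: Mapping[str, np.ndarray]

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.matrices)

    @property
    def n_samples(self) -> int:
        return self.cohort.n_samples

    def feature_counts(self) -> dict[str, int]:
        return {m: mat.n_features for m, mat in self.matrices.items()}

    def subset(self, index: np.ndarray) -> "MultiOmicsDataset":
        index = np.asarray(index)
        cohort = self.cohort.subset(index)
        matrices = {
            m: OmicsMatrix(
                modality_name=m,
                sample_ids=cohort.sample_ids,
                feature_ids=mat.feature_ids,
                values=mat.values[index],
            )
            for m, mat in self.matrices.items()
        }
        mask = {m: v[index] for m, v in self.presence_mask.items()}
        return MultiOmicsDataset(matrices=matrices, cohort=cohort, presence_mask=mask)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for s in ids:
        if s in seen:
            raise ValidationError(f"duplicate {what} {s!r}")
        seen.add(s)


# ---------------------------------------------------------------------------
# File I/O


def read_omics_matrix(path: str | Path, modality: str, format: str | None = None) -> OmicsMatrix:
    """Read a samples x features matrix from TSV, CSV or HDF5.

    Delimited files carry feature ids in the header and sample ids in the
    first column; HDF5 files carry datasets ``values``, ``sample_ids`` and
    ``feature_ids``. Ids are preserved in file order.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            for key in ("values", "sample_ids", "feature_ids"):
                if key not in fh:
                    raise FormatError(f"{path}: missing HDF5 dataset {key!r}")
            values = np.asarray(fh["values"], dtype=float)
            sample_ids = [_to_str(s) for s in fh["sample_ids"][()]]
            feature_ids = [_to_str(s) for s in fh["feature_ids"][()]]
        return OmicsMatrix(modality, tuple(sample_ids), tuple(feature_ids), values)

    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise FormatError(f"unknown matrix format {fmt!r}")
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed delimited file: {exc}") from exc
    if frame.columns.size == 0:
        raise FormatError(f"{path}: header defines no feature columns")
    sample_ids = tuple(str(s) for s in frame.index)
    feature_ids = tuple(str(f) for f in frame.columns)
    _check_unique(sample_ids, "sample id")
    _check_unique(feature_ids, "feature id")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        parsed = pd.to_numeric(frame[col], errors="coerce")
        raw = frame[col]
        bad = parsed.isna() & ~raw.isna() & (raw.str.strip().str.lower() != "nan")
        if bad.any():
            row = str(frame.index[int(np.argmax(bad.to_numpy()))])
            raise ParseError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        values[:, j] = parsed.to_numpy(dtype=float)
    return OmicsMatrix(modality, sample_ids, feature_ids, values)


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix in a layout :func:`read_omics_matrix` round-trips."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=matrix.values)
            str_dt = h5py.string_dtype(encoding="utf-8")
            fh.create_dataset("sample_ids", data=list(matrix.sample_ids), dtype=str_dt)
            fh.create_dataset("feature_ids", data=list(matrix.feature_ids), dtype=str_dt)
        return
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise FormatError(f"unknown matrix format {fmt!r}")
    matrix.to_frame().to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {
        ".tsv": "tsv",
        ".txt": "tsv",
        ".csv": "csv",
        ".h5": "hdf5",
        ".hdf5": "hdf5",
    }.get(suffix, "tsv")


def _to_str(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def read_cohort_table(path: str | Path, sep: str | None = None) -> CohortTable:
    """Read per-sample metadata (mandatory columns ``sample_id``, ``age``).

    Optional columns ``survival_time`` and ``event`` are picked up together;
    anything else lands in ``covariates``.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    for col in ("sample_id", "age"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    has_surv = "survival_time" in frame.columns or "event" in frame.columns
    if has_surv and not {"survival_time", "event"} <= set(frame.columns):
        raise FormatError(f"{path}: survival_time and event must appear together")
    extra = [
        c
        for c in frame.columns
        if c not in {"sample_id", "age", "age_bucket", "survival_time", "event"}
    ]
    return CohortTable(
        sample_ids=tuple(str(s) for s in frame["sample_id"]),
        chronological_age=frame["age"].to_numpy(dtype=float),
        age_bucket=frame["age_bucket"].to_numpy(dtype=int) if "age_bucket" in frame else None,
        survival_time=frame["survival_time"].to_numpy(dtype=float) if has_surv else None,
        event=frame["event"].to_numpy(dtype=float) if has_surv else None,
        covariates=frame[extra].set_axis(frame["sample_id"].astype(str)) if extra else None,
    )


def write_cohort_table(cohort: CohortTable, path: str | Path, sep: str = "\t") -> None:
    frame = pd.DataFrame({"sample_id": list(cohort.sample_ids), "age": cohort.chronological_age})
    if cohort.age_bucket is not None:
        frame["age_bucket"] = cohort.age_bucket
    if cohort.survival_time is not None:
        frame["survival_time"] = cohort.survival_time
        frame["event"] = cohort.event
    if cohort.covariates is not None:
        for col in cohort.covariates.columns:
            frame[col] = cohort.covariates[col].to_numpy()
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Preprocessing


def transform_expression(matrix: OmicsMatrix) -> OmicsMatrix:
    """log2(TPM + 1) transform of a non-negative expression matrix."""
    if np.any(matrix.values < 0):
        raise DomainError(f"{matrix.modality_name}: negative TPM value")
    return dataclasses.replace(matrix, values=np.log2(matrix.values + 1.0))


def filter_methylation(
    matrix: OmicsMatrix,
    beta_threshold: float = 0.3,
    sample_fraction: float = 0.9,
) -> OmicsMatrix:
    """Drop probes with low methylation in more than ``sample_fraction`` of samples.

    A probe (column) is removed when its beta value is below
    ``beta_threshold`` in strictly more than ``sample_fraction`` of samples;
    surviving probes keep their original order. The boundary fraction
    (exactly ``sample_fraction``) is retained. Idempotent.
    """
    if matrix.n_samples == 0 or matrix.n_features == 0:
        raise ValidationError("cannot filter an empty methylation matrix")
    if np.any(matrix.values < 0) or np.any(matrix.values > 1):
        raise DomainError("beta values must lie in [0, 1]")
    low_fraction = np.mean(matrix.values < beta_threshold, axis=0)
    keep = low_fraction <= sample_fraction
    if not np.any(keep):
        logger.warning("%s: every probe removed by the low-beta filter", matrix.modality_name)
    return OmicsMatrix(
        modality_name=matrix.modality_name,
        sample_ids=matrix.sample_ids,
        feature_ids=tuple(f for f, k in zip(matrix.feature_ids, keep) if k),
        values=matrix.values[:, keep],
    )


def assign_age_buckets(
    cohort: CohortTable,
    K: int = DEFAULT_BUCKET_COUNT,
    bucket_width: float = DEFAULT_BUCKET_WIDTH,
) -> CohortTable:
    """Discretize chronological age into K half-open buckets of fixed width.

    Bucket k covers [k*width, (k+1)*width); ages beyond the last edge clamp
    to bucket K-1. Labels start at 0.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if bucket_width <= 0:
        raise ValidationError("bucket_width must be > 0")
    age = cohort.chronological_age
    if np.any(age < 0):
        raise DomainError("negative chronological age")
    buckets = np.minimum(np.floor(age / bucket_width).astype(int), K - 1)
    return dataclasses.replace(cohort, age_bucket=buckets)


def preprocess_dataset(
    dataset: MultiOmicsDataset,
    expression_modalities: Sequence[str] = ("rna",),
    methylation_modalities: Sequence[str] = ("methylation",),
    beta_threshold: float = 0.3,
    sample_fraction: float = 0.9,
    standardize: bool = True,
) -> MultiOmicsDataset:
    """Modality-appropriate preprocessing of an aligned dataset.

    Expression modalities get log2(TPM+1); methylation modalities get the
    low-beta probe filter computed over present samples only (placeholder
    rows of absent samples never influence the filter). With
    ``standardize`` each surviving feature is z-scored over present
    samples, which puts both modalities on the unit scale the
    unit-variance Gaussian reconstruction likelihood assumes; constant
    features are left centered at zero.
    """
    out: dict[str, OmicsMatrix] = {}
    for name, mat in dataset.matrices.items():
        present = dataset.presence_mask[name]
        if name in expression_modalities:
            mat = transform_expression(mat)
        elif name in methylation_modalities:
            observed = OmicsMatrix(name, tuple(np.array(mat.sample_ids)[present]),
                                   mat.feature_ids, mat.values[present])
            kept = filter_methylation(observed, beta_threshold, sample_fraction)
            keep_cols = [f in set(kept.feature_ids) for f in mat.feature_ids]
            mat = OmicsMatrix(name, mat.sample_ids, kept.feature_ids,
                              mat.values[:, np.asarray(keep_cols, dtype=bool)])
        if standardize:
            mean = mat.values[present].mean(axis=0)
            sd = mat.values[present].std(axis=0)
            sd[sd == 0] = 1.0
            values = (mat.values - mean) / sd
            values[~present] = 0.0  # placeholder rows stay inert
            mat = dataclasses.replace(mat, values=values)
        out[name] = mat
    return MultiOmicsDataset(
        matrices=out, cohort=dataset.cohort, presence_mask=dict(dataset.presence_mask)
    )


def align_dataset(
    matrices: Mapping[str, OmicsMatrix] | Sequence[OmicsMatrix],
    cohort: CohortTable,
) -> MultiOmicsDataset:
    """Align modality matrices against the cohort and build the presence mask.

    Samples missing from a modality are recorded as absent in the mask (their
    rows are zero placeholders, never imputed values). A sample present in a
    matrix but not in the cohort is an error.
    """
    if not isinstance(matrices, Mapping):
        matrices = {m.modality_name: m for m in matrices}
    cohort_pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    n = cohort.n_samples
    aligned: dict[str, OmicsMatrix] = {}
    mask: dict[str, np.ndarray] = {}
    for name, mat in matrices.items():
        unknown = [s for s in mat.sample_ids if s not in cohort_pos]
        if unknown:
            raise ValidationError(
                f"modality {name!r}: sample {unknown[0]!r} absent from cohort table"
            )
        if not np.all(np.isfinite(mat.values)):
            raise ValidationError(f"modality {name!r}: non-finite values in raw matrix")
        values = np.zeros((n, mat.n_features))
        present = np.zeros(n, dtype=bool)
        for row, s in enumerate(mat.sample_ids):
            i = cohort_pos[s]
            values[i] = mat.values[row]
            present[i] = True
        aligned[name] = OmicsMatrix(name, cohort.sample_ids, mat.feature_ids, values)
        mask[name] = present
    any_present = np.zeros(n, dtype=bool)
    for v in mask.values():
        any_present |= v
    if not np.all(any_present):
        missing = cohort.sample_ids[int(np.argmin(any_present))]
        raise ValidationError(f"sample {missing!r} present in no modality")
    return MultiOmicsDataset(matrices=aligned, cohort=cohort, presence_mask=mask)
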