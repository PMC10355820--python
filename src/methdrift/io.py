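"""Readers, writers and core data containers.

The universal carrier is the :class:`BetaMatrix`: a CpGs x samples matrix of
methylation fractions (beta values) in [0, 1], paired with a
:class:`SampleSheet` of per-sample covariates (cumulative population doublings,
age, tissue, group labels, survival time/event).

On-disk convention follows the public series-matrix layout: rows are CpGs,
columns are samples; the reader accepts either orientation and normalizes.
Missing beta values are rejected rather than imputed.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance for beta values marginally outside [0, 1] due to rounding
BETA_TOL = 1e-9

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}

MODEL_SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """Input data violates a container invariant."""


@dataclass
class BetaMatrix:
    """CpGs x samples matrix of methylation beta values in [0, 1].

    Parameters
    ----------
    cpg_ids : list of str
        Unique CpG identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_cpgs, n_samples)
        Methylation fractions; finite, in [0, 1].
    """

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValidationError("duplicate CpG identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite beta at CpG {self.cpg_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )
        if self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo < -BETA_TOL or hi > 1 + BETA_TOL:
                bad = np.argwhere(
                    (self.values < -BETA_TOL) | (self.values > 1 + BETA_TOL)
                )[0]
                raise ValidationError(
                    f"beta value outside [0, 1] at CpG {self.cpg_ids[bad[0]]}, "
                    f"sample {self.sample_ids[bad[1]]}: "
                    f"{self.values[bad[0], bad[1]]!r}"
                )
            np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_cpgs(self, cpgs: list[str]) -> "BetaMatrix":
        """Return the rows named in ``cpgs``, in that order."""
        pos = {c: i for i, c in enumerate(self.cpg_ids)}
        missing = [c for c in cpgs if c not in pos]
        if missing:
            raise KeyError(f"CpGs not present: {missing[:10]}")
        idx = [pos[c] for c in cpgs]
        return BetaMatrix(list(cpgs), list(self.sample_ids), self.values[idx].copy())

    def subset_samples(self, samples: list[str]) -> "BetaMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return BetaMatrix(list(self.cpg_ids), list(samples), self.values[:, idx].copy())


#: recognized optional sample-sheet columns and their dtypes
SHEET_COLUMNS = {
    "cpd": float,
    "passage": float,
    "age": float,
    "tissue": str,
    "sex": str,
    "bmi": float,
    "group": str,
    "time": float,
    "event": float,
    "phase": str,
    "division_rate": float,
}


@dataclass
class SampleSheet:
    """Per-sample covariates keyed by ``sample_id``.

    Wraps a DataFrame indexed by sample_id.  Optional columns: cpd, passage,
    age, tissue, sex, bmi, group, time, event, phase, division_rate.
    ``event`` must be present (and 0/1) wherever ``time`` is.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample_id in sample sheet")
        if "time" in df.columns:
            has_time = df["time"].notna()
            if "event" not in df.columns or df.loc[has_time, "event"].isna().any():
                raise ValidationError("event must be present wherever time is")
            ev = df.loc[has_time, "event"]
            if not ev.isin([0, 1]).all():
                raise ValidationError("event must be 0/1")
            if (df.loc[has_time, "time"] <= 0).any():
                raise ValidationError("survival time must be > 0")
        if "cpd" in df.columns and (df["cpd"].dropna() < 0).any():
            raise ValidationError("cpd must be >= 0")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __getitem__(self, column: str) -> pd.Series:
        return self.data[column]

    def __contains__(self, column: str) -> bool:
        return column in self.data.columns

    def aligned_to(self, m: BetaMatrix) -> "SampleSheet":
        """Reorder rows to match the sample order of ``m``.

        Raises if the sample sets differ.
        """
        if set(self.data.index) != set(m.sample_ids):
            raise ValidationError("sample sheet and beta matrix sample sets differ")
        return SampleSheet(self.data.loc[m.sample_ids].copy())


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


def read_beta_matrix(path: str | os.PathLike, orientation: str = "rows-are-cpgs") -> BetaMatrix:
    """Read a delimited beta matrix (TSV or CSV by extension).

    Parameters
    ----------
    path : path
        Text file with one header row and one identifier column.
    orientation : {"rows-are-cpgs", "rows-are-samples"}
        Layout of the file; output is always CpGs x samples.
    """
    if orientation not in ("rows-are-cpgs", "rows-are-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"missing beta value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if orientation == "rows-are-samples":
        numeric = numeric.T
    return BetaMatrix.from_frame(numeric)


def write_beta_matrix(m: BetaMatrix, path: str | os.PathLike) -> None:
    """Write CpGs x samples to TSV/CSV (by extension) at full precision."""
    sep = "," if str(path).endswith(".csv") else "\t"
    m.to_frame().to_csv(path, sep=sep)


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read a sample sheet CSV; the header must include ``sample_id``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValidationError("sample sheet must contain a sample_id column")
    for col, typ in SHEET_COLUMNS.items():
        if col in df.columns and typ is float:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.data.to_csv(path, index_label="sample_id")


def exclude_sex_chromosome_cpgs(m: BetaMatrix, annotation: dict[str, str]) -> BetaMatrix:
    """Drop CpGs annotated to chromosome X or Y.

    CpGs absent from ``annotation`` are retained (and logged): the filter only
    removes what is positively known to be gonosomal.
    """
    unannotated = [c for c in m.cpg_ids if c not in annotation]
    if unannotated:
        logger.warning(
            "%d CpGs lack chromosome annotation and are retained", len(unannotated)
        )
    keep = [c for c in m.cpg_ids if annotation.get(c) not in SEX_CHROMOSOMES]
    if not keep:
        raise ValidationError("no autosomal CpGs remain")
    if len(keep) == m.n_cpgs:
        return m
    return m.subset_cpgs(keep)


def align_to_reference(m: BetaMatrix, reference_cpgs: list[str]) -> BetaMatrix:
    """Restrict to the CpGs on a reference array, in reference order.

    Used to harmonize datasets (e.g. EPIC data aligned to the 450k manifest)
    before consensus analysis.  Idempotent.
    """
    present = set(m.cpg_ids)
    kept = [c for c in reference_cpgs if c in present]
    if not kept:
        raise ValidationError("no CpGs shared with the reference")
    return m.subset_cpgs(kept)


def compute_cpd(initial_density: float, final_density: float) -> float:
    """Population doublings between two cell counts: log2(final / initial).

    Cumulative population doublings (cPD) is the running sum of this quantity
    across passages; it is the clock training target.
    """
    if initial_density <= 0 or final_density <= 0:
        raise ValueError("cell densities must be strictly positive")
    return math.log2(final_density / initial_density)


def cumulative_cpd(densities: list[tuple[float, float]]) -> float:
    """Running cPD across passages given (initial, final) density pairs."""
    return sum(compute_cpd(i, f) for i, f in densities)


# --------------------------------------------------------------------------
# Model serialization: self-describing JSON container, arrays at full double
# precision (json round-trips Python floats bit-exactly).

def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _from_jsonable(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj.get("dtype", "float64"))
        return {k: _from_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_from_jsonable(v) for v in obj]
    return obj


def save_model(model, path: str | os.PathLike) -> None:
    """Serialize a trained model to a self-describing JSON archive.

    The archive records a schema version and a model-kind tag; ``load_model``
    reconstructs an object whose predictions are bit-identical.
    """
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kind": type(model).__name__,
        "state": _to_jsonable(model.to_state()),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | os.PathLike):
    """Load a model archive written by :func:`save_model`."""
    # imported here to avoid a circular module dependency
    from .composite import CompositeModel
    from .pcclock import PCClock, PCModel

    kinds = {"PCClock": PCClock, "PCModel": PCModel, "CompositeModel": CompositeModel}
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"corrupt model archive {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValidationError(
            f"model archive schema version {version!r} != supported "
            f"{MODEL_SCHEMA_VERSION}"
        )
    kind = payload.get("kind")
    if kind not in kinds:
        raise ValidationError(f"unknown model kind {kind!r}")
    return kinds[kind].from_state(_from_jsonable(payload["state"]))
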