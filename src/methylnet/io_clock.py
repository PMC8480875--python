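"""Methylation matrices, clock coefficient files and the epigenetic-age transform.

The central data objects are :class:`MethylationMatrix` — a CpG-by-sample table of
beta values (fraction of methylated copies, in [0, 1]) with optional per-sample
chronological ages — and :class:`ClockModel`, the coefficient vector ``H`` and
adult age threshold ``a_t`` of a multi-tissue epigenetic clock.  The clock maps a
methylation profile ``m`` to an estimated ("DNAm") age via a piecewise transform:
linear in ``S = sum_i H_i m_i`` above the adult threshold, exponential below it,
continuous at ``S = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "ClockModel",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_geo_series_matrix",
    "read_metadata",
    "read_clock",
    "write_clock",
    "horvath_age",
    "horvath_ages",
    "mean_cpg_std",
]


class MethylationMatrix:
    """CpG-by-sample beta values with optional sample ages.

    Parameters
    ----------
    values : (n_cpgs, n_samples) array-like
        Beta values, each finite and in [0, 1].
    cpg_ids, sample_ids : sequences of str
        Unique row and column identifiers, order preserved.
    ages : sequence of float, optional
        Chronological age in years per sample, non-negative, aligned with
        ``sample_ids``.
    """

    def __init__(self, values, cpg_ids, sample_ids, ages=None, *, validate=True):
        self.values = np.asarray(values, dtype=float)
        self.cpg_ids = list(map(str, cpg_ids))
        self.sample_ids = list(map(str, sample_ids))
        self.ages = None if ages is None else np.asarray(ages, dtype=float)
        if validate:
            self._validate()

    def _validate(self):
        v = self.values
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {v.shape}")
        if v.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            dupes = pd.Index(self.cpg_ids)[pd.Index(self.cpg_ids).duplicated()]
            raise ValueError(f"duplicate CpG ids: {sorted(set(dupes))}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Index(self.sample_ids)[pd.Index(self.sample_ids).duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
        bad = ~np.isfinite(v) | (v < 0.0) | (v > 1.0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {v[r, c]!r} out of [0, 1] at "
                f"CpG {self.cpg_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        if self.ages is not None:
            if self.ages.shape != (len(self.sample_ids),):
                raise ValueError(
                    f"ages length {self.ages.shape} does not match "
                    f"{len(self.sample_ids)} samples"
                )
            if not np.all(np.isfinite(self.ages)) or np.any(self.ages < 0):
                raise ValueError("ages must be finite and non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.values.shape

    @property
    def n_cpgs(self):
        return self.values.shape[0]

    @property
    def n_samples(self):
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.cpg_ids, name="cpg_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ages=None) -> "MethylationMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), ages)

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "MethylationMatrix":
        idx = pd.Index(self.cpg_ids)
        missing = [c for c in cpg_ids if c not in idx]
        if missing:
            raise KeyError(f"CpGs not in matrix: {missing}")
        rows = idx.get_indexer(list(cpg_ids))
        return MethylationMatrix(self.values[rows], list(cpg_ids),
                                 self.sample_ids, self.ages, validate=False)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        idx = pd.Index(self.sample_ids)
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = idx.get_indexer(list(sample_ids))
        ages = None if self.ages is None else self.ages[cols]
        return MethylationMatrix(self.values[:, cols], self.cpg_ids,
                                 list(sample_ids), ages, validate=False)

    def profile(self, sample_id: str) -> dict:
        """Methylation profile of one sample, keyed by CpG id."""
        j = self.sample_ids.index(sample_id)
        return dict(zip(self.cpg_ids, self.values[:, j]))

    def __repr__(self):
        ages = "with ages" if self.ages is not None else "no ages"
        return f"<MethylationMatrix {self.n_cpgs} CpGs x {self.n_samples} samples, {ages}>"


@dataclass
class ClockModel:
    """Epigenetic-clock coefficients ``H`` and adult age threshold ``a_t``."""

    coefficients: dict = field(default_factory=dict)
    adult_threshold: float = 20.0

    def __post_init__(self):
        self.coefficients = {str(k): float(v) for k, v in dict(self.coefficients).items()}
        self.adult_threshold = float(self.adult_threshold)
        if not self.adult_threshold > -1:
            raise ValueError(f"adult_threshold must exceed -1, got {self.adult_threshold}")
        if not self.coefficients:
            raise ValueError("clock must have at least one coefficient")
        vals = np.fromiter(self.coefficients.values(), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("all clock coefficients must be finite")
        if np.all(vals == 0):
            raise ValueError("clock must have at least one non-zero coefficient")

    def vector(self, cpg_ids: Sequence[str]) -> np.ndarray:
        """Coefficient vector H aligned with ``cpg_ids`` (error on missing ids)."""
        missing = [c for c in cpg_ids if c not in self.coefficients]
        if missing:
            raise KeyError(f"clock is missing coefficients for: {missing}")
        return np.array([self.coefficients[c] for c in cpg_ids], dtype=float)

    def __len__(self):
        return len(self.coefficients)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _delimiter_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_metadata(path, *, age_column: str = "age") -> pd.Series:
    """Read a sample metadata table and return ages indexed by sample id."""
    meta = pd.read_csv(path, sep=_delimiter_for(path))
    if "sample_id" not in meta.columns:
        raise ValueError(f"metadata {path} lacks a 'sample_id' column")
    if age_column not in meta.columns:
        raise ValueError(f"metadata {path} lacks an {age_column!r} column")
    ages = pd.to_numeric(meta[age_column], errors="coerce")
    if ages.isna().any():
        bad = meta.loc[ages.isna(), "sample_id"].tolist()
        raise ValueError(f"non-numeric {age_column!r} for samples: {bad}")
    return pd.Series(ages.to_numpy(float), index=meta["sample_id"].astype(str))


def read_beta_matrix(path, metadata=None, *, age_column: str = "age",
                     transpose: bool = False) -> MethylationMatrix:
    """Read a delimited beta-value table (rows = CpGs, columns = samples).

    The first column holds CpG ids.  ``metadata``, if given, is a path to a
    TSV/CSV with columns ``sample_id`` and ``age``; every sample of the matrix
    must appear there.  ``transpose=True`` accepts column-major (samples-as-rows)
    exports.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0,
                     float_precision="round_trip")
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # locate non-numeric cells before coercion so the error can name them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric beta value {df.iat[r, c]!r} at "
            f"CpG {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing beta value at CpG {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    ages = None
    if metadata is not None:
        series = read_metadata(metadata, age_column=age_column)
        missing = [s for s in df.columns if s not in series.index]
        if missing:
            raise ValueError(f"metadata lacks ages for samples: {missing}")
        ages = series.loc[list(df.columns)].to_numpy()
    return MethylationMatrix(numeric.to_numpy(float), list(df.index),
                             list(df.columns), ages)


def write_beta_matrix(matrix: MethylationMatrix, path) -> None:
    """Write a beta matrix; full float precision so read-back round-trips."""
    matrix.to_dataframe().to_csv(path, sep=_delimiter_for(path),
                                 float_format="%.17g")


def read_geo_series_matrix(path, *, age_column=None) -> MethylationMatrix:
    """Read a GEO series-matrix export.

    ``!``-prefixed header lines are skipped and the beta table is taken from
    between the ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
    markers.  ``age_column``, if given, names a ``!Sample_characteristics_ch1``
    key (e.g. ``"age"``) parsed from ``key: value`` entries of the header.
    """
    header_chars: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(stripped)
            elif stripped.startswith("!Sample_characteristics_ch1"):
                parts = [p.strip().strip('"') for p in stripped.split("\t")[1:]]
                for p in parts:
                    if ":" in p:
                        key, val = p.split(":", 1)
                        header_chars.setdefault(key.strip(), []).append(val.strip())
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix_table_begin/end block found")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    ages = None
    if age_column is not None:
        if age_column not in header_chars:
            raise ValueError(f"no {age_column!r} entries in sample characteristics")
        vals = header_chars[age_column]
        if len(vals) != df.shape[1]:
            raise ValueError(
                f"{len(vals)} {age_column!r} entries for {df.shape[1]} samples")
        ages = np.array([float(v) for v in vals])
    return MethylationMatrix(df.to_numpy(float), list(df.index), list(df.columns), ages)


def read_clock(path, adult_threshold: float | None = None) -> ClockModel:
    """Read a clock-coefficient CSV with columns ``cpg_id``, ``coefficient``.

    A comment line ``# adult_threshold=<years>`` sets ``a_t``; an explicit
    ``adult_threshold`` argument overrides it; the default is 20.
    """
    at_from_file = None
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("adult_threshold"):
                    at_from_file = float(body.split("=", 1)[1])
                continue
            rows.append(line)
    if not rows:
        raise ValueError(f"{path}: empty clock file")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(rows)), sep=_delimiter_for(path),
                     float_precision="round_trip")
    if not {"cpg_id", "coefficient"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'cpg_id' and 'coefficient'")
    ids = df["cpg_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate CpG ids in clock: "
                         f"{sorted(ids[ids.duplicated()].unique())}")
    coefs = pd.to_numeric(df["coefficient"], errors="coerce")
    if coefs.isna().any():
        bad = ids[coefs.isna()].tolist()
        raise ValueError(f"non-numeric coefficients for CpGs: {bad}")
    at = adult_threshold if adult_threshold is not None else (
        at_from_file if at_from_file is not None else 20.0)
    return ClockModel(dict(zip(ids, coefs.astype(float))), at)


def write_clock(clock: ClockModel, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# adult_threshold={clock.adult_threshold:.17g}\n")
        fh.write("cpg_id,coefficient\n")
        for cpg, coef in clock.coefficients.items():
            fh.write(f"{cpg},{coef:.17g}\n")


# ---------------------------------------------------------------------------
# the age transform
# ---------------------------------------------------------------------------

def horvath_age(profile: Mapping[str, float], clock: ClockModel) -> float:
    """Estimated (DNAm) age of a methylation profile under the clock.

    With ``S = sum_i H_i m_i`` and adult threshold ``a_t``::

        a = (a_t + 1) * S + a_t          if S >= 0
        a = exp(S + ln(a_t + 1)) - 1     if S <  0

    The two branches join continuously at ``S = 0`` (both give ``a_t``).
    """
    missing = [c for c in clock.coefficients if c not in profile]
    if missing:
        raise KeyError(f"profile is missing methylation levels for: {missing}")
    s = float(sum(h * float(profile[c]) for c, h in clock.coefficients.items()))
    return _age_from_score(s, clock.adult_threshold)


def _age_from_score(s, a_t):
    s = np.asarray(s, dtype=float)
    linear = (a_t + 1.0) * s + a_t
    expo = np.exp(s + np.log(a_t + 1.0)) - 1.0
    out = np.where(s >= 0, linear, expo)
    return float(out) if out.ndim == 0 else out


def horvath_ages(matrix: MethylationMatrix, clock: ClockModel) -> np.ndarray:
    """Vectorized clock ages for every sample of a matrix.

    The clock may cover a subset of the matrix CpGs, but every clock CpG must
    be present in the matrix.
    """
    idx = pd.Index(matrix.cpg_ids)
    missing = [c for c in clock.coefficients if c not in idx]
    if missing:
        raise KeyError(f"matrix is missing clock CpGs: {missing}")
    rows = idx.get_indexer(list(clock.coefficients))
    h = np.fromiter(clock.coefficients.values(), dtype=float)
    scores = h @ matrix.values[rows]
    return _age_from_score(scores, clock.adult_threshold)


def mean_cpg_std(matrix: MethylationMatrix, *, ddof: int = 1) -> float:
    """Mean over CpGs of the per-CpG standard deviation across samples.

    Twice this value is the canonical perturbation size ``delta_m`` used in the
    perturbation analysis.  Sample convention (``ddof=1``) by default.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to compute standard deviations")
    return float(np.mean(np.std(matrix.values, axis=1, ddof=ddof)))
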