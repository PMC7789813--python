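"""Expression matrices, design tables, Ct tables, and their normalizations.

Matrices are feature-by-sample: features as rows, samples as columns, TSV
on disk with a header row of sample identifiers and feature identifiers in
the first column. TPM uses gene length in kilobases internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised abundance scales for an ExpressionMatrix.
SCALES = ("count", "TPM", "CPM", "abundance")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(labels: Iterable[str], kind: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {kind} identifiers: {dups}")


@dataclass
class ExpressionMatrix:
    """Nonnegative abundances indexed by feature (rows) and sample (columns).

    Parameters
    ----------
    values
        DataFrame of shape (n_features, n_samples). NaN marks an explicitly
        missing measurement (permitted only on the ``abundance`` scale,
        where it arises from missing Ct wells).
    scale
        One of ``count``, ``TPM``, ``CPM``, ``abundance``.
    """

    values: pd.DataFrame
    scale: str = "count"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any() and self.scale != "abundance":
            raise ValidationError("missing values are only permitted on the abundance scale")
        with np.errstate(invalid="ignore"):
            neg = arr < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative value {arr[i, j]} at feature "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        self.values = self.values.astype(float)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, features=None, samples=None) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given features/samples."""
        vals = self.values
        if features is not None:
            missing = [f for f in features if f not in vals.index]
            if missing:
                raise KeyError(f"features not in matrix: {missing}")
            vals = vals.loc[list(features)]
        if samples is not None:
            missing = [s for s in samples if s not in vals.columns]
            if missing:
                raise KeyError(f"samples not in matrix: {missing}")
            vals = vals[list(samples)]
        return ExpressionMatrix(vals.copy(), scale=self.scale)


@dataclass
class SampleDesign:
    """Maps each sample to a group label and a case/control condition."""

    table: pd.DataFrame  # columns: sample, group, condition

    def __post_init__(self) -> None:
        required = {"sample", "group", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        _check_unique(self.table["sample"], "sample")
        bad = set(self.table["condition"]) - {"case", "control"}
        if bad:
            raise ValidationError(f"condition must be 'case' or 'control', got: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def case_groups(self) -> list[str]:
        sub = self.table[self.table["condition"] == "case"]
        return sorted(sub["group"].unique().tolist())

    def samples_in_group(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample"].tolist()

    def case_samples(self) -> list[str]:
        return self.table.loc[self.table["condition"] == "case", "sample"].tolist()

    def control_samples(self) -> list[str]:
        return self.table.loc[self.table["condition"] == "control", "sample"].tolist()

    def require_case_control(self) -> None:
        if not self.case_samples() or not self.control_samples():
            raise ValidationError("design must contain at least one case and one control sample")


@dataclass
class GeneLengthTable:
    """Feature lengths in base pairs, used for TPM."""

    lengths: pd.Series  # index: feature, values: int bp

    def __post_init__(self) -> None:
        _check_unique(self.lengths.index, "feature")
        vals = self.lengths.astype(float)
        if not np.all(np.isfinite(vals)) or (vals <= 0).any():
            bad = self.lengths.index[(~np.isfinite(vals)) | (vals <= 0)].tolist()
            raise ValidationError(f"lengths must be positive and finite; offending features: {bad}")
        self.lengths = vals


@dataclass
class CtTable:
    """qPCR cycle-threshold values, feature-by-sample; NaN = missing well."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.isinf(arr) | (arr <= 0)
        bad &= ~np.isnan(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"Ct values must be finite and > 0; got {arr[i, j]} at "
                f"feature {self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        self.values = self.values.astype(float)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, sep: str = "\t", scale: str = "count") -> ExpressionMatrix:
    """Read a feature-by-sample matrix from a delimited text file.

    The first column holds feature identifiers, the header row sample
    identifiers. Duplicate identifiers and negative or non-numeric cells
    are hard errors.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    # coerce: any non-numeric cell becomes an error with coordinates
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            feat = df.index[bad][0]
            raise ValidationError(
                f"non-numeric value {df.loc[feat, col]!r} at feature {feat!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any() and scale != "abundance":
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"missing value at feature {df.index[loc[0]]!r}, sample {df.columns[loc[1]]!r}"
        )
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df, scale=scale)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix as delimited text (feature rows, sample columns)."""
    matrix.values.to_csv(path, sep=sep, index_label="feature")


def read_design(path: str | Path, sep: str = "\t") -> SampleDesign:
    """Read a sample design table (columns: sample, group, condition)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path, sep: str = "\t") -> None:
    design.table.to_csv(path, sep=sep, index=False)


def read_lengths(path: str | Path, sep: str = "\t") -> GeneLengthTable:
    """Read a two-column feature/length table."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValidationError("length table needs two columns: feature, length")
    ser = pd.Series(df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="feature"))
    return GeneLengthTable(ser)


def read_ct_table(path: str | Path, sep: str | None = None) -> CtTable:
    """Read a Ct table, long or wide, autodetected by header.

    Long format has columns ``feature, sample, ct``; anything else is
    treated as wide (feature rows, sample columns). Empty cells are
    explicit missing values.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    head = pd.read_csv(path, sep=sep, nrows=0)
    cols = [c.lower() for c in head.columns]
    if cols[:3] == ["feature", "sample", "ct"] or set(cols) >= {"feature", "sample", "ct"}:
        long = pd.read_csv(path, sep=sep)
        long.columns = [c.lower() for c in long.columns]
        dup = long.duplicated(subset=["feature", "sample"])
        if dup.any():
            pair = long.loc[dup, ["feature", "sample"]].iloc[0].tolist()
            raise ValidationError(f"duplicate Ct entry for (feature, sample) = {tuple(pair)}")
        wide = long.pivot(index="feature", columns="sample", values="ct")
        wide.index.name = None
        wide.columns.name = None
        return CtTable(wide)
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CtTable(df)


# ---------------------------------------------------------------------------
# Normalizations
# ---------------------------------------------------------------------------

def compute_tpm(counts: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """Length-normalize counts to transcripts per million.

    Per sample: ``rate_j = count_j / length_kb_j``; ``TPM_j = rate_j /
    sum(rates) * 1e6``. Every sample column sums to 1e6.
    """
    if counts.scale != "count":
        raise ValidationError(f"TPM expects counts, got scale {counts.scale!r}")
    missing = counts.features.difference(lengths.lengths.index)
    if len(missing):
        raise ValidationError(f"no length for features: {missing.tolist()[:10]}")
    kb = lengths.lengths.reindex(counts.features).to_numpy() / 1000.0
    rates = counts.values.to_numpy() / kb[:, None]
    totals = rates.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        bad = counts.samples[zero].tolist()
        raise ValidationError(f"TPM undefined for all-zero samples: {bad}")
    tpm = rates / totals[None, :] * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.features, columns=counts.samples), scale="TPM"
    )


def compute_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalize counts to counts per million per sample."""
    if counts.scale != "count":
        raise ValidationError(f"CPM expects counts, got scale {counts.scale!r}")
    arr = counts.values.to_numpy()
    totals = arr.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        bad = counts.samples[zero].tolist()
        raise ValidationError(f"CPM undefined for all-zero samples: {bad}")
    cpm = arr / totals[None, :] * 1e6
    return ExpressionMatrix(
        pd.DataFrame(cpm, index=counts.features, columns=counts.samples), scale="CPM"
    )


def log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); monotone, maps 0 to 0."""
    arr = matrix.values.to_numpy()
    with np.errstate(invalid="ignore"):
        if np.nanmin(arr) < 0:
            raise ValidationError("log2p1 requires nonnegative values")
    out = np.log2(arr + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.features, columns=matrix.samples), scale=matrix.scale
    )


def ct_to_abundance(ct: CtTable) -> ExpressionMatrix:
    """Convert cycle thresholds to abundances, 2^-Ct per cell.

    Missing wells propagate as missing values; downstream stability
    scorers state their own missing-data policy.
    """
    arr = 2.0 ** (-ct.values.to_numpy(dtype=float))
    n_missing = int(np.isnan(arr).sum())
    if n_missing:
        logger.warning("ct_to_abundance: %d missing Ct cells propagate as missing", n_missing)
    return ExpressionMatrix(
        pd.DataFrame(arr, index=ct.features, columns=ct.samples), scale="abundance"
    )


def relative_ct(ct: CtTable, control_feature: str) -> CtTable:
    """Delta-Ct relative to a control feature: Ct_ij - Ct_control,i.

    The control feature must have a Ct in every sample; its own relative
    values are exactly zero. The result may contain values <= 0, so it is
    returned as a plain DataFrame-backed table without the positivity
    check applied to raw Ct input.
    """
    if control_feature not in ct.features:
        raise ValidationError(f"control feature {control_feature!r} not in Ct table")
    ctrl = ct.values.loc[control_feature]
    missing = ctrl.index[ctrl.isna()].tolist()
    if missing:
        raise ValidationError(
            f"control feature {control_feature!r} missing in samples: {missing}"
        )
    delta = ct.values.sub(ctrl, axis=1)
    out = CtTable.__new__(CtTable)
    out.values = delta.astype(float)
    return out
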