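"""Count-matrix I/O, validation, normalization and (log-)CPM.

The package starts from a feature-by-sample matrix of non-negative integer
read counts and a two-group sample design. Counts are strictly integers:
files carrying decimal "expected counts" are rejected rather than rounded,
so all downstream resampling stays on the Negative-Binomial support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GroupDesign",
    "NormalizationResult",
    "read_counts",
    "write_counts",
    "read_design",
    "size_factors",
    "cpm",
]


class ValidationError(ValueError):
    """Raised when an input violates the count-matrix or design contract."""


@dataclass
class CountMatrix:
    """G x n matrix of non-negative integer read counts with identifiers.

    Parameters
    ----------
    counts
        Integer array of shape (G, n); values must be >= 0.
    feature_ids
        G unique feature identifiers (rows).
    sample_ids
        n unique sample identifiers (columns).
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            # accept float arrays only when every entry is an exact integer
            if np.issubdtype(self.counts.dtype, np.floating):
                if np.any(~np.isfinite(self.counts)) or np.any(self.counts % 1 != 0):
                    bad = np.argwhere(
                        ~np.isfinite(self.counts) | (self.counts % 1 != 0)
                    )[0]
                    raise ValidationError(
                        f"non-integer count at (feature {self.feature_ids[bad[0]]!r}, "
                        f"sample {self.sample_ids[bad[1]]!r}): "
                        f"{self.counts[bad[0], bad[1]]}"
                    )
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValidationError(f"counts must be integers, got dtype {self.counts.dtype}")
        if np.any(self.counts < 0):
            g, i = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at (feature {self.feature_ids[g]!r}, "
                f"sample {self.sample_ids[i]!r})"
            )
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        G, n = self.counts.shape
        if G < 1 or n < 2:
            raise ValidationError(f"need G >= 1 features and n >= 2 samples, got {G} x {n}")
        if len(self.feature_ids) != G:
            raise ValidationError("feature_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match column count")
        if len(set(self.feature_ids)) != G:
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class GroupDesign:
    """Two-condition sample assignment aligned with a CountMatrix's columns."""

    labels: list[str]
    group_indices: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        uniq = sorted(set(self.labels))
        if len(uniq) != 2:
            raise ValidationError(
                f"exactly two conditions required, got {len(uniq)}: {uniq}"
            )
        arr = np.asarray(self.labels)
        self.group_indices = {g: np.flatnonzero(arr == g) for g in uniq}

    @property
    def group_names(self) -> tuple[str, str]:
        a, b = sorted(self.group_indices)
        return a, b

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def indicator(self) -> np.ndarray:
        """0/1 vector: 1 for the second (alphabetically later) condition."""
        _, b = self.group_names
        return (np.asarray(self.labels) == b).astype(int)


@dataclass
class NormalizationResult:
    """Per-sample library-size factors (all > 0)."""

    size_factors: np.ndarray
    method_name: str

    def __post_init__(self) -> None:
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(~np.isfinite(self.size_factors)) or np.any(self.size_factors <= 0):
            raise ValidationError("size factors must be finite and > 0")


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV/CSV (features x samples) or MatrixMarket.

    TSV/CSV files need a header row of sample ids and feature ids in the
    first column. A ``.mtx`` file must sit next to two sidecar id files,
    ``<stem>.features.txt`` and ``<stem>.samples.txt`` (one id per line).
    Non-integer entries are rejected, never rounded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count file not found: {path}")
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx", ".txt": "tsv"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.name[: -len(".mtx")]
        feats = _read_id_file(path.parent / f"{stem}.features.txt")
        samps = _read_id_file(path.parent / f"{stem}.samples.txt")
        return CountMatrix(np.asarray(mat), feats, samps)
    sep = {"tsv": "\t", "csv": ","}[format]
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"failed to parse {path}: {exc}") from exc
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.loc[r, c])
        )
        raise ValidationError(f"missing value at (feature {row!r}, sample {col!r}) in {path}")
    return CountMatrix(df.to_numpy(), list(df.index), list(df.columns))


def _read_id_file(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"MatrixMarket sidecar id file not found: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_counts(cm: CountMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a count matrix in the dialect implied by the file suffix."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix.lower(), "tsv")
    if format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
        stem = path.name[: -len(".mtx")]
        (path.parent / f"{stem}.features.txt").write_text("\n".join(cm.feature_ids) + "\n")
        (path.parent / f"{stem}.samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
        return
    sep = {"tsv": "\t", "csv": ","}[format]
    cm.to_dataframe().to_csv(path, sep=sep)


def read_design(path: str | Path, sample_ids: list[str] | None = None) -> GroupDesign:
    """Read a two-group design.

    Accepts either a two-column file (sample id, condition label) or a
    single-column ordered label list. When ``sample_ids`` is given the
    two-column form is re-ordered to match it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"design file not found: {path}")
    rows = [
        line.replace(",", "\t").split("\t")
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValidationError(f"inconsistent column count in design file {path}")
    if ncol == 1:
        labels = [r[0].strip() for r in rows]
        if sample_ids is not None and len(labels) != len(sample_ids):
            raise ValidationError(
                f"design lists {len(labels)} labels but matrix has {len(sample_ids)} samples"
            )
        return GroupDesign(labels)
    if ncol == 2:
        mapping = {r[0].strip(): r[1].strip() for r in rows}
        # skip an optional header line
        if sample_ids is not None and rows[0][0].strip() not in sample_ids:
            first = rows[0][0].strip()
            if all(first != s for s in sample_ids):
                mapping.pop(first, None)
        if sample_ids is None:
            return GroupDesign(list(mapping.values()))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValidationError(f"design is missing sample ids: {missing}")
        return GroupDesign([mapping[s] for s in sample_ids])
    raise ValidationError(f"design file must have 1 or 2 columns, got {ncol}")


def size_factors(cm: CountMatrix, method: str = "median_ratio") -> NormalizationResult:
    """Library-size factors.

    ``median_ratio`` is the median-of-ratios scheme: each sample's factor is
    the median, over features with all-positive counts, of that sample's
    count divided by the feature's geometric mean across samples.
    ``total_count`` scales column sums to their mean. When no feature has
    all-positive counts, median_ratio falls back to total_count with a
    logged warning.
    """
    colsums = cm.counts.sum(axis=0)
    if np.any(colsums == 0):
        i = int(np.flatnonzero(colsums == 0)[0])
        raise ValidationError(f"sample {cm.sample_ids[i]!r} has all-zero counts")
    if method == "total_count":
        return NormalizationResult(colsums / colsums.mean(), "total_count")
    if method == "median_ratio":
        allpos = np.all(cm.counts > 0, axis=1)
        if not allpos.any():
            logger.warning(
                "median_ratio: no feature with all-positive counts; "
                "falling back to total_count"
            )
            return NormalizationResult(colsums / colsums.mean(), "total_count")
        logc = np.log(cm.counts[allpos].astype(float))
        ref = logc.mean(axis=1)  # log geometric mean per feature
        factors = np.exp(np.median(logc - ref[:, None], axis=0))
        return NormalizationResult(factors, "median_ratio")
    raise ValueError(f"unknown normalization method {method!r}")


def cpm(
    cm: CountMatrix, log2: bool = False, prior_count: float = 0.5
) -> np.ndarray:
    """Counts per million; optionally log2 with a prior count.

    Plain CPM is ``counts / colsum * 1e6``. The log form applies the prior
    to both numerator and denominator:
    ``log2((counts + prior) / (colsum + 2*prior) * 1e6)``.
    """
    colsums = cm.counts.sum(axis=0).astype(float)
    if np.any(colsums == 0):
        i = int(np.flatnonzero(colsums == 0)[0])
        raise ValidationError(f"sample {cm.sample_ids[i]!r} has zero column sum")
    if not log2:
        return cm.counts / colsums * 1e6
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    return np.log2((cm.counts + prior_count) / (colsums + 2 * prior_count) * 1e6)
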