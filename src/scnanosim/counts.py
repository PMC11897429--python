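"""UMI count matrices: I/O, parameter estimation and Gamma-Poisson simulation.

A feature-by-cell UMI count matrix is the ground truth of every simulation
run.  Real single-cell counts are sparse and overdispersed; we model each
entry as a Gamma-Poisson (negative binomial) draw

    X[f, c] ~ Poisson(s_c * Gamma(mean = mu_f, var = phi_f * mu_f**2))

so that Var(X) = s_c*mu_f + (s_c*mu_f)**2 * phi_f / 1, with per-cell
library-size factors ``s_c`` drawn log-normally (median 1).  ``phi_f = 0``
degenerates to a plain Poisson.  Parameters can be estimated from any real
(or previously simulated) matrix by method of moments, so a simulation can
be anchored to an existing experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "CountModelParams",
    "read_count_matrix",
    "write_count_matrix",
    "estimate_count_params",
    "simulate_counts",
]


class CountMatrixFormatError(ValueError):
    """Raised when a CSV does not parse into a valid UMI count matrix."""


@dataclass
class CountMatrix:
    """Non-negative integer UMI counts, features as rows, cells as columns."""

    feature_ids: list[str]
    cell_barcodes: list[str]
    counts: np.ndarray  # shape (n_features, n_cells), integer dtype

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountMatrixFormatError("counts must be a 2-D array")
        nf, nc = self.counts.shape
        if nf != len(self.feature_ids) or nc != len(self.cell_barcodes):
            raise CountMatrixFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_barcodes)} cells"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise CountMatrixFormatError("duplicate feature ids")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise CountMatrixFormatError("duplicate cell barcodes")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise CountMatrixFormatError(
                    f"non-integer count at feature '{self.feature_ids[bad[0]]}', "
                    f"cell '{self.cell_barcodes[bad[1]]}'"
                )
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            bad = np.argwhere(self.counts < 0)[0]
            raise CountMatrixFormatError(
                f"negative count at feature '{self.feature_ids[bad[0]]}', "
                f"cell '{self.cell_barcodes[bad[1]]}'"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.cell_barcodes
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.cell_barcodes == other.cell_barcodes
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class CountModelParams:
    """Parameters of the Gamma-Poisson count simulator.

    ``feature_mean`` is the expected UMI count per feature in a cell with
    library-size factor 1 (the median cell).  ``feature_dispersion`` is the
    negative-binomial overdispersion ``phi`` (variance mu + phi*mu^2); 0
    means Poisson.  Per-cell library sizes are log-normal with the given
    log-scale mean and standard deviation; simulation uses the size factor
    ``exp(libsize_log_sd * z)`` so the median factor is exactly 1.
    """

    feature_mean: np.ndarray
    feature_dispersion: np.ndarray
    libsize_log_mean: float
    libsize_log_sd: float
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.feature_mean = np.asarray(self.feature_mean, dtype=float)
        self.feature_dispersion = np.asarray(self.feature_dispersion, dtype=float)
        if self.feature_mean.shape != self.feature_dispersion.shape:
            raise ValueError("feature_mean and feature_dispersion lengths differ")
        if np.any(self.feature_mean < 0) or np.any(self.feature_dispersion < 0):
            raise ValueError("means and dispersions must be >= 0")
        if self.libsize_log_sd < 0:
            raise ValueError("libsize_log_sd must be >= 0")

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.feature_ids or [f"feature_{i}" for i in range(len(self.feature_mean))]
        return pd.DataFrame(
            {"mean": self.feature_mean, "dispersion": self.feature_dispersion},
            index=ids,
        )


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a feature-by-cell UMI count CSV.

    Dialect: features as rows, first column holds feature ids, header row
    holds cell barcodes, comma separated, UTF-8.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # malformed CSV
        raise CountMatrixFormatError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise CountMatrixFormatError(
                f"non-numeric entry in cell column '{col}'"
                + (f" at feature '{bad.index[0]}'" if len(bad) else "")
            )
    return CountMatrix(
        feature_ids=[str(i) for i in df.index],
        cell_barcodes=[str(c) for c in df.columns],
        counts=df.to_numpy(),
    )


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> Path:
    """Write a matrix in the CSV dialect accepted by :func:`read_count_matrix`."""
    path = Path(path)
    matrix.to_dataframe().to_csv(path)
    return path


def estimate_count_params(matrix: CountMatrix) -> CountModelParams:
    """Method-of-moments fit of the Gamma-Poisson model to a count matrix.

    Library-size factor of a cell is its total count divided by the median
    cell total.  Feature means are means of size-factor-normalised counts;
    dispersion is the excess of the normalised variance over the Poisson
    expectation, floored at 0 for under-dispersed features.
    """
    totals = matrix.counts.sum(axis=0).astype(float)
    if totals.sum() == 0:
        raise ValueError("all-zero count matrix: nothing to estimate")
    median_total = float(np.median(totals))
    if median_total == 0:
        median_total = float(np.mean(totals[totals > 0]))
    s = totals / median_total
    s = np.where(s > 0, s, np.nan)  # empty cells carry no information
    y = matrix.counts / s  # normalised counts, NaN for empty cells
    mu = np.nanmean(y, axis=1)
    n_used = np.sum(~np.isnan(s))
    if n_used > 1:
        var = np.nanvar(y, axis=1, ddof=1)
    else:
        var = np.zeros_like(mu)
    mean_inv_s = np.nanmean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var - mu * mean_inv_s) / mu**2
    phi = np.where(mu > 0, np.maximum(phi, 0.0), 0.0)
    pos = totals > 0
    log_tot = np.log(totals[pos])
    return CountModelParams(
        feature_mean=mu,
        feature_dispersion=phi,
        libsize_log_mean=float(np.mean(log_tot)),
        libsize_log_sd=float(np.std(log_tot, ddof=1)) if pos.sum() > 1 else 0.0,
        feature_ids=list(matrix.feature_ids),
    )


def simulate_counts(
    params: CountModelParams,
    n_cells: int,
    seed: int | np.random.Generator = 0,
    cell_prefix: str = "cell",
) -> CountMatrix:
    """Draw a synthetic count matrix from fitted or user-supplied parameters.

    Each cell gets a log-normal size factor with median 1; each entry is a
    Gamma-Poisson draw with that cell's scaled mean and the feature's
    dispersion.  Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    nf = len(params.feature_mean)
    s = np.exp(params.libsize_log_sd * rng.standard_normal(n_cells))
    mu = params.feature_mean[:, None] * s[None, :]  # (nf, n_cells)
    phi = params.feature_dispersion[:, None]
    counts = np.zeros((nf, n_cells), dtype=np.int64)
    overdisp = params.feature_dispersion > 0
    if np.any(~overdisp):
        rows = ~overdisp
        counts[rows] = rng.poisson(mu[rows])
    if np.any(overdisp):
        rows = overdisp
        shape = 1.0 / phi[rows]
        lam = rng.gamma(shape=np.broadcast_to(shape, mu[rows].shape), scale=mu[rows] * phi[rows])
        counts[rows] = rng.poisson(lam)
    ids = params.feature_ids or [f"feature_{i}" for i in range(nf)]
    barcodes = [f"{cell_prefix}_{i}" for i in range(n_cells)]
    return CountMatrix(feature_ids=list(ids), cell_barcodes=barcodes, counts=counts)
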