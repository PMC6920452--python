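"""Fixed-margin contingency-table randomization test for spatial haplotype data.

The question this module answers: are haplotypes distributed independently of
location, given that both sampling effort per location and overall haplotype
abundances are unequal?  The null model redistributes the observed counts
across the table while holding every row (haplotype) and column (location)
total fixed, sampling tables from the conditional multivariate hypergeometric
distribution with Patefield's AS159 algorithm.  Departure from the null is
measured by

* a whole-table chi-squared statistic,
  ``chi2_obs = sum_ij (Z_obs[i,j] - Zbar_ran[i,j])**2 / Zbar_ran[i,j]``,
  where ``Zbar_ran`` is the per-cell mean over the random tables;
* a per-cell difference statistic ``ts_diff = Z_obs - Zbar_ran`` whose sign
  indicates over- (+) or under- (-) representation;
* two-tailed permutation P-values
  ``P = 2 * min(N_ge, N_le) / M`` capped at 1.0, where ``N_ge`` / ``N_le``
  count random realisations at least / at most as extreme as the observation
  (both inclusive, so the raw ratio can exceed 1).

Per-cell P-values are corrected jointly with the Benjamini-Hochberg step-up
procedure at a configurable false-discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyMatrix",
    "NullEnsemble",
    "TestResult",
    "sample_random_table",
    "build_null_ensemble",
    "chi_squared_obs",
    "ts_diff",
    "whole_table_test",
    "cell_p_values",
    "fdr_calls",
    "pool_locations",
    "spatial_test",
]

# above this many stored values the ensemble falls back to two passes over a
# regenerated stream instead of materializing every random table at once
_MAX_BATCH_CELLS = 50_000_000


@dataclass(frozen=True)
class ContingencyMatrix:
    """Haplotype x location count table.

    Rows are haplotypes, columns are locations; ``counts`` holds non-negative
    integers.  Empty rows/columns make the chi-squared statistic undefined and
    are dropped with a warning at construction.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.size == 0:
            raise ValueError("count matrix must be 2-D and non-empty")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("count matrix has zero total")
        row_labels = tuple(self.row_labels) if self.row_labels else tuple(
            f"R{i+1}" for i in range(counts.shape[0]))
        col_labels = tuple(self.col_labels) if self.col_labels else tuple(
            f"C{j+1}" for j in range(counts.shape[1]))
        if len(row_labels) != counts.shape[0] or len(col_labels) != counts.shape[1]:
            raise ValueError("label lengths do not match matrix shape")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", row_labels)
        object.__setattr__(self, "col_labels", col_labels)

    def drop_empty(self) -> "ContingencyMatrix":
        """Drop all-zero rows/columns (chi-squared is undefined for them).

        Returns self unchanged if none are empty; otherwise warns with the
        dropped labels and returns the reduced matrix.
        """
        rows = self.counts.sum(axis=1) > 0
        cols = self.counts.sum(axis=0) > 0
        if rows.all() and cols.all():
            return self
        dropped = [l for l, k in zip(self.row_labels, rows) if not k]
        dropped += [l for l, k in zip(self.col_labels, cols) if not k]
        warnings.warn(f"dropping empty rows/columns: {', '.join(dropped)}",
                      stacklevel=2)
        return ContingencyMatrix(
            self.counts[rows][:, cols],
            tuple(l for l, k in zip(self.row_labels, rows) if k),
            tuple(l for l, k in zip(self.col_labels, cols) if k),
        )

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ContingencyMatrix":
        return cls(df.to_numpy(dtype=np.int64),
                   tuple(map(str, df.index)), tuple(map(str, df.columns)))

    @classmethod
    def read_csv(cls, path) -> "ContingencyMatrix":
        """Read a labelled count matrix (haplotypes x locations) from CSV."""
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass
class NullEnsemble:
    """Accumulated null distribution for one observed matrix.

    ``mean`` is the per-cell null mean Zbar_ran.  In ``monte_carlo`` mode the
    tail counts record, per cell, how many of the ``m`` random fixed-margin
    tables had a count >= / <= the observed count, and ``chi2_ran`` holds the
    whole-table statistic of each random table evaluated against ``mean``.
    In ``analytic`` mode ``mean = r_i * c_j / N`` exactly and tail quantities
    are None.
    """

    mode: str
    m: int
    mean: np.ndarray
    n_ge: np.ndarray | None = None
    n_le: np.ndarray | None = None
    chi2_ran: np.ndarray | None = None
    seed: int | None = None


def _capped_two_tailed(n_ge, n_le, m):
    return np.minimum(np.minimum(n_ge, n_le) * 2.0 / m, 1.0)


def sample_random_table(row_totals, col_totals, rng, size: int | None = None) -> np.ndarray:
    """Draw random table(s) with the given margins (Patefield AS159).

    Sampling follows the fixed-margin conditional (multivariate
    hypergeometric) distribution.  Returns one R x C table, or a
    ``size x R x C`` array when ``size`` is given.
    """
    row_totals = np.asarray(row_totals, dtype=np.int64)
    col_totals = np.asarray(col_totals, dtype=np.int64)
    if row_totals.sum() != col_totals.sum():
        raise ValueError("row and column totals must have equal sums")
    if row_totals.sum() <= 0:
        raise ValueError("table total must be positive")
    if len(row_totals) == 1 or len(col_totals) == 1:
        # single row/column forces the table; scipy's sampler misbehaves here
        forced = np.outer(row_totals, col_totals) // row_totals.sum()
        if size is None:
            return forced
        return np.broadcast_to(forced, (size, *forced.shape)).copy()
    dist = stats.random_table(row_totals, col_totals)
    out = dist.rvs(size=size, method="patefield", random_state=rng)
    return np.asarray(out, dtype=np.int64)


def _positive_mean(mc_mean: np.ndarray, matrix: ContingencyMatrix) -> np.ndarray:
    """Guard against zero Monte-Carlo means in sparse low-margin cells.

    A cell with tiny margins can receive no count in any of the M random
    tables, leaving an estimated mean of 0 and an undefined chi-squared term;
    the exact conditional expectation r_i * c_j / N (what the Monte-Carlo
    mean estimates) is substituted for those cells only.
    """
    if (mc_mean > 0).all():
        return mc_mean
    analytic = np.outer(matrix.row_totals, matrix.col_totals) / matrix.n
    return np.where(mc_mean > 0, mc_mean, analytic)


def build_null_ensemble(matrix: ContingencyMatrix, m: int = 10_000,
                        mode: str = "monte_carlo",
                        seed: int | None = None) -> NullEnsemble:
    """Build the null ensemble for ``matrix``.

    monte_carlo: draws ``m`` fixed-margin tables from one seeded stream and
    accumulates the per-cell mean, per-cell tail counts against the observed
    counts, and the whole-table chi-squared of every random table against the
    ensemble mean.  analytic: fills the mean with the closed form
    ``r_i c_j / N`` and leaves tail quantities undefined.
    """
    matrix = matrix.drop_empty()
    z = matrix.counts
    if mode == "analytic":
        mean = np.outer(matrix.row_totals, matrix.col_totals) / matrix.n
        return NullEnsemble(mode=mode, m=0, mean=mean)
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    if m < 1:
        raise ValueError("m must be >= 1 in monte_carlo mode")

    if m * z.size <= _MAX_BATCH_CELLS:
        rng = np.random.default_rng(seed)
        tables = sample_random_table(matrix.row_totals, matrix.col_totals,
                                     rng, size=m)
        if tables.ndim == 2:  # size=1 collapses
            tables = tables[None]
        mean = _positive_mean(tables.mean(axis=0), matrix)
        n_ge = (tables >= z).sum(axis=0)
        n_le = (tables <= z).sum(axis=0)
        dev = (tables - mean) ** 2 / mean
        chi2_ran = dev.sum(axis=(1, 2))
    else:
        # two-pass: regenerate the identical stream from the same seed
        mean = np.zeros(z.shape)
        n_ge = np.zeros(z.shape, dtype=np.int64)
        n_le = np.zeros(z.shape, dtype=np.int64)
        rng = np.random.default_rng(seed)
        for _ in range(m):
            t = sample_random_table(matrix.row_totals, matrix.col_totals, rng)
            mean += t
            n_ge += t >= z
            n_le += t <= z
        mean = _positive_mean(mean / m, matrix)
        chi2_ran = np.empty(m)
        rng = np.random.default_rng(seed)
        for k in range(m):
            t = sample_random_table(matrix.row_totals, matrix.col_totals, rng)
            chi2_ran[k] = ((t - mean) ** 2 / mean).sum()
    return NullEnsemble(mode=mode, m=m, mean=mean, n_ge=n_ge, n_le=n_le,
                        chi2_ran=chi2_ran, seed=seed)


def chi_squared_obs(matrix: ContingencyMatrix, ensemble: NullEnsemble) -> float:
    """Whole-table statistic: sum of (Z_obs - Zbar_ran)^2 / Zbar_ran."""
    if ensemble.mean.shape != matrix.shape:
        raise ValueError("ensemble was built for a different matrix shape")
    assert (ensemble.mean > 0).all(), "zero null mean despite margin filtering"
    return float(((matrix.counts - ensemble.mean) ** 2 / ensemble.mean).sum())


def ts_diff(matrix: ContingencyMatrix, ensemble: NullEnsemble) -> np.ndarray:
    """Per-cell difference Z_obs - Zbar_ran; + means over-represented."""
    if ensemble.mean.shape != matrix.shape:
        raise ValueError("ensemble was built for a different matrix shape")
    return matrix.counts - ensemble.mean


def whole_table_test(matrix: ContingencyMatrix, m: int = 10_000,
                     seed: int | None = None,
                     ensemble: NullEnsemble | None = None) -> tuple[float, float]:
    """Whole-table chi-squared with two-tailed permutation P-value.

    P = 2 * min(N_ge, N_le) / m over the distribution of the statistic on the
    random tables, capped at 1.0 (both tail counts are inclusive, so the raw
    ratio can exceed 1).
    """
    matrix = matrix.drop_empty()
    if ensemble is None:
        ensemble = build_null_ensemble(matrix, m=m, seed=seed)
    chi2 = chi_squared_obs(matrix, ensemble)
    n_ge = int((ensemble.chi2_ran >= chi2).sum())
    n_le = int((ensemble.chi2_ran <= chi2).sum())
    p = float(_capped_two_tailed(n_ge, n_le, ensemble.m))
    return chi2, p


def cell_p_values(matrix: ContingencyMatrix, m: int = 10_000,
                  seed: int | None = None,
                  ensemble: NullEnsemble | None = None) -> np.ndarray:
    """Two-tailed permutation P-value per cell, capped at 1.0.

    The same random-table stream serves the whole-table and the per-cell
    statistics; a cell's randomized ts_diff compares to the observed one
    exactly when the random count compares to the observed count, so the tail
    counts are taken on raw counts.
    """
    matrix = matrix.drop_empty()
    if ensemble is None:
        ensemble = build_null_ensemble(matrix, m=m, seed=seed)
    return _capped_two_tailed(ensemble.n_ge, ensemble.n_le, ensemble.m)


def fdr_calls(p_cell: np.ndarray, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up over all cells jointly; True = significant."""
    p = np.asarray(p_cell, dtype=float)
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def pool_locations(matrix: ContingencyMatrix,
                   grouping: dict[str, str]) -> ContingencyMatrix:
    """Sum columns into groups (e.g. Brazil vs non-Brazil); rows unchanged."""
    missing = [c for c in matrix.col_labels if c not in grouping]
    if missing:
        raise ValueError(f"columns without a group: {', '.join(missing)}")
    groups = list(dict.fromkeys(grouping[c] for c in matrix.col_labels))
    pooled = np.zeros((matrix.shape[0], len(groups)), dtype=np.int64)
    for j, col in enumerate(matrix.col_labels):
        pooled[:, groups.index(grouping[col])] += matrix.counts[:, j]
    return ContingencyMatrix(pooled, matrix.row_labels, tuple(groups))


@dataclass
class TestResult:
    """Full output of the spatial randomization test on one matrix."""

    matrix: ContingencyMatrix
    chi2_obs: float
    p_whole: float
    ts_diff: np.ndarray
    p_cell: np.ndarray
    significant: np.ndarray
    fdr_q: float
    m: int
    seed: int | None = None
    direction: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.direction = np.sign(self.ts_diff)

    def to_dict(self) -> dict:
        return {
            "chi2_obs": self.chi2_obs,
            "p_whole": self.p_whole,
            "m": self.m,
            "fdr_q": self.fdr_q,
            "seed": self.seed,
            "row_labels": list(self.matrix.row_labels),
            "col_labels": list(self.matrix.col_labels),
            "ts_diff": self.ts_diff.tolist(),
            "p_cell": self.p_cell.tolist(),
            "significant": self.significant.astype(bool).tolist(),
        }

    def heat_table(self) -> pd.DataFrame:
        """Four-state cell classification: over/under x significant or not."""
        state = np.where(self.ts_diff >= 0, "over", "under")
        state = np.char.add(np.where(self.significant, "sig_", "ns_"), state)
        return pd.DataFrame(state, index=list(self.matrix.row_labels),
                            columns=list(self.matrix.col_labels))


def spatial_test(matrix: ContingencyMatrix, m: int = 10_000,
                 seed: int | None = None, fdr_q: float = 0.10,
                 mode: str = "monte_carlo") -> TestResult:
    """Run the complete test: whole-table statistic, per-cell ts_diff,
    permutation P-values, and FDR significance calls.

    ``mode='analytic'`` uses closed-form null means (no P-values are then
    available for the whole table; per-cell P-values still require sampling,
    so analytic mode raises if they are requested).  For the standard
    workflow leave the default.
    """
    if mode == "analytic":
        raise ValueError("spatial_test needs monte_carlo mode; use "
                         "chi_squared_obs/ts_diff directly for analytic means")
    matrix = matrix.drop_empty()
    ensemble = build_null_ensemble(matrix, m=m, mode=mode, seed=seed)
    chi2, p_whole = whole_table_test(matrix, ensemble=ensemble)
    diffs = ts_diff(matrix, ensemble)
    p_cell = cell_p_values(matrix, ensemble=ensemble)
    sig = fdr_calls(p_cell, q=fdr_q)
    return TestResult(matrix=matrix, chi2_obs=chi2, p_whole=p_whole,
                      ts_diff=diffs, p_cell=p_cell, significant=sig,
                      fdr_q=fdr_q, m=m, seed=seed)
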