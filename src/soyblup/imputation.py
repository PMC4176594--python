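"""Missing-dosage imputation: allele-frequency (naive) and random-forest fills.

Naive imputation replaces every missing call at marker j with twice the
estimated major-allele frequency, 2*theta_j, which leaves per-marker mean
dosage (hence allele frequency) unchanged and yields a complete real-valued
matrix.  Random-forest imputation runs a missForest-style iterative scheme
chromosome-wise: start from the naive fill, visit markers in order of
ascending missingness, regress each marker on the other markers of the same
chromosome, and iterate until the change in imputed values stops decreasing.
Imputed dosages are kept continuous on [0, 2]; relationship kernels accept
real dosages directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from soyblup.marker_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ImputationReport:
    """Bookkeeping for an imputation run.

    ``fill_counts`` holds the number of entries filled per marker (equal to
    the pre-imputation missing counts).  ``iterations`` and
    ``convergence_trace`` (the missForest difference statistic per sweep,
    keyed by chromosome) are populated by the random-forest method only.
    """

    method: str
    fill_counts: np.ndarray
    iterations: dict[str, int] = field(default_factory=dict)
    convergence_trace: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_filled(self) -> int:
        return int(self.fill_counts.sum())


def impute_naive(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, ImputationReport]:
    """Fill missing dosages with 2*theta_j (the marker's mean dosage).

    Raises ``ValueError`` naming the marker if a column is entirely missing.
    Observed entries are untouched and column means are exactly preserved.
    """
    X = matrix.dosage.copy()
    miss = np.isnan(X)
    n_nonmiss = (~miss).sum(axis=0)
    if np.any(n_nonmiss == 0):
        j = int(np.argmax(n_nonmiss == 0))
        raise ValueError(
            f"marker {matrix.marker_meta['marker_id'].iloc[j]!r} has no observed calls; "
            "filter all-missing markers before imputation"
        )
    col_mean = np.nansum(X, axis=0) / n_nonmiss  # = 2 * theta_j
    fill = np.broadcast_to(col_mean, X.shape)
    X[miss] = fill[miss]
    report = ImputationReport(method="naive", fill_counts=miss.sum(axis=0))
    return GenotypeMatrix(X, matrix.marker_meta.copy(), list(matrix.line_ids)), report


def _mf_difference(new: np.ndarray, old: np.ndarray) -> float:
    """missForest convergence statistic: ||new - old||^2 / ||new||^2."""
    denom = float(np.sum(new**2))
    if denom == 0.0:
        return 0.0
    return float(np.sum((new - old) ** 2)) / denom


def impute_random_forest(
    matrix: GenotypeMatrix,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> tuple[GenotypeMatrix, ImputationReport]:
    """missForest-style iterative random-forest imputation, chromosome-wise.

    For each chromosome: initialize missing entries with the naive fill,
    order markers by ascending missingness, and repeatedly re-impute each
    marker's missing entries from a random-forest regression (square-root
    predictor subsampling) on all other markers of that chromosome, using
    the observed entries of the target marker as training responses.  Sweeps
    stop when the missForest difference statistic first increases, at which
    point the previous sweep's values are kept, or after ``max_iter`` sweeps.

    A chromosome with a single marker falls back to the naive fill with a
    warning.  Fully reproducible for a fixed ``seed``; observed entries are
    never modified.
    """
    from sklearn.ensemble import RandomForestRegressor

    miss_all = matrix.missing_mask
    filled, _ = impute_naive(matrix)
    X = filled.dosage  # working copy, already owned by `filled`
    chroms = matrix.marker_meta["chromosome"].to_numpy()
    report = ImputationReport(method="random_forest", fill_counts=miss_all.sum(axis=0))
    rng = np.random.default_rng(seed)

    for chrom in _unique_in_order(chroms):
        cols = np.flatnonzero(chroms == chrom)
        if len(cols) < 2:
            logger.warning(
                "impute_random_forest: chromosome %r has %d marker(s); using naive fill",
                chrom, len(cols),
            )
            report.iterations[str(chrom)] = 0
            continue
        miss = miss_all[:, cols]
        if not miss.any():
            report.iterations[str(chrom)] = 0
            report.convergence_trace[str(chrom)] = []
            continue

        sub = X[:, cols]
        order = np.argsort(miss.sum(axis=0), kind="stable")
        order = order[miss.sum(axis=0)[order] > 0]

        prev = sub[miss].copy()
        best = prev.copy()
        prev_diff = np.inf
        trace: list[float] = []
        n_iter = 0
        for _ in range(max_iter):
            n_iter += 1
            for local_j in order:
                obs_rows = ~miss[:, local_j]
                mis_rows = miss[:, local_j]
                predictors = np.delete(np.arange(sub.shape[1]), local_j)
                rf = RandomForestRegressor(
                    n_estimators=n_trees,
                    max_features="sqrt",
                    random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                )
                rf.fit(sub[obs_rows][:, predictors], sub[obs_rows, local_j])
                sub[mis_rows, local_j] = rf.predict(sub[mis_rows][:, predictors])
            cur = sub[miss].copy()
            diff = _mf_difference(cur, prev)
            trace.append(diff)
            if diff >= prev_diff:
                sub[miss] = best  # revert to the previous (better) sweep
                break
            best = cur
            prev = cur
            prev_diff = diff
        X[:, cols] = sub
        report.iterations[str(chrom)] = n_iter
        report.convergence_trace[str(chrom)] = trace

    np.clip(X, 0.0, 2.0, out=X)
    X[~miss_all] = matrix.dosage[~miss_all]  # guard: observed entries untouched
    return filled, report


def _unique_in_order(values: np.ndarray) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)
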