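"""Cross-validated predictive ability, accuracy conversion, grid evaluation,
and training-population-size experiments.

*Predictive ability* is the correlation between observed phenotypes and
genomic predictions on held-out lines; *prediction accuracy* approximates
the correlation with true breeding value by dividing ability by sqrt(H²).
Cross-validation uses random k-way partitions replicated many times; each
replicate yields one ability (the correlation pooled across its held-out
predictions), and the replicate means feed a percentile bootstrap CI.
The training-population-size sweep holds a fixed random validation set and
grows a nested training set one line at a time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soyblup.imputation import impute_naive, impute_random_forest
from soyblup.kernels import KernelMatrix, additive_kernel, standardize
from soyblup.marker_io import GenotypeMatrix
from soyblup.marker_qc import FilterSpec, filter_markers
from soyblup.mixed_models import GBLUP

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Replicated cross-validation summary for one marker dataset / model."""

    replicate_abilities: np.ndarray
    mean_ability: float
    ci_lower: float
    ci_upper: float
    n_reps: int
    n_dropped: int = 0
    spec_id: str = ""

    def __post_init__(self) -> None:
        a = self.replicate_abilities[np.isfinite(self.replicate_abilities)]
        if a.size and (np.abs(a) > 1 + 1e-9).any():
            raise ValueError("abilities must lie in [-1, 1]")
        if not (self.ci_lower <= self.mean_ability <= self.ci_upper):
            raise ValueError("bootstrap CI must bracket the mean")


@dataclass
class SweepResult:
    """Mean predictive ability as a function of training-population size."""

    sizes: np.ndarray
    mean_ability: np.ndarray
    n_reps: int
    n_missing: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tp_size": self.sizes, "mean_ability": self.mean_ability})


def _pooled_correlation(obs: np.ndarray, pred: np.ndarray) -> float:
    if len(obs) < 2 or np.std(obs) == 0 or np.std(pred) == 0:
        return np.nan
    return float(np.corrcoef(obs, pred)[0, 1])


def _bootstrap_ci(values: np.ndarray, n_boot: int, rng: np.random.Generator,
                  level: float = 0.95) -> tuple[float, float]:
    if values.size == 1:
        return float(values[0]), float(values[0])
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha))


def cross_validate(
    y: np.ndarray,
    kernel: KernelMatrix | list[KernelMatrix],
    k: int = 10,
    reps: int = 200,
    seed: int = 0,
    n_boot: int = 2000,
    spec_id: str = "",
) -> CVResult:
    """k-fold cross-validated predictive ability, replicated.

    Per replicate: a random k-way partition of the phenotyped lines; each
    fold is predicted from the remaining folds by a fresh G-BLUP fit; the
    replicate's ability is the correlation between observed and predicted
    values pooled over all held-out lines.  The mean over replicates and a
    95% percentile bootstrap CI over replicate abilities are reported.
    Replicates whose pooled correlation is undefined are dropped with a
    logged count.
    """
    kernels = [kernel] if isinstance(kernel, KernelMatrix) else list(kernel)
    y = np.asarray(y, float).ravel()
    n = y.size
    if n != kernels[0].n_lines:
        raise ValueError("y must align with the kernel lines")
    if n < k:
        raise ValueError(f"need at least k={k} lines, got {n}")
    rng = np.random.default_rng(seed)

    abilities = np.full(reps, np.nan)
    for rep in range(reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        obs_all, pred_all = [], []
        for fold in folds:
            train_mask = np.ones(n, bool)
            train_mask[fold] = False
            y_masked = y.copy()
            y_masked[fold] = np.nan
            res = GBLUP(y_masked, kernels).fit()
            # ability correlates the observed phenotype with the predicted
            # breeding value.  Each fold's predictions are standardized
            # before pooling: fold-specific intercepts and REML variance
            # ratios set the location/scale of a fold's predictions, and
            # pooling raw values lets those leak (anti-)correlation into the
            # replicate ability under weak signal.  Constant predictions
            # contribute zeros (the fold's pairs still pool).
            ghat = res.gvalues["total"].to_numpy()[fold]
            sd = ghat.std()
            ghat = (ghat - ghat.mean()) / sd if sd > 0 else np.zeros_like(ghat)
            obs_all.append(y[fold])
            pred_all.append(ghat)
        abilities[rep] = _pooled_correlation(np.concatenate(obs_all), np.concatenate(pred_all))

    good = abilities[np.isfinite(abilities)]
    n_dropped = reps - good.size
    if n_dropped:
        logger.warning("cross_validate: %d replicate(s) had undefined ability", n_dropped)
    if good.size == 0:
        raise ValueError("every replicate produced an undefined correlation")
    lo, hi = _bootstrap_ci(good, n_boot, rng)
    return CVResult(
        replicate_abilities=abilities,
        mean_ability=float(good.mean()),
        ci_lower=lo,
        ci_upper=hi,
        n_reps=reps,
        n_dropped=n_dropped,
        spec_id=spec_id,
    )


def prediction_accuracy(ability: float, h2: float) -> float:
    """Approximate accuracy = ability / sqrt(H²), clipped to [-1, 1]."""
    if h2 <= 0:
        raise ValueError("heritability must be positive")
    if h2 > 1:
        raise ValueError("heritability cannot exceed 1")
    acc = ability / np.sqrt(h2)
    if abs(acc) > 1:
        warnings.warn(f"accuracy {acc:.3f} outside [-1, 1]; clipping")
        acc = float(np.clip(acc, -1.0, 1.0))
    return float(acc)


def selection_superiority_threshold(r_a: float, h_x: float) -> float:
    """Maximum genomic-to-phenotypic cycle-length ratio at which genomic
    selection beats phenotypic selection per unit time.

    From the indirect-selection response inequality (Technow-style
    rearrangement): genomic selection wins when L_genomic / L_phenotypic <
    r_A / H_X, where r_A is genomic prediction accuracy and H_X the
    phenotypic selection accuracy (sqrt of entry-mean H²).
    """
    if not 0 < h_x <= 1:
        raise ValueError("H_X must be in (0, 1]")
    return r_a / h_x


def tp_size_sweep(
    y: np.ndarray,
    kernel: KernelMatrix | list[KernelMatrix],
    val_size: int = 50,
    reps: int = 1000,
    seed: int = 0,
    stride: int = 1,
    min_size: int = 2,
) -> SweepResult:
    """Predictive ability vs training-population size with a fixed validation set.

    Per replicate: sample ``val_size`` validation lines without replacement;
    shuffle the rest once so training sets grow by nested increments of one
    from ``min_size`` up to n - val_size (evaluated at every ``stride``-th
    size); ability at each size is the correlation on the fixed validation
    set.  Abilities are averaged over replicates; undefined correlations at
    tiny sizes are excluded from that size's mean with a count.
    """
    kernels = [kernel] if isinstance(kernel, KernelMatrix) else list(kernel)
    y = np.asarray(y, float).ravel()
    n = y.size
    if n <= val_size + 2:
        raise ValueError("need more than val_size + 2 lines")
    rng = np.random.default_rng(seed)
    max_size = n - val_size
    sizes = np.arange(min_size, max_size + 1, stride)

    sums = np.zeros(sizes.size)
    counts = np.zeros(sizes.size, dtype=int)
    for _ in range(reps):
        perm = rng.permutation(n)
        val = perm[:val_size]
        pool = perm[val_size:]
        for si, size in enumerate(sizes):
            train = pool[:size]
            y_masked = np.full(n, np.nan)
            y_masked[train] = y[train]
            try:
                res = GBLUP(y_masked, kernels).fit()
            except ValueError:
                continue
            pred = res.gvalues["total"].to_numpy()[val]
            r = _pooled_correlation(y[val], pred)
            if np.isfinite(r):
                sums[si] += r
                counts[si] += 1

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SweepResult(sizes=sizes, mean_ability=means, n_reps=reps,
                       n_missing=reps - counts)


def run_grid(
    matrix: GenotypeMatrix,
    y: np.ndarray,
    grid: list[FilterSpec],
    k: int = 10,
    reps: int = 200,
    seed: int = 0,
    min_markers: int = 50,
    rf_params: dict | None = None,
    external_matrices: dict[str, GenotypeMatrix] | None = None,
) -> pd.DataFrame:
    """Evaluate every filter spec: filter -> impute -> G kernel -> CV.

    Returns one row per spec with the retained marker count, mean ability
    and bootstrap CI.  Specs leaving fewer than ``min_markers`` markers, and
    ``external`` specs with no supplied pre-imputed matrix, are skipped with
    the reason recorded in the ``status`` column.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    rf_params = rf_params or {}
    rows = []
    for spec in grid:
        row = {
            "spec_id": spec.spec_id, "pmv_max": spec.pmv_max,
            "maf_min": spec.maf_min, "method": spec.imputation_method,
            "n_markers": np.nan, "mean_ability": np.nan,
            "ci_lower": np.nan, "ci_upper": np.nan, "status": "ok",
        }
        kept = filter_markers(matrix, spec)
        row["n_markers"] = kept.n_markers
        if kept.n_markers < min_markers:
            row["status"] = f"skipped: {kept.n_markers} markers < {min_markers}"
            logger.warning("run_grid: %s %s", spec.spec_id, row["status"])
            rows.append(row)
            continue
        if spec.imputation_method == "naive":
            complete, _ = impute_naive(kept)
        elif spec.imputation_method == "random_forest":
            complete, _ = impute_random_forest(kept, seed=seed, **rf_params)
        else:  # external
            ext = (external_matrices or {}).get(spec.spec_id)
            if ext is None:
                row["status"] = "skipped: no external matrix supplied"
                logger.warning("run_grid: %s %s", spec.spec_id, row["status"])
                rows.append(row)
                continue
            complete = ext
        G = additive_kernel(standardize(complete))
        cv = cross_validate(y, G, k=k, reps=reps, seed=seed, spec_id=spec.spec_id)
        row.update(mean_ability=cv.mean_ability, ci_lower=cv.ci_lower, ci_upper=cv.ci_upper)
        rows.append(row)
    return pd.DataFrame(rows)
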