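"""Per-marker QC statistics and the sequential PMV/MAF filtering grid.

GBS genotype tables carry two quality axes: the fraction of lines with a
missing call at a marker (percent missing values, PMV) and the frequency of
the rarer allele among the non-missing calls (minor-allele frequency, MAF).
Filtering is sequential — PMV first, then MAF on the survivors — with PMV
thresholds inclusive (keep PMV <= cutoff) and MAF thresholds strict (keep
MAF > cutoff).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soyblup.marker_io import GenotypeMatrix

logger = logging.getLogger(__name__)

IMPUTATION_METHODS = ("naive", "random_forest", "external")

#: Missing-value percentage levels of the full evaluation grid:
#: every integer percent from 1 to 20, then 25, 30, 40, 50, 60, 70, 80.
PMV_LEVELS: tuple[float, ...] = tuple(range(1, 21)) + (25, 30, 40, 50, 60, 70, 80)
#: MAF levels: 0.05 to 0.10 by 0.01, then 0.15 to 0.40 by 0.05.
MAF_LEVELS: tuple[float, ...] = tuple(np.round(np.arange(5, 11) / 100, 2)) + (
    0.15, 0.20, 0.25, 0.30, 0.35, 0.40,
)


@dataclass
class MarkerStats:
    """Per-marker QC statistics aligned with the source matrix's marker order.

    ``pmv`` is the missing fraction in [0, 1]; ``maf`` the minor-allele
    frequency in [0, 0.5] computed on non-missing calls only.  Markers with
    every call missing have ``pmv`` 1 and ``maf`` NaN with
    ``maf_defined`` False.
    """

    pmv: np.ndarray
    maf: np.ndarray
    n_nonmissing: np.ndarray
    maf_defined: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.maf_defined is None:
            self.maf_defined = ~np.isnan(self.maf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pmv": self.pmv, "maf": self.maf, "n_nonmissing": self.n_nonmissing}
        )


@dataclass(frozen=True)
class FilterSpec:
    """One cell of the filtering grid.

    ``pmv_max`` is a percentage in (0, 100] (markers with PMV <= pmv_max are
    kept); ``maf_min`` is a frequency in [0, 0.5) (markers with MAF > maf_min
    are kept); ``imputation_method`` names how the surviving missing calls
    are filled.
    """

    pmv_max: float
    maf_min: float
    imputation_method: str = "naive"

    def __post_init__(self) -> None:
        if not 0 < self.pmv_max <= 100:
            raise ValueError(f"pmv_max must be in (0, 100], got {self.pmv_max}")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5), got {self.maf_min}")
        if self.imputation_method not in IMPUTATION_METHODS:
            raise ValueError(
                f"imputation_method must be one of {IMPUTATION_METHODS}, "
                f"got {self.imputation_method!r}"
            )

    @property
    def spec_id(self) -> str:
        return f"pmv{self.pmv_max:g}_maf{self.maf_min:g}_{self.imputation_method}"


def marker_stats(matrix: GenotypeMatrix) -> MarkerStats:
    """Compute PMV, MAF and non-missing counts for every marker.

    MAF uses the major-allele dosage coding: with mean dosage 2*theta among
    the ``m`` non-missing calls, the major-allele frequency is theta and
    MAF = min(theta, 1 - theta).
    """
    if matrix.n_lines < 1:
        raise ValueError("matrix must contain at least one line")
    X = matrix.dosage
    miss = np.isnan(X)
    n = X.shape[0]
    n_nonmiss = (~miss).sum(axis=0)
    pmv = miss.sum(axis=0) / n

    with np.errstate(invalid="ignore"):
        theta = np.nansum(X, axis=0) / (2.0 * np.maximum(n_nonmiss, 1))
    maf = np.minimum(theta, 1.0 - theta)
    maf = np.where(n_nonmiss == 0, np.nan, maf)
    return MarkerStats(pmv=pmv, maf=maf, n_nonmissing=n_nonmiss.astype(np.int64))


def filter_markers(matrix: GenotypeMatrix, spec: FilterSpec) -> GenotypeMatrix:
    """Apply sequential PMV-then-MAF filtering; marker order is preserved.

    Keeps markers with PMV <= ``spec.pmv_max`` percent AND MAF >
    ``spec.maf_min``; MAF is evaluated on the non-missing calls of the
    PMV-surviving markers.  An empty result is returned (with a warning),
    never raised.
    """
    stats = marker_stats(matrix)
    keep_pmv = stats.pmv <= spec.pmv_max / 100.0 + 1e-12
    survivors = matrix.subset_markers(np.flatnonzero(keep_pmv))

    stats2 = marker_stats(survivors) if survivors.n_markers else None
    if stats2 is not None:
        with np.errstate(invalid="ignore"):
            # strict threshold, robust to float noise at exact equality
            keep_maf = stats2.maf > spec.maf_min + 1e-9
        keep_maf &= stats2.maf_defined
        out = survivors.subset_markers(np.flatnonzero(keep_maf))
    else:
        out = survivors
    if out.n_markers == 0:
        logger.warning(
            "filter_markers: no markers survive PMV<=%g%% and MAF>%g",
            spec.pmv_max, spec.maf_min,
        )
    return out


def build_filter_grid(
    pmv_levels: tuple[float, ...] = PMV_LEVELS,
    maf_levels: tuple[float, ...] = MAF_LEVELS,
    methods: tuple[str, ...] = IMPUTATION_METHODS,
) -> list[FilterSpec]:
    """Full factorial grid of filter specs (27 PMV x 12 MAF x 3 methods = 972)."""
    return [
        FilterSpec(pmv_max=p, maf_min=m, imputation_method=meth)
        for p, m, meth in itertools.product(pmv_levels, maf_levels, methods)
    ]


def grid_manifest(matrix: GenotypeMatrix, grid: list[FilterSpec]) -> pd.DataFrame:
    """Marker retention counts per grid cell (the filtering-surface table)."""
    rows = []
    for spec in grid:
        kept = filter_markers(matrix, spec)
        rows.append(
            {
                "spec_id": spec.spec_id,
                "pmv_max": spec.pmv_max,
                "maf_min": spec.maf_min,
                "method": spec.imputation_method,
                "n_markers_retained": kept.n_markers,
            }
        )
    return pd.DataFrame(rows)
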