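"""Genotype I/O and numeric dosage coding.

GBS pipelines emit base calls in HapMap-style tab-separated tables: eleven
standard leading columns (``rs#``, ``alleles``, ``chrom``, ``pos``, ``strand``,
``assembly#``, ``center``, ``protLSID``, ``assayLSID``, ``panelLSID``,
``QCcode``) followed by one column per line, one row per marker, with
single-character IUPAC genotype codes and ``N`` for missing.  Downstream
analysis works on numeric dosages x in {0, 1, 2}, the number of copies of the
MAJOR allele, with missing entries kept as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_CALL = "N"
#: IUPAC ambiguity codes for heterozygous single-character genotype calls.
IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
VALID_BASES = frozenset("ACGT")

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class HapmapFormatError(ValueError):
    """Raised when a HapMap-style file is structurally malformed."""


class GenotypeDataError(ValueError):
    """Raised for data inconsistencies (e.g. more than two alleles at a marker)."""


@dataclass
class GenotypeCalls:
    """Raw single-character genotype calls for a panel of lines.

    Attributes
    ----------
    line_ids : list of str
        Ordered line identifiers (columns of the source file).
    marker_ids, chromosomes : list of str
        Per-marker identifiers and chromosome labels.
    positions : ndarray of int
        1-based physical positions (bp).
    calls : ndarray of shape (n_markers, n_lines), dtype ``<U1``
        IUPAC base or heterozygote code; ``N`` marks a missing call.
    """

    line_ids: list[str]
    marker_ids: list[str]
    chromosomes: list[str]
    positions: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype="U1")
        n_markers, n_lines = self.calls.shape
        if n_lines != len(self.line_ids):
            raise ValueError("calls must have one column per line")
        if not (len(self.marker_ids) == len(self.chromosomes) == len(self.positions) == n_markers):
            raise ValueError("per-marker metadata must match the number of call rows")
        if np.any(self.positions < 0):
            raise ValueError("positions must be non-negative")
        if any(not c for c in self.chromosomes):
            raise ValueError("chromosome labels must be non-empty")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class GenotypeMatrix:
    """Lines x markers major-allele dosage matrix with per-marker metadata.

    ``dosage[i, j]`` counts copies of the major allele of marker ``j`` carried
    by line ``i`` (0, 1 or 2; imputed matrices may hold real values in
    [0, 2]).  Missing entries are NaN.  ``marker_meta`` is a DataFrame with
    columns ``marker_id``, ``chromosome``, ``position``, ``major_allele``,
    ``minor_allele`` aligned with the dosage columns.
    """

    dosage: np.ndarray
    marker_meta: pd.DataFrame = field(repr=False)
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (lines x markers)")
        if self.dosage.shape[0] != len(self.line_ids):
            raise ValueError("dosage must have one row per line id")
        if len(self.marker_meta) != self.dosage.shape[1]:
            raise ValueError("marker_meta must have one row per dosage column")
        ids = self.marker_meta["marker_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise GenotypeDataError(f"duplicate marker ids: {dups[:5]}")
        self.marker_meta = self.marker_meta.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the marker columns in ``index`` (order kept)."""
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            marker_meta=self.marker_meta.iloc[np.asarray(index)].reset_index(drop=True),
            line_ids=list(self.line_ids),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.copy(), self.marker_meta.copy(), list(self.line_ids))


def read_hapmap(path) -> GenotypeCalls:
    """Read a HapMap-style TSV of base calls.

    Unknown call symbols (anything outside A/C/G/T, the six IUPAC
    heterozygote codes, and ``N``) are mapped to missing; the count is logged.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise HapmapFormatError(f"{path}: empty file")
        cols = header.split("\t")
        if len(cols) < len(HAPMAP_COLUMNS) + 1:
            raise HapmapFormatError(
                f"{path}: header has {len(cols)} columns; expected the "
                f"{len(HAPMAP_COLUMNS)} standard HapMap columns plus at least one line"
            )
        if cols[0] not in ("rs#", "rs"):
            raise HapmapFormatError(f"{path}: first header column is {cols[0]!r}, expected 'rs#'")
        line_ids = cols[len(HAPMAP_COLUMNS):]
        n_cols = len(cols)

        marker_ids: list[str] = []
        chroms: list[str] = []
        positions: list[int] = []
        rows: list[list[str]] = []
        n_unknown = 0
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != n_cols:
                raise HapmapFormatError(
                    f"{path}:{lineno}: row has {len(fields)} fields, header has {n_cols}"
                )
            marker_ids.append(fields[0])
            chroms.append(fields[2])
            try:
                positions.append(int(fields[3]))
            except ValueError as exc:
                raise HapmapFormatError(f"{path}:{lineno}: non-integer position {fields[3]!r}") from exc
            calls = []
            for c in fields[len(HAPMAP_COLUMNS):]:
                c = c.upper()
                if c in VALID_BASES or c in IUPAC_HET or c == MISSING_CALL:
                    calls.append(c)
                else:
                    n_unknown += 1
                    calls.append(MISSING_CALL)
            rows.append(calls)

    if n_unknown:
        logger.warning("read_hapmap: mapped %d unknown call symbols to missing", n_unknown)
    calls_arr = np.array(rows, dtype="U1") if rows else np.empty((0, len(line_ids)), dtype="U1")
    return GenotypeCalls(
        line_ids=line_ids,
        marker_ids=marker_ids,
        chromosomes=chroms,
        positions=np.array(positions, dtype=np.int64),
        calls=calls_arr,
    )


def _allele_counts(column: np.ndarray) -> dict[str, int]:
    """Allele copy counts at one marker, expanding heterozygote codes."""
    counts: dict[str, int] = {}
    for c in column:
        if c == MISSING_CALL or c == "":
            continue
        if c in VALID_BASES:
            counts[c] = counts.get(c, 0) + 2
        elif c in IUPAC_HET:
            for a in IUPAC_HET[c]:
                counts[a] = counts.get(a, 0) + 1
        else:  # pragma: no cover - calls are sanitized on read
            raise GenotypeDataError(f"unrecognized call symbol {c!r}")
    return counts


def encode_dosage(calls: GenotypeCalls) -> GenotypeMatrix:
    """Convert base calls to major-allele dosages x in {0, 1, 2}.

    The major allele at each marker is the more frequent allele among
    non-missing calls (heterozygotes contribute one copy of each allele);
    frequency ties are broken toward the lexicographically smaller base so
    the coding is deterministic.
    """
    n_markers, n_lines = calls.calls.shape
    dosage = np.full((n_lines, n_markers), np.nan)
    major = np.empty(n_markers, dtype="U1")
    minor = np.empty(n_markers, dtype="U1")

    for j in range(n_markers):
        col = calls.calls[j]
        counts = _allele_counts(col)
        if not counts:
            raise GenotypeDataError(
                f"marker {calls.marker_ids[j]!r}: no non-missing calls"
            )
        if len(counts) > 2:
            raise GenotypeDataError(
                f"marker {calls.marker_ids[j]!r}: more than two alleles {sorted(counts)}"
            )
        # sort by (-count, base): ties at 0.5 go to the smaller base
        alleles = sorted(counts, key=lambda a: (-counts[a], a))
        maj = alleles[0]
        mnr = alleles[1] if len(alleles) > 1 else ""
        major[j] = maj
        minor[j] = mnr
        for i, c in enumerate(col):
            if c == MISSING_CALL or c == "":
                continue
            if c in VALID_BASES:
                dosage[i, j] = 2.0 if c == maj else 0.0
            else:
                a, b = IUPAC_HET[c]
                dosage[i, j] = float((a == maj) + (b == maj))

    meta = pd.DataFrame(
        {
            "marker_id": calls.marker_ids,
            "chromosome": calls.chromosomes,
            "position": calls.positions,
            "major_allele": major,
            "minor_allele": minor,
        }
    )
    return GenotypeMatrix(dosage=dosage, marker_meta=meta, line_ids=list(calls.line_ids))


_NA = "NA"


def _format_dosage(v: float) -> str:
    if np.isnan(v):
        return _NA
    if v == int(v):
        return str(int(v))
    return format(v, ".10g")


def write_matrix(matrix: GenotypeMatrix, path) -> None:
    """Write a dosage matrix as TSV (lines x markers) plus a metadata sidecar.

    The main file has a header row of marker ids, one row per line with the
    line id in the first column, and ``NA`` for missing.  Marker metadata
    goes to ``<path>.meta.tsv``.  Output is deterministic: writing the same
    matrix twice yields byte-identical files.
    """
    path = str(path)
    ids = matrix.marker_meta["marker_id"].tolist()
    with open(path, "w") as fh:
        fh.write("\t".join(["line_id"] + ids) + "\n")
        for i, lid in enumerate(matrix.line_ids):
            row = "\t".join(_format_dosage(v) for v in matrix.dosage[i])
            fh.write(lid + ("\t" + row if ids else "") + "\n")
    matrix.marker_meta.to_csv(path + ".meta.tsv", sep="\t", index=False)


def read_matrix(path) -> GenotypeMatrix:
    """Read a dosage TSV written by :func:`write_matrix`.

    If the ``<path>.meta.tsv`` sidecar is absent (e.g. an externally imputed
    matrix), metadata defaults to chromosome ``"1"`` and positions 1..p.
    """
    import os

    path = str(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    dosage = df.to_numpy(dtype=float) if df.shape[1] else np.empty(df.shape, dtype=float)
    line_ids = [str(i) for i in df.index]
    marker_ids = [str(c) for c in df.columns]

    meta_path = path + ".meta.tsv"
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", dtype={"chromosome": str},
                           keep_default_na=False, na_values=[])
        meta["position"] = meta["position"].astype(np.int64)
    else:
        meta = pd.DataFrame(
            {
                "marker_id": marker_ids,
                "chromosome": ["1"] * len(marker_ids),
                "position": np.arange(1, len(marker_ids) + 1, dtype=np.int64),
                "major_allele": [""] * len(marker_ids),
                "minor_allele": [""] * len(marker_ids),
            }
        )
    return GenotypeMatrix(dosage=dosage, marker_meta=meta, line_ids=line_ids)


_HET_CODE = {pair: code for code, pair in IUPAC_HET.items()}


def matrix_to_calls(matrix: GenotypeMatrix) -> GenotypeCalls:
    """Convert integer dosages back to IUPAC base calls.

    Inverse of :func:`encode_dosage` for matrices with {0, 1, 2, NaN}
    entries; requires allele labels in the metadata (defaults A/C when
    absent).  Dosage 1 becomes the heterozygote code for the allele pair.
    """
    X = matrix.dosage
    vals = X[~np.isnan(X)]
    if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
        raise ValueError("matrix_to_calls requires integer dosages in {0, 1, 2}")
    meta = matrix.marker_meta
    n_lines, n_markers = X.shape
    calls = np.full((n_markers, n_lines), MISSING_CALL, dtype="U1")
    for j in range(n_markers):
        maj = meta["major_allele"].iloc[j] or "A"
        mnr = meta["minor_allele"].iloc[j] or ("C" if maj != "C" else "A")
        het = _HET_CODE[tuple(sorted((maj, mnr)))]
        col = X[:, j]
        calls[j, col == 2.0] = maj
        calls[j, col == 0.0] = mnr
        calls[j, col == 1.0] = het
    return GenotypeCalls(
        line_ids=list(matrix.line_ids),
        marker_ids=meta["marker_id"].tolist(),
        chromosomes=meta["chromosome"].astype(str).tolist(),
        positions=meta["position"].to_numpy(),
        calls=calls,
    )


def write_hapmap(calls: GenotypeCalls, path) -> None:
    """Write calls back out in the HapMap dialect (fixture/round-trip helper)."""
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + list(calls.line_ids)) + "\n")
        for j in range(calls.n_markers):
            fields = [
                calls.marker_ids[j], "NA", calls.chromosomes[j], str(int(calls.positions[j])),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            fields.extend(calls.calls[j])
            fh.write("\t".join(fields) + "\n")
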