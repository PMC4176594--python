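"""Genomic relationship kernels: additive G and additive-by-additive epistasis.

Dosages are centered and standardized VanRaden-style,
``w_ij = (x_ij - 2 theta_j) / sqrt(2 theta_j (1 - theta_j))``, where theta_j
is the major-allele frequency.  The additive realized relationship matrix is
``G = W W' / p``.  Additive-by-additive epistatic covariance is modeled two
ways: the Cockerham–Kempthorne Hadamard square ``G o G``, and the
pairwise-product construction of Xu, ``Kaa = Z Z' / m`` with one column of Z
per marker pair j < k equal to ``w_j * w_k`` elementwise and
``m = p (p - 1) / 2`` pairs.  Kaa is evaluated through the closed-form
identity ``Z Z' = ((W W') o (W W') - (W o W)(W o W)') / 2`` so it never
materializes the p(p-1)/2 pair columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soyblup.marker_io import GenotypeMatrix

KERNEL_KINDS = ("G", "GoG", "Kaa")


@dataclass
class StandardizedMarkers:
    """Centered, standardized marker matrix W with its frequency vector."""

    W: np.ndarray
    theta: np.ndarray
    line_ids: list[str] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return self.W.shape[0]

    @property
    def n_markers(self) -> int:
        return self.W.shape[1]


@dataclass
class KernelMatrix:
    """Symmetric line x line relationship matrix with provenance.

    ``kind`` is one of ``G`` (additive), ``GoG`` (Hadamard epistatic) or
    ``Kaa`` (pairwise-product epistatic).  All kernels are positive
    semidefinite up to numerical tolerance (minimum eigenvalue >= -1e-8
    relative to the largest).
    """

    K: np.ndarray
    kind: str
    line_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if self.K.shape[0] != len(self.line_ids):
            raise ValueError("line_ids must match K's dimension")
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kind must be one of {KERNEL_KINDS}")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        self.K = 0.5 * (self.K + self.K.T)

    @property
    def n_lines(self) -> int:
        return self.K.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.K)[0])

    def subset(self, index: np.ndarray) -> "KernelMatrix":
        index = np.asarray(index)
        return KernelMatrix(
            K=self.K[np.ix_(index, index)],
            kind=self.kind,
            line_ids=[self.line_ids[i] for i in index],
            provenance=dict(self.provenance),
        )

    def save(self, path) -> None:
        """Square TSV with a line-id header plus a JSON sidecar of metadata."""
        path = str(path)
        df = pd.DataFrame(self.K, index=self.line_ids, columns=self.line_ids)
        df.to_csv(path, sep="\t", float_format="%.12g", index_label="line_id")
        with open(path + ".json", "w") as fh:
            json.dump({"kind": self.kind, **self.provenance}, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "KernelMatrix":
        import os

        path = str(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = {}
        if os.path.exists(path + ".json"):
            with open(path + ".json") as fh:
                meta = json.load(fh)
        kind = meta.pop("kind", "G")
        return cls(K=df.to_numpy(float), kind=kind,
                   line_ids=[str(i) for i in df.index], provenance=meta)


def _matrix_hash(X: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()[:16]


def standardize(matrix: GenotypeMatrix | np.ndarray, theta: np.ndarray | None = None) -> StandardizedMarkers:
    """Center and scale a complete dosage matrix.

    theta_j defaults to the column mean divided by 2 (the major-allele
    frequency estimated from the same matrix), in which case W's columns have
    exactly zero mean.  Supplying a reference ``theta`` (e.g. training-set
    frequencies when standardizing selection candidates) overrides this.
    Monomorphic markers (theta of 0 or 1) are rejected: apply MAF filtering
    first.
    """
    if isinstance(matrix, GenotypeMatrix):
        X = matrix.dosage
        line_ids = list(matrix.line_ids)
    else:
        X = np.asarray(matrix, dtype=float)
        line_ids = [str(i) for i in range(X.shape[0])]
    if np.isnan(X).any():
        raise ValueError("standardize requires a complete matrix; impute first")
    if theta is None:
        theta = X.mean(axis=0) / 2.0
    theta = np.asarray(theta, dtype=float)
    bad = (theta <= 0.0) | (theta >= 1.0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} monomorphic marker(s) (theta in {{0,1}}); "
            "filter by MAF before standardizing"
        )
    W = (X - 2.0 * theta) / np.sqrt(2.0 * theta * (1.0 - theta))
    return StandardizedMarkers(W=W, theta=theta, line_ids=line_ids)


def additive_kernel(std: StandardizedMarkers) -> KernelMatrix:
    """Additive realized relationship matrix G = W W' / p."""
    p = std.n_markers
    if p < 1:
        raise ValueError("need at least one marker")
    G = std.W @ std.W.T / p
    return KernelMatrix(
        K=G, kind="G", line_ids=list(std.line_ids),
        provenance={"p": p, "source_hash": _matrix_hash(std.W)},
    )


def hadamard_epistasis(G: KernelMatrix) -> KernelMatrix:
    """Cockerham–Kempthorne additive-by-additive kernel G o G (elementwise square).

    PSD by the Schur product theorem.
    """
    if G.kind != "G":
        raise ValueError(f"hadamard_epistasis expects an additive kernel, got kind={G.kind!r}")
    return KernelMatrix(
        K=G.K * G.K, kind="GoG", line_ids=list(G.line_ids), provenance=dict(G.provenance),
    )


def xu_epistasis(std: StandardizedMarkers) -> KernelMatrix:
    """Pairwise-product additive-by-additive kernel Kaa = Z Z' / m.

    Z has one column per marker pair j < k, the elementwise product
    w_j * w_k; m = p(p-1)/2.  Uses the identity
    Z Z' = ((W W') o (W W') - (W o W)(W o W)') / 2.
    """
    p = std.n_markers
    if p < 2:
        raise ValueError("xu_epistasis needs at least two markers")
    W = std.W
    A = W @ W.T
    W2 = W * W
    ZZt = 0.5 * (A * A - W2 @ W2.T)
    m = p * (p - 1) // 2
    return KernelMatrix(
        K=ZZt / m, kind="Kaa", line_ids=list(std.line_ids),
        provenance={"p": p, "n_pairs": m, "source_hash": _matrix_hash(W)},
    )
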