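"""Dissimilarity between sequence–ensemble relationships.

Two ensembles A and B, reduced to ensemble entropy matrices S_ens,A and
S_ens,B on *identical* bins, are compared through the difference matrix
Δ_AB = S_ens,A − S_ens,B and the scalar

    D_AB = sqrt( Σ_{i=1..3} Σ_{j=i..3} (Δ_ij)² )

i.e. the root of the sum of squared **upper-triangle** elements of Δ_AB,
diagonal included — six terms in total, not the nine-term full-matrix
Frobenius norm.  Because Δ is symmetric the two differ: for the flat-limit
matrix (diagonal ln 4, off-diagonal ln 16, n = 4) against the zero matrix
the upper-triangle sum gives D = 5.369 while the full-matrix norm would
give ≈ 7.20.  The printed theoretical maximum pins the convention.

D is a metric (it is the Euclidean norm of the 6-vector of independent
matrix entries), so identical SERs give D → 0 and the triangle inequality
holds across any set of matrices that share one binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import EnsembleEntropyMatrix
from .errors import ComparabilityError, ValidationError

__all__ = [
    "DifferenceMatrix",
    "DissimilarityMatrix",
    "difference_matrix",
    "dissimilarity",
    "pairwise_dissimilarity",
    "theoretical_bounds",
    "normalize_dissimilarity",
]

_TRIU = np.triu_indices(3)


def _check_comparable(a: EnsembleEntropyMatrix, b: EnsembleEntropyMatrix) -> None:
    if a.spec.fingerprint != b.spec.fingerprint:
        raise ComparabilityError(
            f"entropy matrices were built with different binning "
            f"({a.sequence_id or 'A'}: {a.spec.fingerprint}, "
            f"{b.sequence_id or 'B'}: {b.spec.fingerprint}); rebuild with "
            "shared (pooled) bins before comparing"
        )


@dataclass(frozen=True)
class DifferenceMatrix:
    """Elementwise difference Δ_AB = S_ens,A − S_ens,B (nats)."""

    matrix: np.ndarray
    id_a: str
    id_b: str
    fingerprint: str


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric m×m matrix of pairwise D values over a sequence set."""

    ids: tuple[str, ...]
    values: np.ndarray
    fingerprint: str = ""
    n_bins: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = len(self.ids)
        if v.shape != (m, m):
            raise ValidationError(f"values must be {m}x{m}, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValidationError("dissimilarity matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValidationError("dissimilarities must be nonnegative")
        if len(set(self.ids)) != m:
            raise ValidationError("duplicate sequence ids")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.fingerprint:
                fh.write(f"# fingerprint\t{self.fingerprint}\n")
            if self.n_bins is not None:
                fh.write(f"# n\t{self.n_bins}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DissimilarityMatrix":
        fingerprint, n_bins = "", None
        lines = Path(path).read_text().splitlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "fingerprint":
                    fingerprint = parts[1]
                elif parts[0] == "n":
                    n_bins = int(parts[1])
            else:
                body.append(line)
        import io as _io

        df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", index_col=0)
        return cls(
            ids=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
            fingerprint=fingerprint,
            n_bins=n_bins,
        )

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP-style square distance matrix, for tree tools."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name.replace(' ', '_'):<12s} {row}\n")


def difference_matrix(
    a: EnsembleEntropyMatrix, b: EnsembleEntropyMatrix
) -> DifferenceMatrix:
    """Δ_AB = S_ens,A − S_ens,B; refuses matrices with mismatched binning."""
    _check_comparable(a, b)
    return DifferenceMatrix(
        matrix=a.matrix - b.matrix,
        id_a=a.sequence_id,
        id_b=b.sequence_id,
        fingerprint=a.spec.fingerprint,
    )


def dissimilarity(a: EnsembleEntropyMatrix, b: EnsembleEntropyMatrix) -> float:
    """Upper-triangle (j ≥ i) root-sum-of-squares of Δ_AB; D_AA = 0."""
    delta = difference_matrix(a, b).matrix
    return float(np.sqrt(np.sum(delta[_TRIU] ** 2)))


def pairwise_dissimilarity(
    matrices: Sequence[EnsembleEntropyMatrix],
) -> DissimilarityMatrix:
    """All pairwise D values over a set of matrices sharing one binning."""
    if len(matrices) < 2:
        raise ValidationError("need at least 2 entropy matrices")
    ids = [m.sequence_id for m in matrices]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate sequence ids: {sorted(ids)}")
    for other in matrices[1:]:
        _check_comparable(matrices[0], other)
    m = len(matrices)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = dissimilarity(matrices[i], matrices[j])
    return DissimilarityMatrix(
        ids=tuple(ids),
        values=values,
        fingerprint=matrices[0].spec.fingerprint,
        n_bins=matrices[0].spec.n,
    )


def theoretical_bounds(n: int) -> tuple[float, float]:
    """(0, max D) for n bins per axis.

    The maximum is attained between the flat-limit matrix (diagonal ln n,
    off-diagonal 2 ln n) and the zero matrix:
    max D = sqrt(3 (ln n)² + 3 (2 ln n)²).  For n = 4 this is 5.369.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    ln_n = np.log(n)
    return 0.0, float(np.sqrt(3 * ln_n**2 + 3 * (2 * ln_n) ** 2))


def normalize_dissimilarity(d: DissimilarityMatrix) -> DissimilarityMatrix:
    """Divide every entry by the matrix maximum; the maximum becomes 1."""
    peak = float(d.values.max())
    if peak <= 0:
        raise ValidationError("cannot normalize an all-zero dissimilarity matrix")
    return DissimilarityMatrix(
        ids=d.ids,
        values=d.values / peak,
        fingerprint=d.fingerprint,
        n_bins=d.n_bins,
    )
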