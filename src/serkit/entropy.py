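"""Binned marginal distributions and the ensemble entropy matrix.

A conformational ensemble is summarized by the three-parameter distribution
p(Rg, δ, Re).  Its one-parameter marginals p(X) and two-parameter marginals
p(X, Y) are histogrammed on an n-bin (resp. n×n) grid of equal-width bins,
and each marginal is condensed to a plug-in Shannon entropy in nats:

    s(X)   = −Σᵢ p(Xᵢ) ln p(Xᵢ)
    s(X,Y) = −Σᵢ Σⱼ p(Xᵢ,Yⱼ) ln p(Xᵢ,Yⱼ)

with the convention 0·ln 0 = 0.  The six entropies are arranged in the
symmetric 3×3 **ensemble entropy matrix** S_ens (rows/columns ordered
Rg, δ, Re; one-parameter entropies on the diagonal, two-parameter entropies
off it).  For a flat (maximally heterogeneous) ensemble with n = 4 the
diagonal saturates at ln 4 ≈ 1.386 and the off-diagonal at ln 16 ≈ 2.773.

Binning policy
--------------
Bins are half-open [eᵢ, eᵢ₊₁) with the final bin closed (numpy histogram
convention).  Ranges may be given explicitly or as ``"pooled"``, in which
case they are computed over *all* series being compared so that every
matrix in a comparison shares one set of edges — per-sequence edges would
conflate range shifts with shape changes.  δ is bounded in [0, 1] by
theory and defaults to that range.  Values outside a range are clipped
into the edge bins (with a logged warning) so probabilities always sum
to 1.  Every resolved bin specification carries a fingerprint (hash of n
and the edges) that downstream comparison operations enforce.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import entropy as _shannon

from .errors import ValidationError
from .trajectory_io import PROPERTY_COLUMNS, PropertySeries

logger = logging.getLogger(__name__)

PARAMETERS = PROPERTY_COLUMNS  # ("Rg", "delta", "Re")
PARAMETER_PAIRS = (("Rg", "delta"), ("Rg", "Re"), ("delta", "Re"))

#: relative widening applied to pooled ranges
_RANGE_PAD = 1e-9


@dataclass(frozen=True)
class BinSpec:
    """Binning specification for the three descriptor axes.

    ``ranges`` maps each parameter to an explicit ``(low, high)`` tuple or
    the directive ``"pooled"`` (resolve from data).  After
    :func:`make_bins` the spec is *resolved*: ``edges`` holds n+1 ascending
    edges per parameter and ``fingerprint`` identifies the binning.
    """

    n: int = 4
    ranges: Mapping[str, tuple[float, float] | str] = field(
        default_factory=lambda: {"Rg": "pooled", "delta": (0.0, 1.0), "Re": "pooled"}
    )
    edges: Mapping[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("BinSpec.n must be >= 2")
        for param in PARAMETERS:
            if param not in self.ranges:
                raise ValidationError(f"BinSpec.ranges missing parameter {param!r}")
            rng = self.ranges[param]
            if rng != "pooled":
                low, high = rng
                if not low < high:
                    raise ValidationError(f"{param}: range low must be < high, got {rng}")

    @property
    def resolved(self) -> bool:
        return self.edges is not None

    def edges_for(self, parameter: str) -> np.ndarray:
        if self.edges is None:
            raise ValidationError("BinSpec is not resolved; call make_bins first")
        return np.asarray(self.edges[parameter], dtype=float)

    @property
    def fingerprint(self) -> str:
        """Hash of n plus the resolved edges; pins comparability."""
        if self.edges is None:
            raise ValidationError("BinSpec is not resolved; call make_bins first")
        payload = json.dumps(
            {"n": self.n, "edges": {p: list(self.edges[p]) for p in PARAMETERS}},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_bins(
    series: PropertySeries | Iterable[PropertySeries], spec: BinSpec | None = None
) -> BinSpec:
    """Resolve a :class:`BinSpec` against one series or a pooled collection.

    ``"pooled"`` ranges become [min, max] over all series passed, widened by
    a relative 1e-9 so the maximum falls inside the last bin.
    """
    if spec is None:
        spec = BinSpec()
    collection = [series] if isinstance(series, PropertySeries) else list(series)
    edges: dict[str, tuple[float, ...]] = {}
    for param in PARAMETERS:
        rng = spec.ranges[param]
        if rng == "pooled":
            if not collection:
                raise ValidationError("pooled ranges need at least one series")
            values = np.concatenate([s.values(param) for s in collection])
            low, high = float(values.min()), float(values.max())
            if high <= low:
                raise ValidationError(
                    f"{param}: zero-width data range [{low}, {high}]; "
                    "supply an explicit range"
                )
            pad = _RANGE_PAD * (high - low)
            low, high = low - pad, high + pad
        else:
            low, high = float(rng[0]), float(rng[1])
        edges[param] = tuple(np.linspace(low, high, spec.n + 1))
    return BinSpec(n=spec.n, ranges=dict(spec.ranges), edges=edges)


@dataclass(frozen=True)
class Distribution1D:
    """One-parameter binned marginal distribution."""

    parameter: str
    edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("probabilities must be nonnegative and sum to 1")


@dataclass(frozen=True)
class Distribution2D:
    """Two-parameter binned marginal distribution on an n×n grid."""

    parameters: tuple[str, str]
    edges_x: np.ndarray
    edges_y: np.ndarray
    probabilities: np.ndarray  # shape (n, n), rows index X bins

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("probabilities must be nonnegative and sum to 1")


def _clip_to_range(values: np.ndarray, edges: np.ndarray, parameter: str) -> np.ndarray:
    low, high = edges[0], edges[-1]
    outside = np.count_nonzero((values < low) | (values > high))
    if outside:
        logger.warning(
            "%s: %d value(s) outside [%g, %g] clipped into edge bins",
            parameter, outside, low, high,
        )
    return np.clip(values, low, high)


def marginal_1d(series: PropertySeries, parameter: str, spec: BinSpec) -> Distribution1D:
    """Histogram one descriptor into the spec's bins; counts / total rows."""
    edges = spec.edges_for(parameter)
    values = _clip_to_range(series.values(parameter), edges, parameter)
    counts, _ = np.histogram(values, bins=edges)
    return Distribution1D(parameter, edges, counts / len(series))


def marginal_2d(
    series: PropertySeries, pair: Sequence[str], spec: BinSpec
) -> Distribution2D:
    """Joint histogram of a descriptor pair on the spec's n×n grid."""
    px, py = pair
    ex, ey = spec.edges_for(px), spec.edges_for(py)
    x = _clip_to_range(series.values(px), ex, px)
    y = _clip_to_range(series.values(py), ey, py)
    counts, _, _ = np.histogram2d(x, y, bins=[ex, ey])
    return Distribution2D((px, py), ex, ey, counts / len(series))


def entropy_1d(dist: Distribution1D) -> float:
    """Plug-in Shannon entropy −Σ p ln p in nats; lies in [0, ln n]."""
    return float(_shannon(dist.probabilities))


def entropy_2d(dist: Distribution2D) -> float:
    """Plug-in Shannon entropy of a 2-D grid in nats; lies in [0, 2 ln n]."""
    return float(_shannon(dist.probabilities.ravel()))


@dataclass(frozen=True)
class EnsembleEntropyMatrix:
    """Symmetric 3×3 matrix of marginal entropies (nats), order (Rg, δ, Re).

    Diagonal entries are the one-parameter entropies s(Rg), s(δ), s(Re);
    off-diagonal entries the two-parameter entropies s(X, Y).  The matrix
    records the resolved :class:`BinSpec` it was built with; matrices are
    comparable only when their binning fingerprints agree.
    """

    matrix: np.ndarray
    spec: BinSpec
    sequence_id: str = ""
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError("ensemble entropy matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("ensemble entropy matrix must be symmetric")
        object.__setattr__(self, "matrix", m)
        if not self.spec.resolved:
            raise ValidationError("EnsembleEntropyMatrix requires a resolved BinSpec")

    @property
    def parameters(self) -> tuple[str, ...]:
        return PARAMETERS

    def to_dict(self) -> dict:
        return {
            "sequence_id": self.sequence_id,
            "parameters": list(PARAMETERS),
            "n": self.spec.n,
            "edges": {p: list(self.spec.edges_for(p)) for p in PARAMETERS},
            "fingerprint": self.spec.fingerprint,
            "matrix": self.matrix.tolist(),
            "metadata": dict(self.metadata),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sequence_id\t{self.sequence_id}\n")
            fh.write(f"# n\t{self.spec.n}\n")
            for p in PARAMETERS:
                edges = "\t".join(f"{e:.10g}" for e in self.spec.edges_for(p))
                fh.write(f"# edges:{p}\t{edges}\n")
            fh.write(f"# fingerprint\t{self.spec.fingerprint}\n")
            fh.write("\t" + "\t".join(PARAMETERS) + "\n")
            for i, p in enumerate(PARAMETERS):
                row = "\t".join(f"{v:.10g}" for v in self.matrix[i])
                fh.write(f"{p}\t{row}\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleEntropyMatrix":
        payload = json.loads(Path(path).read_text())
        spec = BinSpec(
            n=int(payload["n"]),
            ranges={p: (payload["edges"][p][0], payload["edges"][p][-1]) for p in PARAMETERS},
            edges={p: tuple(payload["edges"][p]) for p in PARAMETERS},
        )
        return cls(
            matrix=np.asarray(payload["matrix"], dtype=float),
            spec=spec,
            sequence_id=payload.get("sequence_id", ""),
            metadata=payload.get("metadata", {}),
        )


def ensemble_entropy_matrix(series: PropertySeries, spec: BinSpec) -> EnsembleEntropyMatrix:
    """Build S_ens for one series under a resolved bin specification.

    The same edges are used for the 1-D and 2-D marginals of each
    parameter, which guarantees the joint-entropy inequalities
    max(s(X), s(Y)) ≤ s(X, Y) ≤ s(X) + s(Y).
    """
    if not spec.resolved:
        spec = make_bins(series, spec)
    m = np.zeros((3, 3))
    for i, p in enumerate(PARAMETERS):
        m[i, i] = entropy_1d(marginal_1d(series, p, spec))
    index = {p: i for i, p in enumerate(PARAMETERS)}
    for pair in PARAMETER_PAIRS:
        s = entropy_2d(marginal_2d(series, pair, spec))
        i, j = index[pair[0]], index[pair[1]]
        m[i, j] = m[j, i] = s
    return EnsembleEntropyMatrix(
        matrix=m,
        spec=spec,
        sequence_id=series.sequence_id,
        metadata=dict(series.metadata),
    )
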