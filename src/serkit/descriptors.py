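"""Per-conformation polymeric descriptors.

For each conformation of a heterogeneous chain ensemble three global
descriptors are computed:

* **Rg** — radius of gyration, the root-mean-square distance of the atoms
  from their centroid (Å); the overall size of the conformation.
* **δ** — asphericity, a dimensionless shape measure in [0, 1] built from
  the eigenvalues λ1 ≥ λ2 ≥ λ3 of the gyration tensor:
  ``δ = 1 − 3 (λ1λ2 + λ1λ3 + λ2λ3) / (λ1 + λ2 + λ3)²``.
  δ = 0 for a spherically symmetric mass distribution, δ = 1 for a rod.
* **Re** — end-to-end distance, the Euclidean distance between one atom in
  the first residue and one in the last (Å).

The default weighting is uniform over atoms (every atom counts equally in
the centroid and the tensor); per-atom mass weighting is available via the
``weights`` argument.  Asphericity is evaluated per conformation from that
conformation's own eigenvalues, because downstream analyses build the
distribution p(δ) over the ensemble.
"""

from __future__ import annotations

import numpy as np

from .errors import (
    DegenerateConformationError,
    SelectionError,
    StateError,
    ValidationError,
)
from .trajectory_io import ConformationSet, PropertySeries

__all__ = [
    "gyration_tensor",
    "radius_of_gyration",
    "asphericity",
    "end_to_end_distance",
    "compute_property_series",
    "length_normalize",
]

# eigenvalues more negative than this (in units of the trace) indicate a
# real problem rather than round-off
_EIG_CLAMP = 1e-12


def _as_points(conformation: np.ndarray) -> np.ndarray:
    pts = np.asarray(conformation, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"conformation must have shape (n_atoms, 3), got {pts.shape}")
    if pts.shape[0] < 2:
        raise ValidationError("a conformation needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("coordinates must be finite")
    return pts


def _weights(pts: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return np.full(len(pts), 1.0 / len(pts))
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(pts),):
        raise ValidationError("weights must have one entry per atom")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be nonnegative with positive sum")
    return w / w.sum()


def gyration_tensor(conformation: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted gyration tensor T = Σ wᵢ (rᵢ − r̄)(rᵢ − r̄)ᵀ / Σ wᵢ (Å²).

    The trace of the tensor equals Rg² of the same conformation.  A set of
    coincident points gives a valid zero tensor.
    """
    pts = _as_points(conformation)
    w = _weights(pts, weights)
    centered = pts - w @ pts
    tensor = (centered * w[:, None]).T @ centered
    return 0.5 * (tensor + tensor.T)  # enforce exact symmetry


def radius_of_gyration(conformation: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Rg = sqrt(Σ wᵢ |rᵢ − r̄|² / Σ wᵢ) in Å."""
    return float(np.sqrt(np.trace(gyration_tensor(conformation, weights))))


def _sorted_eigenvalues(tensor: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh(tensor)[::-1]  # descending
    scale = max(lam[0], 1.0)
    lam = np.where(lam < 0, np.where(lam > -_EIG_CLAMP * scale, 0.0, lam), lam)
    if np.any(lam < 0):
        raise ValidationError("gyration tensor has a significantly negative eigenvalue")
    return lam


def asphericity(conformation: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Shape anisotropy δ ∈ [0, 1] from the gyration-tensor eigenvalues.

    Raises :class:`DegenerateConformationError` when all points coincide
    (zero trace — the shape is undefined).
    """
    lam = _sorted_eigenvalues(gyration_tensor(conformation, weights))
    trace = lam.sum()
    if trace <= 0.0:
        raise DegenerateConformationError("all points coincide; asphericity undefined")
    pair_sum = lam[0] * lam[1] + lam[0] * lam[2] + lam[1] * lam[2]
    delta = 1.0 - 3.0 * pair_sum / trace**2
    return float(min(max(delta, 0.0), 1.0))


def _resolve_end_atom(
    cset: ConformationSet, residue: int, atom_label: str | None
) -> int:
    mask = cset.residue_indices == residue
    idx = np.flatnonzero(mask)
    if atom_label is not None:
        idx = idx[np.asarray([str(a) == atom_label for a in cset.atom_names[mask]])]
        if len(idx) == 0:
            raise SelectionError(f"no atom {atom_label!r} in residue {residue}")
        if len(idx) > 1:
            raise SelectionError(f"{len(idx)} atoms named {atom_label!r} in residue {residue}")
        return int(idx[0])
    return int(idx[0])


def end_selection_indices(
    cset: ConformationSet, end_selection: str | None = "auto"
) -> tuple[int, int]:
    """Resolve the pair of atom indices defining the chain ends.

    ``end_selection`` is an atom label applied to the first and last residue
    (e.g. ``"CA"``), ``"auto"`` (Cα when present, otherwise the first atom of
    the first residue and the last atom of the last residue), or ``None``
    (synonym for ``"auto"``).
    """
    first = int(cset.residue_indices.min())
    last = int(cset.residue_indices.max())
    if first == last:
        raise SelectionError("chain has a single residue; ends undefined")
    if end_selection in ("auto", None):
        labels = {str(a) for a in cset.atom_names}
        if "CA" in labels:
            return (
                _resolve_end_atom(cset, first, "CA"),
                _resolve_end_atom(cset, last, "CA"),
            )
        i = int(np.flatnonzero(cset.residue_indices == first)[0])
        j = int(np.flatnonzero(cset.residue_indices == last)[-1])
        return i, j
    return (
        _resolve_end_atom(cset, first, end_selection),
        _resolve_end_atom(cset, last, end_selection),
    )


def end_to_end_distance(
    conformation: np.ndarray, i: int = 0, j: int = -1
) -> float:
    """Euclidean distance between the two end atoms (indices i and j), Å."""
    pts = _as_points(conformation)
    return float(np.linalg.norm(pts[i] - pts[j]))


def compute_property_series(
    cset: ConformationSet,
    weights: np.ndarray | None = None,
    end_selection: str | None = "auto",
) -> PropertySeries:
    """Compute one (Rg, δ, Re) row per frame, preserving frame order."""
    import pandas as pd

    i, j = end_selection_indices(cset, end_selection)
    rows = np.empty((cset.n_frames, 3))
    for f in range(cset.n_frames):
        frame = cset.coords[f]
        try:
            tensor = gyration_tensor(frame, weights)
            lam = _sorted_eigenvalues(tensor)
            trace = lam.sum()
            if trace <= 0.0:
                raise DegenerateConformationError("all points coincide")
            rows[f, 0] = np.sqrt(trace)
            pair_sum = lam[0] * lam[1] + lam[0] * lam[2] + lam[1] * lam[2]
            rows[f, 1] = min(max(1.0 - 3.0 * pair_sum / trace**2, 0.0), 1.0)
            rows[f, 2] = np.linalg.norm(frame[i] - frame[j])
        except (ValidationError, DegenerateConformationError) as exc:
            raise type(exc)(f"frame {f}: {exc}") from exc
    return PropertySeries(
        sequence_id=cset.sequence_id,
        n_residues=cset.n_residues,
        data=pd.DataFrame(rows, columns=["Rg", "delta", "Re"]),
        normalized=False,
    )


def length_normalize(series: PropertySeries) -> PropertySeries:
    """Divide the length-dependent columns (Rg, Re) by √N.

    Chains of different length N have Rg and Re that grow roughly as √N, so
    cross-length comparisons of their distributions use Rg/√N and Re/√N.
    δ is dimensionless and unchanged.  Normalizing twice is an error.
    """
    if series.normalized:
        raise StateError(f"{series.sequence_id}: series is already length-normalized")
    factor = np.sqrt(series.n_residues)
    data = series.data.copy()
    data["Rg"] /= factor
    data["Re"] /= factor
    return PropertySeries(
        sequence_id=series.sequence_id,
        n_residues=series.n_residues,
        data=data,
        normalized=True,
        metadata=dict(series.metadata),
    )
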