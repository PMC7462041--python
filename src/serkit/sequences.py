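"""Sequence-side quantities: charge composition, alignment distances and
the sequence-vs-ensemble quadrant analysis.

Charge composition uses the standard neutral-pH convention: D and E are
negative, K and R positive; histidine is excluded by default (it is mostly
neutral at pH 7) but can be added to the positive set.

* FCR  — fraction of charged residues, (n⁺ + n⁻)/N.
* NCPR — net charge per residue, (n⁺ − n⁻)/N, reported signed;
  |NCPR| ≤ FCR always.

Sequence distance is the p-distance over an existing alignment: the
fraction of aligned columns at which two sequences differ.  A column where
one sequence has a gap and the other a residue counts as a difference;
columns where both are gapped are excluded from the denominator.  The
alignment itself is consumed, never computed here.

The quadrant analysis cross-tabulates, over all unordered sequence pairs,
the normalized sequence distance against the normalized SER dissimilarity
(both scaled by their maxima so the largest value is 1) at a 0.5 threshold:
pairs in the lower-left quadrant are similar in sequence *and* ensemble;
pairs in the upper-left have divergent sequences yet preserved ensembles —
the signature of poorly conserved disordered regions with conserved
conformational behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ValidationError

__all__ = [
    "SequenceRecord",
    "QuadrantSummary",
    "read_fasta",
    "composition_params",
    "pairwise_seq_distance",
    "quadrant_analysis",
]

_AMINO = set("ACDEFGHIKLMNPQRSTVWY")
_GAP = "-"

NEGATIVE_RESIDUES = frozenset("DE")
POSITIVE_RESIDUES = frozenset("KR")


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence; gaps allowed only in aligned mode."""

    id: str
    residues: str
    aligned: bool = False

    def __post_init__(self) -> None:
        allowed = _AMINO | ({_GAP} if self.aligned else set())
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise ValidationError(
                f"{self.id}: invalid residue code(s) {sorted(bad)}"
                + ("" if self.aligned else " (gaps only allowed in aligned sets)")
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a (possibly aligned) FASTA file into SequenceRecords."""
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq), aligned=aligned)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    return records


def composition_params(
    seq: SequenceRecord | str, include_histidine: bool = False
) -> tuple[float, float]:
    """(FCR, NCPR) of an ungapped sequence.

    FCR = (count of D,E,K,R)/length; NCPR = (count of K,R − count of D,E)/length.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq).upper()
    if not residues:
        raise ValidationError("empty sequence")
    if _GAP in residues:
        raise ValidationError("composition parameters require an ungapped sequence")
    positive = POSITIVE_RESIDUES | (frozenset("H") if include_histidine else frozenset())
    n_pos = sum(residues.count(r) for r in positive)
    n_neg = sum(residues.count(r) for r in NEGATIVE_RESIDUES)
    length = len(residues)
    return (n_pos + n_neg) / length, (n_pos - n_neg) / length


def pairwise_seq_distance(alignment: Sequence[SequenceRecord]) -> pd.DataFrame:
    """Pairwise p-distances over an alignment, as a square DataFrame.

    Distance = differing columns / scored columns, where a gap-vs-residue
    column counts as a difference and both-gap columns are excluded.
    Symmetric, zero diagonal, entries in [0, 1].
    """
    if len(alignment) < 2:
        raise ValidationError("need at least 2 aligned sequences")
    lengths = {len(rec) for rec in alignment}
    if len(lengths) != 1:
        raise ValidationError(f"aligned sequences have differing lengths: {sorted(lengths)}")
    ids = [rec.id for rec in alignment]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids in alignment")
    chars = np.array([list(rec.residues) for rec in alignment])
    gaps = chars == _GAP
    m = len(alignment)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both_gap = gaps[i] & gaps[j]
            scored = ~both_gap
            n_scored = int(scored.sum())
            if n_scored == 0:
                raise ValidationError(
                    f"sequences {ids[i]!r} and {ids[j]!r} share no scored columns"
                )
            diff = (chars[i] != chars[j]) & scored
            dist[i, j] = dist[j, i] = diff.sum() / n_scored
    return pd.DataFrame(dist, index=ids, columns=ids)


@dataclass(frozen=True)
class QuadrantSummary:
    """Fractions of sequence pairs per quadrant of the normalized
    (sequence distance, SER dissimilarity) plane at a given threshold.

    ``fractions`` keys: ``low_low`` (both ≤ t), ``high_low`` (seq > t,
    ser ≤ t — divergent sequences, preserved ensembles), ``low_high``,
    ``high_high``.  Pairs exactly on the threshold fall in the low class.
    """

    fractions: dict
    n_pairs: int
    threshold: float
    histogram: np.ndarray = field(repr=False, default=None)
    bin_edges: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"quadrant fractions must sum to 1, got {total}")


def _check_normalized(df: pd.DataFrame, name: str) -> None:
    peak = float(np.asarray(df.to_numpy()).max())
    if abs(peak - 1.0) > 1e-9:
        raise ValidationError(
            f"{name} matrix is not normalized (max = {peak:.6g}, expected 1); "
            "divide by the maximum first"
        )


def quadrant_analysis(
    seq_dist: pd.DataFrame,
    ser_dist: pd.DataFrame,
    threshold: float = 0.5,
    histogram_bins: int = 20,
) -> QuadrantSummary:
    """Classify all unordered pairs by their normalized distances.

    Both matrices must be square, share the same id set/order, and be
    normalized so their maximum entry is 1.
    """
    if list(seq_dist.index) != list(seq_dist.columns):
        raise ValidationError("sequence distance matrix index/columns mismatch")
    if list(ser_dist.index) != list(ser_dist.columns):
        raise ValidationError("SER dissimilarity matrix index/columns mismatch")
    if list(seq_dist.index) != list(ser_dist.index):
        raise ValidationError(
            "sequence and SER matrices must share the same ids in the same order"
        )
    _check_normalized(seq_dist, "sequence distance")
    _check_normalized(ser_dist, "SER dissimilarity")
    m = len(seq_dist)
    iu = np.triu_indices(m, k=1)
    seq_pairs = seq_dist.to_numpy()[iu]
    ser_pairs = ser_dist.to_numpy()[iu]
    n_pairs = len(seq_pairs)
    seq_low = seq_pairs <= threshold
    ser_low = ser_pairs <= threshold
    fractions = {
        "low_low": float(np.mean(seq_low & ser_low)),
        "high_low": float(np.mean(~seq_low & ser_low)),
        "low_high": float(np.mean(seq_low & ~ser_low)),
        "high_high": float(np.mean(~seq_low & ~ser_low)),
    }
    hist, ex, _ = np.histogram2d(
        seq_pairs, ser_pairs, bins=histogram_bins, range=[[0, 1], [0, 1]]
    )
    return QuadrantSummary(
        fractions=fractions,
        n_pairs=n_pairs,
        threshold=threshold,
        histogram=hist,
        bin_edges=ex,
    )
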