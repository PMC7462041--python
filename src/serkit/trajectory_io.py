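"""Conformational-ensemble and property-table I/O.

Containers
----------
:class:`ConformationSet`
    An ordered stack of conformations of one chain: per-atom labels and
    residue indices shared across frames, coordinates in Å.
:class:`PropertySeries`
    Per-conformation values of the three global polymeric descriptors
    (Rg in Å, asphericity δ dimensionless, Re in Å) for one sequence.

Formats
-------
* multi-model PDB (read/write, via biotite) — only MODEL/ENDMDL, ATOM and
  TER records are interpreted; HETATM records and alternate locations other
  than blank/'A' are skipped with a logged warning.
* concatenated XYZ blocks (read/write).
* tab-separated property tables with ``#``-prefixed header comments carrying
  ``n_residues`` and the normalization flag (read/write).

Coordinates are Å throughout; there is no unit autodetection.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

PROPERTY_COLUMNS = ("Rg", "delta", "Re")


@dataclass
class ConformationSet:
    """Ordered ensemble of conformations of a single chain.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    atom_names : ndarray of str, shape (n_atoms,)
        Atom labels (e.g. ``"CA"``), shared by every frame.
    residue_indices : ndarray of int, shape (n_atoms,)
        Residue index of each atom, nondecreasing.
    sequence_id : str
        Identifier of the chain/sequence this ensemble belongs to.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    residue_indices: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (frames, atoms, 3), got {self.coords.shape}"
            )
        n_atoms = self.coords.shape[1]
        if len(self.atom_names) != n_atoms or len(self.residue_indices) != n_atoms:
            raise ValidationError("atom_names/residue_indices length must match coords")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if self.n_residues < 2:
            raise ValidationError("a chain needs at least 2 residues")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.residue_indices))

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class PropertySeries:
    """Per-conformation (Rg, δ, Re) values for one sequence.

    ``data`` is a DataFrame with columns ``Rg``, ``delta``, ``Re`` and one row
    per conformation, in trajectory order.  ``normalized`` is True once the
    length-dependent columns have been divided by √N.  ``metadata`` may carry
    auxiliary sequence parameters (κ, FCR, NCPR, ...).
    """

    sequence_id: str
    n_residues: int
    data: pd.DataFrame
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PROPERTY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"property table missing column(s): {missing}")
        self.data = self.data.loc[:, list(PROPERTY_COLUMNS)].astype(float)
        self.data = self.data.reset_index(drop=True)
        if int(self.n_residues) < 2:
            raise ValidationError("n_residues must be >= 2")
        self.n_residues = int(self.n_residues)
        if len(self.data) < 2:
            raise ValidationError(
                "a property series needs at least 2 rows (a distribution "
                "requires multiple conformations)"
            )
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValidationError("property values must be finite")
        d = self.data["delta"].to_numpy()
        if np.any(d < 0) or np.any(d > 1):
            raise ValidationError("asphericity delta must lie in [0, 1]")
        if np.any(self.data["Rg"].to_numpy() <= 0):
            raise ValidationError("Rg must be positive")
        if np.any(self.data["Re"].to_numpy() < 0):
            raise ValidationError("Re must be nonnegative")

    def __len__(self) -> int:
        return len(self.data)

    def values(self, parameter: str) -> np.ndarray:
        if parameter not in PROPERTY_COLUMNS:
            raise ValidationError(f"unknown parameter {parameter!r}")
        return self.data[parameter].to_numpy()


# ---------------------------------------------------------------------------
# multi-model PDB


def _scan_model_atom_counts(text: str) -> list[tuple[int, int]]:
    """Count ATOM records per MODEL block; [(model_number, n_atoms), ...]."""
    counts: list[tuple[int, int]] = []
    current: int | None = None
    n = 0
    seen_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            seen_model = True
            if current is not None:
                counts.append((current, n))
            try:
                current = int(line.split()[1])
            except (IndexError, ValueError):
                current = len(counts) + 1
            n = 0
        elif rec == "ENDMDL":
            counts.append((current if current is not None else 1, n))
            current = None
            n = 0
        elif rec == "ATOM":
            altloc = line[16] if len(line) > 16 else " "
            if altloc in (" ", "A"):
                n += 1
    if current is not None or (not seen_model and n > 0):
        counts.append((current if current is not None else 1, n))
    return counts


def read_multimodel_pdb(path: str | Path, sequence_id: str | None = None) -> ConformationSet:
    """Read a (multi-model) PDB file into a :class:`ConformationSet`.

    One frame per MODEL record; a single-structure file yields a one-frame
    set.  Atom order is preserved.  HETATM records and alternate locations
    other than blank/'A' are skipped with a warning.

    Raises
    ------
    FormatError
        If models disagree in atom count (the offending model is named) or
        the file cannot be parsed.
    """
    path = Path(path)
    text = path.read_text()
    counts = _scan_model_atom_counts(text)
    if not counts:
        raise FormatError(f"{path}: no ATOM records found")
    ref_model, ref_n = counts[0]
    for model, n in counts[1:]:
        if n != ref_n:
            raise FormatError(
                f"{path}: MODEL {model} has {n} atoms, expected {ref_n} "
                f"(as in MODEL {ref_model})"
            )
    try:
        pdb = PDBFile.read(io.StringIO(text))
        stack = pdb.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises its own hierarchy
        raise FormatError(f"{path}: could not parse PDB: {exc}") from exc
    if np.any(stack.hetero):
        logger.warning("%s: skipping %d HETATM atoms", path, int(np.sum(stack.hetero)))
        stack = stack[:, ~stack.hetero]
    if stack.array_length() == 0:
        raise FormatError(f"{path}: no ATOM records found")
    return ConformationSet(
        coords=np.asarray(stack.coord, dtype=float),
        atom_names=np.asarray(stack.atom_name, dtype=object),
        residue_indices=np.asarray(stack.res_id, dtype=int),
        sequence_id=sequence_id if sequence_id is not None else path.stem,
    )


def write_multimodel_pdb(cset: ConformationSet, path: str | Path) -> None:
    """Write a :class:`ConformationSet` as a multi-model PDB file."""
    n_atoms = cset.n_atoms
    atoms = struc.AtomArray(n_atoms)
    atoms.coord = np.zeros((n_atoms, 3))
    atoms.atom_name = np.asarray(cset.atom_names, dtype="U6")
    atoms.res_id = cset.residue_indices
    atoms.res_name = np.full(n_atoms, "GLY", dtype="U5")
    atoms.chain_id = np.full(n_atoms, "A", dtype="U4")
    atoms.element = np.array(
        [str(n)[:1] if str(n) else "C" for n in cset.atom_names], dtype="U2"
    )
    stack = struc.stack([atoms] * cset.n_frames)
    stack.coord = np.asarray(cset.coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# XYZ trajectories


def read_xyz_trajectory(
    path: str | Path,
    residue_map: np.ndarray | list[int] | None = None,
    sequence_id: str | None = None,
) -> ConformationSet:
    """Read concatenated XYZ blocks (constant atom count) into a set.

    Each block is ``n_atoms`` / comment / ``n_atoms`` lines of
    ``label x y z``.  If ``residue_map`` is not given, each atom is its own
    residue.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    labels: list[str] | None = None
    i = 0
    block = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        block += 1
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: block {block}: expected atom count, got {lines[i]!r}")
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise FormatError(f"{path}: block {block} truncated ({len(body)}/{n} atom lines)")
        this_labels: list[str] = []
        xyz = np.empty((n, 3))
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: block {block}, atom line {j + 1}: {line!r}")
            this_labels.append(parts[0])
            try:
                xyz[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise FormatError(f"{path}: block {block}, atom line {j + 1}: non-numeric coordinate")
        if labels is None:
            labels = this_labels
        elif len(this_labels) != len(labels):
            raise FormatError(
                f"{path}: block {block} has {len(this_labels)} atoms, expected {len(labels)}"
            )
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: empty XYZ file")
    assert labels is not None
    if residue_map is None:
        residues = np.arange(1, len(labels) + 1)
    else:
        residues = np.asarray(residue_map, dtype=int)
        if len(residues) != len(labels):
            raise FormatError(f"{path}: residue_map length {len(residues)} != atom count {len(labels)}")
    return ConformationSet(
        coords=np.stack(frames),
        atom_names=np.asarray(labels, dtype=object),
        residue_indices=residues,
        sequence_id=sequence_id if sequence_id is not None else path.stem,
    )


def write_xyz_trajectory(cset: ConformationSet, path: str | Path) -> None:
    """Write a :class:`ConformationSet` as concatenated XYZ blocks."""
    with open(path, "w") as fh:
        for f in range(cset.n_frames):
            fh.write(f"{cset.n_atoms}\n")
            fh.write(f"{cset.sequence_id} frame {f}\n")
            for label, (x, y, z) in zip(cset.atom_names, cset.coords[f]):
                fh.write(f"{label} {x:.8f} {y:.8f} {z:.8f}\n")


# ---------------------------------------------------------------------------
# property tables


def write_property_table(series: PropertySeries, path: str | Path) -> None:
    """Write a :class:`PropertySeries` as a commented TSV file."""
    with open(path, "w") as fh:
        fh.write(f"# sequence_id\t{series.sequence_id}\n")
        fh.write(f"# n_residues\t{series.n_residues}\n")
        fh.write(f"# normalized\t{str(series.normalized).lower()}\n")
        for key, value in sorted(series.metadata.items()):
            fh.write(f"# meta:{key}\t{value}\n")
        fh.write("frame\tRg\tdelta\tRe\n")
        for frame, row in series.data.iterrows():
            fh.write(f"{frame}\t{row.Rg:.10g}\t{row.delta:.10g}\t{row.Re:.10g}\n")


def read_property_table(path: str | Path) -> PropertySeries:
    """Read a property-table TSV written by :func:`write_property_table`.

    Raises
    ------
    FormatError
        On a missing required column or a non-numeric cell (named by row).
    ValidationError
        When values violate the series invariants (δ outside [0,1], <2 rows).
    """
    path = Path(path)
    sequence_id = path.stem
    n_residues: int | None = None
    normalized = False
    metadata: dict = {}
    body_lines: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) >= 2:
                key, value = parts[0], parts[1]
                if key == "sequence_id":
                    sequence_id = value
                elif key == "n_residues":
                    n_residues = int(value)
                elif key == "normalized":
                    normalized = value.strip().lower() == "true"
                elif key.startswith("meta:"):
                    metadata[key[5:]] = _coerce(value)
        elif line.strip():
            body_lines.append(line)
    if n_residues is None:
        raise FormatError(f"{path}: missing '# n_residues' header comment")
    if not body_lines:
        raise FormatError(f"{path}: no data rows")
    header = body_lines[0].split("\t")
    for col in ("frame", *PROPERTY_COLUMNS):
        if col not in header:
            raise FormatError(f"{path}: missing column {col!r}")
    try:
        df = pd.read_csv(
            io.StringIO("\n".join(body_lines)), sep="\t", dtype={"frame": int}
        )
        for col in PROPERTY_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="raise")
    except (ValueError, TypeError):
        # locate the offending row for a useful message
        for rownum, line in enumerate(body_lines[1:], start=1):
            for cell in line.split("\t")[1:]:
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(f"{path}: non-numeric cell {cell!r} in data row {rownum}")
        raise FormatError(f"{path}: malformed table")
    return PropertySeries(
        sequence_id=sequence_id,
        n_residues=n_residues,
        data=df[list(PROPERTY_COLUMNS)],
        normalized=normalized,
        metadata=metadata,
    )


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value
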