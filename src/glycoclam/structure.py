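"""Multi-model PDB reading/writing and atom selection.

Coordinates are kept in Angstrom (PDB native); conversion to nm happens at
the order-parameter boundary (see :mod:`glycoclam.geometry`). Residue numbers
are taken verbatim from the file — no renumbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "PDBFormatError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atoms",
]


class PDBFormatError(ValueError):
    """Raised for structurally invalid multi-model PDB input."""


@dataclass
class AtomRecord:
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    x: float
    y: float
    z: float
    het: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Frame:
    """One model of a multi-model PDB: an ordered list of atoms."""

    model_index: int
    atoms: list[AtomRecord]

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinates in Angstrom."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


@dataclass
class Trajectory:
    """An ordered sequence of frames at uniform time spacing.

    dt defaults to 0.2 ns per frame, the frame spacing used throughout
    this package for LBD ensembles.
    """

    frames: list[Frame]
    dt: float = 0.2
    source_label: str = ""
    parse_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def _infer_element(atom_name: str) -> str:
    """Element from the atom-name column when the element field is blank.

    PDB convention: columns 13-14 hold the element, possibly preceded by a
    digit (e.g. '1HG1'). Strip digits, then take the leading character(s).
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    # Two-letter elements in protein/glycan context start in column 13;
    # a name like 'CA' left-padded (' CA ') is carbon, unpadded 'CA' calcium.
    # We only see single-letter organic elements plus H/D in practice.
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int, warnings_out: list[str]) -> AtomRecord | None:
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip()
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        warnings_out.append(f"line {lineno}: malformed ATOM/HETATM record ({exc})")
        return None
    if not element:
        element = _infer_element(atom_name)
    if not element:
        warnings_out.append(f"line {lineno}: could not infer element for atom '{atom_name}'")
        return None
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
        warnings_out.append(f"line {lineno}: non-finite coordinates")
        return None
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        element=element,
        x=x,
        y=y,
        z=z,
        het=line.startswith("HETATM"),
    )


def read_multimodel_pdb(path: str | Path, dt: float = 0.2) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Frames appear in file order. A file without MODEL records is read as a
    single frame. Malformed ATOM lines are skipped and reported (with line
    numbers) via ``Trajectory.parse_warnings`` and a ``UserWarning``.

    Raises
    ------
    PDBFormatError
        If models have inconsistent atom counts (the error names them) or the
        file contains no atoms.
    """
    path = Path(path)
    frames: list[Frame] = []
    parse_warnings: list[str] = []
    current: list[AtomRecord] | None = None
    model_index = 0
    saw_model = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                try:
                    model_index = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    model_index = len(frames) + 1
                current = []
            elif rec.startswith("ENDMDL"):
                if current is not None:
                    frames.append(Frame(model_index=model_index, atoms=current))
                    current = None
            elif rec.startswith(("ATOM  ", "HETATM")):
                atom = _parse_atom_line(line, lineno, parse_warnings)
                if atom is None:
                    continue
                if current is None:
                    if saw_model:
                        parse_warnings.append(f"line {lineno}: atom outside MODEL/ENDMDL, skipped")
                        continue
                    current = []
                    model_index = 1
                current.append(atom)

    if current is not None and current:
        frames.append(Frame(model_index=model_index, atoms=current))

    if not frames:
        raise PDBFormatError(f"{path}: no atoms found")

    counts = {f.model_index: len(f) for f in frames}
    if len(set(counts.values())) > 1:
        detail = ", ".join(f"model {m}: {n} atoms" for m, n in counts.items())
        raise PDBFormatError(f"{path}: inconsistent atom counts across models ({detail})")

    if parse_warnings:
        warnings.warn(
            f"{path}: {len(parse_warnings)} malformed line(s); first: {parse_warnings[0]}",
            UserWarning,
            stacklevel=2,
        )
    return Trajectory(frames=frames, dt=dt, source_label=str(path), parse_warnings=parse_warnings)


def _format_atom_name(name: str, element: str) -> str:
    # Standard PDB: single-letter elements start in column 14, two-letter in 13.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB with standard column layout."""
    path = Path(path)
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"MODEL     {frame.model_index:4d}\n")
            for atom in frame.atoms:
                record = "HETATM" if atom.het else "ATOM  "
                fh.write(
                    f"{record}{atom.serial:5d} {_format_atom_name(atom.atom_name, atom.element)}"
                    f" {atom.residue_name:<3s} {atom.chain_id:1s}{atom.residue_number:4d}    "
                    f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def select_atoms(
    frame: Frame,
    chain: str | None = None,
    residue_numbers: set[int] | None = None,
    atom_names: set[str] | None = None,
    heavy_only: bool = False,
) -> np.ndarray:
    """Indices (in frame order) of atoms matching all given criteria.

    An empty selection is a legal result; downstream operations decide
    whether that is an error.
    """
    if residue_numbers is not None:
        residue_numbers = set(residue_numbers)
    if atom_names is not None:
        atom_names = {n.strip() for n in atom_names}
    idx = []
    for i, atom in enumerate(frame.atoms):
        if chain is not None and atom.chain_id != chain:
            continue
        if residue_numbers is not None and atom.residue_number not in residue_numbers:
            continue
        if atom_names is not None and atom.atom_name not in atom_names:
            continue
        if heavy_only and atom.is_hydrogen:
            continue
        idx.append(i)
    return np.asarray(idx, dtype=int)
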