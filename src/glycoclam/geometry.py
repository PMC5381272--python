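"""Clamshell order parameters and glycan-contact geometry.

The clamshell order parameter ``d`` is the distance between two marker
C-alpha atoms, one per lobe of a bilobed ligand-binding domain (LBD):
residues 507/701 for GluN1, 503/701 for GluN2B. ``d_g-ol`` is the minimum
heavy-atom distance between a glycan and a residue range on the opposite
lobe (710-723 for the GluN1 N440 glycan). Distances are reported in nm;
structures are stored in Angstrom, converted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Frame, Trajectory, select_atoms

NM_PER_ANGSTROM = 0.1

#: Marker residues for the interlobe distance, by subunit.
SUBUNIT_MARKERS = {"GluN1": (507, 701), "GluN2B": (503, 701)}

__all__ = [
    "SUBUNIT_MARKERS",
    "ContactProfile",
    "JointHistogram",
    "interlobe_distance",
    "glycan_lobe_min_distance",
    "contact_fraction",
    "joint_histogram",
    "trajectory_order_parameters",
]


@dataclass
class ContactProfile:
    """Per-residue fraction of frames in which the probe selection is in contact."""

    fractions: dict[int, float]
    cutoff: float  # nm

    def sorted_items(self) -> list[tuple[int, float]]:
        """Residues from most heavily engaged to least."""
        return sorted(self.fractions.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class JointHistogram:
    """2-D occupancy counts of (d, d_g-ol). Raw counts are stored; any log
    transform is applied only at rendering time."""

    d_edges: np.ndarray
    dgol_edges: np.ndarray
    counts: np.ndarray  # shape (len(d_edges)-1, len(dgol_edges)-1)
    overflow: int  # frames outside the bin range

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum()) + self.overflow

    def block_count(self, d_min: float, dgol_max: float) -> int:
        """Total count in the cell block with d above ``d_min`` and d_g-ol
        below ``dgol_max`` (the region that is empty when glycan-lobe contact
        occurs only in closed-clamshell conformations)."""
        d_sel = self.d_edges[:-1] >= d_min
        g_sel = self.dgol_edges[1:] <= dgol_max
        return int(self.counts[np.ix_(d_sel, g_sel)].sum())


def _single_atom(frame: Frame, residue: int, atom_name: str, chain: str | None) -> np.ndarray:
    idx = select_atoms(frame, chain=chain, residue_numbers={residue}, atom_names={atom_name})
    if len(idx) != 1:
        raise ValueError(
            f"selection residue {residue} atom {atom_name!r} matched {len(idx)} atoms; need exactly 1"
        )
    atom = frame.atoms[int(idx[0])]
    return np.array([atom.x, atom.y, atom.z])


def interlobe_distance(
    frame: Frame,
    res_a: int = 507,
    res_b: int = 701,
    atom_name: str = "CA",
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> float:
    """Clamshell order parameter d: CA(res_a)-CA(res_b) distance in nm."""
    pa = _single_atom(frame, res_a, atom_name, chain_a)
    pb = _single_atom(frame, res_b, atom_name, chain_b)
    return float(np.linalg.norm(pa - pb)) * NM_PER_ANGSTROM


def _heavy_coords(frame: Frame, indices: np.ndarray) -> np.ndarray:
    keep = [i for i in np.asarray(indices, dtype=int) if not frame.atoms[i].is_hydrogen]
    return np.array([[frame.atoms[i].x, frame.atoms[i].y, frame.atoms[i].z] for i in keep])


def glycan_lobe_min_distance(
    frame: Frame,
    glycan_indices: np.ndarray,
    lobe_residues=range(710, 724),
    lobe_chain: str | None = None,
) -> float:
    """d_g-ol: minimum heavy-atom distance (nm) between a glycan selection and
    the opposite-lobe residue range."""
    gly = _heavy_coords(frame, glycan_indices)
    lobe_idx = select_atoms(
        frame, chain=lobe_chain, residue_numbers=set(lobe_residues), heavy_only=True
    )
    if gly.size == 0:
        raise ValueError("glycan selection empty after heavy-atom filtering")
    if len(lobe_idx) == 0:
        raise ValueError(f"lobe selection empty (residues {min(lobe_residues)}-{max(lobe_residues)})")
    lobe = _heavy_coords(frame, lobe_idx)
    return float(cdist(gly, lobe).min()) * NM_PER_ANGSTROM


def min_heavy_distance(frame: Frame, indices_a: np.ndarray, indices_b: np.ndarray) -> float:
    """Minimum pairwise heavy-atom distance (nm) between two atom selections."""
    a = _heavy_coords(frame, indices_a)
    b = _heavy_coords(frame, indices_b)
    if a.size == 0 or b.size == 0:
        side = "first" if a.size == 0 else "second"
        raise ValueError(f"{side} selection empty after heavy-atom filtering")
    return float(cdist(a, b).min()) * NM_PER_ANGSTROM


def contact_fraction(
    trajectory: Trajectory,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    cutoff: float = 0.5,
) -> tuple[float, ContactProfile]:
    """Fraction of frames in which the two selections are in heavy-atom
    contact (min pairwise distance < cutoff, nm), plus a per-residue profile
    on side b.

    The 0.5 nm default mirrors the empty-region boundary of the (d, d_g-ol)
    occupancy map; it is a declared convention, not a measured property.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    selection_a = np.asarray(selection_a, dtype=int)
    selection_b = np.asarray(selection_b, dtype=int)

    first = trajectory.frames[0]
    b_residues = sorted({first.atoms[i].residue_number for i in selection_b})
    by_residue = {
        r: np.asarray([i for i in selection_b if first.atoms[i].residue_number == r]) for r in b_residues
    }

    n_contact = 0
    res_counts = dict.fromkeys(b_residues, 0)
    cutoff_ang = cutoff / NM_PER_ANGSTROM
    for frame in trajectory.frames:
        a = _heavy_coords(frame, selection_a)
        b = _heavy_coords(frame, selection_b)
        if a.size == 0 or b.size == 0:
            side = "a" if a.size == 0 else "b"
            raise ValueError(f"selection {side} empty after heavy-atom filtering")
        if cdist(a, b).min() < cutoff_ang:
            n_contact += 1
        for r in b_residues:
            br = _heavy_coords(frame, by_residue[r])
            if br.size and cdist(a, br).min() < cutoff_ang:
                res_counts[r] += 1

    n = len(trajectory)
    profile = ContactProfile(fractions={r: c / n for r, c in res_counts.items()}, cutoff=cutoff)
    return n_contact / n, profile


def joint_histogram(
    d: np.ndarray,
    dgol: np.ndarray,
    d_edges: np.ndarray,
    dgol_edges: np.ndarray,
) -> JointHistogram:
    """2-D count matrix of (d, d_g-ol) over an ensemble of frames.

    Frames outside the bin range go to an overflow count so that total mass
    is conserved: counts.sum() + overflow == len(d).
    """
    d = np.asarray(d, dtype=float)
    dgol = np.asarray(dgol, dtype=float)
    d_edges = np.asarray(d_edges, dtype=float)
    dgol_edges = np.asarray(dgol_edges, dtype=float)
    for name, e in (("d_edges", d_edges), ("dgol_edges", dgol_edges)):
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
    if d.shape != dgol.shape:
        raise ValueError("d and dgol must have the same length")
    counts, _, _ = np.histogram2d(d, dgol, bins=(d_edges, dgol_edges))
    overflow = len(d) - int(counts.sum())
    return JointHistogram(d_edges=d_edges, dgol_edges=dgol_edges, counts=counts.astype(int), overflow=overflow)


def trajectory_order_parameters(
    trajectory: Trajectory,
    res_a: int = 507,
    res_b: int = 701,
    glycan_chain: str | None = "G",
    lobe_residues=range(710, 724),
    lobe_chain: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-frame (d, d_g-ol) series for a structural trajectory, in nm.

    d_g-ol is None when no glycan chain is present.
    """
    d = np.array([interlobe_distance(f, res_a, res_b) for f in trajectory.frames])
    dgol = None
    if glycan_chain is not None:
        gly_idx = select_atoms(trajectory.frames[0], chain=glycan_chain, heavy_only=True)
        if len(gly_idx) > 0:
            dgol = np.array(
                [
                    glycan_lobe_min_distance(f, gly_idx, lobe_residues, lobe_chain)
                    for f in trajectory.frames
                ]
            )
    return d, dgol
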