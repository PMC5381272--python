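"""Synthetic inputs for the clamshell-dynamics pipeline.

Everything downstream consumes is generated here with seeded randomness:

* discrete Markov chains (oracle input for the MSM machinery),
* ensembles of a scalar clamshell coordinate d switching between an open
  basin (~4.7 nm) and a closed basin (~3.7 nm) as an *exact* continuous-time
  two-state process sampled at the frame spacing, so the equilibrium closed
  fraction rate_close/(rate_close+rate_open) and the relaxation time
  1/(rate_close+rate_open) are known in closed form,
* toy two-lobe glycoprotein structures (multi-model PDB) with a tethered
  pseudo-glycan that touches the opposite lobe only in closed conformations,
* replicate sigmoidal dose-response curves from a Hill model.

The generator defaults mirror the study conditions for glycosylated GluN1
LBD ensembles: 262 trajectories of 2000 frames at 0.2 ns per frame, basin
means 3.7 / 4.7 nm with 0.15 nm emission width.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .doseresponse import DoseResponseCurve, hill
from .ensembles import ScalarEnsemble
from .structure import AtomRecord, Frame, Trajectory

__all__ = [
    "STATE_OPEN",
    "STATE_CLOSED",
    "TwoStateSpec",
    "ToyGlycoproteinSpec",
    "DoseResponseSpec",
    "sample_markov_chain",
    "generate_two_state_ensemble",
    "generate_toy_glycoprotein_ensemble",
    "generate_dose_response",
]

STATE_OPEN = 0
STATE_CLOSED = 1


# ---------------------------------------------------------------------------
# two-state scalar ensembles


@dataclass(frozen=True)
class TwoStateSpec:
    """Two-state (open/closed) clamshell dynamics with Gaussian emissions.

    Rates are in 1/ns: ``rate_close`` is open->closed, ``rate_open`` is
    closed->open. The slowest relaxation time is exactly
    1/(rate_close + rate_open) and the equilibrium closed fraction is
    rate_close/(rate_close + rate_open).
    """

    rate_close: float = 0.002
    rate_open: float = 0.001
    mean_closed: float = 3.7  # nm
    mean_open: float = 4.7  # nm
    sd_closed: float = 0.15  # nm
    sd_open: float = 0.15  # nm
    dt: float = 0.2  # ns per frame
    n_traj: int = 262
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_close <= 0 or self.rate_open <= 0:
            raise ValueError("rates must be positive")
        if self.sd_closed < 0 or self.sd_open < 0:
            raise ValueError("emission sd must be nonnegative")
        if self.mean_open <= self.mean_closed:
            raise ValueError("mean_open must exceed mean_closed")
        if self.dt <= 0 or self.n_traj < 1 or self.n_frames < 1:
            raise ValueError("dt, n_traj and n_frames must be positive")

    @property
    def relaxation_time(self) -> float:
        """Exact slowest relaxation time, ns."""
        return 1.0 / (self.rate_close + self.rate_open)

    @property
    def closed_fraction(self) -> float:
        """Exact equilibrium probability of the closed state."""
        return self.rate_close / (self.rate_close + self.rate_open)

    def replace(self, **kwargs) -> "TwoStateSpec":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def with_relaxation(
        cls, relaxation_ns: float, closed_fraction: float = 2.0 / 3.0, **kwargs
    ) -> "TwoStateSpec":
        """Spec whose analytic relaxation time and closed fraction are given.

        Used to calibrate ensembles to a target slowest timescale.
        """
        lam = 1.0 / relaxation_ns
        return cls(rate_close=lam * closed_fraction, rate_open=lam * (1 - closed_fraction), **kwargs)


def sample_markov_chain(
    transition_matrix: np.ndarray, n_steps: int, seed: int, start: int | None = None
) -> np.ndarray:
    """Sample a discrete-state trajectory from a row-stochastic matrix.

    ``start`` defaults to a uniformly random initial state. Reproducible for
    a fixed seed.
    """
    T = np.asarray(transition_matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    row_sums = T.sum(axis=1)
    bad = np.where(np.abs(row_sums - 1.0) > 1e-12)[0]
    if len(bad):
        raise ValueError(
            f"matrix is not row-stochastic: row {int(bad[0])} sums to {row_sums[bad[0]]!r}"
        )
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    k = T.shape[0]
    cum = np.cumsum(T, axis=1)
    out = np.empty(n_steps, dtype=int)
    state = int(rng.integers(k)) if start is None else int(start)
    out[0] = state
    u = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        state = int(np.searchsorted(cum[state], u[t - 1], side="right"))
        state = min(state, k - 1)
        out[t] = state
    return out


def _two_state_step_probs(spec: TwoStateSpec) -> tuple[float, float]:
    """Exact per-frame switching probabilities of the sampled CTMC."""
    lam = spec.rate_close + spec.rate_open
    decay = 1.0 - np.exp(-lam * spec.dt)
    p_open_to_closed = spec.closed_fraction * decay
    p_closed_to_open = (1.0 - spec.closed_fraction) * decay
    return p_open_to_closed, p_closed_to_open


def generate_two_state_ensemble(spec: TwoStateSpec, warn_coarse: bool = True) -> ScalarEnsemble:
    """Ensemble of scalar d trajectories from the exact two-state process.

    The hidden chain is the continuous-time two-state process sampled at
    ``dt`` (exact matrix exponential, not an Euler step), initialised from
    equilibrium; emissions are state-dependent Gaussians. The hidden states
    are kept on the returned ensemble for oracle checks.
    """
    if warn_coarse and spec.dt >= spec.relaxation_time:
        warnings.warn(
            f"dt ({spec.dt} ns) >= relaxation time ({spec.relaxation_time:.3g} ns): "
            "discretization coarser than the process",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    p_oc, p_co = _two_state_step_probs(spec)

    states = np.empty((spec.n_traj, spec.n_frames), dtype=np.int8)
    states[:, 0] = rng.random(spec.n_traj) < spec.closed_fraction
    switch_u = rng.random((spec.n_traj, spec.n_frames - 1))
    for t in range(1, spec.n_frames):
        prev = states[:, t - 1]
        p_switch = np.where(prev == STATE_CLOSED, p_co, p_oc)
        states[:, t] = np.where(switch_u[:, t - 1] < p_switch, 1 - prev, prev)

    means = np.where(states == STATE_CLOSED, spec.mean_closed, spec.mean_open)
    sds = np.where(states == STATE_CLOSED, spec.sd_closed, spec.sd_open)
    d = means + sds * rng.standard_normal(states.shape)
    return ScalarEnsemble(
        d=list(d),
        dt=spec.dt,
        states=[s.astype(int) for s in states],
        label=f"two-state(tau={spec.relaxation_time:.4g}ns,pc={spec.closed_fraction:.4g})",
    )


# ---------------------------------------------------------------------------
# toy glycoprotein structures

_ARM_LENGTH = 40.0  # Angstrom: hinge-to-marker arm of each lobe


def hinge_angle_from_d(d_nm: np.ndarray) -> np.ndarray:
    """Hinge opening angle (radians) whose marker-marker distance is d."""
    d_ang = np.asarray(d_nm, dtype=float) * 10.0
    if np.any(d_ang >= 2 * _ARM_LENGTH):
        raise ValueError(f"d must be below {2 * _ARM_LENGTH / 10} nm for the toy geometry")
    return 2.0 * np.arcsin(d_ang / (2.0 * _ARM_LENGTH))


def d_from_hinge_angle(theta: np.ndarray) -> np.ndarray:
    """Marker-marker distance (nm) at a hinge angle; monotone inverse of
    :func:`hinge_angle_from_d`."""
    return 2.0 * _ARM_LENGTH * np.sin(np.asarray(theta) / 2.0) / 10.0


@dataclass(frozen=True)
class ToyGlycoproteinSpec:
    """Toy two-lobe glycoprotein with a tethered pseudo-glycan.

    Two chains of pseudo C-alpha atoms (chain A carries marker residue 507,
    chain B carries marker residue 701 and the opposite-lobe range starting
    at 710) hinge at the origin; the hinge angle maps monotonically to the
    marker distance d. A linear pseudo-glycan chain (chain G, heavy atoms) is
    tethered to lobe A; in closed frames it is rotated toward lobe B with
    probability ``contact_when_closed``, producing a <0.5 nm contact. Open
    frames (d above ``contact_d_max``) never have contact, by construction.
    """

    hinge_angle_series: np.ndarray  # radians per frame
    n_lobe_atoms: int = 16
    glycan_length: int = 11
    contact_when_closed: float = 0.8
    contact_d_max: float = 4.2  # nm; contact only attempted below this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lobe_atoms < 3:
            raise ValueError(f"n_lobe_atoms must be >= 3, got {self.n_lobe_atoms}")
        if self.glycan_length < 1:
            raise ValueError("glycan_length must be >= 1")
        if not 0 <= self.contact_when_closed <= 1:
            raise ValueError("contact_when_closed must be a probability")
        object.__setattr__(
            self, "hinge_angle_series", np.asarray(self.hinge_angle_series, dtype=float)
        )

    @property
    def d_series(self) -> np.ndarray:
        return d_from_hinge_angle(self.hinge_angle_series)

    @classmethod
    def from_d_series(cls, d_nm: np.ndarray, **kwargs) -> "ToyGlycoproteinSpec":
        return cls(hinge_angle_series=hinge_angle_from_d(d_nm), **kwargs)

    @classmethod
    def from_two_state(cls, two_state: TwoStateSpec, n_frames: int = 200, **kwargs) -> "ToyGlycoproteinSpec":
        ens = generate_two_state_ensemble(
            two_state.replace(n_traj=1, n_frames=n_frames), warn_coarse=False
        )
        return cls.from_d_series(ens.d[0], seed=kwargs.pop("seed", two_state.seed), **kwargs)


def _lobe_atoms(theta_half: float, side: int, n: int, serial_start: int) -> list[AtomRecord]:
    """Pseudo-Calpha atoms of one lobe arm at +/- theta/2 from the x axis."""
    ang = side * theta_half
    u = np.array([np.cos(ang), np.sin(ang), 0.0])
    atoms = []
    if side < 0:  # lobe A: residues ending at marker 507 on the tip
        radii = np.linspace(16.0, _ARM_LENGTH, n)
        residues = range(508 - n, 508)
        chain = "A"
    else:  # lobe B: marker 701 on the tip, then the 710+ range inward
        radii = np.concatenate([[_ARM_LENGTH], np.linspace(36.0, 16.0, n - 1)])
        residues = [701] + list(range(710, 710 + n - 1))
        chain = "B"
    for i, (r, resnum) in enumerate(zip(radii, residues)):
        pos = r * u
        atoms.append(
            AtomRecord(
                serial=serial_start + i,
                atom_name="CA",
                residue_name="ALA",
                chain_id=chain,
                residue_number=int(resnum),
                element="C",
                x=float(pos[0]),
                y=float(pos[1]),
                z=float(pos[2]),
            )
        )
    return atoms


def _glycan_atoms(
    theta_half: float, contact: bool, length: int, serial_start: int, lobe_b: list[AtomRecord]
) -> list[AtomRecord]:
    ang_a = -theta_half
    u_a = np.array([np.cos(ang_a), np.sin(ang_a), 0.0])
    anchor = 30.0 * u_a  # tether site on lobe A (the N440-like position)
    if contact:
        # extend toward the lobe-B atom nearest radius 30, stopping 3.5 A away
        coords = np.array([[a.x, a.y, a.z] for a in lobe_b])
        radii = np.linalg.norm(coords, axis=1)
        target = coords[int(np.argmin(np.abs(radii - 30.0)))]
        span = target - anchor
        dist = np.linalg.norm(span)
        ts = np.linspace(3.0, dist - 3.5, length) / dist
        positions = anchor[None, :] + ts[:, None] * span[None, :]
    else:
        # extend away from lobe B (perpendicular to the lobe-A arm, -y side)
        away = np.array([np.cos(ang_a - np.pi / 2), np.sin(ang_a - np.pi / 2), 0.0])
        steps = 3.0 * np.arange(1, length + 1)
        positions = anchor[None, :] + steps[:, None] * away[None, :]
    return [
        AtomRecord(
            serial=serial_start + i,
            atom_name="C1",
            residue_name="MAN",
            chain_id="G",
            residue_number=i + 1,
            element="C",
            x=float(p[0]),
            y=float(p[1]),
            z=float(p[2]),
            het=True,
        )
        for i, p in enumerate(positions)
    ]


def generate_toy_glycoprotein_ensemble(spec: ToyGlycoproteinSpec, dt: float = 0.2) -> Trajectory:
    """Multi-model toy glycoprotein trajectory.

    Per-frame d is recomputable from the CA atoms of marker residues 507 and
    701. The joint event (d > 5.2 nm and glycan-lobe distance < 0.5 nm) has
    count exactly zero by construction.
    """
    rng = np.random.default_rng(spec.seed)
    d_series = spec.d_series
    contact_draws = rng.random(len(d_series)) < spec.contact_when_closed
    frames = []
    for f, theta in enumerate(spec.hinge_angle_series):
        lobe_a = _lobe_atoms(theta / 2.0, side=-1, n=spec.n_lobe_atoms, serial_start=1)
        lobe_b = _lobe_atoms(theta / 2.0, side=+1, n=spec.n_lobe_atoms, serial_start=1 + len(lobe_a))
        contact = bool(contact_draws[f]) and d_series[f] <= spec.contact_d_max
        glycan = _glycan_atoms(
            theta / 2.0, contact, spec.glycan_length, 1 + len(lobe_a) + len(lobe_b), lobe_b
        )
        frames.append(Frame(model_index=f + 1, atoms=lobe_a + lobe_b + glycan))
    return Trajectory(frames=frames, dt=dt, source_label="toy-glycoprotein")


# ---------------------------------------------------------------------------
# dose-response curves

_DEFAULT_CONCENTRATIONS = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)  # uM half-log ladder


@dataclass(frozen=True)
class DoseResponseSpec:
    """Replicate glycine dose-response curves from a Hill model.

    ``noise_sd`` is the relative amplitude of multiplicative Gaussian noise
    on each measured current (0.03 = 3%). Concentrations default to the
    0.1-100 uM half-log ladder used in oocyte perfusion experiments.
    """

    ec50: float  # uM
    hill: float = 1.4
    imax: float = 1.0
    concentrations: tuple[float, ...] = _DEFAULT_CONCENTRATIONS
    n_curves: int = 12
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly positive and sorted")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ec50 <= 0 or self.hill <= 0 or self.imax <= 0:
            raise ValueError("ec50, hill and imax must be positive")


def generate_dose_response(spec: DoseResponseSpec) -> list[DoseResponseCurve]:
    """n_curves replicate curves; the noiseless mean at concentration c is
    imax * c^h / (ec50^h + c^h)."""
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.concentrations, dtype=float)
    mean = hill(c, spec.ec50, spec.hill, spec.imax)
    curves = []
    for i in range(spec.n_curves):
        noise = 1.0 + spec.noise_sd * rng.standard_normal(len(c))
        curves.append(
            DoseResponseCurve(
                curve_id=f"curve{i:03d}",
                concentrations=c.copy(),
                currents=mean * noise,
            )
        )
    return curves
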