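"""Container for ensembles of scalar order-parameter trajectories.

TSV layout (External interface): columns trajectory_id, frame_index,
time_ns, d_nm and optionally dgol_nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ScalarEnsemble"]


@dataclass
class ScalarEnsemble:
    """Scalar clamshell-coordinate trajectories at uniform time spacing.

    Attributes
    ----------
    d : list of 1-D arrays
        Order parameter per frame, nm, one array per trajectory.
    dt : float
        Frame spacing in ns.
    dgol : optional list of 1-D arrays
        Glycan-to-opposite-lobe minimum distance per frame, nm.
    states : optional list of 1-D int arrays
        Hidden generating states when the ensemble is synthetic (0 = open,
        1 = closed); used only by oracles and tests.
    """

    d: list[np.ndarray]
    dt: float = 0.2
    dgol: list[np.ndarray] | None = None
    states: list[np.ndarray] | None = None
    label: str = ""
    trajectory_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        self.d = [np.asarray(x, dtype=float) for x in self.d]
        for arr in self.d:
            if np.any(arr <= 0):
                raise ValueError("order parameter d must be positive")
        if self.dgol is not None and len(self.dgol) != len(self.d):
            raise ValueError("dgol must have one series per trajectory")
        if not self.trajectory_ids:
            self.trajectory_ids = [f"traj{i:04d}" for i in range(len(self.d))]

    @property
    def n_traj(self) -> int:
        return len(self.d)

    @property
    def n_frames_total(self) -> int:
        return int(sum(len(x) for x in self.d))

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.d) if self.d else np.empty(0)

    def subset(self, indices) -> "ScalarEnsemble":
        """New ensemble containing the given trajectories (with repetition
        allowed — used by trajectory-level bootstrap resampling)."""
        indices = list(indices)
        return ScalarEnsemble(
            d=[self.d[i] for i in indices],
            dt=self.dt,
            dgol=[self.dgol[i] for i in indices] if self.dgol is not None else None,
            states=[self.states[i] for i in indices] if self.states is not None else None,
            label=self.label,
            trajectory_ids=[self.trajectory_ids[i] for i in indices],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, arr in enumerate(self.d):
            df = pd.DataFrame(
                {
                    "trajectory_id": self.trajectory_ids[t],
                    "frame_index": np.arange(len(arr)),
                    "time_ns": np.arange(len(arr)) * self.dt,
                    "d_nm": arr,
                }
            )
            if self.dgol is not None:
                df["dgol_nm"] = self.dgol[t]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt: float | None = None, label: str = "") -> "ScalarEnsemble":
        ids = list(dict.fromkeys(df["trajectory_id"]))
        d, dgol = [], []
        has_dgol = "dgol_nm" in df.columns
        for tid in ids:
            sub = df[df["trajectory_id"] == tid].sort_values("frame_index")
            d.append(sub["d_nm"].to_numpy())
            if has_dgol:
                dgol.append(sub["dgol_nm"].to_numpy())
        if dt is None:
            times = df[df["trajectory_id"] == ids[0]].sort_values("frame_index")["time_ns"].to_numpy()
            dt = float(times[1] - times[0]) if len(times) > 1 else 0.2
        return cls(d=d, dt=dt, dgol=dgol if has_dgol else None, label=label, trajectory_ids=[str(i) for i in ids])

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "ScalarEnsemble":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"), label=label)
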