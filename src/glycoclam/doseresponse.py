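"""Hill-function fitting of glycine dose-response curves and group
comparison of EC50 values (wild-type vs glycosylation-deficient mutant).

The response model is I(c) = Imax * c^h / (EC50^h + c^h): Imax is the
maximal current, EC50 the half-maximal agonist concentration (uM) and h the
Hill coefficient. Curves are normalized to the observed maximum by default,
fitted per curve by unweighted least squares, and groups compared with an
equal-variance two-sample Student's t-test on the per-curve EC50 values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "GroupComparison",
    "hill",
    "normalize_curve",
    "fit_hill",
    "compare_groups",
]


def hill(c: np.ndarray, ec50: float, h: float, imax: float) -> np.ndarray:
    """Hill response at concentration(s) c."""
    c = np.asarray(c, dtype=float)
    return imax * c**h / (ec50**h + c**h)


@dataclass
class DoseResponseCurve:
    curve_id: str
    concentrations: np.ndarray  # uM, strictly increasing and positive
    currents: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.concentrations) != len(self.currents):
            raise ValueError("concentrations and currents must have equal length")


@dataclass
class HillFit:
    ec50: float  # uM
    hill_coefficient: float
    imax: float
    residual_sum_squares: float
    converged: bool
    message: str = ""


@dataclass
class GroupComparison:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    percent_change: float  # 100 * (mean_b - mean_a) / mean_a
    t_statistic: float
    p_value: float
    on_log_scale: bool = False


def normalize_curve(curve: DoseResponseCurve, mode: str = "observed") -> DoseResponseCurve:
    """Divide currents by the maximum response.

    mode "observed" (default) uses the largest measured current; mode
    "fitted" uses the Imax of a Hill fit to the raw curve.
    """
    if mode == "observed":
        peak = float(curve.currents.max())
    elif mode == "fitted":
        peak = fit_hill(replace(curve, normalized=True)).imax
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if peak <= 0:
        raise ValueError(f"curve {curve.curve_id}: nonpositive maximum current ({peak})")
    return DoseResponseCurve(
        curve_id=curve.curve_id,
        concentrations=curve.concentrations.copy(),
        currents=curve.currents / peak,
        normalized=True,
    )


def fit_hill(curve: DoseResponseCurve, h_bounds: tuple[float, float] = (0.2, 5.0)) -> HillFit:
    """Least-squares Hill fit of a normalized curve.

    Initialization: EC50 at the geometric mean of the concentrations, h = 1,
    Imax at the maximum response. Non-convergence is reported on the returned
    fit, never raised.
    """
    c, y = curve.concentrations, curve.currents
    if len(c) < 4:
        raise ValueError(f"curve {curve.curve_id}: need >= 4 points to fit, got {len(c)}")
    p0 = [float(np.exp(np.mean(np.log(c)))), 1.0, float(y.max())]
    bounds = ([1e-9, h_bounds[0], 1e-9], [np.inf, h_bounds[1], np.inf])
    try:
        popt, _ = optimize.curve_fit(hill, c, y, p0=p0, bounds=bounds, maxfev=20000)
        rss = float(np.sum((y - hill(c, *popt)) ** 2))
        return HillFit(
            ec50=float(popt[0]),
            hill_coefficient=float(popt[1]),
            imax=float(popt[2]),
            residual_sum_squares=rss,
            converged=True,
        )
    except RuntimeError as exc:
        return HillFit(
            ec50=float("nan"),
            hill_coefficient=float("nan"),
            imax=float("nan"),
            residual_sum_squares=float("nan"),
            converged=False,
            message=str(exc),
        )


def compare_groups(
    fits_a: list[HillFit], fits_b: list[HillFit], log_scale: bool = False
) -> GroupComparison:
    """Equal-variance Student's t-test on per-curve EC50 between two groups.

    percent_change is the change of group b relative to group a; a 50%
    increase in EC50 of the mutant over wild-type appears as +50. Set
    ``log_scale`` to test log-EC50 instead (the group means and percent
    change stay on the linear scale).
    """
    a = np.array([f.ec50 for f in fits_a if f.converged])
    b = np.array([f.ec50 for f in fits_b if f.converged])
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 converged fits per group (got {len(a)} and {len(b)})")
    ta, tb = (np.log(a), np.log(b)) if log_scale else (a, b)
    t_stat, p = sps.ttest_ind(ta, tb, equal_var=True)
    return GroupComparison(
        mean_a=float(a.mean()),
        sem_a=float(sps.sem(a)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sem_b=float(sps.sem(b)),
        n_b=len(b),
        percent_change=float(100.0 * (b.mean() - a.mean()) / a.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        on_log_scale=log_scale,
    )
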