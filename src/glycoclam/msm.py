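"""Markov state models and tICA for order-parameter trajectory ensembles.

The estimator grid mirrors the standard practice for LBD clamshell dynamics:
k-means discretization of the 1-D clamshell coordinate (k = 99 or 6),
sliding-window transition counting at a fixed lag (128 or 256 ns), ergodic
trimming to the largest strongly connected set, maximum-likelihood
transition-matrix estimation (reversible by default), and implied timescales
t_i = -lag / ln(lambda_i). tICA provides an independent timescale estimate
from time-lagged covariances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .ensembles import ScalarEnsemble

__all__ = [
    "ClusterModel",
    "CountMatrix",
    "MSModel",
    "TICAModel",
    "cluster_features",
    "count_transitions",
    "largest_connected_set",
    "estimate_transition_matrix",
    "implied_timescales",
    "slowest_timescale",
    "its_convergence",
    "tica_timescales",
]


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterModel:
    """k-means cluster definitions with a deterministic assignment rule:
    nearest centre, Euclidean, ties broken by lowest centre index."""

    k: int
    centers: np.ndarray  # (k, n_features)
    seed: int

    def assign(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if self.centers.shape[1] == 1:
            # 1-D: exact nearest centre via sorted midpoints (fast and
            # reproducible; argmin over midpoints ties to the lower index).
            order = np.argsort(self.centers[:, 0], kind="stable")
            sorted_centers = self.centers[order, 0]
            mids = 0.5 * (sorted_centers[1:] + sorted_centers[:-1])
            pos = np.searchsorted(mids, x[:, 0], side="right")
            return order[pos]
        labels = np.empty(len(x), dtype=int)
        for start in range(0, len(x), 65536):
            chunk = x[start : start + 65536]
            d2 = ((chunk[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
            labels[start : start + len(chunk)] = np.argmin(d2, axis=1)
        return labels


def _as_feature_list(data) -> list[np.ndarray]:
    if isinstance(data, ScalarEnsemble):
        return [np.asarray(x, dtype=float)[:, None] for x in data.d]
    out = []
    for x in data:
        x = np.asarray(x, dtype=float)
        out.append(x[:, None] if x.ndim == 1 else x)
    return out


def cluster_features(data, k: int, seed: int) -> tuple[ClusterModel, list[np.ndarray]]:
    """Discretize trajectories into k states by seeded k-means.

    Parameters
    ----------
    data : ScalarEnsemble or list of per-trajectory feature arrays
    k : number of clusters
    seed : RNG seed for k-means++ initialisation (deterministic output)

    Returns the fitted :class:`ClusterModel` and one discrete trajectory
    (int labels, frame order) per input trajectory.
    """
    feats = _as_feature_list(data)
    stacked = np.concatenate(feats, axis=0)
    if len(stacked) < k:
        raise ValueError(f"total frames ({len(stacked)}) < k ({k})")
    n_distinct = len(np.unique(stacked, axis=0))
    if n_distinct < k:
        raise ValueError(f"k ({k}) exceeds the number of distinct feature values ({n_distinct})")
    km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(stacked)
    model = ClusterModel(k=k, centers=np.asarray(km.cluster_centers_, dtype=float), seed=seed)
    dtrajs = [model.assign(f) for f in feats]
    return model, dtrajs


# ---------------------------------------------------------------------------
# counting and trimming


@dataclass
class CountMatrix:
    counts: np.ndarray  # (k, k) nonnegative integers, sliding-window counts
    lag_frames: int
    lag_ns: float
    state_labels: np.ndarray = field(default=None)  # original state index per row

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.state_labels is None:
            self.state_labels = np.arange(self.counts.shape[0])

    @property
    def k(self) -> int:
        return self.counts.shape[0]


def count_transitions(dtrajs: list[np.ndarray], lag_frames: int, dt: float = 0.2) -> CountMatrix:
    """Sliding-window transition counts at the given lag.

    For each trajectory, every pair (s_t, s_{t+lag}) contributes one count.
    Trajectories not longer than the lag are skipped with a warning; if all
    are too short, an error is raised.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    n_states = max(int(d.max()) for d in dtrajs if len(d)) + 1
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    skipped = 0
    for d in dtrajs:
        if len(d) <= lag_frames:
            skipped += 1
            continue
        np.add.at(counts, (d[:-lag_frames], d[lag_frames:]), 1)
    if skipped == len(dtrajs):
        raise ValueError(f"all {skipped} trajectories are shorter than the lag ({lag_frames} frames)")
    if skipped:
        warnings.warn(f"skipped {skipped} trajectories shorter than the lag", UserWarning, stacklevel=2)
    return CountMatrix(counts=counts, lag_frames=lag_frames, lag_ns=lag_frames * dt)


def largest_connected_set(count_matrix: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Trim to the strongly connected component with maximal total counts.

    Returns the trimmed count matrix and the retained original state indices
    (the active set, which doubles as the old->new index mapping).
    """
    C = count_matrix.counts
    adjacency = (C > 0).astype(np.int8)
    n_comp, labels = connected_components(adjacency, directed=True, connection="strong")
    best, best_counts = 0, -1
    for comp in range(n_comp):
        members = np.where(labels == comp)[0]
        total = C[np.ix_(members, members)].sum()
        if total > best_counts:
            best, best_counts = comp, total
    active = np.where(labels == best)[0]
    trimmed = C[np.ix_(active, active)]
    return (
        CountMatrix(
            counts=trimmed,
            lag_frames=count_matrix.lag_frames,
            lag_ns=count_matrix.lag_ns,
            state_labels=count_matrix.state_labels[active],
        ),
        count_matrix.state_labels[active],
    )


# ---------------------------------------------------------------------------
# transition-matrix estimation


@dataclass
class MSModel:
    """Estimated Markov state model at a fixed lag time.

    eigenvalues are sorted descending; lambda_1 = 1 corresponds to the
    stationary process. Implied timescales are defined for eigenvalues
    strictly inside (0, 1).
    """

    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    eigenvalues: np.ndarray
    lag_ns: float
    active_set: np.ndarray
    reversible: bool

    @property
    def k(self) -> int:
        return self.transition_matrix.shape[0]


def _reversible_mle(C: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Detailed-balance maximum-likelihood transition matrix by the standard
    fixed-point iteration on the symmetric count variables x_ij."""
    C = C.astype(float)
    Csym = C + C.T
    c_i = C.sum(axis=1)
    x = Csym.copy()  # feasible start
    for _ in range(max_iter):
        x_i = x.sum(axis=1)
        q = c_i / x_i
        denom = q[:, None] + q[None, :]
        x_new = np.where(Csym > 0, Csym / denom, 0.0)
        x_new_i = x_new.sum(axis=1)
        delta = np.max(np.abs(x_new_i - x_i) / np.maximum(x_i, 1e-300))
        x = x_new
        if delta < tol:
            T = x / x.sum(axis=1)[:, None]
            return T
    raise RuntimeError(
        f"reversible MLE did not converge in {max_iter} iterations (residual {delta:.3e})"
    )


def _stationary_from_T(T: np.ndarray) -> np.ndarray:
    vals, vecs = scipy.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _eigenvalues(T: np.ndarray, pi: np.ndarray, reversible: bool) -> np.ndarray:
    if reversible:
        # similarity transform to a symmetric matrix: real spectrum guaranteed
        sqrt_pi = np.sqrt(pi)
        S = sqrt_pi[:, None] * T / sqrt_pi[None, :]
        vals = scipy.linalg.eigvalsh(0.5 * (S + S.T))
    else:
        vals = np.real(scipy.linalg.eigvals(T))
    return np.sort(vals)[::-1]


def estimate_transition_matrix(
    count_matrix: CountMatrix,
    reversible: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1_000_000,
) -> MSModel:
    """Estimate a row-stochastic transition matrix from (connected) counts.

    Non-reversible mode row-normalizes the counts; reversible mode (default)
    maximizes the likelihood under detailed balance via fixed-point iteration,
    converged when the max relative change drops below ``tol``. The stationary
    distribution comes from the detailed-balance weights (reversible) or the
    leading left eigenvector (non-reversible).
    """
    trimmed, active = largest_connected_set(count_matrix)
    C = trimmed.counts.astype(float)
    if reversible:
        T = _reversible_mle(C, tol=tol, max_iter=max_iter)
        pi = _stationary_from_T(T)
    else:
        T = C / C.sum(axis=1)[:, None]
        pi = _stationary_from_T(T)
    eigenvalues = _eigenvalues(T, pi, reversible)
    return MSModel(
        transition_matrix=T,
        stationary_distribution=pi,
        eigenvalues=eigenvalues,
        lag_ns=count_matrix.lag_ns,
        active_set=active,
        reversible=reversible,
    )


def implied_timescales(model: MSModel) -> np.ndarray:
    """Implied timescales t_i = -lag / ln(lambda_i) in ns, for the non-unit
    eigenvalues sorted descending.

    Eigenvalues >= 1 map to +inf (no finite relaxation); eigenvalues <= 0
    have no defined timescale and map to NaN (the undefined flag).
    """
    lam = model.eigenvalues[1:]  # drop the stationary eigenvalue
    out = np.full(lam.shape, np.nan)
    out[lam >= 1.0] = np.inf
    good = (lam > 0.0) & (lam < 1.0)
    out[good] = -model.lag_ns / np.log(lam[good])
    return out


def slowest_timescale(model: MSModel) -> float:
    """Largest finite implied timescale (ns); NaN if none is defined."""
    ts = implied_timescales(model)
    finite = ts[np.isfinite(ts)]
    return float(finite.max()) if len(finite) else float("nan")


# ---------------------------------------------------------------------------
# tICA


@dataclass
class TICAModel:
    lag_ns: float
    cov_instantaneous: np.ndarray
    cov_lagged: np.ndarray  # symmetrized
    eigenvalues: np.ndarray  # sorted descending
    components: np.ndarray  # columns are tICs
    timescales: np.ndarray  # ns; NaN where undefined

    @property
    def slowest_timescale(self) -> float:
        finite = self.timescales[np.isfinite(self.timescales)]
        return float(finite.max()) if len(finite) else float("nan")


def tica_timescales(data, lag_frames: int, dt: float = 0.2, epsilon: float = 1e-10) -> TICAModel:
    """Time-lagged independent component analysis over an ensemble.

    Mean-free instantaneous and symmetrized time-lagged covariances are
    accumulated across trajectories (no cross-trajectory pairs), the
    generalized eigenproblem C_tau v = lambda C_0 v is solved, and timescales
    follow t = -lag / ln(lambda) for eigenvalues in (0, 1). Eigenvalues
    outside (0, 1) are flagged undefined (NaN).
    """
    if isinstance(data, ScalarEnsemble):
        dt = data.dt
    feats = _as_feature_list(data)
    usable = [f for f in feats if len(f) >= lag_frames + 2]
    if not usable:
        raise ValueError("no trajectory has >= 2 frames beyond the lag")

    # global mean over all frames entering either covariance
    total = np.zeros(usable[0].shape[1])
    n = 0
    for f in usable:
        x0, xt = f[:-lag_frames], f[lag_frames:]
        total += x0.sum(axis=0) + xt.sum(axis=0)
        n += 2 * len(x0)
    mean = total / n

    dim = usable[0].shape[1]
    C0 = np.zeros((dim, dim))
    Ct = np.zeros((dim, dim))
    for f in usable:
        x0 = f[:-lag_frames] - mean
        xt = f[lag_frames:] - mean
        C0 += x0.T @ x0 + xt.T @ xt
        Ct += x0.T @ xt + xt.T @ x0
    C0 /= n
    Ct /= n

    try:
        vals, vecs = scipy.linalg.eigh(Ct, C0 + epsilon * np.eye(dim))
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular instantaneous covariance; increase the regularization epsilon "
            f"(currently {epsilon:g})"
        ) from exc
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    timescales = np.full(vals.shape, np.nan)
    good = (vals > 0.0) & (vals < 1.0)
    timescales[good] = -lag_frames * dt / np.log(vals[good])
    return TICAModel(
        lag_ns=lag_frames * dt,
        cov_instantaneous=C0,
        cov_lagged=Ct,
        eigenvalues=vals,
        components=vecs,
        timescales=timescales,
    )


# ---------------------------------------------------------------------------
# estimator grid


def its_convergence(
    data,
    lags_ns: list[float],
    k: int,
    seed: int,
    dt: float | None = None,
    reversible: bool = True,
) -> pd.DataFrame:
    """Slowest implied timescale versus lag for one cluster count.

    Returns a table with one row per lag: estimator, k, lag_ns,
    slowest_timescale_ns. For exactly Markovian input the timescale is flat
    in the lag up to estimator noise.
    """
    if isinstance(data, ScalarEnsemble):
        dt = data.dt
    if dt is None:
        raise ValueError("dt required when data is not a ScalarEnsemble")
    _, dtrajs = cluster_features(data, k=k, seed=seed)
    rows = []
    for lag_ns in lags_ns:
        lag_frames = int(round(lag_ns / dt))
        cm = count_transitions(dtrajs, lag_frames, dt=dt)
        model = estimate_transition_matrix(cm, reversible=reversible)
        rows.append(
            {
                "estimator": "MSM",
                "k": k,
                "lag_ns": lag_ns,
                "slowest_timescale_ns": slowest_timescale(model),
            }
        )
    return pd.DataFrame(rows)
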