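"""Two-state hidden-Markov idealization of constant-separation trajectories.

A filtered extension-time trace that flickers between a membrane-bound
(low extension) and an unbound (high extension) level is modeled as a
two-state Markov chain with Gaussian emissions of state-dependent mean and
variance.  Baum-Welch EM (via :mod:`hmmlearn`) yields the maximum-likelihood
levels, the per-step transition matrix (converted to continuous-time binding
and unbinding rates), and state occupancies; the Viterbi algorithm gives the
idealized state path from which dwell times and per-state mean forces are
derived.

State convention: index 0 = bound (lower extension), 1 = unbound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .trajectory import Trajectory

__all__ = [
    "TwoStateHMMFit",
    "GaussianMixtureFit",
    "fit_two_state_hmm",
    "viterbi_idealize",
    "extension_histogram",
    "state_mean_forces",
    "dwell_times",
]

BOUND, UNBOUND = 0, 1


class _TraceMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the full log-likelihood trace."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.trace: List[float] = []

    def _reset(self):
        self.trace = []
        return super()._reset()

    def report(self, log_prob):
        self.trace.append(float(log_prob))
        super().report(log_prob)


@dataclass
class TwoStateHMMFit:
    """Maximum-likelihood two-state description of one trajectory."""

    state_means: np.ndarray  # nm, (bound, unbound)
    state_stds: np.ndarray  # nm
    k_b: float  # binding rate (unbound -> bound), s^-1
    k_ub: float  # unbinding rate (bound -> unbound), s^-1
    unbinding_probability: float  # posterior-mean occupancy of the unbound state
    occupancy_viterbi: float  # Viterbi-path occupancy of the unbound state
    extension_change: float  # unbound mean - bound mean, nm
    state_mean_forces: Tuple[float, float, float]  # (bound, unbound, mean), pN
    viterbi_path: np.ndarray  # per-sample labels (0 bound / 1 unbound)
    log_likelihood: float
    log_likelihood_trace: List[float]
    sampling_rate: float
    transition_matrix: np.ndarray  # per-step
    degenerate: bool = False
    _order: Tuple[int, int] = (0, 1)
    _model: Optional[GaussianHMM] = field(default=None, repr=False)


def _rates_from_transmat(transmat: np.ndarray, dt: float) -> Tuple[float, float]:
    """Continuous-time (k_b, k_ub) from a per-step 2x2 transition matrix.

    Uses the exact 2-state matrix logarithm when it exists (second
    eigenvalue in (0, 1)); otherwise falls back to k = p / dt.
    """
    a = transmat[BOUND, UNBOUND]  # bound -> unbound step probability
    b = transmat[UNBOUND, BOUND]  # unbound -> bound
    lam = 1.0 - a - b
    if 0.0 < lam < 1.0 and (a + b) > 0:
        c = -math.log(lam) / ((a + b) * dt)
        return c * b, c * a
    return b / dt, a / dt


def fit_two_state_hmm(
    traj: Trajectory,
    init: Optional[dict] = None,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-3,
) -> TwoStateHMMFit:
    """Fit a two-state Gaussian-emission HMM to a (filtered) trajectory.

    EM restarts ``n_restarts`` times from a k-means split with perturbed
    kinetics; the best likelihood wins, ties broken by the lower unbinding
    rate.  Emission variances are independent per state (membrane-side
    noise is state-dependent and never pooled).
    """
    x = traj.extension.reshape(-1, 1)
    if len(traj) < 100:
        raise ValueError("need at least 100 samples to fit a two-state HMM")
    rng = np.random.default_rng(seed)

    km = KMeans(n_clusters=2, n_init=3, random_state=int(rng.integers(2**31 - 1)))
    km_labels = km.fit_predict(x)
    centers = np.sort(km.cluster_centers_.ravel())
    pooled_std = float(
        np.sqrt(
            np.mean(
                [
                    np.var(x[km_labels == k]) if np.any(km_labels == k) else 0.0
                    for k in (0, 1)
                ]
            )
        )
    )
    if init and "state_means" in init:
        centers = np.sort(np.asarray(init["state_means"], dtype=float))

    best = None
    for _ in range(max(n_restarts, 1)):
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            init_params="",
            params="stmc",
            n_iter=max_iter,
            tol=tol,
            random_state=int(rng.integers(2**31 - 1)),
        )
        model.monitor_ = _TraceMonitor(model.tol, model.n_iter, model.verbose)
        model.startprob_ = np.array([0.5, 0.5])
        p = float(rng.uniform(0.005, 0.08))
        q = float(rng.uniform(0.005, 0.08))
        model.transmat_ = np.array([[1 - p, p], [q, 1 - q]])
        jitter = rng.normal(0.0, 0.05 * (centers[1] - centers[0] + 1e-9), size=2)
        model.means_ = (centers + jitter).reshape(2, 1)
        var0 = max(pooled_std**2, 1e-6)
        model.covars_ = np.full((2, 1), var0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x)
        ll = model.monitor_.trace[-1] if model.monitor_.trace else -np.inf
        converged = model.monitor_.converged
        kb, kub = _ordered_rates(model, 1.0 / traj.sampling_rate)
        cand = (ll, -kub, model, converged)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    ll, _, model, converged = best
    if not converged:
        err = RuntimeError(
            f"EM did not converge in {max_iter} iterations (best log-likelihood "
            f"{ll:.3f})"
        )
        err.log_likelihood_trace = list(model.monitor_.trace)
        raise err
    return _build_fit(model, traj, ll, list(model.monitor_.trace))


def _state_order(model: GaussianHMM) -> Tuple[int, int]:
    """(bound_index, unbound_index) in the raw model: bound = lower mean."""
    means = model.means_.ravel()
    return (0, 1) if means[0] <= means[1] else (1, 0)


def _ordered_rates(model: GaussianHMM, dt: float) -> Tuple[float, float]:
    b_i, u_i = _state_order(model)
    A = model.transmat_[np.ix_([b_i, u_i], [b_i, u_i])]
    return _rates_from_transmat(A, dt)


def _build_fit(
    model: GaussianHMM, traj: Trajectory, ll: float, trace: List[float]
) -> TwoStateHMMFit:
    x = traj.extension.reshape(-1, 1)
    b_i, u_i = _state_order(model)
    order = (b_i, u_i)
    means = model.means_.ravel()[list(order)]
    stds = np.sqrt(model.covars_.ravel()[list(order)])
    dt = 1.0 / traj.sampling_rate
    A = model.transmat_[np.ix_(list(order), list(order))]
    k_b, k_ub = _rates_from_transmat(A, dt)

    raw_path = model.predict(x)
    path = np.where(raw_path == u_i, UNBOUND, BOUND)
    posterior = model.predict_proba(x)
    p_ub = float(posterior[:, u_i].mean())
    occ_vit = float(np.mean(path == UNBOUND))

    gap = means[1] - means[0]
    pooled = math.sqrt(float(np.mean(stds**2)))
    degenerate = bool(gap < 0.1) or min(p_ub, 1 - p_ub) < 1e-4
    if degenerate:
        warnings.warn(
            "HMM fit is effectively single-state (levels closer than 0.1 nm or "
            "one state unoccupied)",
            RuntimeWarning,
            stacklevel=2,
        )
    elif gap < 0.5 * pooled:
        warnings.warn(
            "extension levels are poorly separated (gap < 0.5 pooled emission "
            "std); two-state fit may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    forces = state_mean_forces(traj, path)
    return TwoStateHMMFit(
        state_means=means,
        state_stds=stds,
        k_b=k_b,
        k_ub=k_ub,
        unbinding_probability=p_ub,
        occupancy_viterbi=occ_vit,
        extension_change=float(means[1] - means[0]),
        state_mean_forces=forces,
        viterbi_path=path,
        log_likelihood=ll,
        log_likelihood_trace=trace,
        sampling_rate=traj.sampling_rate,
        transition_matrix=A,
        degenerate=degenerate,
        _order=order,
        _model=model,
    )


def viterbi_idealize(traj: Trajectory, fit: TwoStateHMMFit) -> np.ndarray:
    """Most probable state path (0 bound / 1 unbound) for ``traj`` under ``fit``."""
    if fit._model is None:
        raise ValueError("fit carries no underlying model")
    raw = fit._model.predict(traj.extension.reshape(-1, 1))
    return np.where(raw == fit._order[1], UNBOUND, BOUND)


def dwell_times(path: np.ndarray, sampling_rate: float) -> Tuple[np.ndarray, np.ndarray]:
    """(bound, unbound) dwell durations in s from an idealized path.

    The first and last (censored) dwells are discarded.
    """
    path = np.asarray(path)
    change = np.flatnonzero(np.diff(path) != 0)
    if change.size < 2:
        return np.array([]), np.array([])
    starts = change[:-1] + 1
    ends = change[1:] + 1
    durations = (ends - starts) / sampling_rate
    states = path[starts]
    return durations[states == BOUND], durations[states == UNBOUND]


@dataclass
class GaussianMixtureFit:
    """Two-Gaussian description of the extension histogram."""

    means: np.ndarray  # nm, sorted ascending (bound, unbound)
    stds: np.ndarray  # nm
    weights: np.ndarray  # sum to 1; weights[1] ~ unbound occupancy
    degenerate: bool


def extension_histogram(traj: Trajectory, seed: int = 0) -> GaussianMixtureFit:
    """Fit the extension probability density with a sum of two Gaussians."""
    x = traj.extension.reshape(-1, 1)
    if len(traj) < 1000:
        raise ValueError("need at least 1000 samples for the mixture fit")
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed).fit(x)
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    stds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    gap = means[1] - means[0]
    # Ashman's D < 2 means the two Gaussians do not produce a bimodal density
    ashman_d = math.sqrt(2.0) * gap / math.sqrt(float(np.sum(stds**2)))
    degenerate = bool(gap < 0.1 or ashman_d < 2.0)
    if degenerate:
        warnings.warn(
            "mixture components unresolved (gap < 0.1 nm or Ashman's D < 2); "
            "histogram fit is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return GaussianMixtureFit(means=means, stds=stds, weights=weights, degenerate=degenerate)


def state_mean_forces(
    traj: Trajectory, labels: np.ndarray
) -> Tuple[float, float, float]:
    """Per-state mean forces and their unweighted mean, in pN.

    The mean of the bound- and unbound-state forces is the force coordinate
    used in all force-dependent plots.  If one state has no samples its
    force is NaN and the mean falls back to the global average (flagged by
    a warning).
    """
    labels = np.asarray(labels)
    if labels.size != len(traj):
        raise ValueError("labels must align with the trajectory")
    f_b = float(traj.force[labels == BOUND].mean()) if np.any(labels == BOUND) else np.nan
    f_u = (
        float(traj.force[labels == UNBOUND].mean()) if np.any(labels == UNBOUND) else np.nan
    )
    if np.isnan(f_b) or np.isnan(f_u):
        warnings.warn(
            "a state has no samples; mean force falls back to the global average",
            RuntimeWarning,
            stacklevel=2,
        )
        return f_b, f_u, float(traj.force.mean())
    return f_b, f_u, 0.5 * (f_b + f_u)
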