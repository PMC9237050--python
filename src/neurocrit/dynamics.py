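"""Stochastic 3-state whole-brain dynamics, threshold sweep, criticality profile.

Each node is inactive (I), active (A) or refractory (R).  Per synchronous
step: I -> A with probability 1 when the summed row-normalized weights of
active neighbours exceed the threshold T, otherwise with probability r1;
A -> R with probability 1; R -> I with probability r2.  Sweeping T over
[0, 0.2] and tracking the largest (S1) and second-largest (S2) cluster of
simultaneously active, structurally connected nodes localizes the critical
point T_c at the S2 peak; the curve integrals I1, I2 serve as
threshold-independent criticality indexes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from neurocrit._kernel import run_chain
from neurocrit.connectome import NormalizedConnectome

__all__ = [
    "STATE_I",
    "STATE_A",
    "STATE_R",
    "ModelParams",
    "CriticalityProfile",
    "PowerLawFit",
    "step_network",
    "simulate_trajectory",
    "simulate_sweep",
    "cluster_sizes",
    "find_critical_point",
    "classify_s2_monotonic",
    "integrate_profile",
    "profile_distance",
    "cluster_exponent",
    "fit_discrete_power_law",
]

STATE_I, STATE_A, STATE_R = 0, 1, 2


def default_t_grid() -> np.ndarray:
    """101 thresholds, step 0.002 over [0, 0.2]."""
    return np.round(np.arange(101) * 0.002, 6)


@dataclass
class ModelParams:
    """Simulation parameters; r1 defaults to 2/N and r2 to r1**(1/5)."""

    r1: Optional[float] = None
    r2: Optional[float] = None
    T_grid: np.ndarray = field(default_factory=default_t_grid)
    t_s: int = 2000
    burn_in: int = 100
    n_reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        if self.T_grid.ndim != 1 or np.any(np.diff(self.T_grid) <= 0):
            raise ValueError("T_grid must be strictly increasing")
        if not 0 <= self.burn_in < self.t_s:
            raise ValueError("burn_in must satisfy 0 <= burn_in < t_s")
        for r in (self.r1, self.r2):
            if r is not None and not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def resolve_rates(self, n_nodes: int) -> tuple[float, float]:
        r1 = 2.0 / n_nodes if self.r1 is None else self.r1
        r2 = r1 ** (1.0 / 5.0) if self.r2 is None else self.r2
        return float(r1), float(r2)


@dataclass
class CriticalityProfile:
    """Replicate-averaged threshold sweep curves and derived indexes."""

    T_grid: np.ndarray
    mean_A: np.ndarray
    sd_A: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    T_c: float = float("nan")
    I1: float = float("nan")
    I2: float = float("nan")
    monotonic_s2: bool = False
    n_nodes: int = 0
    subject_id: str = "unknown"
    timepoint: str = "t1"

    def curve(self, name: str) -> np.ndarray:
        return {"mean_A": self.mean_A, "sd_A": self.sd_A,
                "S1": self.S1, "S2": self.S2}[name]


def _chain_seed(seed: int, t_index: int, rep: int) -> int:
    """Independent deterministic stream per (subject seed, threshold, replicate)."""
    return int(np.random.SeedSequence((seed, t_index, rep)).generate_state(1)[0])


def step_network(
    states: np.ndarray,
    norm: NormalizedConnectome,
    T: float,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous update; input is computed from the given (previous) states."""
    r1, r2 = params.resolve_rates(norm.n_nodes)
    active = (states == STATE_A).astype(float)
    drive = norm.W_tilde @ active
    u = rng.random(states.shape[0])
    new = np.empty_like(states)
    is_a = states == STATE_A
    is_r = states == STATE_R
    is_i = states == STATE_I
    new[is_a] = STATE_R
    new[is_r] = np.where(u[is_r] < r2, STATE_I, STATE_R)
    fires = (drive > T) | (u < r1)
    new[is_i] = np.where(fires[is_i], STATE_A, STATE_I)
    return new


def simulate_trajectory(
    norm: NormalizedConnectome,
    T: float,
    params: ModelParams,
    seed: int = 0,
    initial_states: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Full state trajectory (t_s x N, int8) from a random initial configuration."""
    rng = np.random.default_rng(seed)
    n = norm.n_nodes
    if initial_states is None:
        states = rng.integers(0, 3, size=n).astype(np.int8)
    else:
        states = np.asarray(initial_states, dtype=np.int8).copy()
    out = np.empty((params.t_s, n), dtype=np.int8)
    for t in range(params.t_s):
        states = step_network(states, norm, T, params, rng)
        out[t] = states
    return out


def cluster_sizes(active_mask: np.ndarray, adjacency: np.ndarray) -> tuple[int, int]:
    """Largest and second-largest connected component among active nodes."""
    active = np.flatnonzero(active_mask)
    if active.size == 0:
        return 0, 0
    sub = adjacency[np.ix_(active, active)]
    _, labels = connected_components(csr_array(sub.astype(np.int8)), directed=False)
    counts = np.sort(np.bincount(labels))[::-1]
    s1 = int(counts[0])
    s2 = int(counts[1]) if counts.size > 1 else 0
    return s1, s2


def _kernel_inputs(norm: NormalizedConnectome):
    wt = csr_array(norm.W_tilde.T.copy())
    iu, ju = np.nonzero(np.triu(norm.adjacency, k=1))
    return (
        wt.indptr.astype(np.int64),
        wt.indices.astype(np.int64),
        wt.data.astype(np.float64),
        iu.astype(np.int64),
        ju.astype(np.int64),
    )


def simulate_sweep(
    norm: NormalizedConnectome, params: Optional[ModelParams] = None
) -> CriticalityProfile:
    """Run the full threshold sweep and populate the criticality profile.

    For every threshold, ``n_reps`` independent chains are run from random
    initial configurations; the first ``burn_in`` steps are discarded; the
    per-replicate time averages (and the per-replicate standard deviation of
    the instantaneous activity) are then averaged across replicates.
    """
    params = params or ModelParams()
    n = norm.n_nodes
    r1, r2 = params.resolve_rates(n)
    indptr, indices, data, eu, ev = _kernel_inputs(norm)
    grid = params.T_grid
    nT = grid.size
    mean_A = np.zeros(nT)
    sd_A = np.zeros(nT)
    S1 = np.zeros(nT)
    S2 = np.zeros(nT)
    for ti, T in enumerate(grid):
        for rep in range(params.n_reps):
            a, sd, s1, s2, _ = run_chain(
                indptr, indices, data, eu, ev, n, float(T), r1, r2,
                params.t_s, params.burn_in,
                _chain_seed(params.seed, ti, rep), False,
            )
            mean_A[ti] += a
            sd_A[ti] += sd
            S1[ti] += s1
            S2[ti] += s2
    for arr in (mean_A, sd_A, S1, S2):
        arr /= params.n_reps

    profile = CriticalityProfile(
        T_grid=grid.copy(), mean_A=mean_A, sd_A=sd_A, S1=S1, S2=S2,
        n_nodes=n, subject_id=norm.subject_id, timepoint=norm.timepoint,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile.T_c = find_critical_point(profile)
    profile.I1, profile.I2 = integrate_profile(profile)
    if grid.size >= 3:
        profile.monotonic_s2 = classify_s2_monotonic(profile)
    return profile


def find_critical_point(profile: CriticalityProfile) -> float:
    """Threshold maximizing the replicate-averaged S2 (ties -> smallest T)."""
    s2 = profile.S2
    if not np.any(s2 > 0):
        warnings.warn("S2 curve is all zero; critical point undefined", stacklevel=2)
        return float("nan")
    return float(profile.T_grid[int(np.argmax(s2))])


def classify_s2_monotonic(
    profile: CriticalityProfile, noise_cutoff: float = 0.07
) -> bool:
    """True when the S2 forward-difference sign is constant for T >= cutoff.

    Sign changes at thresholds below ``noise_cutoff`` are attributed to noise
    and ignored.  A monotonic S2 indicates the loss of the critical phase
    transition.
    """
    if profile.T_grid.size < 3:
        raise ValueError("S2 curve must have at least 3 points")
    diffs = np.diff(profile.S2)
    keep = profile.T_grid[:-1] >= noise_cutoff
    signs = np.sign(diffs[keep])
    signs = signs[signs != 0]
    return bool(signs.size == 0 or np.all(signs == signs[0]))


def integrate_profile(profile: CriticalityProfile) -> tuple[float, float]:
    """Trapezoidal integrals of S1 and S2 over the threshold grid."""
    i1 = float(np.trapezoid(profile.S1, profile.T_grid))
    i2 = float(np.trapezoid(profile.S2, profile.T_grid))
    return i1, i2


def profile_distance(
    profile: CriticalityProfile,
    reference_curve: np.ndarray,
    curve: str = "S2",
) -> float:
    """Euclidean distance between one profile curve and a reference curve."""
    ref = np.asarray(reference_curve, dtype=float)
    values = profile.curve(curve)
    if ref.shape != values.shape:
        raise ValueError("reference curve does not match the threshold grid")
    return float(np.sqrt(((values - ref) ** 2).sum()))


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    n_tail: int
    ks: float


def fit_discrete_power_law(
    sizes: Optional[np.ndarray] = None,
    counts: Optional[np.ndarray] = None,
    xmin: Optional[int] = None,
    alpha_bounds: tuple[float, float] = (1.01, 6.0),
    max_xmin: int = 32,
) -> PowerLawFit:
    """Discrete truncated power-law MLE with KS-optimal lower cutoff.

    The model is P(s) proportional to s**(-alpha) on the integer support
    [xmin, smax] where smax is the largest observed size (upper truncation
    absorbs the finite-size cutoff).  When ``xmin`` is not given it is
    selected by minimizing the Kolmogorov-Smirnov distance between the
    fitted model and the empirical tail distribution.

    Pass either raw observations ``sizes`` or a ``counts`` histogram where
    ``counts[s]`` is the number of clusters of size ``s``.
    """
    if counts is None:
        if sizes is None:
            raise ValueError("provide sizes or counts")
        sizes = np.asarray(sizes, dtype=np.int64)
        counts = np.bincount(sizes)
    counts = np.asarray(counts, dtype=np.int64)
    support = np.flatnonzero(counts)
    support = support[support >= 1]
    if support.size == 0:
        raise ValueError("no observations")
    smax = int(support.max())

    def _fit_at(x0: int) -> PowerLawFit:
        sup = support[support >= x0]
        n_tail = int(counts[sup].sum())
        logs = np.log(sup)
        w = counts[sup]

        def negll(alpha: float) -> float:
            # normalizer over [x0, smax]
            z = special.zeta(alpha, x0) - special.zeta(alpha, smax + 1)
            return alpha * float((w * logs).sum()) + n_tail * math.log(z)

        res = optimize.minimize_scalar(negll, bounds=alpha_bounds, method="bounded")
        alpha = float(res.x)
        # KS distance on the tail
        s_all = np.arange(x0, smax + 1, dtype=float)
        z = special.zeta(alpha, x0) - special.zeta(alpha, smax + 1)
        pmf = s_all ** (-alpha) / z
        model_cdf = np.cumsum(pmf)
        emp = np.zeros(smax + 1 - x0)
        emp[sup - x0] = counts[sup]
        emp_cdf = np.cumsum(emp) / n_tail
        ks = float(np.abs(model_cdf - emp_cdf).max())
        return PowerLawFit(alpha=alpha, xmin=x0, n_tail=n_tail, ks=ks)

    if xmin is not None:
        return _fit_at(int(xmin))

    best: Optional[PowerLawFit] = None
    for x0 in support[support <= max_xmin]:
        sup = support[support >= x0]
        if sup.size < 3 or counts[sup].sum() < 50:
            break
        fit = _fit_at(int(x0))
        if best is None or fit.ks < best.ks:
            best = fit
    if best is None:
        best = _fit_at(int(support[0]))
    return best


def cluster_exponent(
    norm: NormalizedConnectome,
    params: Optional[ModelParams] = None,
    T: Optional[float] = None,
    min_clusters: int = 100,
) -> float:
    """MLE exponent of the active-cluster size distribution at threshold T.

    Pools per-step cluster sizes across replicates; near the critical point
    the distribution follows a truncated power law with exponent ~3/2.
    Returns NaN (with a warning) when fewer than ``min_clusters`` clusters
    are pooled.
    """
    params = params or ModelParams()
    if T is None:
        raise ValueError("threshold T is required (use the detected T_c)")
    n = norm.n_nodes
    r1, r2 = params.resolve_rates(n)
    indptr, indices, data, eu, ev = _kernel_inputs(norm)
    hist = np.zeros(n + 1, dtype=np.int64)
    for rep in range(params.n_reps):
        *_, h = run_chain(
            indptr, indices, data, eu, ev, n, float(T), r1, r2,
            params.t_s, params.burn_in, _chain_seed(params.seed, 10**6, rep), True,
        )
        hist += h
    if hist.sum() < min_clusters:
        warnings.warn("too few pooled clusters for a power-law fit", stacklevel=2)
        return float("nan")
    return fit_discrete_power_law(counts=hist).alpha
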