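"""Statistical quality tests for an estimated Markov state model.

Two complementary checks of the Markov property:

* **Implied timescales (convergence analysis).**  For each candidate lag
  ``tau`` a transition matrix is re-estimated and its non-unit
  eigenvalue magnitudes are converted to relaxation timescales
  ``t_i(tau) = -tau / ln |lambda_i(tau)|``.  If the discretized process
  is Markovian the timescales are lag-independent, so the curves flatten
  ("converge") after a few lag steps; curves trapped in the cutoff
  region ``t <= tau`` indicate a discretization too coarse to resolve
  that process.  Magnitudes (not real parts) are used because the
  non-reversible estimator can produce complex spectra.

* **Chapman-Kolmogorov (CK) test.**  The model estimated at lag ``tau``
  is propagated, ``[T(tau)]^k``, and compared with models independently
  re-estimated at each longer lag, ``T(k tau)``, on the self-transition
  probabilities of the most metastable states.  Uncertainty bands come
  from a trajectory-level bootstrap; a Markovian discretization keeps
  the propagated curve inside the bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .msm_core import (
    DiscreteTrajectory,
    count_transitions,
    estimate_transition_matrix,
)

__all__ = [
    "ITSProfile",
    "CKResult",
    "implied_timescales",
    "timescales_from_matrix",
    "is_converged",
    "ck_test",
]

INFINITE_EIGENVALUE_TOL = 1e-12


@dataclass
class ITSProfile:
    """Relaxation timescales (frames) per lag; ragged rows are allowed
    since the active set can shrink at long lags.

    ``timescales[j][i]`` is the (i+2)-th slowest process at ``lags[j]``;
    entries are positive or ``inf`` (eigenvalue magnitude at 1 within
    tolerance).  The cutoff region is ``t <= tau``.
    """

    lags: np.ndarray
    timescales: list[np.ndarray]

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        for ts in self.timescales:
            if np.any(ts[np.isfinite(ts)] <= 0):
                raise ValueError("timescales must be positive or infinite")

    def curve(self, i: int) -> np.ndarray:
        """Timescale ``i`` (0 = slowest) across lags; NaN where absent."""
        return np.array(
            [ts[i] if i < ts.size else np.nan for ts in self.timescales]
        )

    @property
    def n_timescales(self) -> int:
        return max(ts.size for ts in self.timescales)


@dataclass
class CKResult:
    """Predicted vs estimated self-transition probabilities over k tau.

    ``predicted[s, k-1] = [T(tau)^k]`` and ``estimated[s, k-1] = T(k tau)``
    self-transition entries for the tested states; ``lower``/``upper``
    bound the bootstrap band of the estimate.  At k = 1 predicted and
    estimated coincide exactly by construction.
    """

    tested_states: np.ndarray
    steps: np.ndarray
    predicted: np.ndarray
    estimated: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    lag_frames: int

    def deviations(self) -> np.ndarray:
        return np.abs(self.predicted - self.estimated)

    def within_band(self) -> np.ndarray:
        """Boolean (state, step) grid: predicted inside the bootstrap band."""
        return (self.predicted >= self.lower) & (self.predicted <= self.upper)

    def passes(self) -> bool:
        ok = self.within_band()
        return bool(np.all(ok[np.isfinite(self.predicted) & np.isfinite(self.estimated)]))


def timescales_from_matrix(t: np.ndarray, lag_frames: int = 1, n_its: int | None = None) -> np.ndarray:
    """Implied timescales of a given transition matrix.

    Eigenvalue magnitudes are sorted descending; the unit eigenvalue is
    dropped and ``t_i = -lag / ln |lambda_i|``; magnitudes within 1e-12
    of 1 map to ``inf`` rather than overflowing.
    """
    t = np.asarray(t, dtype=float)
    mags = np.sort(np.abs(np.linalg.eigvals(t)))[::-1]
    mags = mags[1:]  # drop the stationary eigenvalue
    if n_its is not None:
        mags = mags[:n_its]
    out = np.empty_like(mags)
    for i, m in enumerate(mags):
        if m >= 1.0 - INFINITE_EIGENVALUE_TOL:
            out[i] = np.inf
        elif m <= 0.0:
            out[i] = np.nan  # relaxes within one lag step; unresolvable
        else:
            out[i] = -lag_frames / np.log(m)
    return out


def implied_timescales(
    dtrajs: Sequence[DiscreteTrajectory] | Sequence[np.ndarray],
    lags: Sequence[int] = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 1500),
    n_its: int | None = None,
) -> ITSProfile:
    """Estimate a model per lag and collect its relaxation timescales.

    Lags longer than every trajectory are dropped; disconnected count
    matrices are handled by the largest-SCC restriction inside the
    estimator.
    """
    arrays = [d.labels if isinstance(d, DiscreteTrajectory) else np.asarray(d, int) for d in dtrajs]
    max_len = max(a.size for a in arrays)
    usable = [int(l) for l in lags if l < max_len]
    if not usable:
        raise ValueError("every candidate lag exceeds the trajectory length")
    ts = []
    for lag in usable:
        model = estimate_transition_matrix(count_transitions(arrays, lag))
        ts.append(timescales_from_matrix(model.transition_matrix, lag, n_its=n_its))
    return ITSProfile(lags=np.array(usable), timescales=ts)


def is_converged(
    profile: ITSProfile,
    window: int = 3,
    rel_tol: float = 0.10,
) -> list[dict]:
    """Per-timescale convergence verdicts.

    Timescale ``i`` is converged at the first lag ``tau*`` where (a) its
    relative variation over the next ``window`` grid points is at most
    ``rel_tol`` and (b) the curve stays above the cutoff region
    ``t <= tau`` over that window.  Returns one dict per timescale with
    keys ``timescale_index``, ``converged`` and ``lag`` (None when the
    curve never settles or never leaves the cutoff region).
    """
    out = []
    lags = profile.lags
    for i in range(profile.n_timescales):
        curve = profile.curve(i)
        verdict = {"timescale_index": i, "converged": False, "lag": None}
        for j in range(len(lags) - window + 1):
            seg = curve[j : j + window]
            seg_lags = lags[j : j + window]
            if np.any(~np.isfinite(seg)):
                if np.all(np.isinf(seg)):  # flat at infinity still counts
                    if np.all(seg > seg_lags):
                        verdict = {"timescale_index": i, "converged": True, "lag": int(lags[j])}
                        break
                continue
            if np.any(seg <= seg_lags):  # inside the cutoff region t <= tau
                continue
            center = np.median(seg)
            if center <= 0:
                continue
            if (seg.max() - seg.min()) / center <= rel_tol:
                verdict = {"timescale_index": i, "converged": True, "lag": int(lags[j])}
                break
        out.append(verdict)
    return out


def _self_transitions_at(
    arrays: list[np.ndarray], lag: int, states: np.ndarray
) -> np.ndarray:
    """Self-transition probability of each requested state at one lag;
    NaN for states that drop out of the active/connected set."""
    out = np.full(states.size, np.nan)
    try:
        model = estimate_transition_matrix(count_transitions(arrays, lag))
    except ValueError:
        return out
    for i, s in enumerate(states):
        hits = np.flatnonzero(model.active_states == s)
        if hits.size:
            out[i] = model.transition_matrix[hits[0], hits[0]]
    return out


def ck_test(
    dtrajs: Sequence[DiscreteTrajectory] | Sequence[np.ndarray],
    lag_frames: int,
    n_steps: int = 5,
    n_sets: int = 5,
    n_boot: int = 200,
    seed: int = 0,
    confidence: float = 0.95,
) -> CKResult:
    """Chapman-Kolmogorov test on the most metastable states.

    The ``n_sets`` states with the highest self-transition probability in
    the lag-``tau`` model are tracked; for each k = 1..``n_steps`` the
    propagated prediction ``[T(tau)^k]`` is compared with an independent
    estimate ``T(k tau)``, whose uncertainty band is the bootstrap
    percentile interval over trajectory resampling (fixed seed).
    """
    arrays = [d.labels if isinstance(d, DiscreteTrajectory) else np.asarray(d, int) for d in dtrajs]
    if n_steps < 1:
        raise ValueError("need at least one step")
    base = estimate_transition_matrix(count_transitions(arrays, lag_frames))
    n_avail = base.n_states
    if n_avail < n_sets:
        import warnings

        warnings.warn(
            f"only {n_avail} active states; testing all of them", stacklevel=2
        )
        n_sets = n_avail
    self_probs = np.diag(base.transition_matrix)
    order = np.argsort(-self_probs, kind="stable")[:n_sets]
    states = base.active_states[order]

    steps = np.arange(1, n_steps + 1)
    predicted = np.empty((n_sets, n_steps))
    estimated = np.empty((n_sets, n_steps))
    power = np.eye(n_avail)
    for k in steps:
        power = power @ base.transition_matrix
        for i, s in enumerate(states):
            predicted[i, k - 1] = power[base.state_index(s), base.state_index(s)]
        estimated[:, k - 1] = (
            np.diag(base.transition_matrix)[order]
            if k == 1
            else _self_transitions_at(arrays, k * lag_frames, states)
        )
    predicted[:, 0] = estimated[:, 0]  # identical by definition at k = 1

    rng = np.random.default_rng(seed)
    boot = np.full((n_boot, n_sets, n_steps), np.nan)
    n_traj = len(arrays)
    for b in range(n_boot):
        pick = rng.integers(n_traj, size=n_traj)
        sample = [arrays[p] for p in pick]
        for k in steps:
            boot[b, :, k - 1] = _self_transitions_at(sample, k * lag_frames, states)
    alpha = (1.0 - confidence) / 2.0
    with np.errstate(all="ignore"):
        lower = np.nanpercentile(boot, 100 * alpha, axis=0)
        upper = np.nanpercentile(boot, 100 * (1 - alpha), axis=0)
    return CKResult(
        tested_states=states,
        steps=steps,
        predicted=predicted,
        estimated=estimated,
        lower=lower,
        upper=upper,
        lag_frames=lag_frames,
    )
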