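"""Ground-truth synthetic trajectories from a hidden Markov chain.

The generator emulates the raw inputs of an MSM study: several
independent trajectories whose frames are noisy 3D conformations sampled
around per-state template structures, a hidden Markov chain with a known
transition matrix driving the state sequence, and a potential energy
recorded only every ``energy_stride`` frames (as when an expensive
implicit-solvent energy is evaluated on a subsample).

Emission happens in structure space — template coordinates plus
isotropic Gaussian noise, optionally rigidly rotated per frame — so the
featurization, basin-finding and clustering stages are all exercised by
the same data.  The energy is quadratic in the conformation-space
(USR feature) displacement from the template,
``e = base_energy[state] + curvature * |f(frame) - f(template)|^2``,
which makes each state's template the floor of one energy basin in the
very space where neighbor-graph distances are measured, so the basin
decomposition has a known ground truth of (essentially) one basin per
state.

What this emulates and what it does not: the data has genuinely
metastable, geometrically separated states, Markovian switching, and
stride-limited energies, but frames are temporally uncorrelated within a
state (no inertial or diffusive motion), the noise is isotropic rather
than along collective modes, and the energy is a clean function of
displacement with no thermal roughness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .featurize import kabsch_superpose, usr_feature_matrix
from .msm_core import stationary_distribution
from .trajectory_io import EnergyTable, StructureFrame, Trajectory

__all__ = [
    "SyntheticSpec",
    "make_templates",
    "generate",
    "sample_dtrajs",
    "match_labels",
    "matched_row_tv",
    "default_spec",
]


def _feature_spread(coords: np.ndarray, noise_sd: float, rng: np.random.Generator,
                    n_samples: int = 100) -> float:
    """Typical USR-feature displacement of a template under emission noise
    (root mean squared distance from the noise-free feature vector)."""
    if noise_sd <= 0:
        return 0.0
    noisy = coords[None] + rng.normal(scale=noise_sd, size=(n_samples, *coords.shape))
    f = usr_feature_matrix(noisy)
    f0 = usr_feature_matrix(coords[None])[0]
    return float(np.sqrt(np.mean(np.sum((f - f0) ** 2, axis=1))))


def make_templates(
    n_states: int,
    n_atoms: int = 50,
    seed: int = 0,
    min_rmsd: float = 2.0,
    noise_sd: float = 0.4,
    separability: float = 5.0,
    scale: float = 5.0,
    max_tries: int = 5000,
) -> list[StructureFrame]:
    """Random point-cloud templates, pairwise separated both in structure
    space (superposed RMSD >= ``min_rmsd`` Angstrom) and in USR feature
    space, where each pair must satisfy

        |f_i - f_j|  >=  separability * (spread_i + spread_j)

    with ``spread`` the RMS feature displacement a template suffers under
    emission noise of the given ``noise_sd`` (estimated by sampling).
    The default ratio of 5 makes state overlap in feature space
    negligible, so shape-based clustering can recover the states.

    Each cloud is an anisotropic Gaussian whose three axis scales are
    drawn independently (0.3x to 2x the nominal ``scale``), so templates
    differ in overall shape — oblate, prolate, compact — and not merely
    in atom placement; shape descriptors such as USR then separate them.
    Candidates violating either floor against an accepted template are
    rejected and resampled, so the returned set is separated by
    construction.
    """
    if n_states < 1 or n_atoms < 3:
        raise ValueError("need n_states >= 1 and n_atoms >= 3")
    rng = np.random.default_rng(seed)
    names = tuple(f"C{i}" if i % 5 else "CA" for i in range(n_atoms))
    templates: list[StructureFrame] = []
    feats: list[np.ndarray] = []
    spreads: list[float] = []
    tries = 0
    stale = 0
    while len(templates) < n_states:
        axes = scale * rng.uniform(0.3, 2.0, size=3)
        cand = rng.normal(size=(n_atoms, 3)) * axes
        cand_feat = usr_feature_matrix(cand[None])[0]
        cand_spread = _feature_spread(cand, noise_sd, rng)
        ok = all(
            kabsch_superpose(t.coords, cand)[2] >= min_rmsd
            and np.linalg.norm(f - cand_feat) >= separability * (s + cand_spread)
            for t, f, s in zip(templates, feats, spreads)
        )
        if ok:
            templates.append(StructureFrame(cand, names))
            feats.append(cand_feat)
            spreads.append(cand_spread)
            stale = 0
        else:
            stale += 1
            if stale > 500:  # early accepts can crowd shape space: restart
                templates.clear()
                feats.clear()
                spreads.clear()
                stale = 0
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not separate templates; lower the floors")
    return templates


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset.

    Defaults describe the package's standard study conditions: a 6-state
    chain with self-transition probability 0.9 and uniform off-diagonal
    mass, 12 independent trajectories, frames every 4 ps, energies every
    32nd frame, and emission noise 5x smaller than the 2 Angstrom
    template separation floor.
    """

    transition_matrix: np.ndarray
    templates: list[StructureFrame]
    noise_sd: float = 0.4
    base_energy: np.ndarray = field(default=None)  # type: ignore[assignment]
    energy_curvature: float = 0.05
    n_traj: int = 12
    n_frames: int = 1000
    frame_interval: float = 4.0
    energy_stride: int = 32
    rotate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition_matrix, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(t < 0) or np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("transition matrix must be row-stochastic")
        if len(self.templates) != t.shape[0]:
            raise ValueError("need one template per state")
        if self.base_energy is None:
            # deeper wells for earlier states; 1 kcal/mol spacing
            self.base_energy = -10.0 + np.arange(t.shape[0], dtype=float)
        self.base_energy = np.asarray(self.base_energy, dtype=float)
        if self.energy_stride < 1:
            raise ValueError("energy_stride must be >= 1")
        self.transition_matrix = t

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def uniform_chain(n_states: int, self_prob: float = 0.9) -> np.ndarray:
    """Row-stochastic matrix with constant self-transition probability and
    the remaining mass spread uniformly over the other states."""
    if not 0.0 <= self_prob <= 1.0:
        raise ValueError("self_prob must be a probability")
    if n_states == 1:
        return np.array([[1.0]])
    off = (1.0 - self_prob) / (n_states - 1)
    t = np.full((n_states, n_states), off)
    np.fill_diagonal(t, self_prob)
    return t


def default_spec(
    n_states: int = 6,
    self_prob: float = 0.9,
    n_traj: int = 12,
    n_frames: int = 1000,
    n_atoms: int = 50,
    seed: int = 0,
    **kwargs,
) -> SyntheticSpec:
    """Convenience constructor for the standard study conditions."""
    noise_sd = kwargs.get("noise_sd", 0.4)
    return SyntheticSpec(
        transition_matrix=uniform_chain(n_states, self_prob),
        templates=make_templates(n_states, n_atoms, seed=seed, noise_sd=noise_sd),
        n_traj=n_traj,
        n_frames=n_frames,
        seed=seed,
        **kwargs,
    )


def sample_dtrajs(
    transition_matrix: np.ndarray,
    n_traj: int,
    n_frames: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """State paths only (no structures): each trajectory starts from the
    stationary distribution and follows the chain independently."""
    t = np.asarray(transition_matrix, dtype=float)
    n_states = t.shape[0]
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(t)
    cdf = np.cumsum(t, axis=1)
    out = []
    for _ in range(n_traj):
        path = np.empty(n_frames, dtype=int)
        path[0] = rng.choice(n_states, p=pi)
        u = rng.random(n_frames)
        for i in range(1, n_frames):
            path[i] = np.searchsorted(cdf[path[i - 1]], u[i])
        out.append(path)
    return out


def generate(
    spec: SyntheticSpec,
) -> tuple[list[Trajectory], list[EnergyTable], list[np.ndarray]]:
    """Sample trajectories, stride-limited energy tables and true dtrajs.

    Unreachable or absorbing states in the chain are tolerated but
    warned about, since they starve the estimators of counts.
    """
    t = spec.transition_matrix
    reach = np.linalg.matrix_power((t > 0).astype(float) + np.eye(spec.n_states), spec.n_states)
    if np.any(reach == 0):
        import warnings

        warnings.warn("transition matrix is not irreducible; some states "
                      "may never be visited", stacklevel=2)
    dtrajs = sample_dtrajs(t, spec.n_traj, spec.n_frames, seed=spec.seed)
    template_coords = np.stack([f.coords for f in spec.templates])
    template_feats = usr_feature_matrix(template_coords)
    names = spec.templates[0].atom_names
    n_atoms = template_coords.shape[1]
    rng = np.random.default_rng(spec.seed + 1)
    trajs: list[Trajectory] = []
    tables: list[EnergyTable] = []
    for ti, path in enumerate(dtrajs):
        noise = rng.normal(scale=spec.noise_sd, size=(spec.n_frames, n_atoms, 3)) if spec.noise_sd > 0 else np.zeros((spec.n_frames, n_atoms, 3))
        coords = template_coords[path] + noise
        # energies only materialize at the stride, so featurize only there
        idx = np.arange(0, spec.n_frames, spec.energy_stride)
        feat_disp = usr_feature_matrix(coords[idx]) - template_feats[path[idx]]
        energies_at_idx = (
            spec.base_energy[path[idx]]
            + spec.energy_curvature * (feat_disp**2).sum(axis=1)
        )
        if spec.rotate:
            rots = Rotation.random(spec.n_frames, rng).as_matrix()
            shifts = rng.normal(scale=10.0, size=(spec.n_frames, 1, 3))
            coords = np.einsum("fij,fnj->fni", rots, coords) + shifts
        frames = [StructureFrame(coords[i], names) for i in range(spec.n_frames)]
        trajs.append(
            Trajectory(frames, frame_interval=spec.frame_interval, trajectory_id=f"synth-{ti:02d}")
        )
        tables.append(
            EnergyTable(idx, energies_at_idx, stride=spec.energy_stride)
        )
    return trajs, tables, dtrajs


def match_labels(est: np.ndarray, true: np.ndarray) -> dict[int, int]:
    """Optimal one-to-one map from estimated to true labels (Hungarian on
    the agreement/confusion matrix).  Surplus estimated labels map to -1."""
    est = np.asarray(est, int)
    true = np.asarray(true, int)
    if est.shape != true.shape:
        raise ValueError("label sequences must align")
    e_states = np.unique(est)
    t_states = np.unique(true)
    conf = np.zeros((e_states.size, t_states.size))
    e_idx = {s: i for i, s in enumerate(e_states)}
    t_idx = {s: i for i, s in enumerate(t_states)}
    for a, b in zip(est, true):
        conf[e_idx[a], t_idx[b]] += 1
    rows, cols = linear_sum_assignment(-conf)
    mapping = {int(e_states[r]): int(t_states[c]) for r, c in zip(rows, cols)}
    for s in e_states:
        mapping.setdefault(int(s), -1)
    return mapping


def matched_row_tv(
    t_est: np.ndarray,
    est_states: np.ndarray,
    t_true: np.ndarray,
    mapping: dict[int, int],
) -> float:
    """Max over rows of the total-variation distance between the estimated
    and true transition matrices after relabeling estimated states
    through ``mapping``.  Rows or columns without a counterpart count
    their full mass as error."""
    t_est = np.asarray(t_est, float)
    t_true = np.asarray(t_true, float)
    n_true = t_true.shape[0]
    worst = 0.0
    for i, s in enumerate(est_states):
        ti = mapping.get(int(s), -1)
        if ti < 0 or ti >= n_true:
            worst = max(worst, 1.0)
            continue
        row_true = t_true[ti]
        row_est = np.zeros(n_true)
        lost = 0.0
        for j, s2 in enumerate(est_states):
            tj = mapping.get(int(s2), -1)
            if 0 <= tj < n_true:
                row_est[tj] += t_est[i, j]
            else:
                lost += t_est[i, j]
        tv = 0.5 * (np.abs(row_est - row_true).sum() + lost)
        worst = max(worst, tv)
    return float(worst)
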