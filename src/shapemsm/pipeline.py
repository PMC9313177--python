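"""End-to-end MSM construction pipelines ("Settings").

Three standard recipes combine a featurizer with a macrostate method:

* **A** — CA-skip Cartesian features + energy-basin macrostates over the
  energy-bearing frames (superposed-RMSD distances);
* **B** — USR features + energy-basin macrostates over the
  energy-bearing frames (Euclidean distances);
* **C** — USR features on *all* frames + k-medoids macrostates with
  knee-selected k.

Each run estimates the transition model at the configured lag and
evaluates it with the implied-timescales and Chapman-Kolmogorov tests.
Settings A and B require per-trajectory energy tables; their discrete
trajectories live on the energy stride, so lags there are multiples of
``energy_stride`` source frames.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np

from . import featurize as _feat
from .landscape import assign_basins, build_knn_graph
from .macrostates import assign_states, knee_select
from .msm_core import (
    DiscreteTrajectory,
    count_transitions,
    estimate_transition_matrix,
    state_summary,
)
from .msm_validation import ck_test, implied_timescales, is_converged
from .trajectory_io import EnergyTable, Trajectory

__all__ = ["RunConfig", "ConfigurationError", "run_setting", "SettingReport"]

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised when a run configuration is internally inconsistent."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    ``setting`` picks featurizer + macrostate method; the remaining
    fields parameterize the individual stages.  ``its_lags`` and ``lag``
    are in frames of the discrete trajectories the setting produces
    (i.e. energy-stride units for A/B).
    """

    setting: str = "C"
    skip: int = 4
    selection: str = "all"
    knn_k: int = 10
    k_range: tuple[int, int] = (2, 25)
    n_restarts: int = 5
    lag: int = 1
    top_m: int = 6
    its_lags: tuple[int, ...] = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 1500)
    ck_steps: int = 5
    ck_sets: int = 5
    ck_bootstrap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.setting = self.setting.upper()
        if self.setting not in ("A", "B", "C"):
            raise ConfigurationError(f"unknown setting {self.setting!r}")

    def to_file(self, path: str | Path) -> None:
        """Flat key=value text representation (round-trips exactly)."""
        with Path(path).open("w") as fh:
            for f in fields(self):
                val = getattr(self, f.name)
                if isinstance(val, tuple):
                    val = ",".join(str(v) for v in val)
                fh.write(f"{f.name}={val}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        kwargs: dict = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name in ("k_range", "its_lags"):
                kwargs[f.name] = tuple(int(v) for v in val.split(","))
            elif f.name in ("setting", "selection"):
                kwargs[f.name] = val
            else:
                kwargs[f.name] = int(val)
        return cls(**kwargs)


@dataclass
class SettingReport:
    """Everything one pipeline run produced."""

    config: RunConfig
    model: object
    dtrajs: list[DiscreteTrajectory]
    its: object
    its_verdicts: list[dict]
    ck: object
    summary: object
    knee: object = None
    basins: object = None
    timings: dict[str, float] = field(default_factory=dict)


def _featurize_all(trajs, kind, skip, selection):
    return [
        _feat.featurize_trajectory(t, kind=kind, skip=skip, selection=selection)
        for t in trajs
    ]


def run_setting(
    config: RunConfig,
    trajectories: Sequence[Trajectory],
    energies: Sequence[EnergyTable] | None = None,
) -> SettingReport:
    """Execute one setting end-to-end and validate the resulting MSM."""
    tic = time.perf_counter()
    timings: dict[str, float] = {}
    if config.setting in ("A", "B") and energies is None:
        raise ConfigurationError(
            f"setting {config.setting} builds basins and requires energy tables"
        )
    kind = "ca_skip" if config.setting == "A" else "usr"
    feats = _featurize_all(trajectories, kind, config.skip, config.selection)
    timings["featurize"] = time.perf_counter() - tic

    knee = None
    basins = None
    tic = time.perf_counter()
    if config.setting == "C":
        pooled = np.vstack([f.matrix for f in feats])
        knee = knee_select(
            pooled,
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            seed=config.seed,
            n_restarts=config.n_restarts,
        )
        model_for_assign = knee.models[knee.knee_k]
        dtrajs = [assign_states(f, model_for_assign) for f in feats]
    else:
        # pool the energy-bearing rows across trajectories into one graph
        rows = []
        evals = []
        bounds = [0]
        for f, e in zip(feats, energies):
            rows.append(f.matrix[e.frame_indices])
            evals.append(e.energies)
            bounds.append(bounds[-1] + e.frame_indices.size)
        pooled = np.vstack(rows)
        pooled_e = np.concatenate(evals)
        metric = "rmsd" if config.setting == "A" else "euclidean"
        graph = build_knn_graph(pooled, pooled_e, k=config.knn_k, metric=metric)
        basins = assign_basins(graph)
        logger.info("setting %s: %d basins over %d vertices",
                    config.setting, basins.n_basins, graph.n_vertices)
        dtrajs = []
        for i, (f, e) in enumerate(zip(feats, energies)):
            labels = basins.frame_assignment[bounds[i] : bounds[i + 1]]
            dtrajs.append(
                DiscreteTrajectory(
                    labels=labels,
                    frame_interval=f.frame_interval * e.stride,
                    trajectory_id=f.source_id,
                )
            )
    timings["macrostates"] = time.perf_counter() - tic

    tic = time.perf_counter()
    counts = count_transitions(dtrajs, config.lag)
    model = estimate_transition_matrix(
        counts, frame_interval=dtrajs[0].frame_interval
    )
    summary = state_summary(model, top_m=config.top_m)
    timings["msm"] = time.perf_counter() - tic

    tic = time.perf_counter()
    max_len = max(len(d) for d in dtrajs)
    its = implied_timescales(dtrajs, [l for l in config.its_lags if l < max_len])
    verdicts = is_converged(its)
    ck = ck_test(
        dtrajs,
        config.lag,
        n_steps=config.ck_steps,
        n_sets=config.ck_sets,
        n_boot=config.ck_bootstrap,
        seed=config.seed,
    )
    timings["validation"] = time.perf_counter() - tic
    for stage, dt in timings.items():
        logger.info("setting %s: %s took %.2f s", config.setting, stage, dt)
    return SettingReport(
        config=config,
        model=model,
        dtrajs=dtrajs,
        its=its,
        its_verdicts=verdicts,
        ck=ck,
        summary=summary,
        knee=knee,
        basins=basins,
        timings=timings,
    )
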