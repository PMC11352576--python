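"""Two-state telegraph-process simulator for synthetic smFRET track data.

A FRET signal is modelled as a molecule switching between an *on* state
(receptor-ligand bond present, fluorophores alive) and an *off* state.  Dwell
times are exponential with decay times ``tau_app`` (on) and ``tau_off`` (off).
The on-state decay time at a given recording interval is set by the
photobleaching model, ``tau_app = tau_app_model(delta_t, tau_lt, c_b)``, so
simulated track lengths carry exactly the bias structure the analysis must
undo.

Trajectories are sampled stroboscopically: the state is evaluated at
``n_samples`` instants separated by ``delta_t``, starting after a burn-in
period that, together with an initial state drawn from the stationary
distribution, makes the observation window statistically stationary.  Each
maximal run of consecutive on-samples becomes one track observation; runs
still on at the final sample are right-censored.  Runs already on at the
first sample are *not* flagged: by memorylessness of the exponential their
remaining length is distributed like that of a fresh track.

``simulate_dataset`` uses a vectorized batch generator; the scalar functions
``simulate_state_trajectory`` and ``sample_trajectory`` are the readable
reference path and are statistically equivalent (the test suite checks this).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bleachfit import tau_app_model
from .exceptions import GenerationError
from .trackdata import TrackDataset, TrackObservation

__all__ = [
    "SimulationConfig",
    "StateTrajectory",
    "SampledTrajectory",
    "simulate_state_trajectory",
    "sample_trajectory",
    "simulate_dataset",
]

# study conditions: bond lifetime 10 s, bleaching constant 30 (typical
# experimental range), off-state decay 1000 s, 2000 s burn-in
@dataclass
class SimulationConfig:
    """Telegraph-process and sampling parameters for synthetic datasets.

    ``n_samples_per_dt`` overrides the observation-window length per recording
    interval; when absent, the window spans ``window_lifetimes`` apparent
    lifetimes (``n_samples = ceil(window_lifetimes * tau_app / delta_t)``), a
    deliberately short window producing a substantial censored fraction.
    """

    tau_lt: float = 10.0
    c_b: float = 30.0
    tau_off: float = 1000.0
    delta_t_set: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 3.0)
    n_samples_per_dt: Mapping[float, int] | None = None
    burn_in: float = 2000.0
    target_tracks_per_dt: int = 100
    min_frame_count: int = 1
    window_lifetimes: float = 6.0
    seed: int = 0
    max_trajectories: int = 50_000_000

    def __post_init__(self) -> None:
        for name in ("tau_lt", "c_b", "tau_off", "window_lifetimes"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        self.delta_t_set = tuple(float(dt) for dt in self.delta_t_set)
        if len(set(self.delta_t_set)) != len(self.delta_t_set):
            raise ValueError("delta_t_set entries must be distinct")
        if any(dt <= 0 for dt in self.delta_t_set):
            raise ValueError("delta_t_set entries must be positive")
        if self.target_tracks_per_dt < 1:
            raise ValueError("target_tracks_per_dt must be >= 1")

    def tau_app(self, delta_t: float) -> float:
        """Ground-truth on-state decay time at this recording interval."""
        return tau_app_model(delta_t, self.tau_lt, self.c_b)

    def n_samples(self, delta_t: float) -> int:
        if self.n_samples_per_dt is not None and delta_t in self.n_samples_per_dt:
            return int(self.n_samples_per_dt[delta_t])
        return math.ceil(self.window_lifetimes * self.tau_app(delta_t) / delta_t)


@dataclass
class StateTrajectory:
    """Alternating dwell durations; segment ``j`` is on iff ``initial_on XOR (j odd)``."""

    initial_on: bool
    durations: np.ndarray

    @property
    def total_time(self) -> float:
        return float(self.durations.sum())


@dataclass
class SampledTrajectory:
    """Maximal runs of consecutive on-samples with window-edge flags."""

    on_sample_runs: list[tuple[int, bool, bool]]  # (length, touches_start, touches_end)
    n_samples: int


def simulate_state_trajectory(
    tau_app: float,
    tau_off: float,
    total_time: float,
    rng: np.random.Generator,
    initial_on: bool | None = None,
) -> StateTrajectory:
    """Draw an alternating on/off trajectory covering at least ``total_time``.

    The initial state is drawn from the stationary distribution
    ``P(on) = tau_app / (tau_app + tau_off)`` unless forced via ``initial_on``.
    """
    if not (tau_app > 0 and tau_off > 0 and total_time > 0):
        raise ValueError("tau_app, tau_off and total_time must be positive")
    if initial_on is None:
        initial_on = bool(rng.random() < tau_app / (tau_app + tau_off))

    blocks: list[np.ndarray] = []
    covered = 0.0
    j0 = 0
    while covered < total_time:
        block = 16
        parity_odd = (np.arange(j0, j0 + block) % 2) == 1
        on_segment = parity_odd != initial_on  # XOR
        scales = np.where(on_segment, tau_app, tau_off)
        d = rng.standard_exponential(block) * scales
        blocks.append(d)
        covered += float(d.sum())
        j0 += block
        if j0 > 1_000_000:
            raise GenerationError("trajectory did not reach total_time")
    return StateTrajectory(initial_on=initial_on, durations=np.concatenate(blocks))


def _runs_from_bool(on: np.ndarray) -> list[tuple[int, bool, bool]]:
    n = on.size
    padded = np.zeros(n + 2, dtype=np.int8)
    padded[1:-1] = on
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [
        (int(e - s), bool(s == 0), bool(e == n)) for s, e in zip(starts, ends)
    ]


def sample_trajectory(
    trajectory: StateTrajectory,
    delta_t: float,
    n_samples: int,
    burn_in: float,
) -> SampledTrajectory:
    """Evaluate the state at ``burn_in + k*delta_t`` and extract on-runs."""
    times = burn_in + np.arange(n_samples) * delta_t
    cum = np.cumsum(trajectory.durations)
    if cum[-1] < times[-1]:
        raise ValueError("trajectory too short for the requested window")
    idx = np.searchsorted(cum, times, side="right")
    on = trajectory.initial_on ^ (idx % 2 == 1)
    return SampledTrajectory(on_sample_runs=_runs_from_bool(on), n_samples=n_samples)


def _simulate_runs_batch(
    n_traj: int,
    tau_on: float,
    tau_off: float,
    n_samples: int,
    delta_t: float,
    burn_in: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized equivalent of simulate + sample over ``n_traj`` trajectories.

    Returns (run_lengths, touches_start, touches_end) for all on-runs, ordered
    by trajectory then position.
    """
    p_on = tau_on / (tau_on + tau_off)
    init_on = rng.random(n_traj) < p_on
    total = burn_in + (n_samples - 1) * delta_t

    blocks: list[np.ndarray] = []
    ncols = 0
    cum_last = np.zeros(n_traj)
    while True:
        block = 12 if ncols == 0 else 6
        parity_odd = ((np.arange(ncols, ncols + block) % 2) == 1)[None, :]
        on_segment = parity_odd != init_on[:, None]
        scales = np.where(on_segment, tau_on, tau_off)
        d = rng.standard_exponential((n_traj, block)) * scales
        blocks.append(d)
        ncols += block
        cum_last = cum_last + d.sum(axis=1)
        if cum_last.min() >= total:
            break
        if ncols > 100_000:
            raise GenerationError("trajectories did not reach the window end")
    cum = np.cumsum(np.hstack(blocks), axis=1)

    times = burn_in + np.arange(n_samples) * delta_t
    on = np.empty((n_traj, n_samples), dtype=bool)
    # chunk rows to bound the (rows x segments x samples) comparison buffer
    chunk = max(1, int(8_000_000 // max(1, cum.shape[1] * n_samples)))
    for s in range(0, n_traj, chunk):
        c = cum[s : s + chunk]
        idx = (c[:, :, None] <= times[None, None, :]).sum(axis=1)
        on[s : s + chunk] = init_on[s : s + chunk, None] ^ (idx % 2 == 1)

    padded = np.zeros((n_traj, n_samples + 2), dtype=np.int8)
    padded[:, 1:-1] = on
    d = np.diff(padded, axis=1)
    start_rows, start_cols = np.nonzero(d == 1)
    _, end_cols = np.nonzero(d == -1)
    lengths = end_cols - start_cols
    return lengths, start_cols == 0, end_cols == n_samples


def simulate_dataset(config: SimulationConfig, delta_t: float) -> TrackDataset:
    """Simulate tracks at one recording interval until the target count is met.

    Each maximal on-run becomes one :class:`TrackObservation` with
    ``frame_count`` equal to the run length and ``right_censored`` set iff the
    run touches the window end.  The dataset is reproducible from
    ``config.seed`` and the recording interval's index in ``delta_t_set``.
    """
    if delta_t not in config.delta_t_set:
        raise ValueError(f"delta_t={delta_t} is not in the configured delta_t_set")
    dt_index = config.delta_t_set.index(delta_t)
    rng = np.random.default_rng([int(config.seed), dt_index])

    tau_on = config.tau_app(delta_t)
    n_samples = config.n_samples(delta_t)
    target = config.target_tracks_per_dt

    # expected on-runs per trajectory window, used only to size batches
    p_on = tau_on / (tau_on + config.tau_off)
    rate = p_on + (n_samples - 1) * (1 - p_on) * -math.expm1(
        -delta_t / config.tau_off
    )

    counts: list[np.ndarray] = []
    censored: list[np.ndarray] = []
    have = 0
    n_traj_total = 0
    while have < target:
        if n_traj_total >= config.max_trajectories:
            raise GenerationError(
                f"collected only {have}/{target} tracks after "
                f"{n_traj_total} trajectories"
            )
        need = target - have
        batch = min(
            int(need / max(rate, 1e-12) * 1.2) + 64,
            config.max_trajectories - n_traj_total,
        )
        lengths, _, touches_end = _simulate_runs_batch(
            batch, tau_on, config.tau_off, n_samples, delta_t,
            config.burn_in, rng,
        )
        n_traj_total += batch
        keep = lengths >= config.min_frame_count
        counts.append(lengths[keep])
        censored.append(touches_end[keep])
        have += int(keep.sum())

    all_counts = np.concatenate(counts)[:target]
    all_censored = np.concatenate(censored)[:target]
    obs = [
        TrackObservation(
            frame_count=int(c), right_censored=bool(z), track_id=f"sim-{i:06d}"
        )
        for i, (c, z) in enumerate(zip(all_counts, all_censored))
    ]
    return TrackDataset(
        delta_t=delta_t, min_frame_count=config.min_frame_count, observations=obs
    )
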