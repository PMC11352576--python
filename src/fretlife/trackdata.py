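"""Data model for censored single-molecule track observations and tabular I/O.

A single-molecule FRET track is summarised by the number of camera frames in
which the signal was detected (``frame_count``) and a flag stating whether the
signal was still present in the last frame of the observation window
(``right_censored``).  The observed duration of track *i* is
``t_i = (n_i - 1) * delta_t`` and is only meaningful in the context of the
dataset's recording interval ``delta_t``; it is therefore computed on demand
and never stored.

Tracks shorter than a minimum frame count ``n_min`` are discarded to guard
against short-lived noise; this introduces a left truncation at
``t_min = (n_min - 1) * delta_t`` which the survival likelihood conditions on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "TrackObservation",
    "TrackDataset",
    "ApparentLifetimeEstimate",
    "LifetimeFitResult",
    "read_track_table",
    "write_track_table",
    "apply_min_length_filter",
]

_REQUIRED_COLUMNS = ("track_id", "frame_count", "right_censored", "delta_t")
_BOOL_LITERALS = {"true": True, "false": False}


@dataclass(frozen=True)
class TrackObservation:
    """One smFRET track: frame count and whether it outlived the window."""

    frame_count: int
    right_censored: bool
    track_id: str = ""

    def __post_init__(self) -> None:
        if int(self.frame_count) < 1:
            raise ValidationError(
                f"frame_count must be >= 1, got {self.frame_count} "
                f"(track_id={self.track_id!r})"
            )
        object.__setattr__(self, "frame_count", int(self.frame_count))
        object.__setattr__(self, "right_censored", bool(self.right_censored))


@dataclass
class TrackDataset:
    """All tracks recorded at one recording interval ``delta_t``.

    Parameters
    ----------
    delta_t
        Interval between consecutive frames, in seconds. Must be positive.
    min_frame_count
        Minimum accepted track length ``n_min`` (frames); every observation
        must satisfy ``frame_count >= min_frame_count``.
    observations
        The track observations, in acquisition order.
    """

    delta_t: float
    min_frame_count: int
    observations: list[TrackObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.delta_t > 0:
            raise ValidationError(f"delta_t must be positive, got {self.delta_t}")
        if int(self.min_frame_count) < 1:
            raise ValidationError(
                f"min_frame_count must be >= 1, got {self.min_frame_count}"
            )
        self.min_frame_count = int(self.min_frame_count)
        self.observations = list(self.observations)
        for obs in self.observations:
            if obs.frame_count < self.min_frame_count:
                raise ValidationError(
                    f"observation {obs.track_id!r} has frame_count "
                    f"{obs.frame_count} < min_frame_count {self.min_frame_count}"
                )

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def t_min(self) -> float:
        """Left-truncation time ``(n_min - 1) * delta_t`` in seconds."""
        return (self.min_frame_count - 1) * self.delta_t

    @property
    def frame_counts(self) -> np.ndarray:
        return np.array([o.frame_count for o in self.observations], dtype=np.int64)

    @property
    def censored(self) -> np.ndarray:
        return np.array([o.right_censored for o in self.observations], dtype=bool)

    @property
    def durations(self) -> np.ndarray:
        """Observed durations ``t_i = (n_i - 1) * delta_t`` in seconds."""
        return (self.frame_counts - 1) * self.delta_t


@dataclass
class ApparentLifetimeEstimate:
    """Apparent-lifetime MLE and bookkeeping at a single recording interval."""

    tau_app: float
    std_error: float
    delta_t: float
    n_tracks: int
    n_censored: int
    log_likelihood_at_max: float
    method: str  # "survival" or "conventional"

    def __post_init__(self) -> None:
        if not self.tau_app > 0:
            raise ValidationError(f"tau_app must be positive, got {self.tau_app}")
        if self.std_error < 0:
            raise ValidationError(f"std_error must be >= 0, got {self.std_error}")
        if self.n_censored > self.n_tracks:
            raise ValidationError("n_censored cannot exceed n_tracks")
        if self.method not in ("survival", "conventional"):
            raise ValidationError(f"unknown method {self.method!r}")


FIT_FAILURE_REASONS = (
    "none",
    "no_convergence",
    "infinite_covariance",
    "large_negative_value",
)


@dataclass
class LifetimeFitResult:
    """Result of fitting the photobleaching model tau_app(delta_t).

    ``tau_lt`` is the characteristic bond lifetime (seconds) and ``c_b`` the
    dimensionless bleaching constant.  ``failed`` marks fits that did not
    converge, produced a non-finite covariance, or yielded a negative
    (unphysical) lifetime.
    """

    tau_lt: float
    c_b: float
    se_tau_lt: float
    se_c_b: float
    covariance: np.ndarray
    failed: bool = False
    failure_reason: str = "none"

    def __post_init__(self) -> None:
        if self.failure_reason not in FIT_FAILURE_REASONS:
            raise ValidationError(f"unknown failure_reason {self.failure_reason!r}")
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not self.failed:
            if not self.tau_lt > 0:
                raise ValidationError(
                    "non-failed fit requires tau_lt > 0; flag the fit as failed"
                )
            if not np.all(np.isfinite(self.covariance)):
                raise ValidationError("non-failed fit requires finite covariance")


def _parse_bool_column(values: pd.Series) -> np.ndarray:
    out = np.empty(len(values), dtype=bool)
    for i, v in enumerate(values):
        key = str(v).strip().lower()
        if key not in _BOOL_LITERALS:
            raise ValidationError(
                f"row {values.index[i]}: right_censored must be 'true' or "
                f"'false', got {v!r}"
            )
        out[i] = _BOOL_LITERALS[key]
    return out


def read_track_table(
    path: str | Path,
    default_nmin: int = 2,
) -> list[TrackDataset]:
    """Read a CSV track table, returning one :class:`TrackDataset` per ``delta_t``.

    The table must contain columns ``track_id``, ``frame_count``,
    ``right_censored`` (true/false literals) and ``delta_t`` (seconds); an
    optional ``nmin`` column overrides ``default_nmin`` per dataset.  Grouping
    by ``delta_t`` compares the literal column text, not a floating-point
    tolerance: the recording interval is an instrument setting, and two
    settings are the same only if written identically.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"track table is missing required column {col!r}")

    try:
        frame_counts = df["frame_count"].astype(int)
    except ValueError as exc:
        raise ValidationError(f"frame_count column is not integer: {exc}") from exc
    bad = np.flatnonzero(frame_counts < 1)
    if bad.size:
        raise ValidationError(
            f"row {bad[0]}: frame_count must be >= 1, got {frame_counts.iloc[bad[0]]}"
        )
    censored = _parse_bool_column(df["right_censored"])

    datasets: list[TrackDataset] = []
    # sorted by numeric value for a stable, meaningful order; grouped by text
    keys = sorted(df["delta_t"].unique(), key=float)
    for key in keys:
        delta_t = float(key)
        idx = np.flatnonzero((df["delta_t"] == key).to_numpy())
        if not delta_t > 0:
            raise ValidationError(
                f"row {idx[0]}: delta_t must be positive, got {key!r}"
            )
        if "nmin" in df.columns:
            nmin_values = {int(v) for v in df["nmin"].iloc[idx]}
            if len(nmin_values) != 1:
                raise FormatError(
                    f"nmin column is not constant within delta_t={key!r}"
                )
            nmin = nmin_values.pop()
        else:
            nmin = default_nmin
        obs = [
            TrackObservation(
                frame_count=int(frame_counts.iloc[i]),
                right_censored=bool(censored[i]),
                track_id=str(df["track_id"].iloc[i]),
            )
            for i in idx
        ]
        datasets.append(TrackDataset(delta_t=delta_t, min_frame_count=nmin, observations=obs))
    return datasets


def write_track_table(datasets: Iterable[TrackDataset], path: str | Path) -> None:
    """Write datasets to a CSV table; ``read_track_table`` round-trips it."""
    rows = []
    for ds in datasets:
        for obs in ds.observations:
            rows.append(
                {
                    "track_id": obs.track_id,
                    "frame_count": obs.frame_count,
                    "right_censored": "true" if obs.right_censored else "false",
                    "delta_t": repr(float(ds.delta_t)),
                    "nmin": ds.min_frame_count,
                }
            )
    df = pd.DataFrame(
        rows, columns=["track_id", "frame_count", "right_censored", "delta_t", "nmin"]
    )
    df.to_csv(path, index=False)


def apply_min_length_filter(dataset: TrackDataset, nmin: int) -> TrackDataset:
    """Return a copy of ``dataset`` keeping tracks with ``frame_count >= nmin``.

    Lowering ``nmin`` below the dataset's current threshold would require raw
    counts that an already-filtered dataset no longer holds, so it is an error.
    """
    nmin = int(nmin)
    if nmin < 1:
        raise ValidationError(f"nmin must be >= 1, got {nmin}")
    if nmin < dataset.min_frame_count:
        raise ValidationError(
            f"cannot relax nmin from {dataset.min_frame_count} to {nmin}: "
            "tracks below the current threshold were already discarded"
        )
    kept = [o for o in dataset.observations if o.frame_count >= nmin]
    return TrackDataset(
        delta_t=dataset.delta_t, min_frame_count=nmin, observations=kept
    )
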