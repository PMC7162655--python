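"""Filopodia and actin-bundle kinematics from time-lapse track tables.

Filopodia are thin tip-cell protrusions whose length over time defines
extension/retraction behaviour; actin-rich bundles are tracked as moving
points.  Tracks come from manual tracking of time-lapse stacks (one
position per frame, constant frame interval Δt in minutes); everything
here is closed-form arithmetic on those positions in µm.

Conventions
-----------
* A filopodium is "alive" while its length exceeds ``epsilon_um``
  (default 0.5 µm); lifetime spans the half-open interval from the
  first alive frame to the first subsequent dead frame.  If the series
  never returns below epsilon the lifetime is right-censored at the end
  of the recording.
* Extension / retraction speeds are means of the positive / negative
  per-frame length rates (µm/min); a maximum-rate variant is exposed as
  well.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class Track:
    """One tracked object: positions (µm, columns x,y,z) per frame."""

    id: object
    frames: np.ndarray
    positions: np.ndarray
    dt_min: float = 1.0
    base: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] == 2:
            self.positions = np.column_stack(
                [self.positions, np.zeros(len(self.positions))]
            )
        if self.positions.shape[0] != self.frames.shape[0]:
            raise ValueError("positions and frames length mismatch")
        if len(self.frames) > 1:
            d = np.diff(self.frames)
            if np.any(d <= 0):
                raise ValueError(f"track {self.id}: frames not strictly increasing")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be > 0")
        if self.base is not None:
            self.base = np.asarray(self.base, dtype=float)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class FilopodiumStats:
    track_id: object
    max_length_um: float
    lifetime_min: float
    censored: bool
    extension_speed_um_min: float
    retraction_speed_um_min: float
    no_retraction: bool = False
    max_extension_speed_um_min: float = 0.0
    max_retraction_speed_um_min: float = 0.0


@dataclass
class BundleStats:
    track_id: object
    path_length_um: float
    duration_min: float
    average_speed_um_min: float
    cumulative_distance_um: np.ndarray = field(repr=False, default=None)


def filopodium_lengths(track: Track, base: Sequence[float] | None = None) -> np.ndarray:
    """Per-frame filopodium length: Euclidean tip→base distance in µm.

    The base is the supplied anchor, the track's own base point, or —
    matching manual tip-only tracks — the first recorded tip position.
    """
    if base is None:
        base = track.base if track.base is not None else track.positions[0]
    base = np.asarray(base, dtype=float)
    if base.shape[0] == 2:
        base = np.append(base, 0.0)
    return np.linalg.norm(track.positions - base[None, :], axis=1)


def filopodium_stats(
    lengths: Sequence[float],
    dt_min: float,
    epsilon_um: float = 0.5,
    track_id: object = None,
) -> FilopodiumStats:
    """Summarize one filopodium length series.

    Appearance is the first frame with length > epsilon; disappearance
    the first later frame with length <= epsilon (censored at the end of
    the series if it never dies).  Lifetime = (disappearance −
    appearance) × Δt.  Max length is taken over the alive interval.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length series")
    alive = lengths > epsilon_um
    if not alive.any():
        raise ValueError("no filopodium: series never exceeds epsilon")
    appear = int(np.argmax(alive))
    dead_after = np.nonzero(~alive[appear:])[0]
    if dead_after.size:
        disappear = appear + int(dead_after[0])
        censored = False
    else:
        disappear = len(lengths)
        censored = True
    lifetime = (disappear - appear) * dt_min
    max_length = float(lengths[appear:disappear].max())

    rates = np.diff(lengths) / dt_min
    pos, neg = rates[rates > 0], rates[rates < 0]
    ext = float(pos.mean()) if pos.size else 0.0
    ret = float(np.abs(neg).mean()) if neg.size else 0.0
    return FilopodiumStats(
        track_id=track_id,
        max_length_um=max_length,
        lifetime_min=float(lifetime),
        censored=censored,
        extension_speed_um_min=ext,
        retraction_speed_um_min=ret,
        no_retraction=neg.size == 0,
        max_extension_speed_um_min=float(pos.max()) if pos.size else 0.0,
        max_retraction_speed_um_min=float(np.abs(neg).max()) if neg.size else 0.0,
    )


def bundle_stats(track: Track, dt_min: float | None = None) -> BundleStats:
    """Path length, duration and average speed of a tracked bundle."""
    if len(track) < 2:
        raise ValueError(f"track {track.id}: need >= 2 frames for bundle stats")
    dt = float(dt_min if dt_min is not None else track.dt_min)
    steps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    duration = (len(track) - 1) * dt
    path = float(cum[-1])
    return BundleStats(
        track_id=track.id,
        path_length_um=path,
        duration_min=float(duration),
        average_speed_um_min=path / duration,
        cumulative_distance_um=cum,
    )


def summarize_condition(
    records: Sequence[FilopodiumStats] | Sequence[BundleStats],
    groups: Sequence[object] | None = None,
    metrics: Sequence[str] | None = None,
    ttest_between: tuple[object, object] | None = None,
) -> dict:
    """Per-group n / mean / median / SD for each kinematic metric.

    ``groups`` assigns one label per record (one pooled group when
    omitted).  When ``ttest_between`` names two groups, an unpaired
    t-test on each metric is appended (delegating to the vessel module's
    group-comparison test).
    """
    if not records:
        raise ValueError("no records to summarize")
    rows = [vars(r) for r in records]
    df = pd.DataFrame(rows)
    if metrics is None:
        metrics = [
            c
            for c in df.columns
            if df[c].dtype.kind == "f" and c.endswith(("_um", "_min", "_um_min"))
        ]
    df["_group"] = list(groups) if groups is not None else "all"
    summary: dict = {"groups": {}}
    for g, sub in df.groupby("_group"):
        entry = {"n": int(len(sub))}
        for m in metrics:
            vals = sub[m].to_numpy(float)
            entry[m] = {
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        summary["groups"][g] = entry
    if ttest_between is not None:
        from .vesselgeom import unpaired_ttest

        a, b = ttest_between
        summary["ttest"] = {}
        for m in metrics:
            x = df.loc[df["_group"] == a, m].to_numpy(float)
            y = df.loc[df["_group"] == b, m].to_numpy(float)
            summary["ttest"][m] = unpaired_ttest(x, y)
    return summary
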