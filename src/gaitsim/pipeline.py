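"""Multi-channel gait-recording comparison.

The pipeline compares quasi-periodic multi-sensor recordings (4 body positions
× 3 sensor modalities × 3 axes) in four stages:

1. channel selection — keep only the x and z axes (24 of 36 channels);
2. synchronization — integer-lag alignment by maximal cross-correlation on a
   single reference channel, then truncation to the common window;
3. membership conversion — per-channel min-max rescaling into [0, 1];
4. scoring — either the channel-averaged fuzzy measure ``1 − d(min, max)``
   (mode ``"fuzzy"``), or an Lp distance between fixed-length peak-feature
   descriptors (mode ``"lp"``).

Scores are aggregated into the three cohort tables: within-person
cross-behavior means, cross-person within-behavior means, and the full
person × person matrix for one behavior.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import (
    EmptyInputError,
    MissingChannelError,
    SynchronizationError,
)
from .metrics import DataVector, SimilarityMatrix, lp_distance

__all__ = [
    "POSITIONS",
    "SENSORS",
    "AXES",
    "SELECTED_AXES",
    "BEHAVIORS",
    "DEFAULT_REFERENCE_CHANNEL",
    "channel_name",
    "parse_channel_name",
    "GaitRecording",
    "BehaviorProfile",
    "ChannelFeatureSet",
    "select_channels",
    "synchronize",
    "estimate_lag",
    "to_membership",
    "extract_features",
    "behavior_similarity",
    "person_similarity",
    "SimilarityTables",
    "similarity_tables",
]

POSITIONS = ("head", "waist", "left_leg", "right_leg")
SENSORS = ("accelerometer", "magnetometer", "gyro")
AXES = ("x", "y", "z")
SELECTED_AXES = ("x", "z")
BEHAVIORS = ("walking", "stair_up", "stair_down")

DEFAULT_REFERENCE_CHANNEL = "waist_accelerometer_z"

_MODES = ("fuzzy", "lp")


def channel_name(position: str, sensor: str, axis: str) -> str:
    """Canonical channel key, e.g. ``waist_gyro_z``."""
    return f"{position}_{sensor}_{axis}"


def parse_channel_name(name: str) -> tuple[str, str, str]:
    """Split ``<position>_<sensor>_<axis>`` (position may itself contain ``_``)."""
    head, sensor, axis = name.rsplit("_", 2)
    return head, sensor, axis


def all_channel_names(axes: Sequence[str] = AXES) -> list[str]:
    return [
        channel_name(p, s, a)
        for p in POSITIONS
        for s in SENSORS
        for a in axes
    ]


@dataclass(frozen=True)
class GaitRecording:
    """One behavior recording: equal-length sample vectors per channel."""

    subject_id: str
    behavior: str
    sampling_rate: float
    channels: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(
                f"behavior must be one of {BEHAVIORS}, got {self.behavior!r}"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            raise EmptyInputError("recording must have at least one channel")
        chans = {}
        lengths = set()
        for name, vec in self.channels.items():
            arr = np.array(vec, dtype=float, copy=True)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"channel {name!r} must be a non-empty 1-d vector")
            arr.flags.writeable = False
            chans[name] = arr
            lengths.add(arr.size)
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        object.__setattr__(self, "channels", chans)

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def channel_names(self) -> tuple:
        return tuple(sorted(self.channels))

    def with_channels(self, channels: Mapping[str, np.ndarray]) -> "GaitRecording":
        return GaitRecording(self.subject_id, self.behavior, self.sampling_rate, channels)


@dataclass(frozen=True)
class BehaviorProfile:
    """A subject's full triple of behavior recordings."""

    subject_id: str
    recordings: Mapping[str, GaitRecording]

    def __post_init__(self) -> None:
        missing = [b for b in BEHAVIORS if b not in self.recordings]
        if missing:
            raise ValueError(f"profile {self.subject_id!r} missing behaviors: {missing}")
        for b, rec in self.recordings.items():
            if rec.subject_id != self.subject_id:
                raise ValueError(
                    f"recording for {b!r} belongs to {rec.subject_id!r}, "
                    f"not {self.subject_id!r}"
                )
        object.__setattr__(self, "recordings", dict(self.recordings))

    @property
    def walking(self) -> GaitRecording:
        return self.recordings["walking"]

    @property
    def stair_up(self) -> GaitRecording:
        return self.recordings["stair_up"]

    @property
    def stair_down(self) -> GaitRecording:
        return self.recordings["stair_down"]


@dataclass(frozen=True)
class ChannelFeatureSet:
    """Per-channel peak amplitudes and successive peak-amplitude differences."""

    peak_values: dict
    magnitude_distances: dict

    def __post_init__(self) -> None:
        for name, peaks in self.peak_values.items():
            md = self.magnitude_distances[name]
            expected = max(len(peaks) - 1, 0)
            if len(md) != expected:
                raise ValueError(
                    f"channel {name!r}: expected {expected} magnitude distances, "
                    f"got {len(md)}"
                )


def select_channels(rec: GaitRecording) -> GaitRecording:
    """Keep only x- and z-axis channels (24 of the full 36); idempotent.

    Raises :class:`MissingChannelError` if any of the 24 required channels is
    absent.
    """
    required = all_channel_names(SELECTED_AXES)
    missing = [c for c in required if c not in rec.channels]
    if missing:
        raise MissingChannelError(f"recording lacks required channels: {missing}")
    kept = {c: rec.channels[c] for c in required}
    return rec.with_channels(kept)


def estimate_lag(reference: np.ndarray, x: np.ndarray) -> int:
    """Integer delay of *x* relative to *reference* by maximal cross-correlation.

    Positive result means *x* is delayed: ``x[t] ≈ reference[t − lag]``.
    Signals are mean-centered first so a DC offset cannot bias the peak.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(x, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    corr = _signal.correlate(b, a, mode="full", method="auto")
    lags = _signal.correlation_lags(b.size, a.size, mode="full")
    return int(lags[int(np.argmax(corr))])


def synchronize(
    recs: Sequence[GaitRecording],
    reference_channel: str = DEFAULT_REFERENCE_CHANNEL,
) -> tuple[list[GaitRecording], list[int]]:
    """Align recordings to the first by integer lag and truncate to the overlap.

    Returns the aligned recordings (all the same length) and the per-recording
    lags (first entry always 0). Raises :class:`SynchronizationError` when the
    estimated lags leave no overlapping window.
    """
    if len(recs) < 2:
        raise ValueError("need at least two recordings to synchronize")
    for rec in recs:
        if reference_channel not in rec.channels:
            raise MissingChannelError(
                f"reference channel {reference_channel!r} absent from recording "
                f"({rec.subject_id}, {rec.behavior})"
            )
    ref = recs[0].channels[reference_channel]
    lags = [0] + [
        estimate_lag(ref, rec.channels[reference_channel]) for rec in recs[1:]
    ]
    # recording i covers timeline [-lag_i, n_i - lag_i) on the reference clock
    start = max(-lag for lag in lags)
    start = max(start, 0)
    stop = min(rec.n_samples - lag for rec, lag in zip(recs, lags))
    if stop <= start:
        raise SynchronizationError(
            f"no overlapping window after lag compensation (lags={lags})"
        )
    aligned = []
    for rec, lag in zip(recs, lags):
        lo, hi = start + lag, stop + lag
        aligned.append(
            rec.with_channels({c: v[lo:hi] for c, v in rec.channels.items()})
        )
    return aligned, lags


def to_membership(samples: np.ndarray) -> np.ndarray:
    """Min-max rescale a sample vector into [0, 1].

    A constant vector maps to all 0.5 by convention (no shape information to
    preserve, and 0.5 is the neutral membership).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise EmptyInputError("cannot rescale an empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def extract_features(
    rec: GaitRecording, prominence_fraction: float = 0.1
) -> ChannelFeatureSet:
    """Detect peaks per channel and derive successive peak-amplitude differences.

    A local maximum qualifies as a peak when its prominence is at least
    ``prominence_fraction × (channel max − channel min)``. A flat channel has
    no peaks. Magnitude distances are the signed differences between
    consecutive peak amplitudes.
    """
    if not 0.0 < prominence_fraction < 1.0:
        raise ValueError("prominence_fraction must be in (0, 1)")
    peak_values = {}
    magnitude_distances = {}
    for name, x in rec.channels.items():
        span = float(x.max() - x.min())
        if span == 0.0:
            peak_values[name] = np.empty(0)
            magnitude_distances[name] = np.empty(0)
            continue
        idx, _ = _signal.find_peaks(x, prominence=prominence_fraction * span)
        heights = x[idx]
        peak_values[name] = heights
        magnitude_distances[name] = np.diff(heights)
    return ChannelFeatureSet(peak_values, magnitude_distances)


def _maybe_select(rec: GaitRecording) -> GaitRecording:
    """Apply x/z channel selection when the recording still carries y axes."""
    if any(parse_channel_name(c)[2] == "y" for c in rec.channels):
        return select_channels(rec)
    return rec


def _feature_descriptor(
    rec: GaitRecording, prominence_fraction: float
) -> np.ndarray:
    """Fixed-length per-channel descriptor on membership-normalized signals.

    Three components per channel, each bounded in [0, 1] so the maximal Lp
    distance between two descriptors is known in closed form:
    peak density (peak count over the n/2 ceiling), mean peak height, and mean
    absolute successive peak-amplitude difference.
    """
    mem = rec.with_channels(
        {c: to_membership(v) for c, v in rec.channels.items()}
    )
    feats = extract_features(mem, prominence_fraction)
    comps = []
    for name in sorted(mem.channels):
        heights = feats.peak_values[name]
        if heights.size == 0:
            comps.extend([0.0, 0.0, 0.0])
            continue
        density = min(1.0, 2.0 * heights.size / mem.n_samples)
        mean_height = float(heights.mean())
        mean_md = (
            float(np.abs(feats.magnitude_distances[name]).mean())
            if heights.size > 1
            else 0.0
        )
        comps.extend([density, mean_height, mean_md])
    return np.asarray(comps)


def _recording_similarity(
    rec_a: GaitRecording,
    rec_b: GaitRecording,
    mode: str = "fuzzy",
    reference_channel: str = DEFAULT_REFERENCE_CHANNEL,
    p: float = 2.0,
    prominence_fraction: float = 0.1,
) -> float:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    rec_a = _maybe_select(rec_a)
    rec_b = _maybe_select(rec_b)
    if rec_a.channel_names != rec_b.channel_names:
        raise MissingChannelError(
            "recordings expose different channel sets: "
            f"{set(rec_a.channel_names) ^ set(rec_b.channel_names)}"
        )
    (rec_a, rec_b), _ = synchronize([rec_a, rec_b], reference_channel)

    if mode == "fuzzy":
        scores = []
        for name in rec_a.channel_names:
            mu_a = to_membership(rec_a.channels[name])
            mu_b = to_membership(rec_b.channels[name])
            # 1 - d(min, max) == 1 - mean |mu_a - mu_b| channel-wise
            scores.append(1.0 - float(np.mean(np.abs(mu_a - mu_b))))
        return float(np.mean(scores))

    fa = _feature_descriptor(rec_a, prominence_fraction)
    fb = _feature_descriptor(rec_b, prominence_fraction)
    d = lp_distance(DataVector("a", fa), DataVector("b", fb), p=p)
    # descriptors live on the unit cube: the attainable maximum of the Lp
    # distance is m^(1/p) (1 for the max-norm), which fixes the [0, 1] scale
    dmax = 1.0 if math.isinf(p) else fa.size ** (1.0 / p)
    return float(np.clip(1.0 - d / dmax, 0.0, 1.0))


def behavior_similarity(
    profile: BehaviorProfile,
    b1: str,
    b2: str,
    mode: str = "fuzzy",
    reference_channel: str = DEFAULT_REFERENCE_CHANNEL,
    p: float = 2.0,
    prominence_fraction: float = 0.1,
) -> float:
    """Similarity between two behaviors of the same subject, in [0, 1]."""
    for b in (b1, b2):
        if b not in profile.recordings:
            raise ValueError(f"profile {profile.subject_id!r} lacks behavior {b!r}")
    return _recording_similarity(
        profile.recordings[b1],
        profile.recordings[b2],
        mode=mode,
        reference_channel=reference_channel,
        p=p,
        prominence_fraction=prominence_fraction,
    )


def person_similarity(
    profile_i: BehaviorProfile,
    profile_j: BehaviorProfile,
    behavior: str = "walking",
    mode: str = "fuzzy",
    reference_channel: str = DEFAULT_REFERENCE_CHANNEL,
    p: float = 2.0,
    prominence_fraction: float = 0.1,
) -> float:
    """Similarity between two subjects for one fixed behavior, in [0, 1]."""
    for prof in (profile_i, profile_j):
        if behavior not in prof.recordings:
            raise ValueError(
                f"profile {prof.subject_id!r} lacks behavior {behavior!r}"
            )
    return _recording_similarity(
        profile_i.recordings[behavior],
        profile_j.recordings[behavior],
        mode=mode,
        reference_channel=reference_channel,
        p=p,
        prominence_fraction=prominence_fraction,
    )


_BEHAVIOR_PAIRS = tuple(itertools.combinations(BEHAVIORS, 2))


def _pair_label(b1: str, b2: str) -> str:
    return f"{b1}~{b2}"


@dataclass(frozen=True)
class SimilarityTables:
    """The three cohort summaries.

    ``cross_behavior``
        per-subject within-person similarities, one column per behavior pair;
        the cohort mean is ``cross_behavior.mean()``.
    ``cross_person``
        mean cross-person similarity per behavior (over all subject pairs).
    ``person_matrix``
        full person × person similarity matrix for ``matrix_behavior``.
    """

    cross_behavior: pd.DataFrame
    cross_person: pd.Series
    person_matrix: SimilarityMatrix
    matrix_behavior: str = "walking"

    @property
    def cross_behavior_mean(self) -> pd.Series:
        return self.cross_behavior.mean()


def similarity_tables(
    cohort: Sequence[BehaviorProfile],
    mode: str = "fuzzy",
    matrix_behavior: str = "walking",
    reference_channel: str = DEFAULT_REFERENCE_CHANNEL,
    p: float = 2.0,
    prominence_fraction: float = 0.1,
) -> SimilarityTables:
    """Compute the three cohort similarity tables.

    Deterministic given the cohort and options; requires every profile to be
    complete (enforced by :class:`BehaviorProfile` itself).
    """
    if len(cohort) == 0:
        raise EmptyInputError("cohort is empty")
    ids = [prof.subject_id for prof in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in cohort")
    kwargs = dict(
        mode=mode,
        reference_channel=reference_channel,
        p=p,
        prominence_fraction=prominence_fraction,
    )

    rows = {
        prof.subject_id: {
            _pair_label(b1, b2): behavior_similarity(prof, b1, b2, **kwargs)
            for b1, b2 in _BEHAVIOR_PAIRS
        }
        for prof in cohort
    }
    cross_behavior = pd.DataFrame.from_dict(rows, orient="index")
    cross_behavior.index.name = "subject_id"

    n = len(cohort)
    per_behavior_mats = {}
    for behavior in BEHAVIORS:
        mat = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                s = person_similarity(cohort[i], cohort[j], behavior, **kwargs)
                mat[i, j] = mat[j, i] = s
        per_behavior_mats[behavior] = mat

    if n >= 2:
        iu = np.triu_indices(n, k=1)
        cross_person = pd.Series(
            {b: float(per_behavior_mats[b][iu].mean()) for b in BEHAVIORS},
            name="mean_cross_person_similarity",
        )
    else:
        cross_person = pd.Series(
            {b: float("nan") for b in BEHAVIORS},
            name="mean_cross_person_similarity",
        )
    cross_person.index.name = "behavior"

    if matrix_behavior not in BEHAVIORS:
        raise ValueError(f"unknown behavior {matrix_behavior!r}")
    person_matrix = SimilarityMatrix(
        tuple(ids), np.clip(per_behavior_mats[matrix_behavior], 0.0, 1.0)
    )
    return SimilarityTables(cross_behavior, cross_person, person_matrix, matrix_behavior)
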