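"""Seeded synthetic data: disjoint point-set examples and a multi-sensor gait cohort.

The gait generator produces quasi-periodic behavior-specific signals for a
cohort of subjects. Each channel is a three-harmonic series

    x(t) = Σ_{h=1..3} A_h · (1 + η_h) · sin(2π h f t + φ_h) + ε(t)

where the harmonic template ``(A_h, φ_h)`` is fixed per (behavior, channel)
and ``ε`` is white noise. Each subject carries a personal signature — a
per-(subject, channel, harmonic) amplitude jitter ``η_h`` plus a harmonic
phase jitter, both governed by ``subject_variation_sd``, drawn once per
subject and shared across behaviors, then scaled by a per-behavior
variability factor (stair ascent is the most constrained movement, free
walking the most idiosyncratic). Behaviors further differ in stride
frequency and harmonic richness (walking has the richest waveform, stair
climbing the most fundamental-dominated one).

The two stair behaviors are tied together by ``stair_shared_fraction``: the
stair-down template, phase, and effective stride frequency are convex blends
of the stair-up ones (plus a phase flip for the opposite movement direction).
At 1 the stairs share one cadence and waveform; at 0 they are unrelated. This
knob — not any hard-coded score — is what makes stair-up/stair-down the most
similar behavior pair downstream.

Randomness is fully deterministic: every draw comes from a
``numpy.random.SeedSequence`` keyed by ``(seed, stream, subject, behavior,
channel, ...)``, so results do not depend on generation order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .nonoverlap import SingletonSample
from .pipeline import (
    AXES,
    BEHAVIORS,
    BehaviorProfile,
    GaitRecording,
    all_channel_names,
)

__all__ = [
    "GaitSimConfig",
    "generate_pointsets",
    "generate_recording",
    "generate_cohort",
    "POINTSET_KINDS",
]

N_HARMONICS = 3

# substream tags so different uses of the same key cannot collide
_TEMPLATE_STREAM = 0
_VARIATION_STREAM = 1
_NOISE_STREAM = 2
_POINTSET_STREAM = 3

_CHANNELS = tuple(all_channel_names(AXES))  # fixed 36-channel order
_CHANNEL_INDEX = {c: i for i, c in enumerate(_CHANNELS)}
_BEHAVIOR_INDEX = {b: i for i, b in enumerate(BEHAVIORS)}


def _default_frequencies() -> dict:
    return {"walking": 1.2, "stair_up": 0.7, "stair_down": 0.85}


def _default_variability() -> dict:
    # how strongly subjects differ per behavior: stair ascent is the most
    # constrained movement (people climb stairs alike), free walking the most
    # idiosyncratic; this ranks cross-person similarity stair_up highest
    return {"walking": 1.4, "stair_up": 0.7, "stair_down": 1.0}


def _default_decay() -> dict:
    # harmonic richness: walking has the most overtone energy, stair_up the
    # least; this is what ranks cross-person similarity stair_up > stair_down
    # > walking downstream
    return {"walking": 0.75, "stair_up": 0.25, "stair_down": 0.6}


@dataclass(frozen=True)
class GaitSimConfig:
    """Generator configuration; all defaults give the standard 20-subject cohort."""

    n_subjects: int = 20
    duration_s: float = 10.0
    sampling_rate_hz: float = 100.0
    stride_frequency_hz: Mapping[str, float] = field(default_factory=_default_frequencies)
    harmonic_decay: Mapping[str, float] = field(default_factory=_default_decay)
    behavior_variability: Mapping[str, float] = field(default_factory=_default_variability)
    subject_variation_sd: float = 0.1
    noise_sd: float = 0.05
    stair_shared_fraction: float = 0.8
    template_seed: int = 1234
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        for mapping, what in (
            (self.stride_frequency_hz, "stride_frequency_hz"),
            (self.harmonic_decay, "harmonic_decay"),
            (self.behavior_variability, "behavior_variability"),
        ):
            missing = [b for b in BEHAVIORS if b not in mapping]
            if missing:
                raise ValueError(f"{what} missing behaviors: {missing}")
        if any(f <= 0 for f in self.stride_frequency_hz.values()):
            raise ValueError("stride frequencies must be positive")
        if any(v < 0 for v in self.behavior_variability.values()):
            raise ValueError("behavior_variability factors must be >= 0")
        if self.subject_variation_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.stair_shared_fraction <= 1.0:
            raise ValueError("stair_shared_fraction must lie in [0, 1]")
        object.__setattr__(self, "stride_frequency_hz", dict(self.stride_frequency_hz))
        object.__setattr__(self, "harmonic_decay", dict(self.harmonic_decay))
        object.__setattr__(self, "behavior_variability", dict(self.behavior_variability))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for output provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _raw_template(config: GaitSimConfig, behavior: str, channel: str):
    """Behavior/channel harmonic template before stair blending."""
    bi = _BEHAVIOR_INDEX[behavior]
    ci = _CHANNEL_INDEX[channel]
    rng = _rng(config.template_seed, _TEMPLATE_STREAM, bi, ci)
    decay = float(config.harmonic_decay[behavior])
    h = np.arange(N_HARMONICS)
    amps = (0.75 + 0.5 * rng.random(N_HARMONICS)) * decay**h
    # unit total amplitude: keeps the noise-to-signal-range ratio comparable
    # across behaviors regardless of their harmonic richness
    amps = amps / amps.sum()
    phases = rng.uniform(0.0, 2.0 * np.pi, N_HARMONICS)
    return amps, phases


def _channel_template(config: GaitSimConfig, behavior: str, channel: str):
    """Final (amplitudes, phases, frequency) for one behavior/channel.

    stair_down is a convex blend of the stair_up template with its own raw
    template, plus a pi phase offset (opposite movement direction); its
    effective stride frequency is blended the same way so that at
    ``stair_shared_fraction = 1`` both stairs share one cadence.
    """
    freq = float(config.stride_frequency_hz[behavior])
    if behavior != "stair_down":
        amps, phases = _raw_template(config, behavior, channel)
        return amps, phases, freq
    f = config.stair_shared_fraction
    up_amps, up_phases = _raw_template(config, "stair_up", channel)
    own_amps, own_phases = _raw_template(config, "stair_down", channel)
    amps = f * up_amps + (1.0 - f) * own_amps
    phases = f * up_phases + (1.0 - f) * own_phases + np.pi
    freq = f * float(config.stride_frequency_hz["stair_up"]) + (1.0 - f) * freq
    return amps, phases, freq


def generate_recording(
    config: GaitSimConfig, subject: int, behavior: str
) -> GaitRecording:
    """Generate the full 36-channel recording of one subject/behavior."""
    if not 0 <= subject < config.n_subjects:
        raise ValueError(
            f"subject must be in [0, {config.n_subjects}), got {subject}"
        )
    if behavior not in BEHAVIORS:
        raise ValueError(f"behavior must be one of {BEHAVIORS}, got {behavior!r}")
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate_hz
    bi = _BEHAVIOR_INDEX[behavior]
    channels = {}
    for channel in _CHANNELS:
        ci = _CHANNEL_INDEX[channel]
        amps, phases, freq = _channel_template(config, behavior, channel)
        # personal signature: a per-(subject, channel, harmonic) amplitude
        # jitter plus phase jitter, drawn once per subject-channel and shared
        # across behaviors, then scaled by the behavior's variability factor.
        # Phase jitter survives membership normalization (amplitude scaling
        # alone would cancel) and grows linearly with harmonic order: a time
        # warp delta enters harmonic h as h*delta, so harmonically rich
        # behaviors vary more between subjects than fundamental-dominated ones
        var_rng = _rng(config.seed, _VARIATION_STREAM, subject, ci)
        scale = float(config.behavior_variability[behavior])
        eta = scale * var_rng.normal(0.0, config.subject_variation_sd, N_HARMONICS)
        kappa = scale * var_rng.normal(0.0, 1.0, N_HARMONICS) * (
            2.0
            * np.pi
            * config.subject_variation_sd
            * np.arange(1, N_HARMONICS + 1)
        )
        x = np.zeros(n)
        for h in range(N_HARMONICS):
            x += (
                amps[h]
                * (1.0 + eta[h])
                * np.sin(2.0 * np.pi * (h + 1) * freq * t + phases[h] + kappa[h])
            )
        if config.noise_sd > 0:
            x += _rng(config.seed, _NOISE_STREAM, subject, bi, ci).normal(
                0.0, config.noise_sd, n
            )
        channels[channel] = x
    return GaitRecording(
        subject_id=f"s{subject:02d}",
        behavior=behavior,
        sampling_rate=config.sampling_rate_hz,
        channels=channels,
    )


def generate_cohort(config: GaitSimConfig) -> list[BehaviorProfile]:
    """Generate complete behavior profiles for every subject; seed-deterministic."""
    cohort = []
    for subject in range(config.n_subjects):
        recs = {b: generate_recording(config, subject, b) for b in BEHAVIORS}
        cohort.append(BehaviorProfile(f"s{subject:02d}", recs))
    return cohort


# ---------------------------------------------------------------------------
# point-set examples

#: The two disjoint-distribution worked examples (exact published values) plus
#: seeded random kinds.
POINTSET_KINDS = ("overlapped", "disjoint_a", "disjoint_b", "random_disjoint")

_DISJOINT_A = {
    "diamond": (0.5, 0.8, 0.6, 0.5, 0.4, 1.0),
    "circle": (0.4, 0.6, 0.7, 0.5, 0.8, 0.6),
}
_DISJOINT_B = {
    "diamond": (0.5, 0.8, 0.6, 0.4, 0.5, 0.4),
    "circle": (0.6, 0.7, 0.5, 1.0, 0.8, 0.6),
}


def generate_pointsets(
    kind: str, seed: int = 0, size: int = 6
) -> tuple[SingletonSample, SingletonSample]:
    """Return a (diamond, circle) pair of labeled point samples.

    ``disjoint_a`` and ``disjoint_b`` are the two fixed worked-example
    partitions of the same twelve values (returned exactly, ignoring *seed*);
    ``overlapped`` and ``random_disjoint`` draw seeded random heights.
    """
    if kind not in POINTSET_KINDS:
        raise ValueError(f"kind must be one of {POINTSET_KINDS}, got {kind!r}")
    if kind == "disjoint_a":
        fixed = _DISJOINT_A
    elif kind == "disjoint_b":
        fixed = _DISJOINT_B
    else:
        rng = _rng(seed, _POINTSET_STREAM, POINTSET_KINDS.index(kind))
        if kind == "overlapped":
            # same underlying distribution for both classes
            fixed = {
                "diamond": tuple(rng.uniform(0.3, 0.9, size)),
                "circle": tuple(rng.uniform(0.3, 0.9, size)),
            }
        else:  # random_disjoint
            fixed = {
                "diamond": tuple(rng.random(size)),
                "circle": tuple(rng.random(size)),
            }
    return (
        SingletonSample("diamond", fixed["diamond"]),
        SingletonSample("circle", fixed["circle"]),
    )
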