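"""Seeded generator of device-like in-air signature corpora.

Real in-air signature corpora are distributed only on request, so every
downstream stage is exercised on synthetic corpora that emulate their
structure: per-subject smooth latent trajectories (a subject's "motor
program"), within-subject repetition variability, an additive second-session
offset (collection sessions were separated by days), noisy dwell segments at
both ends of each recording (the user stares at the device before pressing
start/finish), ~215-230 ms sampling, and an optional missing-record pattern.

The per-channel ``channel_informativeness`` weight is the design handle for
attribution experiments: it is the fraction of a channel's (pre-scaling)
variance carried by the subject-specific latent rather than by
repetition-specific noise, so it directly controls how discriminative a
channel is for subject identification.  The latent motor program is a sum of
random-frequency, random-phase sinusoids per (subject, channel) — smooth and
subject-stable without claiming a biomechanical model.

Every record draws from an RNG stream keyed by (seed, subject, round), so
removing one record never shifts any other record's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from airsig.errors import ConfigError, DataError
from airsig.schema import (
    CHANNEL_NAMES,
    MissingIndex,
    SignatureDataset,
    SignatureRecord,
)

#: the documented missing-record pattern of the phone corpus:
#: (participant index, signature round, collection section)
PHONE_MISSING_INDEX = MissingIndex(entries=(
    (16, 5, 1), (18, 6, 2), (18, 7, 2), (58, 4, 1), (78, 3, 1), (88, 4, 1),
    (99, 8, 2), (100, 1, 1), (137, 7, 2), (156, 9, 2), (165, 8, 2),
    (178, 5, 1), (189, 3, 1), (204, 7, 2), (210, 4, 1), (211, 5, 1),
    (230, 5, 1), (239, 6, 2), (270, 6, 2), (270, 9, 2), (278, 4, 1),
    (279, 2, 1), (280, 1, 1),
))

# Cosmetic per-device channel offsets/scales so generated values live in the
# same ballpark as the published sample rows (phone accelerometer in m/s^2
# with gravity mostly on the y axis; smartwatch channels are small).
_DEVICE_OFFSET = {
    "phone": np.array([-0.5, -8.8, 3.0, -11.0, -0.5, -2.5, 0.0, 1.5, 2.0]),
    "smartwatch": np.array([0.005, 0.01, 0.0, 0.05, 0.025, 0.05, 0.46, 0.71, 0.07]),
}
_DEVICE_SCALE = {
    "phone": np.array([0.5, 0.5, 1.0, 2.0, 0.5, 1.0, 1.0, 1.5, 4.0]),
    "smartwatch": np.array([0.01, 0.01, 0.01, 0.04, 0.01, 0.03, 0.002, 0.002, 0.002]),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for one synthetic corpus."""

    n_subjects: int
    n_repetitions: int = 10
    n_sessions: int = 2
    duration_steps: int = 1000
    #: fixed per-sample interval in ms, or None to sample uniformly in [215, 230]
    sampling_interval_ms: Optional[float] = None
    channel_informativeness: tuple[float, ...] = (0.7,) * 9
    repetition_noise_sd: float = 1.0
    session_shift_sd: float = 0.3
    dwell_steps: int = 5
    #: relative record-length jitter (0 disables variable lengths)
    length_jitter: float = 0.1
    n_sinusoids: int = 6
    missing: Optional[MissingIndex] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_repetitions < 1:
            raise ConfigError("n_subjects and n_repetitions must be positive")
        if self.n_sessions not in (1, 2):
            raise ConfigError("n_sessions must be 1 or 2")
        if len(self.channel_informativeness) != len(CHANNEL_NAMES):
            raise ConfigError("channel_informativeness must have 9 entries")
        if any(not 0.0 <= w <= 1.0 for w in self.channel_informativeness):
            raise ConfigError("channel_informativeness entries must lie in [0, 1]")
        if self.duration_steps <= 2 * self.dwell_steps:
            raise ConfigError("duration_steps must exceed 2 * dwell_steps")
        if self.dwell_steps < 0:
            raise ConfigError("dwell_steps must be non-negative")
        if self.repetition_noise_sd < 0 or self.session_shift_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        if not 0.0 <= self.length_jitter < 0.5:
            raise ConfigError("length_jitter must lie in [0, 0.5)")
        if self.sampling_interval_ms is not None and self.sampling_interval_ms <= 0:
            raise ConfigError("sampling_interval_ms must be positive")
        if self.n_sinusoids < 1:
            raise ConfigError("n_sinusoids must be positive")


def _sinusoid_bank(rng: np.random.Generator, k: int, n_channels: int):
    """Random amplitudes/frequencies/phases for a smooth band-limited process.

    Frequencies are in cycles per step, kept low (periods of ~12-200 steps)
    so trajectories are smooth at any plausible sampling interval.
    """
    amp = rng.uniform(0.5, 1.0, size=(n_channels, k))
    freq = rng.uniform(0.005, 0.08, size=(n_channels, k))
    phase = rng.uniform(0.0, 2 * np.pi, size=(n_channels, k))
    return amp, freq, phase


def _evaluate_bank(bank, t: np.ndarray) -> np.ndarray:
    """Evaluate the sinusoid bank on time grid `t`; rows normalized to unit SD."""
    amp, freq, phase = bank
    # (C, K) x (T,) -> (T, C)
    sig = np.einsum("ck,ckt->tc", amp, np.sin(2 * np.pi * freq[..., None] * t + phase[..., None]))
    sd = sig.std(axis=0)
    sd[sd == 0] = 1.0
    return sig / sd


def _session_of(round_index: int, config: GeneratorConfig) -> int:
    if config.n_sessions == 1:
        return 1
    half = (config.n_repetitions + 1) // 2
    return 1 if round_index <= half else 2


def generate_dataset(config: GeneratorConfig, device: str = "phone") -> SignatureDataset:
    """Generate a corpus of ``n_subjects x n_repetitions`` records (minus any missing)."""
    if device not in _DEVICE_OFFSET:
        raise ConfigError(f"unknown device {device!r}")
    n_ch = len(CHANNEL_NAMES)
    iota = np.asarray(config.channel_informativeness)
    w_subject = np.sqrt(iota)
    w_noise = np.sqrt(1.0 - iota) * config.repetition_noise_sd
    offset = _DEVICE_OFFSET[device]
    scale = _DEVICE_SCALE[device]

    records = []
    for s in range(config.n_subjects):
        subject_id = f"s{s + 1:03d}"
        subj_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0, s))
        )
        latent_bank = _sinusoid_bank(subj_rng, config.n_sinusoids, n_ch)
        session_shift = subj_rng.normal(0.0, config.session_shift_sd, size=n_ch)

        for r in range(1, config.n_repetitions + 1):
            rec_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(1, s, r))
            )
            if config.length_jitter > 0:
                jitter = rec_rng.uniform(-config.length_jitter, config.length_jitter)
                t_len = int(round(config.duration_steps * (1.0 + jitter)))
                t_len = max(t_len, 2 * config.dwell_steps + 2)
            else:
                t_len = config.duration_steps
            t = np.linspace(0.0, config.duration_steps, t_len)

            u = _evaluate_bank(latent_bank, t)                       # subject latent
            noise_bank = _sinusoid_bank(rec_rng, config.n_sinusoids, n_ch)
            e = _evaluate_bank(noise_bank, t)                        # repetition noise
            x = w_subject * u + w_noise * e

            session = _session_of(r, config)
            if session == 2:
                x = x + session_shift

            if config.dwell_steps > 0:
                dwell = rec_rng.normal(0.0, 0.2, size=(2 * config.dwell_steps, n_ch))
                x[: config.dwell_steps] = dwell[: config.dwell_steps]
                x[t_len - config.dwell_steps:] = dwell[config.dwell_steps:]

            values = offset + scale * x
            if config.sampling_interval_ms is not None:
                interval = float(config.sampling_interval_ms)
            else:
                interval = float(rec_rng.uniform(215.0, 230.0))

            records.append(SignatureRecord(
                subject_id=subject_id,
                round_index=r,
                session=session,
                device=device,
                values=values,
                sampling_interval_ms=interval,
            ))

    dataset = SignatureDataset(
        records=records,
        device=device,
        provenance={"generator": _config_provenance(config), "device": device},
    )
    if config.missing is not None:
        dataset = apply_missing(dataset, config.missing)
    return dataset


def apply_missing(dataset: SignatureDataset, missing: MissingIndex) -> SignatureDataset:
    """Drop the records listed in `missing`; participant index i is the i-th subject."""
    subjects = dataset.subjects
    drop: set[tuple[str, int]] = set()
    for part, sig, section in missing.entries:
        if part > len(subjects):
            raise DataError(
                f"missing-index participant {part} exceeds corpus size {len(subjects)}"
            )
        subject_id = subjects[part - 1]
        match = [r for r in dataset if r.subject_id == subject_id and r.round_index == sig]
        if not match:
            raise DataError(f"missing-index entry ({part}, {sig}, {section}) matches no record")
        if match[0].session != section:
            raise DataError(
                f"missing-index entry ({part}, {sig}, {section}) conflicts with "
                f"record session {match[0].session}"
            )
        drop.add((subject_id, sig))
    kept = [r for r in dataset if (r.subject_id, r.round_index) not in drop]
    return dataset.replace_records(kept, missing_applied=len(missing))


def informativeness_oracle(config: GeneratorConfig) -> np.ndarray:
    """Expected discriminability ranks per channel (1 = most informative, ties averaged)."""
    iota = np.asarray(config.channel_informativeness)
    return stats.rankdata(-iota, method="average")


def _config_provenance(config: GeneratorConfig) -> dict:
    out = {k: v for k, v in vars(config).items() if k != "missing"}
    out["channel_informativeness"] = list(config.channel_informativeness)
    out["missing_entries"] = len(config.missing) if config.missing else 0
    return out


def mias_profile(seed: int = 0, **overrides) -> GeneratorConfig:
    """Phone-corpus profile: 427 subjects x 10 repetitions over two sessions."""
    base = GeneratorConfig(n_subjects=427, n_repetitions=10, seed=seed)
    return replace(base, **overrides) if overrides else base


def smartwatch_profile(seed: int = 0, **overrides) -> GeneratorConfig:
    """Smartwatch-corpus profile: 22 subjects x 10 repetitions."""
    base = GeneratorConfig(n_subjects=22, n_repetitions=10, seed=seed)
    return replace(base, **overrides) if overrides else base
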