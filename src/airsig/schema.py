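"""Domain types for in-air signature signals and corpora.

A recording is a T x C matrix of sensor samples.  The canonical channel
layout has C = 9: accelerometer x/y/z (m/s^2), gyroscope x/y/z and attitude
pitch/roll/yaw (att_x = pitch, att_y = roll, att_z = yaw).  Coalition views
produced by :func:`airsig.preprocess.extract_coalition` carry a subset of the
canonical channels, always in canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from airsig.errors import ConfigError, EmptySignalError, IntegrityError, SchemaError

CHANNEL_NAMES: tuple[str, ...] = (
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "att_x", "att_y", "att_z",
)

SENSOR_OF: Mapping[str, str] = {
    **{f"acc_{a}": "accelerometer" for a in "xyz"},
    **{f"gyr_{a}": "gyroscope" for a in "xyz"},
    **{f"att_{a}": "attitude" for a in "xyz"},
}

AXIS_OF: Mapping[str, str] = {
    "acc_x": "x", "acc_y": "y", "acc_z": "z",
    "gyr_x": "x", "gyr_y": "y", "gyr_z": "z",
    "att_x": "pitch", "att_y": "roll", "att_z": "yaw",
}

#: plausible per-sample interval range in ms (fastest to slowest SDK mode)
PLAUSIBLE_INTERVAL_MS: tuple[float, float] = (18.0, 230.0)

DEVICES = ("phone", "smartwatch")


@dataclass(frozen=True)
class ChannelSchema:
    """The fixed 9-channel sensor layout."""

    names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if self.names != CHANNEL_NAMES:
            raise SchemaError(
                f"channel schema must be the fixed 9-channel order {CHANNEL_NAMES}, got {self.names}"
            )

    @property
    def sensor_of(self) -> Mapping[str, str]:
        return dict(SENSOR_OF)

    @property
    def axis_of(self) -> Mapping[str, str]:
        return dict(AXIS_OF)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


def validate_channels(channels: Iterable[str]) -> tuple[str, ...]:
    """Check that `channels` is a non-empty subset of the canonical names in canonical order."""
    channels = tuple(channels)
    if not channels:
        raise SchemaError("empty channel list")
    unknown = [c for c in channels if c not in CHANNEL_NAMES]
    if unknown:
        raise SchemaError(f"unknown channel name(s): {unknown}")
    order = [CHANNEL_NAMES.index(c) for c in channels]
    if order != sorted(order) or len(set(order)) != len(order):
        raise SchemaError(f"channels must be unique and in canonical order, got {channels}")
    return channels


@dataclass
class SignatureRecord:
    """One multivariate in-air signature: a T x C sample matrix plus metadata."""

    subject_id: str
    round_index: int
    session: int
    device: str
    values: np.ndarray
    sampling_interval_ms: float
    channels: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.channels = validate_channels(self.channels)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise SchemaError(
                f"values must be T x {len(self.channels)}, got shape {self.values.shape}"
            )
        if self.values.shape[0] < 2:
            raise EmptySignalError(
                f"signature needs at least 2 samples, got {self.values.shape[0]}"
            )
        if not np.isfinite(self.values).all():
            raise SchemaError("values contain missing or non-finite cells")
        if not 1 <= self.round_index <= 10:
            raise ConfigError(f"round_index must be in 1..10, got {self.round_index}")
        if self.session not in (1, 2):
            raise ConfigError(f"session must be 1 or 2, got {self.session}")
        if self.device not in DEVICES:
            raise ConfigError(f"device must be one of {DEVICES}, got {self.device!r}")
        lo, hi = PLAUSIBLE_INTERVAL_MS
        if not (lo <= self.sampling_interval_ms <= hi):
            raise ConfigError(
                f"sampling_interval_ms {self.sampling_interval_ms} outside plausible range [{lo}, {hi}]"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.subject_id, self.round_index, self.session)

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D array."""
        return self.values[:, self.channels.index(name)]


@dataclass
class SignatureDataset:
    """A corpus of signature records sharing device and channel layout."""

    records: list[SignatureRecord]
    device: str
    channels: tuple[str, ...] = CHANNEL_NAMES
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = validate_channels(self.channels)
        seen: set[tuple[str, int, int]] = set()
        for rec in self.records:
            if rec.device != self.device:
                raise IntegrityError(
                    f"record {rec.key} has device {rec.device!r}, dataset is {self.device!r}"
                )
            if rec.channels != self.channels:
                raise IntegrityError(f"record {rec.key} channel layout differs from dataset")
            if rec.key in seen:
                raise IntegrityError(f"duplicate (subject, round, session) triple {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SignatureRecord]:
        return iter(self.records)

    @property
    def subjects(self) -> list[str]:
        """Sorted unique subject identifiers."""
        return sorted({r.subject_id for r in self.records})

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def by_subject(self) -> dict[str, list[SignatureRecord]]:
        out: dict[str, list[SignatureRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.subject_id, []).append(rec)
        return out

    def replace_records(self, records: list[SignatureRecord], **extra_provenance) -> "SignatureDataset":
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        return SignatureDataset(
            records=list(records), device=self.device, channels=self.channels, provenance=prov
        )


@dataclass(frozen=True)
class MissingIndex:
    """Records lost in transfer, identified by (participant index, signature round, section).

    Sections are the two collection sessions: rounds 1-5 belong to section 1
    and rounds 6-10 to section 2.
    """

    entries: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        for part, sig, section in self.entries:
            if not 1 <= sig <= 10:
                raise ConfigError(f"signature index must be in 1..10, got {sig}")
            if section not in (1, 2):
                raise ConfigError(f"section must be 1 or 2, got {section}")
            if part < 1:
                raise ConfigError(f"participant index must be positive, got {part}")

    def __len__(self) -> int:
        return len(self.entries)
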