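"""Length standardization, splitting, coalition slicing, re-weighting, heatmap summary.

Closed-set subject identification requires every subject to appear in
training, so the default split is stratified per subject: each subject
contributes floor(n_i * test_fraction) records to the test set (at least one
when n_i >= 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from airsig.errors import (
    ConfigError,
    DataError,
    EmptyCoalitionError,
    StratificationError,
)
from airsig.schema import SignatureDataset, SignatureRecord


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    stratify_by_subject: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError(f"test_fraction must be in (0, 1), got {self.test_fraction}")


@dataclass(frozen=True)
class Coalition:
    """A subset of channel indices (0-based positions in the dataset layout)."""

    members: tuple[int, ...]

    def __post_init__(self) -> None:
        members = tuple(sorted(set(int(m) for m in self.members)))
        if any(m < 0 for m in members):
            raise ConfigError(f"coalition members must be non-negative indices, got {self.members}")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: int) -> bool:
        return item in self.members

    def __iter__(self):
        return iter(self.members)


def standardize_length(record: SignatureRecord, target_length: int) -> SignatureRecord:
    """Linearly resample every channel onto `target_length` uniform points over the
    original time span.  Identity when the record already has that length."""
    if target_length < 2:
        raise ConfigError(f"target_length must be >= 2, got {target_length}")
    t = record.n_samples
    if t == target_length:
        return record
    old_grid = np.arange(t, dtype=np.float64)
    new_grid = np.linspace(0.0, t - 1.0, target_length)
    values = np.empty((target_length, record.values.shape[1]))
    for j in range(record.values.shape[1]):
        values[:, j] = np.interp(new_grid, old_grid, record.values[:, j])
    # stretch the per-sample interval so the record keeps its physical time span
    interval = record.sampling_interval_ms * (t - 1) / (target_length - 1)
    interval = float(np.clip(interval, 18.0, 230.0))
    return SignatureRecord(
        subject_id=record.subject_id,
        round_index=record.round_index,
        session=record.session,
        device=record.device,
        values=values,
        sampling_interval_ms=interval,
        channels=record.channels,
    )


def split_dataset(
    dataset: SignatureDataset, spec: SplitSpec
) -> tuple[SignatureDataset, SignatureDataset]:
    """Disjoint, exhaustive train/test partition; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    test_keys: set[tuple[str, int, int]] = set()
    if spec.stratify_by_subject:
        for subject in dataset.subjects:
            recs = sorted(
                (r for r in dataset if r.subject_id == subject),
                key=lambda r: (r.round_index, r.session),
            )
            n_i = len(recs)
            if n_i < 2:
                raise StratificationError(
                    f"subject {subject!r} has only {n_i} record(s); stratified splitting "
                    "needs at least 2 per subject"
                )
            n_test = int(np.floor(n_i * spec.test_fraction))
            if n_test == 0 and n_i >= 5:
                n_test = 1
            if n_i - n_test < 1:
                raise StratificationError(
                    f"subject {subject!r} has {n_i} record(s); cannot keep one in training"
                )
            order = rng.permutation(n_i)
            test_keys.update(recs[i].key for i in order[:n_test])
    else:
        recs = sorted(dataset.records, key=lambda r: r.key)
        n_test = int(np.floor(len(recs) * spec.test_fraction))
        order = rng.permutation(len(recs))
        test_keys.update(recs[i].key for i in order[:n_test])

    train = [r for r in dataset if r.key not in test_keys]
    test = [r for r in dataset if r.key in test_keys]
    split_meta = {
        "test_fraction": spec.test_fraction,
        "stratified": spec.stratify_by_subject,
        "seed": spec.seed,
    }
    return (
        dataset.replace_records(train, split={"role": "train", **split_meta}),
        dataset.replace_records(test, split={"role": "test", **split_meta}),
    )


def reweight_for_missing(
    train: SignatureDataset, full_counts: dict[str, int]
) -> list[tuple[SignatureRecord, float]]:
    """Sampling weight expected_count / actual_count per record, compensating
    subjects with lost recordings; complete subjects get weight 1."""
    actual = {s: len(rs) for s, rs in train.by_subject().items()}
    for subject, expected in full_counts.items():
        if actual.get(subject, 0) == 0:
            raise DataError(f"subject {subject!r} has zero records; cannot re-weight")
    out = []
    for rec in train:
        expected = full_counts.get(rec.subject_id, actual[rec.subject_id])
        out.append((rec, expected / actual[rec.subject_id]))
    return out


def extract_coalition(dataset: SignatureDataset, coalition: Coalition) -> SignatureDataset:
    """Restrict every record to the coalition's channels (canonical order kept)."""
    if len(coalition) == 0:
        raise EmptyCoalitionError("cannot project a dataset onto the empty coalition")
    n_ch = len(dataset.channels)
    if any(m >= n_ch for m in coalition):
        raise ConfigError(
            f"coalition {coalition.members} out of range for {n_ch}-channel dataset"
        )
    channels = tuple(dataset.channels[m] for m in coalition)
    records = [
        SignatureRecord(
            subject_id=r.subject_id,
            round_index=r.round_index,
            session=r.session,
            device=r.device,
            values=r.values[:, list(coalition.members)],
            sampling_interval_ms=r.sampling_interval_ms,
            channels=channels,
        )
        for r in dataset
    ]
    out = SignatureDataset(
        records=records,
        device=dataset.device,
        channels=channels,
        provenance={**dataset.provenance, "coalition": list(coalition.members)},
    )
    return out


def subject_mean_series(dataset: SignatureDataset, horizon: int = 1000) -> pd.DataFrame:
    """Per-subject 1-D summary: average over channels and repetitions, `horizon` steps.

    Records longer than the horizon are truncated; shorter ones are linearly
    resampled up to it.  Returns a (subjects x horizon) DataFrame.
    """
    if len(dataset) == 0:
        raise DataError("cannot summarize an empty dataset")
    if horizon < 2:
        raise ConfigError(f"horizon must be >= 2, got {horizon}")
    rows: dict[str, list[np.ndarray]] = {}
    for rec in dataset:
        series = rec.values.mean(axis=1)
        if series.size >= horizon:
            series = series[:horizon]
        else:
            grid = np.linspace(0.0, series.size - 1.0, horizon)
            series = np.interp(grid, np.arange(series.size), series)
        rows.setdefault(rec.subject_id, []).append(series)
    subjects = sorted(rows)
    matrix = np.vstack([np.mean(rows[s], axis=0) for s in subjects])
    return pd.DataFrame(matrix, index=subjects)


def dataset_to_arrays(
    dataset: SignatureDataset, target_length: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Length-standardize and stack a corpus into (X, y, subjects).

    X has shape (n_records, target_length, n_channels); y holds integer labels
    indexing the sorted subject list.
    """
    subjects = dataset.subjects
    label = {s: i for i, s in enumerate(subjects)}
    recs = sorted(dataset.records, key=lambda r: r.key)
    x = np.stack([standardize_length(r, target_length).values for r in recs])
    y = np.array([label[r.subject_id] for r in recs], dtype=np.int64)
    return x, y, subjects
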