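"""Exhaustive coalition experiments and exact Shapley-value channel attribution.

The sensor channels are treated as cooperating players in a coalitional game
whose characteristic function v(S) is the validation accuracy of a classifier
trained on exactly the channels in S.  With p channels there are 2^p
coalitions (the empty set included); training all non-empty coalitions gives
the complete characteristic map, from which the exact Shapley value of
channel i is the coalition-size-weighted average of its marginal accuracy
contributions:

    phi_i = sum over S in P\\{i} of  |S|! (p-|S|-1)! / p!  * [v(S+i) - v(S)]

The empty coalition cannot train a model; its value defaults to chance
accuracy 1/n_classes (a `zero` baseline is available).  Efficiency then reads
sum(phi) = v(P) - v(empty), which holds exactly and is asserted on every
computed map.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from airsig.errors import ConfigError, DataError, IncompleteMapError
from airsig.models import ModelSpec, TrainConfig, build_model, train_model
from airsig.preprocess import Coalition, SplitSpec, split_dataset
from airsig.preprocess import dataset_to_arrays
from airsig.schema import SignatureDataset

log = logging.getLogger(__name__)


def enumerate_coalitions(p: int) -> list[Coalition]:
    """All 2^p channel subsets (empty set included), ordered by size then
    lexicographically."""
    if not 1 <= p <= 20:
        raise ConfigError(f"player count must be in 1..20, got {p}")
    subsets: list[tuple[int, ...]] = []
    for mask in range(2**p):
        subsets.append(tuple(i for i in range(p) if mask >> i & 1))
    subsets.sort(key=lambda s: (len(s), s))
    return [Coalition(s) for s in subsets]


@dataclass
class CharacteristicMap:
    """Coalition -> value mapping: the v(S) of the attribution game."""

    p: int
    values: dict[tuple[int, ...], float]
    baseline: float
    provenance: dict = field(default_factory=dict)

    def value(self, coalition: Coalition | Sequence[int]) -> float:
        members = tuple(coalition.members if isinstance(coalition, Coalition) else sorted(coalition))
        if members == ():
            return self.baseline
        return self.values[members]

    @property
    def complete(self) -> bool:
        return len(self.missing_coalitions()) == 0

    def missing_coalitions(self) -> list[tuple[int, ...]]:
        present = set(self.values) | {()}
        return [c.members for c in enumerate_coalitions(self.p) if c.members not in present]

    @property
    def grand_value(self) -> float:
        return self.value(tuple(range(self.p)))


@dataclass
class ShapleyReport:
    """Raw per-channel Shapley values and their percentage shares."""

    phi: np.ndarray
    shares: np.ndarray
    grand_value: float
    baseline: float
    channels: Optional[tuple[str, ...]] = None

    def as_frame(self) -> pd.DataFrame:
        names = self.channels or tuple(f"ch{i}" for i in range(self.phi.size))
        return pd.DataFrame({"channel": names, "phi": self.phi, "share_pct": self.shares})


def shapley_values(char: CharacteristicMap,
                   channels: Optional[tuple[str, ...]] = None) -> ShapleyReport:
    """Exact Shapley values from a complete characteristic map."""
    missing = char.missing_coalitions()
    if missing:
        raise IncompleteMapError(
            f"characteristic map is missing {len(missing)} coalition(s), e.g. {missing[:5]}"
        )
    p = char.p
    fact = [math.factorial(k) for k in range(p + 1)]
    phi = np.zeros(p)
    for coalition in enumerate_coalitions(p):
        s = coalition.members
        v_s = char.value(s)
        weight = fact[len(s)] * fact[p - len(s) - 1] / fact[p]
        for i in range(p):
            if i in coalition:
                continue
            v_si = char.value(tuple(sorted(s + (i,))))
            phi[i] += weight * (v_si - v_s)
    try:
        shares = normalize_shares(phi)
    except DataError:
        # degenerate game: no channel with a positive contribution
        log.warning("all Shapley values non-positive; percentage shares undefined")
        shares = np.full(p, np.nan)
    report = ShapleyReport(
        phi=phi,
        shares=shares,
        grand_value=char.grand_value,
        baseline=char.baseline,
        channels=channels,
    )
    residual = abs(phi.sum() - (report.grand_value - report.baseline))
    if residual > 1e-9:
        raise AssertionError(f"efficiency axiom violated: residual {residual}")  # pragma: no cover
    return report


def normalize_shares(phi: np.ndarray) -> np.ndarray:
    """Percentage shares summing to 100.  Negative raw values (possible with
    noisy accuracies) are clipped to zero before renormalization, with a
    logged warning."""
    phi = np.asarray(phi, dtype=np.float64)
    if (phi < 0).any():
        log.warning("negative Shapley values clipped to 0 for percentage shares: %s", phi)
        phi = np.clip(phi, 0.0, None)
    total = phi.sum()
    if total == 0:
        raise DataError("cannot normalize shares: all Shapley values are zero")
    return 100.0 * phi / total


def compute_characteristic(
    dataset: SignatureDataset,
    architecture: str,
    train_config: TrainConfig,
    input_length: int = 100,
    params: Optional[dict] = None,
    baseline: str = "chance",
    test_fraction: float = 0.2,
    cache_dir: Optional[str | Path] = None,
    coalitions: Optional[Sequence[Coalition]] = None,
) -> CharacteristicMap:
    """Train one classifier per non-empty channel coalition and record its
    validation accuracy.

    One shared subject-stratified split and one shared training seed are used
    across all coalitions, isolating the channel effect from sampling noise.
    With `cache_dir` set, per-coalition results are stored as JSON keyed by a
    configuration hash so interrupted runs resume.
    """
    p = len(dataset.channels)
    if coalitions is None:
        coalitions = enumerate_coalitions(p)
    n_classes = dataset.n_subjects
    if baseline == "chance":
        base_value = 1.0 / n_classes
    elif baseline == "zero":
        base_value = 0.0
    else:
        raise ConfigError(f"baseline must be 'chance' or 'zero', got {baseline!r}")

    train_ds, test_ds = split_dataset(
        dataset, SplitSpec(test_fraction=test_fraction, seed=train_config.seed)
    )
    x_tr, y_tr, _ = dataset_to_arrays(train_ds, input_length)
    x_te, y_te, _ = dataset_to_arrays(test_ds, input_length)

    config_key = _config_hash(
        architecture, input_length, params, train_config, p, len(dataset), test_fraction
    )
    cache_path = Path(cache_dir) if cache_dir else None
    if cache_path:
        cache_path.mkdir(parents=True, exist_ok=True)

    values: dict[tuple[int, ...], float] = {}
    nonempty = [c for c in coalitions if len(c) > 0]
    for idx, coalition in enumerate(nonempty, start=1):
        members = coalition.members
        cached = _cache_load(cache_path, members, config_key)
        if cached is not None:
            values[members] = cached
            continue
        cols = list(members)
        spec = ModelSpec(
            architecture=architecture, input_length=input_length,
            n_channels=len(cols), n_classes=n_classes, params=params or {},
        )
        model = build_model(spec, seed=train_config.seed)
        result = train_model(
            model, (x_tr[:, :, cols], y_tr), (x_te[:, :, cols], y_te),
            train_config, spec=spec,
        )
        values[members] = result.val_acc
        _cache_store(cache_path, members, config_key, result.val_acc)
        log.info("coalition %d/%d %s -> val acc %.4f", idx, len(nonempty), members, result.val_acc)

    return CharacteristicMap(
        p=p, values=values, baseline=base_value,
        provenance={
            "architecture": architecture, "input_length": input_length,
            "params": params or {}, "seed": train_config.seed,
            "baseline": baseline, "config_hash": config_key,
            "n_records": len(dataset), "channels": list(dataset.channels),
        },
    )


def compatibility_curves(char: CharacteristicMap) -> pd.DataFrame:
    """Mean accuracy by coalition size, overall and per channel when the
    channel is included vs excluded.

    Tidy frame with columns size, channel ('all' for the global curve),
    condition ('all' | 'include' | 'exclude') and mean_value; the exclude
    condition is undefined (absent) at size p.
    """
    missing = char.missing_coalitions()
    if missing:
        raise IncompleteMapError(f"characteristic map incomplete: {len(missing)} coalition(s) missing")
    rows = []
    by_size: dict[int, list[tuple[tuple[int, ...], float]]] = {}
    for coalition in enumerate_coalitions(char.p):
        if len(coalition) == 0:
            continue
        by_size.setdefault(len(coalition), []).append((coalition.members, char.value(coalition)))
    for size, entries in sorted(by_size.items()):
        vals = [v for _, v in entries]
        rows.append({"size": size, "channel": "all", "condition": "all",
                     "mean_value": float(np.mean(vals))})
        for i in range(char.p):
            inc = [v for members, v in entries if i in members]
            exc = [v for members, v in entries if i not in members]
            rows.append({"size": size, "channel": str(i), "condition": "include",
                         "mean_value": float(np.mean(inc))})
            if exc:
                rows.append({"size": size, "channel": str(i), "condition": "exclude",
                             "mean_value": float(np.mean(exc))})
    return pd.DataFrame(rows)


def coalition_experiment_count(p: int = 9, n_devices: int = 2) -> dict[str, int]:
    """Design sizes of the exhaustive coalition study."""
    per_device = 2**p
    return {
        "coalitions_per_device": per_device,
        "experiments": per_device * n_devices,
    }


def _config_hash(architecture, input_length, params, config: TrainConfig,
                 p, n_records, test_fraction) -> str:
    payload = json.dumps({
        "arch": architecture, "input_length": input_length,
        "params": params or {}, "optimizer": config.optimizer,
        "lr": config.learning_rate, "epochs": config.epochs,
        "batch": config.batch_size, "seed": config.seed,
        "normalize": config.normalize, "paper_defaults": config.paper_defaults,
        "p": p, "n_records": n_records, "test_fraction": test_fraction,
    }, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def _cache_file(cache_path: Path, members: tuple[int, ...]) -> Path:
    tag = "-".join(map(str, members))
    return cache_path / f"coalition_{tag}.json"


def _cache_load(cache_path: Optional[Path], members, config_key) -> Optional[float]:
    if cache_path is None:
        return None
    f = _cache_file(cache_path, members)
    if not f.exists():
        return None
    data = json.loads(f.read_text())
    if data.get("config_hash") != config_key:
        return None
    return float(data["value"])


def _cache_store(cache_path: Optional[Path], members, config_key, value: float) -> None:
    if cache_path is None:
        return
    _cache_file(cache_path, members).write_text(json.dumps({
        "members": list(members), "config_hash": config_key, "value": value,
    }))
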