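"""Readers and writers for the per-signature CSV dialect.

One file per signature: a header row with the 9 channel names followed by T
numeric rows.  Both documented header spellings are accepted (``acc_x`` /
``Acc_x``, and ``Ori_*`` as an alias for the attitude channels ``att_*``);
columns may appear in any order and are normalized to the canonical layout.
A corpus is a directory of files named ``{subject}_{round}_{session}.csv``
with an optional ``provenance.json`` sidecar.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from airsig.errors import EmptySignalError, IntegrityError, ParseError, SchemaError
from airsig.schema import CHANNEL_NAMES, SignatureDataset, SignatureRecord

log = logging.getLogger(__name__)

_FILENAME_RE = re.compile(r"^(?P<subject>.+)_(?P<round>\d+)_(?P<session>[12])\.csv$")


def normalize_channel_name(raw: str) -> str:
    """Map a header spelling onto the canonical abbreviation.

    Raises :class:`SchemaError` if the name is not a documented spelling.
    """
    name = raw.strip().lower()
    if name.startswith("ori_"):
        name = "att_" + name[4:]
    if name not in CHANNEL_NAMES:
        raise SchemaError(f"unrecognized channel column {raw!r}")
    return name


def read_signature_csv(
    path: str | Path,
    *,
    subject_id: str,
    round_index: int,
    session: int,
    device: str,
    sampling_interval_ms: float = 222.5,
) -> SignatureRecord:
    """Read one per-signature CSV into a :class:`SignatureRecord`.

    Columns are normalized to canonical order regardless of the order in the
    file.  Row order is preserved.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=0, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise EmptySignalError(f"{path}: file is empty") from None

    canonical = []
    for col in frame.columns:
        canonical.append(normalize_channel_name(str(col)))
    if sorted(canonical) != sorted(CHANNEL_NAMES):
        missing = set(CHANNEL_NAMES) - set(canonical)
        raise SchemaError(f"{path}: header does not cover the 9 channels (missing {sorted(missing)})")
    frame.columns = canonical

    if len(frame) < 2:
        raise EmptySignalError(f"{path}: fewer than 2 data rows")

    frame = frame[list(CHANNEL_NAMES)]
    values = np.empty((len(frame), 9), dtype=np.float64)
    for j, col in enumerate(CHANNEL_NAMES):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = np.nonzero(converted.isna().to_numpy())[0]
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric cell at data row {bad[0] + 1}, column {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=np.float64)

    return SignatureRecord(
        subject_id=subject_id,
        round_index=round_index,
        session=session,
        device=device,
        values=values,
        sampling_interval_ms=sampling_interval_ms,
    )


def write_signature_csv(record: SignatureRecord, path: str | Path) -> Path:
    """Write a record to CSV with 6 decimal places; inverse of :func:`read_signature_csv`."""
    path = Path(path)
    frame = pd.DataFrame(record.values, columns=list(record.channels))
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def record_filename(record: SignatureRecord) -> str:
    return f"{record.subject_id}_{record.round_index}_{record.session}.csv"


def save_dataset(dataset: SignatureDataset, root: str | Path) -> Path:
    """Write a corpus as a directory of per-signature CSVs plus a provenance sidecar."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for rec in dataset:
        write_signature_csv(rec, root / record_filename(rec))
    sidecar = {
        "device": dataset.device,
        "channels": list(dataset.channels),
        "n_records": len(dataset),
        "sampling_interval_ms": {
            record_filename(r): r.sampling_interval_ms for r in dataset
        },
        "provenance": _jsonable(dataset.provenance),
    }
    (root / "provenance.json").write_text(json.dumps(sidecar, indent=2))
    return root


def load_dataset(root: str | Path, device: str) -> SignatureDataset:
    """Load a directory of per-signature CSVs into a :class:`SignatureDataset`.

    Files that do not follow the ``{subject}_{round}_{session}.csv`` naming
    convention are skipped with a logged warning; duplicate metadata triples
    raise :class:`IntegrityError`.
    """
    root = Path(root)
    sidecar = {}
    sidecar_path = root / "provenance.json"
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar.get("device") and sidecar["device"] != device:
            raise IntegrityError(
                f"{root}: sidecar records device {sidecar['device']!r}, requested {device!r}"
            )
    intervals = sidecar.get("sampling_interval_ms", {})

    records = []
    paths = sorted(p for p in root.glob("*.csv"))
    if not paths:
        log.warning("load_dataset: no CSV files under %s", root)
    for path in paths:
        m = _FILENAME_RE.match(path.name)
        if m is None:
            log.warning("load_dataset: skipping %s (does not match subject_round_session.csv)", path.name)
            continue
        rec = read_signature_csv(
            path,
            subject_id=m["subject"],
            round_index=int(m["round"]),
            session=int(m["session"]),
            device=device,
            sampling_interval_ms=float(intervals.get(path.name, 222.5)),
        )
        records.append(rec)
    return SignatureDataset(
        records=records,
        device=device,
        provenance={"source": str(root), "n_files": len(paths), **sidecar.get("provenance", {})},
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
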