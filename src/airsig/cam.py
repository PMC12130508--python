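"""Class activation maps for the global-average-pooling architectures.

For a network ending in global average pooling followed by a linear softmax
head (FCN, ResNet, InceptionTime), the class activation map for class c is
the head-weighted sum of the last convolutional feature maps,

    CAM_c(t) = sum_k w_k^c f_k(t),

linearly upsampled to the input length and min-max normalized to [0, 1].
High values mark the time regions most discriminative for the class — for
in-air signatures typically the heavy strokes, though the start/end dwell
segments sometimes contribute too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from airsig.errors import ConfigError, UnsupportedArchitectureError
from airsig.models import GAPNet
from airsig.nn import Module
from airsig.schema import SignatureRecord


@dataclass
class CAMResult:
    activation: np.ndarray     # length = input length, in [0, 1]
    raw: np.ndarray            # pre-normalization weighted feature sum
    class_index: int


def compute_cam(
    model: Module,
    record: Union[SignatureRecord, np.ndarray],
    class_index: int,
    input_length: Optional[int] = None,
    normalization: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> CAMResult:
    """Class activation map of `record` for `class_index`.

    `model` must be a trained GAP-headed network; `record` is a single
    signature (or a (length, channels) array) matching the model's channel
    count.  `normalization` is the (mean, std) pair the model was trained
    with, if any.
    """
    if not isinstance(model, GAPNet):
        raise UnsupportedArchitectureError(
            "class activation maps need a global-average-pooling head "
            "(FCN, ResNet or InceptionTime)"
        )
    x = record.values if isinstance(record, SignatureRecord) else np.asarray(record, dtype=np.float64)
    if x.ndim != 2:
        raise ConfigError(f"record must be a (length, channels) matrix, got shape {x.shape}")
    length = input_length or x.shape[0]
    if x.shape[0] != length:
        grid = np.linspace(0.0, x.shape[0] - 1.0, length)
        x = np.stack([np.interp(grid, np.arange(x.shape[0]), x[:, j]) for j in range(x.shape[1])], axis=1)
    if normalization is not None:
        mean, std = normalization
        x = (x - mean) / std

    head_w = model.head.w.value
    if not 0 <= class_index < head_w.shape[1]:
        raise ConfigError(f"class_index {class_index} out of range 0..{head_w.shape[1] - 1}")

    model.forward(x[None], training=False)
    feats = model.features_[0]                      # (L', K)
    raw_short = feats @ head_w[:, class_index]      # (L',)

    if raw_short.size == length:
        raw = raw_short
    else:
        grid = np.linspace(0.0, raw_short.size - 1.0, length)
        raw = np.interp(grid, np.arange(raw_short.size), raw_short)

    span = raw.max() - raw.min()
    activation = np.zeros_like(raw) if span == 0 else (raw - raw.min()) / span
    return CAMResult(activation=activation, raw=raw, class_index=int(class_index))
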