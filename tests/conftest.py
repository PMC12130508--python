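"""Shared fixtures: small seeded synthetic corpora and published sample rows."""

import numpy as np
import pytest

from airsig.schema import SignatureRecord
from airsig.synthetic import GeneratorConfig, generate_dataset

# First rows of the published phone sample recording (subject 1, signature 1);
# columns in canonical order, attitude columns printed under the Ori_* spelling.
PHONE_SAMPLE_ROWS = np.array([
    [-0.44313, -8.78151, 4.868727, -10.784, 0.039824, -5.61297, 2.446671, -1.38939, -18.3264],
    [-0.48447, -8.56189, 3.485494, -12.9766, -0.40324, -2.60337, 0.356771, 1.152709, -2.50698],
    [-0.61656, -8.61197, 2.981159, -13.828, -0.51613, -1.65867, -0.28343, 1.931627, 2.336218],
    [-0.77201, -8.78855, 3.000329, -13.7056, -0.46182, -1.93873, -0.28343, 1.931627, 2.336218],
    [-0.88342, -8.94843, 3.187611, -12.9766, -0.40324, -2.60337, -0.28343, 1.931627, 2.336218],
    [-0.88342, -8.94843, 3.187611, -11.9682, -0.46815, -2.97202, -0.28343, 1.931627, 2.336218],
    [-0.72352, -8.68269, 2.726951, -10.8453, -0.6436, -3.00261, -0.28343, 1.931627, 2.336218],
    [-0.43086, -8.19468, 1.860314, -9.73243, -0.88144, -2.81264, -0.28343, 1.931627, 2.704359],
    [-0.05149, -7.56522, 0.724398, -8.75415, -1.13354, -2.51963, -0.28343, 1.931627, 2.985879],
])

# First rows of the published smartwatch sample recording (subject 1, signature 1).
WATCH_SAMPLE_ROWS = np.array([
    [0.006494, 0.009239, 0.01121, 0.086356, 0.029508, 0.011415, 0.45407, 0.70815, 0.070161],
    [-0.00074, 0.01422, 0.001814, 0.088319, 0.029273, 0.027723, 0.455669, 0.708618, 0.070167],
    [-0.00668, 0.013277, -0.00159, 0.066002, 0.026148, 0.058603, 0.456869, 0.709155, 0.070393],
    [-0.00844, 0.017108, 0.001519, 0.037187, 0.023975, 0.072369, 0.457283, 0.70961, 0.070874],
    [-0.00716, 0.013046, -0.00435, 0.019389, 0.026953, 0.083881, 0.457445, 0.710026, 0.071477],
    [0.003638, 0.006969, -0.00419, 0.010959, 0.020459, 0.093629, 0.457578, 0.710534, 0.072157],
    [0.011639, 0.002621, -0.00286, 0.029967, 0.015235, 0.077567, 0.457893, 0.710999, 0.072829],
    [0.012988, 0.001942, -0.01286, 0.070353, 0.018348, 0.053111, 0.45838, 0.711309, 0.073376],
    [0.01261, 0.007601, -0.01088, 0.115285, 0.029243, 0.035008, 0.459069, 0.711681, 0.073653],
])


@pytest.fixture(scope="session")
def toy_dataset():
    """5 subjects x 6 repetitions, short records, strongly subject-specific."""
    config = GeneratorConfig(
        n_subjects=5, n_repetitions=6, duration_steps=60, dwell_steps=3,
        channel_informativeness=(0.9,) * 9, repetition_noise_sd=0.5, seed=11,
    )
    return generate_dataset(config, "phone")


@pytest.fixture
def one_record(toy_dataset):
    return toy_dataset.records[0]


def make_record(values, subject="s001", round_index=1, session=1, device="phone",
                interval=222.5, channels=None):
    kwargs = {} if channels is None else {"channels": tuple(channels)}
    return SignatureRecord(
        subject_id=subject, round_index=round_index, session=session,
        device=device, values=np.asarray(values, dtype=float),
        sampling_interval_ms=interval, **kwargs,
    )
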