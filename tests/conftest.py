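import numpy as np
import pandas as pd
import pytest

from upalign.records import RecordSet


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def make_recordset(
    scores,
    labels=None,
    device_id="dev",
    time_index=0,
    images_per_case=1,
    prefix="c",
):
    """Build a small RecordSet from plain vectors (one image per row)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    case = np.repeat(
        [f"{prefix}{i}" for i in range(int(np.ceil(n / images_per_case)))],
        images_per_case,
    )[:n]
    df = pd.DataFrame(
        {
            "score": scores,
            "label": np.nan if labels is None else np.asarray(labels, dtype=float),
            "case_id": case,
            "image_id": [f"{prefix}img{i}" for i in range(n)],
            "device_id": device_id,
            "time_index": time_index,
        }
    )
    return RecordSet(df)


@pytest.fixture
def tiny_labelled():
    return make_recordset([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
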