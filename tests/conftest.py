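import numpy as np
import pytest

from fedhetero.aggregation import ClientReport, LabelDistribution
from fedhetero.params import ParamVector


def make_report(client_id, n_train, probs, head, backbone=(0.0,)):
    """Small helper: a client report with a backbone+head parameter vector."""
    backbone = np.asarray(backbone, dtype=float)
    head = np.asarray(head, dtype=float)
    values = np.concatenate([backbone, head])
    segments = {
        "backbone": (0, backbone.size),
        "head": (backbone.size, backbone.size + head.size),
    }
    return ClientReport(
        client_id=client_id,
        params=ParamVector(values, segments),
        n_train=n_train,
        label_dist=LabelDistribution(probs),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
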