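import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from netprio.network import AssociationNetwork

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def path_net():
    """The 3-node path A-B-C with confidences c_AB=1.0, c_BC=0.5."""
    return AssociationNetwork.from_edges([("A", "B", 1.0), ("B", "C", 0.5)])


@pytest.fixture
def path_sig():
    """Signature giving signal x = (A: 2, B: 0, C: 1) under -log10 P."""
    return pd.DataFrame({
        "gene": ["A", "B", "C"],
        "log2_ratio": [1.5, 0.0, -0.8],
        "p_value": [0.01, 1.0, 0.1],
    })


@pytest.fixture
def two_group_matrix():
    """120 genes x (3 control + 3 treatment), heterogeneous variances,
    first 15 genes shifted."""
    from netprio.io import ExpressionMatrix

    rng = np.random.default_rng(11)
    d0, s0 = 4.0, 0.05
    sigma2 = s0 * d0 / rng.chisquare(d0, 120)
    data = rng.standard_normal((120, 6)) * np.sqrt(sigma2)[:, None]
    data[:15, 3:] += 1.0
    genes = [f"G{i:03d}" for i in range(120)]
    samples = ["C1", "C2", "C3", "T1", "T2", "T3"]
    groups = pd.Series({s: "control" if s.startswith("C") else "treatment"
                        for s in samples})
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples),
                            groups)
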