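import numpy as np
import pandas as pd
import pytest

from metabrobust.features import FeatureTable


def make_feature_table(abundance: dict, roles: dict | None = None,
                       methods: dict | None = None, replicates: dict | None = None,
                       design_runs: dict | None = None, injection_order: dict | None = None,
                       mz0: float = 200.0) -> FeatureTable:
    """Build a FeatureTable from {feature_id: {sample_id: abundance-or-None}}."""
    fids = list(abundance)
    samples = sorted(
        {s for row in abundance.values() for s in row}
        | set(roles or {}) | set(methods or {}) | set(design_runs or {})
        | set(injection_order or {})
    )
    mat = pd.DataFrame(
        [[abundance[f].get(s, None) for s in samples] for f in fids],
        index=pd.Index(fids, name="feature_id"), columns=samples, dtype=float,
    )
    features = pd.DataFrame(
        {
            "mz": [mz0 + i for i in range(len(fids))],
            "rt": [1.0 + 0.5 * i for i in range(len(fids))],
            "adduct_group": pd.array([pd.NA] * len(fids), dtype="Int64"),
        },
        index=mat.index,
    )
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "role": [(roles or {}).get(s, "study") for s in samples],
            "method": [(methods or {}).get(s) for s in samples],
            "replicate": [(replicates or {}).get(s) for s in samples],
            "design_run": [(design_runs or {}).get(s) for s in samples],
            "injection_order": [(injection_order or {}).get(s) for s in samples],
        },
        index=pd.Index(samples),
    )
    return FeatureTable(features=features, abundance=mat, samples=meta)


@pytest.fixture
def table1():
    from metabrobust.design import load_table1_design

    return load_table1_design()


@pytest.fixture
def design15():
    """Generated 12-run design for 11 factors with 3 interleaved centre points."""
    from metabrobust.design import add_centre_points, generate_pb_matrix

    return add_centre_points(generate_pb_matrix(11), 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
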