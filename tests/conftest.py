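import numpy as np
import pandas as pd
import pytest

from cernaffl.data_io import ExpressionMatrix, RegulatoryEdge


def make_meta(n_pairs: int) -> pd.DataFrame:
    rows = []
    for p in range(n_pairs):
        rows.append({"sample_id": f"P{p:03d}_N", "condition": "normal", "pair_id": f"P{p:03d}"})
        rows.append({"sample_id": f"P{p:03d}_T", "condition": "tumor", "pair_id": f"P{p:03d}"})
    return pd.DataFrame(rows).set_index("sample_id")


def make_matrix(values: np.ndarray, feature_ids=None, feature_type="mRNA",
                meta=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n_feat, n_samples = values.shape
    if feature_ids is None:
        feature_ids = [f"F{i:03d}" for i in range(n_feat)]
    if meta is None:
        assert n_samples % 2 == 0
        meta = make_meta(n_samples // 2)
    df = pd.DataFrame(values, index=feature_ids, columns=meta.index)
    return ExpressionMatrix(df, meta, feature_type)


def mirna_edge(src: str, tgt: str, **kw) -> RegulatoryEdge:
    return RegulatoryEdge(src, "miRNA", tgt, "gene", **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
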