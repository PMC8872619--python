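import pandas as pd
import pytest

from ncregnet.network import RegulatoryNetwork


def make_de_table(ids, feature_class, log2fc=2.0, pvalue=1e-5, qvalue=1e-4):
    """DE table whose rows pass the default thresholds unless overridden."""
    n = len(ids)
    as_list = lambda v: list(v) if hasattr(v, "__len__") else [v] * n
    return pd.DataFrame({
        "feature_id": list(ids),
        "feature_class": feature_class,
        "log2fc": as_list(log2fc),
        "pvalue": as_list(pvalue),
        "qvalue": as_list(qvalue),
    })


def make_network(edges):
    """Network from (regulator_id, regulator_class, target_gene) triples."""
    rows = [
        {"regulator_id": r, "regulator_class": c, "target_gene": t,
         "source_db": "testdb", "evidence": "manual"}
        for r, c, t in edges
    ]
    frame = pd.DataFrame(
        rows,
        columns=["regulator_id", "regulator_class", "target_gene",
                 "source_db", "evidence"],
    )
    return RegulatoryNetwork(edges=frame)


@pytest.fixture
def star_network():
    """One miRNA regulating five genes."""
    return make_network([("miR-a", "miRNA", f"G{i}") for i in range(1, 6)])
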