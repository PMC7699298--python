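import numpy as np
import pandas as pd
import pytest

from mirtrend.pool import PoolCountTable
from mirtrend.qpcr import CtTable
from mirtrend.screen import ExpressionStudy


def make_study(mono_means, csc_means, replicates=2, noise_sd=0.0, seed=0, n_genes=1):
    """Expression study from per-treatment means (inhibitor, control, mimic)
    for each context; every gene gets the same means."""
    rng = np.random.default_rng(seed)
    treatments = ("inhibitor", "control", "mimic")
    cols, design_rows = [], []
    for ctx, means in (("monolayer", mono_means), ("csc", csc_means)):
        for trt, mu in zip(treatments, means):
            for r in range(1, replicates + 1):
                sid = f"{ctx}_{trt}_r{r}"
                design_rows.append(
                    {"sample_id": sid, "context": ctx, "treatment": trt, "replicate": r}
                )
                noise = rng.normal(0, noise_sd, n_genes) if noise_sd > 0 else 0.0
                cols.append(np.full(n_genes, float(mu)) + noise)
    expr = pd.DataFrame(
        np.column_stack(cols),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[d["sample_id"] for d in design_rows],
    )
    return ExpressionStudy(expression=expr, design=pd.DataFrame(design_rows).set_index("sample_id"))


def make_ct_table(rows):
    """CtTable from (sample, condition, assay, replicate, ct) tuples."""
    return CtTable(
        pd.DataFrame(rows, columns=["sample_id", "condition", "assay", "replicate", "ct"])
    )


@pytest.fixture
def two_group_table():
    counts = pd.DataFrame(
        {
            "a1": [100, 200, 50, 400],
            "a2": [110, 190, 55, 410],
            "b1": [300, 220, 60, 380],
            "b2": [290, 210, 65, 390],
        },
        index=["m1", "m2", "m3", "m4"],
    )
    groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    return PoolCountTable(counts=counts, groups=groups)
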