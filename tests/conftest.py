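import numpy as np
import pandas as pd
import pytest

from hepatarget.annotation_and_peaks import GeneModel, Peak
from hepatarget.synthetic_data import ScenarioConfig, make_bundle
from hepatarget.transcriptome_dynamics import ExpressionMatrix


@pytest.fixture
def plus_gene():
    return GeneModel("G1", "G1", "chr1", "+", 999, 2000)


@pytest.fixture
def minus_gene():
    return GeneModel("G2", "G2", "chr1", "-", 999, 2000)


@pytest.fixture
def small_expr():
    """Two conditions × two days × two replicates, 4 genes, no noise."""
    genes = ["A", "B", "C", "D"]
    columns, meta_rows, data = [], [], {}
    base = {"A": 32.0, "B": 8.0, "C": 100.0, "D": 0.0}
    for condition in ("control", "depleted"):
        for day in (5, 8):
            for rep in (1, 2):
                name = f"{condition[:4]}_d{day}_r{rep}"
                columns.append(name)
                meta_rows.append(
                    {"sample": name, "condition": condition, "day": day, "replicate": rep}
                )
                col = dict(base)
                if condition == "control" and day == 8:
                    col["A"] = 32.0 * 8  # induced 8-fold
                if condition == "depleted":
                    col["B"] = 1.0  # reduced 8-fold
                data[name] = [col[g] for g in genes]
    values = pd.DataFrame(data, index=genes)[columns]
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionMatrix(values, meta)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = ScenarioConfig(seed=11)
    bundle, manifest = make_bundle(config, outdir)
    return config, bundle, manifest
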