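import numpy as np
import pandas as pd
import pytest

from bicellnet.datatypes import ExpressionMatrix
from bicellnet.simulate import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def default_sim():
    """One moderately sized simulated experiment shared across tests."""
    return simulate_expression(SimulationConfig(n_genes=800, seed=11))


@pytest.fixture()
def small_matrix():
    """Tiny handmade matrix: 4 genes, 2 cell types x 2 groups x 2 reps."""
    samples = [f"{c}_{g}_r{r}" for c in ("SC", "MAC")
               for g in ("mut-1mo", "mut-7mo") for r in (1, 2)]
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.normal(6.0, 1.0, size=(4, len(samples))),
        index=["GA", "GB", "GC", "GD"], columns=samples,
    )
    meta = pd.DataFrame(
        [
            {"cell_type": s.split("_")[0], "group": s.split("_")[1],
             "batch": f"b{int(s[-1]) % 2 + 1}", "replicate": int(s[-1])}
            for s in samples
        ],
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(values, meta)


def make_matrix(values: np.ndarray, genes=None, cell_type="SC", group="g",
                batch=None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with minimal metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes if genes is not None else [f"G{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "cell_type": cell_type,
            "group": group,
            "batch": batch if batch is not None else ["b1"] * n_samples,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)
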