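import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from germscreen import (
    CANONICAL_ROLE_ORDER,
    CountMatrix,
    ExpressionMatrix,
    SampleRole,
    ScreenConfig,
    generate_dataset,
    run_screen,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_count_matrix(data: dict[SampleRole, list[int]], gene_ids=None) -> CountMatrix:
    """Build a CountMatrix from per-role count columns."""
    roles = list(data)
    n = len(next(iter(data.values())))
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    df = pd.DataFrame(
        {f"S_{r.value}": np.asarray(v, dtype=np.int64) for r, v in data.items()},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return CountMatrix(df, {f"S_{r.value}": r for r in roles})


def make_expression_matrix(data: dict[SampleRole, list[float]], gene_ids=None) -> ExpressionMatrix:
    roles = list(data)
    n = len(next(iter(data.values())))
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    df = pd.DataFrame(
        {f"S_{r.value}": np.asarray(v, dtype=float) for r, v in data.items()},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionMatrix(df, {f"S_{r.value}": r for r in roles})


def full_profile(**overrides) -> dict[SampleRole, list[float]]:
    """An 11-role expression dict, zero everywhere unless overridden."""
    n = len(next(iter(overrides.values()))) if overrides else 1
    data = {r: [0.0] * n for r in CANONICAL_ROLE_ORDER}
    for name, values in overrides.items():
        data[SampleRole(name)] = list(values)
    return data


@pytest.fixture(scope="session")
def default_dataset():
    """The default 5,000-gene synthetic dataset (seed 1), generated once."""
    counts, lengths, truth = generate_dataset(seed=1)
    return counts, lengths, truth


@pytest.fixture(scope="session")
def default_screen(default_dataset):
    """Full screen of the default synthetic dataset, run once per session."""
    counts, lengths, truth = default_dataset
    table, summary, contrasts = run_screen(counts, lengths, ScreenConfig())
    return table, summary, contrasts, truth
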