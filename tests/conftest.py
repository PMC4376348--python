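import numpy as np
import pandas as pd
import pytest

from genesetdyn import ExpressionMatrix, GeneSet, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_expr():
    """4 genes x 3 samples with distinct values, one group per sample pair."""
    genes = pd.Index(["G1", "G2", "G3", "G4"], name="gene")
    samples = pd.Index(["s1", "s2", "s3"], name="sample")
    values = pd.DataFrame(
        [[1.0, 4.0, 2.5], [2.0, 3.0, 0.5], [3.0, 2.0, 4.5], [4.0, 1.0, 1.5]],
        index=genes,
        columns=samples,
    )
    group = pd.Series(["a", "a", "b"], index=samples, name="group")
    return ExpressionMatrix(values, group=group)


@pytest.fixture
def tiny_collection():
    return GeneSetCollection(
        {
            "TOP": GeneSet("TOP", "top-ranked pair in s1", ("G3", "G4")),
            "BOTTOM": GeneSet("BOTTOM", "bottom pair in s1", ("G1", "G2")),
        },
        min_size=2,
    )


def random_expression(rng, n_genes, n_samples, groups=None):
    """Helper: random matrix with optional group labels cycling over *groups*."""
    genes = pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene")
    samples = pd.Index([f"s{i:04d}" for i in range(n_samples)], name="sample")
    values = pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)), index=genes, columns=samples
    )
    group = None
    if groups is not None:
        group = pd.Series(
            [groups[i % len(groups)] for i in range(n_samples)], index=samples
        )
    return ExpressionMatrix(values, group=group)


def random_collection(rng, genes, n_sets, min_size=5, max_size=15):
    """Helper: random gene-sets sampled without replacement from *genes*."""
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = tuple(rng.choice(genes, size=size, replace=False))
        name = f"rs{i:03d}"
        sets[name] = GeneSet(name, "random set", members)
    return GeneSetCollection(sets, min_size=min(min_size, 5))
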