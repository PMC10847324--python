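import numpy as np
import pytest

from sctme import synthetic
from sctme.io import CountMatrix
from sctme.preprocess import NormalizedMatrix


def make_count_matrix(rng, n_genes=50, n_cells=100, lam=2.0):
    values = rng.poisson(lam, size=(n_genes, n_cells))
    genes = [f"G{i:04d}" for i in range(n_genes)]
    cells = [f"C{i:04d}" for i in range(n_cells)]
    return CountMatrix(values, genes, cells)


def make_normalized(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    genes = genes if genes is not None else [f"G{i:04d}" for i in range(g)]
    cells = cells if cells is not None else [f"C{i:04d}" for i in range(c)]
    return NormalizedMatrix(values, np.asarray(genes, dtype=object),
                            np.asarray(cells, dtype=object))


def two_type_spec(seed=0, n_cells=400, marker_fold=10.0, planted_lr=()):
    types = [
        synthetic.CellTypeSpec("alpha", 20, marker_fold),
        synthetic.CellTypeSpec("beta", 20, marker_fold),
    ]
    samples = [
        synthetic.SampleSpec("S1", "primary", "HGSOC", n_cells,
                             {"alpha": 0.5, "beta": 0.5}),
    ]
    return synthetic.CohortSpec(
        n_genes=300, cell_types=types, samples=samples,
        planted_lr=list(planted_lr), template_sample_id="S1", seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    spec = two_type_spec(seed=11)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def standard_cohort():
    """8 types, marker_fold 10, 2,000 cells across 2 samples, fixed seed."""
    names = [f"type{i}" for i in range(8)]
    types = [synthetic.CellTypeSpec(n, 25, 10.0) for n in names]
    comp = {n: 1.0 / 8 for n in names}
    samples = [
        synthetic.SampleSpec("S1", "primary", "HGSOC", 1000, comp),
        synthetic.SampleSpec("S2", "metastatic", "HGSOC", 1000, comp),
    ]
    spec = synthetic.CohortSpec(
        n_genes=1000, cell_types=types, samples=samples,
        template_sample_id="S1", seed=2024,
    )
    matrix, cells, truth = synthetic.generate_cohort(spec)
    return spec, matrix, cells, truth
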