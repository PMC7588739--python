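import numpy as np
import pandas as pd
import pytest

import evdeconv as ev
from evdeconv.deconvolution import NormalizedPair


def make_pair(basis: np.ndarray, mixture: np.ndarray, labels=None) -> NormalizedPair:
    """Wrap raw arrays as a NormalizedPair for direct solver tests (no rescaling)."""
    basis = np.asarray(basis, dtype=float)
    mixture = np.asarray(mixture, dtype=float)
    n, p = basis.shape
    if labels is None:
        labels = [f"s{i}" for i in range(p)]
    return NormalizedPair(
        genes=[f"g{i}" for i in range(n)],
        mixture=mixture,
        basis=basis,
        subset_labels=list(labels),
        matched_count=n,
        matched_fraction=1.0,
    )


@pytest.fixture(scope="session")
def blood_reference():
    """Hemopoietic-style reference atlas at the default study conditions (seed 42)."""
    rng = np.random.default_rng(42)
    spec = ev.blood_spec(seed=42)
    atlas, groups = ev.generate_reference(spec, rng)
    return spec, atlas, groups, rng


@pytest.fixture(scope="session")
def blood_signature(blood_reference):
    spec, atlas, groups, _ = blood_reference
    tss = ev.compute_tss(atlas, groups)
    candidates = ev.select_specific_genes(tss, 2)
    return ev.optimize_signature(atlas, groups, candidates, range(2, 51))


@pytest.fixture(scope="session")
def small_signature():
    """A compact 7-subset signature for permutation-heavy tests."""
    rng = np.random.default_rng(3)
    spec = ev.GeneratorSpec(
        n_subsets=7, markers_per_subset=8, samples_per_subset=4, n_background_genes=300, seed=3
    )
    atlas, groups = ev.generate_reference(spec, rng)
    candidates = ev.select_specific_genes(ev.compute_tss(atlas, groups), 2)
    return spec, ev.build_signature(atlas, groups, candidates, 8)


@pytest.fixture()
def tiny_atlas():
    """3 subsets x 2 replicates with clean orthogonal markers plus a flat housekeeping gene."""
    genes = ["mkA1", "mkA2", "mkB1", "mkB2", "mkC1", "mkC2", "hk1"]
    data = {}
    means = {
        "alpha": [100, 80, 1, 1, 1, 1, 50],
        "beta": [1, 1, 120, 90, 1, 1, 50],
        "gamma": [1, 1, 1, 1, 60, 110, 50],
    }
    assignment = {}
    for subset, mu in means.items():
        for r in (1, 2):
            sample = f"{subset}_{r}"
            data[sample] = mu
            assignment[sample] = subset
    atlas = ev.ExpressionMatrix(pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), dtype=float))
    groups = ev.SubsetAssignment(pd.Series(assignment))
    return atlas, groups
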