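import numpy as np
import pandas as pd
import pytest

from rficlass.preprocess import adjust_for_components, normalize, run_pca, top_variable_genes
from rficlass.simulate import SimConfig, generate_counts, generate_phenotypes


@pytest.fixture(scope="session")
def cohort():
    """A small signal-bearing cohort shared by read-only tests."""
    cfg = SimConfig(n_samples=65, n_genes=600, n_signal_genes=30,
                    signal_logfc=1.5, seed=42)
    cm = generate_counts(cfg)
    pheno = generate_phenotypes(cfg, cm.meta["rfi_class"].to_numpy())
    return cfg, cm, pheno


@pytest.fixture(scope="session")
def adjusted(cohort):
    _, cm, _ = cohort
    em = normalize(cm)
    pca = run_pca(em, top_variable_genes(em, min(500, em.shape[0])))
    return adjust_for_components(em, pca, which=(1,)), cm


def normal_equations_residuals(X, y):
    """Independent OLS oracle: solve X'X b = X'y and return y - X b."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta
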