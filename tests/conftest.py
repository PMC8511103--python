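import numpy as np
import pytest

from mvgreml.genotype_grm import compute_grm, maf_filter, standardize
from mvgreml.model import CovariateSet, PhenotypeSet
from mvgreml.simulate import (
    SimulationSpec,
    default_covariances,
    simulate_genotypes,
    simulate_phenotypes,
)


def simulate_dataset(N, M, T, seed, h2=None, r_g=0.4, r_e=0.15, k_covars=2,
                     V_G=None, V_E=None):
    """Genotypes + phenotypes + unit-weight GRM under the generative model."""
    if V_G is None:
        V_G, V_E = default_covariances(T, h2=h2, r_g=r_g, r_e=r_e)
    beta = None
    if k_covars:
        beta = np.vstack([np.full(T, 0.5), np.full(T, -0.25)])[:k_covars]
    spec = SimulationSpec(N=N, M=M, T=T, V_G_true=V_G, V_E_true=V_E,
                          beta_true=beta, seed=seed)
    g = maf_filter(simulate_genotypes(spec), 0.01)
    ph, cov, truth = simulate_phenotypes(g, spec)
    grm = compute_grm(standardize(g), ids=g.ids)
    return grm, ph, cov, truth


def random_instance(rng, n_max=40, t_max=3):
    """A small random model instance for oracle cross-checks."""
    n = int(rng.integers(10, n_max + 1))
    t = int(rng.integers(1, t_max + 1))
    G = rng.standard_normal((n, 3 * n))
    G = (G - G.mean(0)) / G.std(0)
    grm = compute_grm(G)
    ids = grm.ids
    Y = rng.standard_normal((n, t))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    ph = PhenotypeSet(ids=ids, Y=Y, trait_names=[f"y{i}" for i in range(t)])
    cov = CovariateSet.shared(ids, X, t)
    C_G = np.tril(rng.standard_normal((t, t))) * 0.4 + 0.8 * np.eye(t)
    C_E = np.tril(rng.standard_normal((t, t))) * 0.4 + 0.8 * np.eye(t)
    return grm, ph, cov, C_G, C_E


@pytest.fixture(scope="session")
def small_fit():
    """One converged 3-trait joint fit with SEs, reused across tests."""
    from mvgreml.estimates import fit_model

    grm, ph, cov, truth = simulate_dataset(400, 800, 3, seed=42)
    est, res = fit_model(grm, ph, cov)
    return dict(grm=grm, ph=ph, cov=cov, truth=truth, est=est, res=res)
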