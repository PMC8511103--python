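"""Synthetic genotypes and multivariate phenotypes under the fitted model.

Genotypes are drawn at Hardy-Weinberg equilibrium with independent SNPs
(allele frequencies uniform on a chosen range, allele counts binomial).
Phenotypes follow the generative model the estimator assumes: per-SNP effect
vectors on the standardized-genotype scale with across-trait covariance
V_G / M (so every SNP contributes equally to heritability — the
homoscedastic, GCTA-style model), Gaussian environmental noise with
covariance V_E, and optional fixed effects.

With a finite SNP panel the realized GRM has mean diagonal c = tr(A)/N
slightly different from 1, so the genetic values have covariance c * V_G
rather than V_G exactly.  The truth record reports both the nominal and the
c-rescaled ("effective") heritabilities so recovery checks can target the
quantity the data actually carry.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_grm import (
    GRM,
    GenotypeMatrix,
    compute_grm,
    maf_filter,
    standardize,
    write_grm,
    write_plink,
)
from .model import CovariateSet, PhenotypeSet

__all__ = [
    "SimulationSpec",
    "SIZE_CLASSES",
    "default_covariances",
    "simulate_genotypes",
    "simulate_phenotypes",
    "make_fixture",
]


def _psd_factor(V: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish factor L with L L' = V for any PSD V."""
    V = np.asarray(V, float)
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(V)
        if w.min() < -1e-8 * max(abs(w.max()), 1.0):
            raise ValueError("covariance matrix is not positive semidefinite") from None
        return Q * np.sqrt(np.clip(w, 0.0, None))


def correlation_to_covariance(variances: np.ndarray, R: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.asarray(variances, float))
    return np.outer(d, d) * np.asarray(R, float)


def default_covariances(t: int, h2=None, r_g: float | np.ndarray = 0.4,
                        r_e: float | np.ndarray = 0.15) -> tuple[np.ndarray, np.ndarray]:
    """Unit-phenotypic-variance V_G, V_E from heritabilities and correlations."""
    h2 = np.full(t, 0.4) if h2 is None else np.asarray(h2, float)
    R_G = np.full((t, t), r_g) if np.isscalar(r_g) else np.asarray(r_g, float)
    R_E = np.full((t, t), r_e) if np.isscalar(r_e) else np.asarray(r_e, float)
    np.fill_diagonal(R_G, 1.0)
    np.fill_diagonal(R_E, 1.0)
    V_G = correlation_to_covariance(h2, R_G)
    V_E = correlation_to_covariance(1.0 - h2, R_E)
    return V_G, V_E


@dataclasses.dataclass
class SimulationSpec:
    """Sizes, true covariance matrices and seed for one synthetic data set."""

    N: int
    M: int
    T: int
    V_G_true: np.ndarray
    V_E_true: np.ndarray
    freq_range: tuple[float, float] = (0.05, 0.5)
    beta_true: np.ndarray | None = None    # k_covars x T
    k_covars: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.V_G_true = np.asarray(self.V_G_true, float)
        self.V_E_true = np.asarray(self.V_E_true, float)
        for name, V in (("V_G_true", self.V_G_true), ("V_E_true", self.V_E_true)):
            if V.shape != (self.T, self.T):
                raise ValueError(f"{name} must be T x T")
            if np.linalg.eigvalsh((V + V.T) / 2).min() < -1e-8:
                raise ValueError(f"{name} is not positive semidefinite")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_range must satisfy 0 < lo <= hi < 1")
        tot = np.diag(self.V_G_true) + np.diag(self.V_E_true)
        if np.any(tot <= 0):
            raise ValueError("each trait needs positive total variance")
        if self.beta_true is not None:
            self.beta_true = np.atleast_2d(np.asarray(self.beta_true, float))
            self.k_covars = self.beta_true.shape[0]

    @property
    def h2_true(self) -> np.ndarray:
        dG = np.diag(self.V_G_true)
        return dG / (dG + np.diag(self.V_E_true))

    @property
    def r_g_true(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.V_G_true))
        with np.errstate(invalid="ignore", divide="ignore"):
            R = self.V_G_true / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        return R


SIZE_CLASSES = {
    "tiny": dict(N=40, M=100, T=2),
    "small": dict(N=500, M=1000, T=3),
    "recovery": dict(N=3000, M=5000, T=3),
}


def spec_for_size(size_class: str, seed: int = 0) -> SimulationSpec:
    """Canonical simulation settings per named size class.

    The recovery class uses h2 = (0.5, 0.3, 0.2) with r_g(1,2) = 0.6 (and
    moderate correlations elsewhere); the other classes use generic moderate
    heritabilities.  Two standardized covariates with fixed effects are
    included in every class.
    """
    if size_class not in SIZE_CLASSES:
        raise ValueError(f"unknown size class {size_class!r}")
    sizes = SIZE_CLASSES[size_class]
    t = sizes["T"]
    if size_class == "recovery":
        R_G = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.2], [0.3, 0.2, 1.0]])
        V_G, V_E = default_covariances(t, h2=[0.5, 0.3, 0.2], r_g=R_G)
    else:
        V_G, V_E = default_covariances(t)
    beta = np.vstack([np.full(t, 0.5), np.full(t, -0.25)])
    return SimulationSpec(**sizes, V_G_true=V_G, V_E_true=V_E,
                          beta_true=beta, seed=seed)


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Independent Hardy-Weinberg SNPs: f ~ U(freq_range), counts ~ Bin(2, f)."""
    rng = np.random.default_rng(spec.seed)
    f = rng.uniform(*spec.freq_range, size=spec.M)
    counts = rng.binomial(2, f, size=(spec.N, spec.M)).astype(np.int8)
    ids = [("FAM", f"IID{j:05d}") for j in range(spec.N)]
    snp_ids = pd.DataFrame({
        "snp": [f"snp{m:05d}" for m in range(spec.M)],
        "chrom": "1",
        "pos": np.arange(1, spec.M + 1) * 5000,   # 5 kb spacing, 1-based
        "a1": "A",
        "a2": "G",
    })
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids, counts=counts,
                          freqs=GenotypeMatrix.empirical_freqs(counts))


def simulate_phenotypes(
    g: GenotypeMatrix, spec: SimulationSpec
) -> tuple[PhenotypeSet, CovariateSet, dict]:
    """Draw multivariate phenotypes from the variance-component model.

    Per-SNP effect vectors have covariance V_G_true / M on the standardized
    scale; environmental deviations have covariance V_E_true; fixed effects
    (if any) act through standard-normal covariates.  The truth record
    carries the realized genetic values, the GRM diagonal factor c and the
    c-rescaled effective heritabilities.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    std = standardize(g)
    n, m = std.shape
    t = spec.T
    L_G = _psd_factor(spec.V_G_true)
    alpha = rng.standard_normal((m, t)) @ L_G.T / np.sqrt(m)
    genetic = std @ alpha
    eps = rng.standard_normal((n, t)) @ _psd_factor(spec.V_E_true).T

    if spec.k_covars > 0:
        Xc = rng.standard_normal((n, spec.k_covars))
        beta = spec.beta_true if spec.beta_true is not None \
            else rng.normal(0.0, 0.5, size=(spec.k_covars, t))
        fixed = Xc @ beta
        cov = CovariateSet.shared(
            g.ids, np.column_stack([np.ones(n), Xc]), t,
            names=["intercept"] + [f"covar{i+1}" for i in range(spec.k_covars)],
        )
    else:
        beta = np.zeros((0, t))
        fixed = 0.0
        cov = CovariateSet.intercept_only(g.ids, t)

    Y = genetic + fixed + eps
    ph = PhenotypeSet(ids=g.ids, Y=Y,
                      trait_names=[f"trait{i+1}" for i in range(t)])
    c = float(np.mean(np.sum(std**2, axis=1)) / m)   # mean diag of unit-weight GRM
    dG, dE = np.diag(spec.V_G_true), np.diag(spec.V_E_true)
    truth = {
        "V_G": spec.V_G_true.tolist(),
        "V_E": spec.V_E_true.tolist(),
        "h2": spec.h2_true.tolist(),
        "r_g": spec.r_g_true.tolist(),
        "grm_diag_factor": c,
        "h2_effective": (c * dG / (c * dG + dE)).tolist(),
        "beta": np.asarray(beta).tolist(),
        "seed": spec.seed,
        "genetic_values": genetic,          # in-memory only; not serialized
    }
    return ph, cov, truth


def make_fixture(
    name: str,
    size_class: str,
    out_dir: str | Path,
    seed: int = 0,
    overwrite: bool = False,
) -> Path:
    """Write a complete on-disk data set for one named size class.

    Produces bed/bim/fam, the binary GRM triplet, phenotype and covariate
    TSVs, and a truth JSON with the generating parameters.
    """
    out = Path(out_dir) / name
    if out.exists() and not overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)

    spec = spec_for_size(size_class, seed=seed)
    g = simulate_genotypes(spec)
    g = maf_filter(g, 0.01)
    ph, cov, truth = simulate_phenotypes(g, spec)

    write_plink(g, out / "geno")
    grm = compute_grm(standardize(g), ids=g.ids)
    write_grm(grm, out / "geno")

    pheno = pd.DataFrame(ph.Y, columns=ph.trait_names)
    pheno.insert(0, "IID", [i[1] for i in ph.ids])
    pheno.insert(0, "FID", [i[0] for i in ph.ids])
    pheno.to_csv(out / "pheno.tsv", sep="\t", index=False, float_format="%.10g")

    X = cov.designs[0]
    covar_cols = [c for c in cov.names[0] if c != "intercept"]
    covar = pd.DataFrame(X[:, 1:], columns=covar_cols)
    covar.insert(0, "IID", [i[1] for i in ph.ids])
    covar.insert(0, "FID", [i[0] for i in ph.ids])
    covar.to_csv(out / "covar.tsv", sep="\t", index=False, float_format="%.10g")

    truth_json = {k: v for k, v in truth.items() if k != "genetic_values"}
    truth_json.update(size_class=size_class, N=len(ph.ids), M=g.n_snps, T=spec.T)
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2) + "\n")
    return out
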