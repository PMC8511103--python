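"""Multivariate variance-component model and its restricted likelihood.

The model for T traits observed on N individuals stacks the trait vectors
(trait-major) and assumes

    y ~ N( X beta,  V_G (x) A  +  V_E (x) I_N )

where ``A`` is the genomic-relatedness matrix, ``V_G``/``V_E`` the T x T
genetic/environmental covariance matrices and ``(x)`` the Kronecker product.
Both covariance matrices are parameterized through lower-triangular factor
loadings, ``V_G = C_G C_G'`` and ``V_E = C_E C_E'``, so they are positive
semidefinite at every point of the parameter space.

A one-time eigendecomposition ``A = P diag(lam) P'`` turns the NT x NT
covariance into N independent T x T blocks ``Sigma_j = lam_j V_G + V_E``
after rotating phenotypes and covariates by ``P'`` (the canonical
transformation).  The restricted log-likelihood and its analytic gradient
are then accumulated blockwise, with cost linear in N and polynomial in T
and the fixed-effect count K — no NT-dimensional matrix is ever formed.
A dense brute-force evaluator is provided as an independent cross-check
for small problems.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import scipy.linalg

from .genotype_grm import GRM

__all__ = [
    "PhenotypeSet",
    "CovariateSet",
    "FactorCoefficients",
    "RotatedModel",
    "LikelihoodUndefinedError",
    "CollinearCovariatesError",
    "read_phenotypes",
    "read_covariates",
    "eigendecompose",
    "rotate",
    "reml_loglik",
    "reml_gradient",
    "reml_loglik_grad",
    "dense_reml_loglik",
]


class LikelihoodUndefinedError(ValueError):
    """Sigma_j = lam_j V_G + V_E is singular at the evaluated parameters."""

    def __init__(self, block: int | None = None):
        self.block = block
        where = f" (eigen-block {block})" if block is not None else ""
        super().__init__(f"restricted likelihood undefined: singular Sigma{where}")


class CollinearCovariatesError(ValueError):
    pass


@dataclasses.dataclass
class PhenotypeSet:
    """Complete-case phenotype matrix: N individuals x T traits."""

    ids: list[tuple[str, str]]
    Y: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.Y.ndim != 2:
            raise ValueError("Y must be N x T")
        n, t = self.Y.shape
        if len(self.ids) != n or len(self.trait_names) != t:
            raise ValueError("ids/trait_names do not match Y")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("phenotypes must be complete cases (no missing values)")
        if n <= t * (t + 1):
            warnings.warn(
                f"N={n} is small relative to the {t * (t + 1)} variance parameters",
                stacklevel=2,
            )

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]


@dataclasses.dataclass
class CovariateSet:
    """Per-trait fixed-effect design matrices (a shared design is T copies)."""

    ids: list[tuple[str, str]]
    designs: list[np.ndarray]              # X_t, each N x k_t
    names: list[list[str]]

    def __post_init__(self) -> None:
        self.designs = [np.atleast_2d(np.asarray(X, dtype=np.float64)) for X in self.designs]
        n = len(self.ids)
        for t, X in enumerate(self.designs):
            if X.shape[0] != n:
                raise ValueError(f"design for trait {t} has wrong row count")
            if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
                raise CollinearCovariatesError(f"design for trait {t} is rank deficient")

    @classmethod
    def shared(
        cls, ids: list[tuple[str, str]], X: np.ndarray, n_traits: int,
        names: list[str] | None = None,
    ) -> "CovariateSet":
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        names = names if names is not None else [f"x{i}" for i in range(X.shape[1])]
        return cls(ids=ids, designs=[X] * n_traits, names=[list(names)] * n_traits)

    @classmethod
    def intercept_only(cls, ids: list[tuple[str, str]], n_traits: int) -> "CovariateSet":
        X = np.ones((len(ids), 1))
        return cls.shared(ids, X, n_traits, names=["intercept"])

    @property
    def k_per_trait(self) -> list[int]:
        return [X.shape[1] for X in self.designs]

    @property
    def total_k(self) -> int:
        return sum(self.k_per_trait)


def _tril_indices_colmajor(t: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the lower triangle in column-major order."""
    cols, rows = [], []
    for b in range(t):
        for a in range(b, t):
            rows.append(a)
            cols.append(b)
    return np.array(rows), np.array(cols)


@dataclasses.dataclass
class FactorCoefficients:
    """Lower-triangular loadings whose outer products are V_G and V_E.

    The packed parameter vector theta of length T(T+1) lists the C_G
    triangle column-major, then the C_E triangle column-major.
    """

    C_G: np.ndarray
    C_E: np.ndarray

    def __post_init__(self) -> None:
        self.C_G = np.tril(np.asarray(self.C_G, dtype=np.float64))
        self.C_E = np.tril(np.asarray(self.C_E, dtype=np.float64))
        if self.C_G.shape != self.C_E.shape or self.C_G.shape[0] != self.C_G.shape[1]:
            raise ValueError("C_G and C_E must be square and the same size")

    @property
    def n_traits(self) -> int:
        return self.C_G.shape[0]

    @property
    def V_G(self) -> np.ndarray:
        return self.C_G @ self.C_G.T

    @property
    def V_E(self) -> np.ndarray:
        return self.C_E @ self.C_E.T

    def pack(self) -> np.ndarray:
        r, c = _tril_indices_colmajor(self.n_traits)
        return np.concatenate([self.C_G[r, c], self.C_E[r, c]])

    @classmethod
    def unpack(cls, theta: np.ndarray, n_traits: int) -> "FactorCoefficients":
        theta = np.asarray(theta, dtype=np.float64)
        half = n_traits * (n_traits + 1) // 2
        if theta.size != 2 * half:
            raise ValueError("theta has wrong length")
        r, c = _tril_indices_colmajor(n_traits)
        C_G = np.zeros((n_traits, n_traits))
        C_E = np.zeros((n_traits, n_traits))
        C_G[r, c] = theta[:half]
        C_E[r, c] = theta[half:]
        return cls(C_G=C_G, C_E=C_E)


@dataclasses.dataclass
class RotatedModel:
    """GRM eigenvalues plus eigenvector-rotated phenotypes and designs."""

    lam: np.ndarray                        # length N, descending
    Ytil: np.ndarray                       # N x T
    Xtil: list[np.ndarray]                 # per-trait N x k_t
    trait_names: list[str]
    dropped_dims: int = 0

    @property
    def n_obs(self) -> int:
        return self.Ytil.shape[0]

    @property
    def n_traits(self) -> int:
        return self.Ytil.shape[1]

    @property
    def k_per_trait(self) -> list[int]:
        return [X.shape[1] for X in self.Xtil]

    @property
    def total_k(self) -> int:
        return sum(self.k_per_trait)


# ---------------------------------------------------------------------------
# Table I/O


def _read_id_table(path, id_error: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected FID, IID plus at least one data column")
    if df.duplicated(subset=df.columns[:2].tolist()).any():
        raise ValueError(f"{path}: {id_error}")
    return df


def read_phenotypes(path, traits: list[str] | None = None) -> PhenotypeSet:
    """Read a tab-separated phenotype table (FID, IID, then trait columns).

    Rows with any missing value among the selected traits are dropped
    (complete-case analysis).
    """
    df = _read_id_table(path, "duplicate individual IDs")
    trait_cols = list(df.columns[2:]) if traits is None else list(traits)
    missing = [c for c in trait_cols if c not in df.columns]
    if missing:
        raise KeyError(f"{path}: phenotype column(s) not found: {missing}")
    sub = df[list(df.columns[:2]) + trait_cols].dropna()
    ids = list(zip(sub.iloc[:, 0], sub.iloc[:, 1]))
    return PhenotypeSet(ids=ids, Y=sub[trait_cols].to_numpy(float), trait_names=trait_cols)


def read_covariates(path, n_traits: int, add_intercept: bool = True) -> CovariateSet:
    """Read a shared tab-separated covariate table and replicate it per trait."""
    df = _read_id_table(path, "duplicate individual IDs")
    sub = df.dropna()
    ids = list(zip(sub.iloc[:, 0], sub.iloc[:, 1]))
    names = list(sub.columns[2:])
    X = sub[names].to_numpy(float)
    if add_intercept:
        X = np.column_stack([np.ones(len(sub)), X])
        names = ["intercept"] + names
    return CovariateSet.shared(ids, X, n_traits, names=names)


# ---------------------------------------------------------------------------
# Rotation


def eigendecompose(grm: GRM) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose A = P diag(lam) P' with a deterministic convention.

    Eigenvalues are returned descending; tiny negatives from round-off are
    clipped to zero; each eigenvector is signed so its largest-magnitude
    entry is positive.
    """
    if not np.all(np.isfinite(grm.A)):
        raise ValueError("GRM contains non-finite entries")
    lam, P = np.linalg.eigh(grm.A)
    order = np.argsort(lam)[::-1]
    lam, P = lam[order], P[:, order]
    lam_max = max(lam[0], 0.0)
    if lam_max > 0 and lam.min() < -1e-8 * lam_max:
        warnings.warn("GRM has eigenvalues well below zero; clipping", stacklevel=2)
    lam = np.clip(lam, 0.0, None)
    pivot = np.argmax(np.abs(P), axis=0)
    signs = np.sign(P[pivot, np.arange(P.shape[1])])
    signs[signs == 0] = 1.0
    return P * signs, lam


def rotate(ph: PhenotypeSet, cov: CovariateSet, P: np.ndarray) -> RotatedModel:
    """Rotate phenotypes and per-trait designs by the GRM eigenvectors."""
    if ph.ids != cov.ids:
        bad = [i for i in ph.ids if i not in set(cov.ids)] or \
              [i for i in cov.ids if i not in set(ph.ids)]
        raise ValueError(
            f"phenotype/covariate IDs are not aligned; offenders include {bad[:5]}"
        )
    if P.shape[0] != len(ph.ids):
        raise ValueError("rotation matrix does not match sample size")
    return RotatedModel(
        lam=np.zeros(0),  # caller supplies eigenvalues; see fit_model
        Ytil=P.T @ ph.Y,
        Xtil=[P.T @ X for X in cov.designs],
        trait_names=list(ph.trait_names),
    )


def rotated_model(grm: GRM, ph: PhenotypeSet, cov: CovariateSet) -> RotatedModel:
    """Eigendecompose the GRM and rotate data into its eigenbasis."""
    if ph.ids != grm.ids:
        raise ValueError("phenotype IDs are not aligned with the GRM")
    P, lam = eigendecompose(grm)
    rm = rotate(ph, cov, P)
    rm.lam = lam
    return rm


# ---------------------------------------------------------------------------
# Blockwise restricted likelihood and gradient


def _common_terms(rm: RotatedModel, fc: FactorCoefficients):
    """Shared per-block quantities for the likelihood and gradient."""
    lam, Ytil, Xs = rm.lam, rm.Ytil, rm.Xtil
    n, t = Ytil.shape
    if lam.shape[0] != n:
        raise ValueError("eigenvalue count does not match rotated data")
    V_G, V_E = fc.V_G, fc.V_E
    Sig = lam[:, None, None] * V_G + V_E
    try:
        chol = np.linalg.cholesky(Sig)
    except np.linalg.LinAlgError:
        eigmin = np.linalg.eigvalsh(Sig)[:, 0]
        raise LikelihoodUndefinedError(int(np.argmin(eigmin))) from None
    logdet_sig = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)))
    Sinv = np.linalg.inv(Sig)
    Sinv = (Sinv + Sinv.transpose(0, 2, 1)) / 2.0

    ks = rm.k_per_trait
    offs = np.concatenate([[0], np.cumsum(ks)])
    K = int(offs[-1])

    # F = sum_j Xt_j' Sinv_j Xt_j and b = sum_j Xt_j' Sinv_j ytil_j, with
    # Xt_j the T x K block-diagonal design row-set for eigen-index j.
    F = np.zeros((K, K))
    for s in range(t):
        for u in range(s, t):
            blk = np.einsum("j,ja,jb->ab", Sinv[:, s, u], Xs[s], Xs[u])
            F[offs[s]:offs[s + 1], offs[u]:offs[u + 1]] = blk
            if u != s:
                F[offs[u]:offs[u + 1], offs[s]:offs[s + 1]] = blk.T
    Z = np.einsum("jsu,ju->js", Sinv, Ytil)
    if K == 0:
        b = np.zeros(0)
        cF = None
        logdet_F = 0.0
        beta = np.zeros(0)
    else:
        b = np.concatenate([Xs[s].T @ Z[:, s] for s in range(t)])
        try:
            cF = scipy.linalg.cho_factor(F)
        except scipy.linalg.LinAlgError:
            raise CollinearCovariatesError(
                "X'V^-1X is singular (collinear covariates)"
            ) from None
        logdet_F = 2.0 * np.sum(np.log(np.diag(cF[0])))
        beta = scipy.linalg.cho_solve(cF, b)
    return dict(
        Sinv=Sinv, logdet_sig=logdet_sig, F=F, cF=cF, logdet_F=logdet_F,
        b=b, beta=beta, Z=Z, offs=offs, K=K,
    )


def reml_loglik(rm: RotatedModel, fc: FactorCoefficients) -> float:
    """Restricted log-likelihood, accumulated over T x T eigen-blocks."""
    c = _common_terms(rm, fc)
    n, t = rm.Ytil.shape
    quad_y = float(np.einsum("js,js->", rm.Ytil, c["Z"]))
    const = -0.5 * (n * t - c["K"]) * math.log(2.0 * math.pi)
    return const - 0.5 * (
        c["logdet_sig"] + quad_y + c["logdet_F"] - float(c["b"] @ c["beta"])
    )


def reml_gradient(rm: RotatedModel, fc: FactorCoefficients) -> np.ndarray:
    """Analytic gradient of the restricted log-likelihood in theta."""
    return reml_loglik_grad(rm, fc)[1]


def reml_loglik_grad(rm: RotatedModel, fc: FactorCoefficients) -> tuple[float, np.ndarray]:
    """Restricted log-likelihood and its analytic gradient, sharing work.

    For a loading parameter C_G[a, b], dV_G = E_ab C_G' + C_G E_ab', so the
    blockwise score reduces to the lower triangle of (Q_G - S_G) C_G with
    S_G = sum_j lam_j (Sinv_j - W_j), Q_G = sum_j lam_j e_j e_j', where W_j
    is the REML fixed-effect correction and e_j = Sinv_j (ytil_j - Xt_j beta)
    the weighted residual; analogously for C_E with unit weights.
    """
    c = _common_terms(rm, fc)
    lam, Ytil, Xs = rm.lam, rm.Ytil, rm.Xtil
    n, t = Ytil.shape
    Sinv, offs, K = c["Sinv"], c["offs"], c["K"]

    quad_y = float(np.einsum("js,js->", Ytil, c["Z"]))
    const = -0.5 * (n * t - K) * math.log(2.0 * math.pi)
    ll = const - 0.5 * (
        c["logdet_sig"] + quad_y + c["logdet_F"] - float(c["b"] @ c["beta"])
    )

    # residuals e_j = Sinv_j (ytil_j - Xt_j beta)
    beta = c["beta"]
    fitted = np.column_stack(
        [Xs[s] @ beta[offs[s]:offs[s + 1]] for s in range(t)]
    )
    e = np.einsum("jsu,ju->js", Sinv, Ytil - fitted)

    Q_G = np.einsum("j,js,ju->su", lam, e, e)
    Q_E = e.T @ e
    Sinv_sum = Sinv.sum(axis=0)
    Sinv_lam = np.einsum("j,jsu->su", lam, Sinv)

    # REML correction: W_j = Sinv_j Xt_j F^-1 Xt_j' Sinv_j, accumulated
    # with and without lam weights.
    if K > 0:
        U = np.empty((n, t, K))
        for s in range(t):
            U[:, :, offs[s]:offs[s + 1]] = Sinv[:, :, s, None] * Xs[s][:, None, :]
        Fi = scipy.linalg.cho_solve(c["cF"], np.eye(K))
        T1 = U @ Fi                                   # (n, t, K)
        SW_E = np.einsum("jtk,juk->tu", T1, U)
        SW_G = np.einsum("j,jtk,juk->tu", lam, T1, U)
    else:
        SW_E = np.zeros((t, t))
        SW_G = np.zeros((t, t))

    S_G = Sinv_lam - SW_G
    S_E = Sinv_sum - SW_E
    grad_G = (Q_G - S_G) @ fc.C_G
    grad_E = (Q_E - S_E) @ fc.C_E
    r, col = _tril_indices_colmajor(t)
    return ll, np.concatenate([grad_G[r, col], grad_E[r, col]])


# ---------------------------------------------------------------------------
# Dense oracle


def dense_reml_loglik(
    grm: GRM,
    ph: PhenotypeSet,
    cov: CovariateSet,
    V_G: np.ndarray,
    V_E: np.ndarray,
) -> float:
    """Brute-force restricted log-likelihood from the explicit NT x NT matrix.

    Builds V = V_G (x) A + V_E (x) I_N with trait-major stacking and
    evaluates the textbook REML expression by dense factorization.  Intended
    as an independent cross-check; guarded to N*T <= 600.
    """
    n = len(ph.ids)
    t = ph.n_traits
    if n * t > 600:
        raise ValueError(f"dense oracle refused: N*T = {n * t} exceeds 600")
    if ph.ids != grm.ids or ph.ids != cov.ids:
        raise ValueError("IDs of GRM, phenotypes and covariates must be aligned")
    V = np.kron(np.asarray(V_G, float), grm.A) + np.kron(np.asarray(V_E, float), np.eye(n))
    X = scipy.linalg.block_diag(*cov.designs)
    y = ph.Y.T.ravel()                                 # trait-major stacking
    k = X.shape[1]

    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        raise LikelihoodUndefinedError()
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    sign_F, logdet_F = np.linalg.slogdet(XtViX)
    if sign_F <= 0:
        raise CollinearCovariatesError("X'V^-1X is singular")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    quad = float(resid @ np.linalg.solve(V, resid))
    const = -0.5 * (n * t - k) * math.log(2.0 * math.pi)
    return const - 0.5 * (logdet_V + logdet_F + quad)
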