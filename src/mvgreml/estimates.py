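"""Reported quantities and consistency diagnostics.

Fitted variance components are transformed into per-trait SNP heritabilities
``h2(t) = vG_tt / (vG_tt + vE_tt)`` and correlation matrices
``r(s,t) = v_st / sqrt(v_ss v_tt)`` for both the genetic and environmental
parts.  Because the joint fit parameterizes V_G and V_E through factor
loadings, the resulting genetic correlation matrix is positive semidefinite
by construction; matrices assembled by stacking independent pairwise
bivariate fits carry no such guarantee, and the audit utilities here
quantify how badly a stacked matrix violates internal consistency.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .genotype_grm import GRM
from .model import CovariateSet, FactorCoefficients, PhenotypeSet, rotated_model
from .optimizer import FitResult, delta_se, fit, initialize, parameter_covariance

__all__ = [
    "EstimateSet",
    "ConsistencyReport",
    "summarize",
    "triple_consistency",
    "psd_audit",
    "fit_model",
    "pairwise_bivariate_fit",
    "ward_cluster",
    "write_estimates",
]


@dataclasses.dataclass
class EstimateSet:
    """Fitted heritabilities and correlation matrices with standard errors."""

    trait_names: list[str]
    h2: np.ndarray
    se_h2: np.ndarray | None
    R_G: np.ndarray
    se_R_G: np.ndarray | None
    R_E: np.ndarray
    V_G: np.ndarray
    V_E: np.ndarray
    loglik: float | None = None
    degenerate_traits: list[int] = dataclasses.field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclasses.dataclass
class ConsistencyReport:
    """Eigenvalue audit of a correlation matrix, optionally with triple scan."""

    eigenvalues: np.ndarray                # sorted ascending
    n_negative: int
    triple_stats: list[tuple[int, int, int, float, bool]] | None = None

    def to_dict(self) -> dict:
        out = {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "n_negative": int(self.n_negative),
        }
        if self.triple_stats is not None:
            out["triples"] = [
                {"traits": [s, t, u], "statistic": float(x), "violated": bool(v)}
                for s, t, u, x, v in self.triple_stats
            ]
        return out


def _cov_to_corr(V: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(V))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = V / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def summarize(
    V_G: np.ndarray,
    V_E: np.ndarray,
    trait_names: list[str] | None = None,
    se_h2: np.ndarray | None = None,
    se_R_G: np.ndarray | None = None,
    loglik: float | None = None,
) -> EstimateSet:
    """Heritabilities and correlation matrices from fitted covariances.

    Traits with zero genetic variance get h2 = 0 and undefined (NaN,
    flagged) genetic correlations rather than propagating division noise.
    """
    V_G = np.asarray(V_G, float)
    V_E = np.asarray(V_E, float)
    t = V_G.shape[0]
    names = trait_names if trait_names is not None else [f"trait{i}" for i in range(t)]
    dG, dE = np.diag(V_G), np.diag(V_E)
    tot = dG + dE
    if np.any(tot <= 0):
        bad = [names[i] for i in np.flatnonzero(tot <= 0)]
        raise ValueError(f"degenerate trait(s) with zero total variance: {bad}")
    h2 = dG / tot
    degenerate = [int(i) for i in np.flatnonzero(dG == 0)]
    R_G = _cov_to_corr(V_G)
    for i in degenerate:
        R_G[i, :] = R_G[:, i] = np.nan
        R_G[i, i] = 1.0
    return EstimateSet(
        trait_names=list(names), h2=h2, se_h2=se_h2, R_G=R_G, se_R_G=se_R_G,
        R_E=_cov_to_corr(V_E), V_G=V_G, V_E=V_E, loglik=loglik,
        degenerate_traits=degenerate,
    )


def triple_consistency(r12: float, r13: float, r23: float) -> tuple[float, bool]:
    """Internal-consistency statistic for three pairwise correlations.

    The 3 x 3 correlation matrix built from (r12, r13, r23) is positive
    semidefinite iff r12^2 + r13^2 + r23^2 - 2 r12 r13 r23 <= 1; the
    statistic is that left-hand side, and ``violated`` is True when it
    exceeds 1 (the triple cannot coexist).
    """
    for r in (r12, r13, r23):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    stat = r12**2 + r13**2 + r23**2 - 2.0 * r12 * r13 * r23
    return float(stat), bool(stat > 1.0)


def psd_audit(R: np.ndarray, scan_triples: bool = False) -> ConsistencyReport:
    """Eigenvalue audit of a correlation matrix.

    Reports the sorted spectrum and the count of eigenvalues below -1e-10.
    With ``scan_triples`` (T <= 30 only) every 3-trait submatrix is checked
    against the pairwise consistency bound.
    """
    R = np.asarray(R, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("audit input must be a square matrix")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("audit input must be symmetric (within 1e-8)")
    w = np.sort(np.linalg.eigvalsh((R + R.T) / 2.0))
    n_neg = int(np.sum(w < -1e-10))
    triples = None
    if scan_triples:
        t = R.shape[0]
        if t > 30:
            raise ValueError("triple scan capped at T <= 30")
        triples = []
        for s in range(t):
            for u in range(s + 1, t):
                for v in range(u + 1, t):
                    stat, bad = triple_consistency(R[s, u], R[s, v], R[u, v])
                    triples.append((s, u, v, stat, bad))
    return ConsistencyReport(eigenvalues=w, n_negative=n_neg, triple_stats=triples)


def fit_model(
    grm: GRM,
    ph: PhenotypeSet,
    cov: CovariateSet,
    tol: float = 1e-5,
    max_iter: int = 300,
    compute_se: bool = True,
) -> tuple[EstimateSet, FitResult]:
    """End-to-end joint fit: rotate, optimize, standard errors, summarize."""
    rm = rotated_model(grm, ph, cov)
    res = fit(rm, initialize(ph, cov), tol=tol, max_iter=max_iter)
    fc = res.coefficients
    se_h2 = se_rg = None
    if compute_se:
        res.param_cov, res.info_clipped = parameter_covariance(rm, fc)
        se_h2, se_rg = delta_se(fc, res.param_cov)
    est = summarize(
        fc.V_G, fc.V_E, trait_names=ph.trait_names,
        se_h2=se_h2, se_R_G=se_rg, loglik=res.loglik,
    )
    return est, res


def pairwise_bivariate_fit(
    grm: GRM,
    ph: PhenotypeSet,
    cov: CovariateSet,
    pairs: list[tuple[int, int]] | None = None,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack genetic correlations from independent two-trait fits.

    Runs the bivariate special case for each requested trait pair and
    assembles a T x T matrix with unit diagonal.  The stacked matrix is the
    conventional output of pairwise analyses and may legitimately fail
    :func:`psd_audit` — that contrast with the always-PSD joint fit is the
    point of this routine.  The boolean mask marks non-converged pairs.
    """
    t = ph.n_traits
    if t < 2:
        raise ValueError("need at least two traits")
    if pairs is None:
        pairs = [(s, u) for s in range(t) for u in range(s + 1, t)]
    R = np.eye(t)
    ok = np.ones((t, t), dtype=bool)
    for s, u in pairs:
        sub_ph = PhenotypeSet(
            ids=ph.ids, Y=ph.Y[:, [s, u]],
            trait_names=[ph.trait_names[s], ph.trait_names[u]],
        )
        sub_cov = CovariateSet(
            ids=cov.ids, designs=[cov.designs[s], cov.designs[u]],
            names=[cov.names[s], cov.names[u]],
        )
        try:
            est, res = fit_model(grm, sub_ph, sub_cov, tol=tol,
                                 max_iter=max_iter, compute_se=False)
            R[s, u] = R[u, s] = est.R_G[0, 1]
            ok[s, u] = ok[u, s] = res.converged
        except Exception:
            R[s, u] = R[u, s] = np.nan
            ok[s, u] = ok[u, s] = False
    return R, ok


def ward_cluster(R_G: np.ndarray, n_clusters: int) -> np.ndarray:
    """Ward-D2 hierarchical clustering of traits by genetic correlation.

    Traits are embedded with the Euclidean-compatible correlation distance
    d(s,t) = sqrt(2 (1 - r_g(s,t))) and agglomerated with Ward's D2
    criterion.  Labels are renumbered 0..n_clusters-1 by first occurrence.
    """
    R_G = np.asarray(R_G, float)
    t = R_G.shape[0]
    if not 1 <= n_clusters <= t:
        raise ValueError("n_clusters must lie in [1, T]")
    D = np.sqrt(np.maximum(2.0 * (1.0 - R_G), 0.0))
    np.fill_diagonal(D, 0.0)
    condensed = scipy.spatial.distance.squareform((D + D.T) / 2.0, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="ward")
    raw = scipy.cluster.hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    out = np.empty(t, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        out[i] = relabel[lab]
    return out


# ---------------------------------------------------------------------------
# Output files


def _write_matrix(path: Path, M: np.ndarray, names: list[str]) -> None:
    pd.DataFrame(M, index=names, columns=names).to_csv(
        path, sep="\t", float_format="%.6g", index_label="trait"
    )


def write_estimates(est: EstimateSet, prefix: str | Path) -> list[Path]:
    """Write the estimate bundle as tab-separated tables plus an audit JSON."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    names = est.trait_names
    written = []

    hs = pd.DataFrame({"trait": names, "h2": est.h2})
    if est.se_h2 is not None:
        hs["se"] = est.se_h2
    p = Path(f"{prefix}.HSq.tsv")
    hs.to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)

    p = Path(f"{prefix}.RhoG.tsv"); _write_matrix(p, est.R_G, names); written.append(p)
    if est.se_R_G is not None:
        p = Path(f"{prefix}.RhoG.SE.tsv"); _write_matrix(p, est.se_R_G, names); written.append(p)
    p = Path(f"{prefix}.RhoE.tsv"); _write_matrix(p, est.R_E, names); written.append(p)

    rows = []
    for comp, V in (("G", est.V_G), ("E", est.V_E)):
        for s in range(est.n_traits):
            for u in range(s, est.n_traits):
                rows.append((comp, names[s], names[u], V[s, u]))
    p = Path(f"{prefix}.VCs.tsv")
    pd.DataFrame(rows, columns=["component", "trait1", "trait2", "value"]).to_csv(
        p, sep="\t", index=False, float_format="%.6g"
    )
    written.append(p)

    if est.loglik is not None:
        p = Path(f"{prefix}.loglik.txt")
        p.write_text(f"{est.loglik:.10f}\n")
        written.append(p)

    audit = psd_audit(np.nan_to_num(est.R_G, nan=0.0))
    p = Path(f"{prefix}.audit.json")
    p.write_text(json.dumps(audit.to_dict(), indent=2) + "\n")
    written.append(p)
    return written
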