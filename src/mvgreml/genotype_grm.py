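"""Genotype I/O, standardization and genomic-relatedness-matrix (GRM) construction.

The GRM ``A`` quantifies genetic similarity between pairs of individuals as the
average cross-product of their standardized genotypes, ``A = M^-1 G G'`` for
``M`` SNPs, or the weighted variant ``A = d^-1 G D G'`` with nonnegative
per-SNP weights ``D`` summing to ``d``.  Genotypes are standardized under the
Hardy-Weinberg scaling ``(g* - 2f) / sqrt(2 f (1 - f))`` using in-sample
allele frequencies ``f``; missing calls are mean-imputed (zero on the
standardized scale).

PLINK bed/bim/fam and the de-facto standard binary GRM triplet
(``.grm.bin`` / ``.grm.N.bin`` / ``.grm.id``) are supported for interchange
with other GREML tooling.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SnpWeights",
    "GRM",
    "read_plink",
    "write_plink",
    "maf_filter",
    "standardize",
    "compute_grm",
    "gcta_weights",
    "ldak_thin_weights",
    "prune_relatedness",
    "read_grm",
    "write_grm",
]

MISSING = -1  # sentinel for a missing genotype call in the int8 count matrix

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01


@dataclasses.dataclass
class GenotypeMatrix:
    """Raw allele counts for N individuals x M SNPs.

    ``counts[j, m]`` is the number of copies of the coded (A1) allele carried
    by individual ``j`` at SNP ``m``: 0, 1, 2 or :data:`MISSING`.  ``freqs``
    holds the in-sample coded-allele frequency computed over non-missing
    calls; it is NaN for a SNP with no non-missing calls.
    """

    ids: list[tuple[str, str]]            # (family-id, individual-id)
    snp_ids: pd.DataFrame                  # columns: snp, chrom, pos, a1, a2
    counts: np.ndarray                     # int8, N x M
    freqs: np.ndarray                      # float64, length M

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        n, m = self.counts.shape
        if n < 2:
            raise ValueError("need at least 2 individuals")
        if m < 1:
            raise ValueError("need at least 1 SNP")
        if len(self.ids) != n:
            raise ValueError("ids/counts row mismatch")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids/counts column mismatch")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual IDs")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @staticmethod
    def empirical_freqs(counts: np.ndarray) -> np.ndarray:
        """Coded-allele frequency per SNP over non-missing calls (NaN if none)."""
        counts = np.asarray(counts)
        obs = counts != MISSING
        n_obs = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(obs, counts, 0).sum(axis=0) / (2.0 * n_obs)
        f[n_obs == 0] = np.nan
        return f


@dataclasses.dataclass
class SnpWeights:
    """Diagonal of the per-SNP weight matrix D, and its sum d."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if np.any(self.w < 0):
            raise ValueError("SNP weights must be nonnegative")
        if self.d <= 0:
            raise ValueError("sum of SNP weights must be positive")

    @property
    def d(self) -> float:
        return float(self.w.sum())


@dataclasses.dataclass
class GRM:
    """Symmetric N x N genomic-relatedness matrix with per-pair SNP counts."""

    ids: list[tuple[str, str]]
    A: np.ndarray
    n_snps: np.ndarray                     # per-pair count of SNPs used

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.n_snps = np.asarray(self.n_snps, dtype=np.float64)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if len(self.ids) != n:
            raise ValueError("ids/A size mismatch")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("A must be symmetric (within 1e-10)")

    @property
    def n_individuals(self) -> int:
        return self.A.shape[0]


# ---------------------------------------------------------------------------
# PLINK binary I/O


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triplet into a :class:`GenotypeMatrix`.

    The .bed file must be in SNP-major mode (magic bytes 0x6C 0x1B 0x01).
    Two-bit codes decode as: 00 -> homozygous A1 (count 2), 01 -> missing,
    10 -> heterozygous (count 1), 11 -> homozygous A2 (count 0); counts are
    copies of the A1 (coded) allele.
    """
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")

    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    ids = list(zip(fam_df[0], fam_df[1]))
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None, dtype=str,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    snp_ids = bim_df[["snp", "chrom", "pos", "a1", "a2"]].copy()
    snp_ids["pos"] = snp_ids["pos"].astype(np.int64)

    n, m = len(ids), len(snp_ids)
    raw = np.fromfile(bed, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise ValueError(f"{bed}: not a PLINK .bed file (bad magic bytes)")
    if raw[2] == 0x00:
        raise ValueError(f"{bed}: individual-major .bed files are not supported")
    if raw[2] != _BED_SNP_MAJOR:
        raise ValueError(f"{bed}: unrecognized .bed mode byte {raw[2]:#04x}")

    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * m:
        raise ValueError(
            f"{bed}: size {len(body)} inconsistent with N={n}, M={m}"
        )
    # unpack 2-bit codes, little-endian within each byte
    codes = body.reshape(m, bytes_per_snp)[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (codes & 0x03).reshape(m, -1)[:, :n]          # M x N
    # 00->2 copies of A1, 10 (2)->1, 11 (3)->0, 01 (1)->missing
    decode = np.array([2, MISSING, 1, 0], dtype=np.int8)
    counts = decode[codes].T.copy()                        # N x M
    freqs = GenotypeMatrix.empirical_freqs(counts)
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids, counts=counts, freqs=freqs)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as a SNP-major PLINK bed/bim/fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.counts.shape

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for fid, iid in g.ids:
            fh.write(f"{fid}\t{iid}\t0\t0\t0\t-9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in g.snp_ids.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")

    encode = np.zeros(4, dtype=np.uint8)
    encode[[2, 1, 0]] = [0b00, 0b10, 0b11]
    codes = np.where(g.counts == MISSING, 0b01, encode[np.clip(g.counts, 0, 2)]).astype(np.uint8)
    pad = (-n) % 4
    if pad:
        # pad with 0b00; harmless filler beyond N individuals
        codes = np.vstack([codes, np.zeros((pad, m), dtype=np.uint8)])
    codes = codes.T.reshape(m, -1, 4)                      # M x bytes x 4
    packed = (codes * np.array([1, 4, 16, 64], dtype=np.uint8)).sum(axis=2, dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        packed.astype(np.uint8).tofile(fh)


# ---------------------------------------------------------------------------
# Filtering and standardization


def maf_filter(g: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Retain SNPs with minor-allele frequency >= ``min_maf`` (order preserved).

    SNPs with undefined frequency (all calls missing) are always removed.
    """
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must lie in [0, 0.5)")
    maf = np.minimum(g.freqs, 1.0 - g.freqs)
    keep = np.isfinite(maf) & (maf >= min_maf)
    if min_maf == 0:
        keep &= (g.freqs > 0) & (g.freqs < 1)   # drop monomorphic SNPs
    if not keep.any():
        raise ValueError("MAF filter removed every SNP")
    return GenotypeMatrix(
        ids=g.ids,
        snp_ids=g.snp_ids.loc[keep].reset_index(drop=True),
        counts=g.counts[:, keep],
        freqs=g.freqs[keep],
    )


def standardize(g: GenotypeMatrix) -> np.ndarray:
    """Hardy-Weinberg standardization of the count matrix.

    Entry ``(j, m)`` becomes ``(g*_jm - 2 f_m) / sqrt(2 f_m (1 - f_m))``;
    missing calls are imputed to 0 on the standardized scale (the column
    mean when frequencies are empirical).
    """
    bad = ~((g.freqs > 0) & (g.freqs < 1))
    if bad.any():
        names = g.snp_ids["snp"].iloc[np.flatnonzero(bad)[:5]].tolist()
        raise ZeroDivisionError(
            f"cannot standardize monomorphic/undefined SNP(s): {names}"
        )
    scale = np.sqrt(2.0 * g.freqs * (1.0 - g.freqs))
    std = (g.counts.astype(np.float64) - 2.0 * g.freqs) / scale
    std[g.counts == MISSING] = 0.0
    return std


# ---------------------------------------------------------------------------
# GRM construction


def compute_grm(
    std: np.ndarray,
    w: SnpWeights | None = None,
    ids: list[tuple[str, str]] | None = None,
    n_nonmissing: np.ndarray | None = None,
) -> GRM:
    """Weighted GRM ``A = d^-1 std diag(w) std'`` from standardized genotypes.

    With unit weights this is exactly ``M^-1 G G'``.  ``n_nonmissing`` is an
    optional per-SNP count of non-missing calls used to fill the per-pair
    SNP-count matrix; when omitted all pairs are credited with the full count
    of positively-weighted SNPs.
    """
    std = np.asarray(std, dtype=np.float64)
    n, m = std.shape
    if w is None:
        w = SnpWeights(np.ones(m))
    if len(w.w) != m:
        raise ValueError("weight length does not match SNP count")
    A = (std * w.w) @ std.T / w.d
    A = (A + A.T) / 2.0
    if ids is None:
        ids = [("FAM", f"I{j}") for j in range(n)]
    n_used = float(np.count_nonzero(w.w))
    n_snps = np.full((n, n), n_used)
    if n_nonmissing is not None:
        n_snps[:] = float(np.mean(n_nonmissing[w.w > 0]))
    return GRM(ids=ids, A=A, n_snps=n_snps)


def gcta_weights(m: int) -> SnpWeights:
    """Unit weights: the homoscedastic (GCTA) model, ``A = M^-1 G G'``."""
    return SnpWeights(np.ones(m))


def ldak_thin_weights(
    g: GenotypeMatrix,
    r2_max: float = 0.98,
    window_bp: int = 100_000,
    alpha: float = -0.25,
) -> SnpWeights:
    """LDAK-Thin style weights: LD-thin, then frequency-weight retained SNPs.

    SNPs are scanned in file order; a SNP is dropped if its squared sample
    correlation with any previously retained SNP within ``window_bp`` on the
    same chromosome exceeds ``r2_max``.  Retained SNP ``m`` receives weight
    ``[2 f_m (1 - f_m)]^(1 + alpha)``; dropped SNPs receive 0.  With
    ``alpha = -1`` retained weights are 1 (homoscedastic on the thinned set).
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must lie in (0, 1]")
    if window_bp < 0:
        raise ValueError("window_bp must be nonnegative")
    std = standardize(g)
    chrom = g.snp_ids["chrom"].to_numpy()
    pos = g.snp_ids["pos"].to_numpy()
    m = g.n_snps
    kept: list[int] = []
    keep = np.zeros(m, dtype=bool)
    for i in range(m):
        ok = True
        for k in reversed(kept):
            if chrom[k] != chrom[i] or abs(int(pos[i]) - int(pos[k])) > window_bp:
                continue
            r = np.corrcoef(std[:, i], std[:, k])[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
            keep[i] = True
    w = np.zeros(m)
    het = 2.0 * g.freqs[keep] * (1.0 - g.freqs[keep])
    w[keep] = het ** (1.0 + alpha)
    return SnpWeights(w)


def prune_relatedness(grm: GRM, cutoff: float) -> tuple[GRM, list[tuple[str, str]]]:
    """Greedily drop individuals until all off-diagonal relatedness < cutoff.

    At each step the individual participating in the most violating pairs is
    removed; ties are broken by dropping the later ID in file order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = grm.n_individuals
    alive = np.ones(n, dtype=bool)
    viol = (np.triu(grm.A, 1) >= cutoff)
    viol = viol | viol.T
    removed: list[int] = []
    while True:
        deg = (viol & alive & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        worst = np.flatnonzero(deg == deg.max())[-1]   # tie -> later in file order
        alive[worst] = False
        removed.append(worst)
    if not alive.any():
        raise ValueError("relatedness pruning removed every individual")
    keep_idx = np.flatnonzero(alive)
    pruned = GRM(
        ids=[grm.ids[j] for j in keep_idx],
        A=grm.A[np.ix_(keep_idx, keep_idx)],
        n_snps=grm.n_snps[np.ix_(keep_idx, keep_idx)],
    )
    return pruned, [grm.ids[j] for j in sorted(removed)]


# ---------------------------------------------------------------------------
# Binary GRM triplet I/O (lower triangle incl. diagonal, float32, row-major)


def write_grm(grm: GRM, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n_individuals
    tril = np.tril_indices(n)
    grm.A[tril].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.n_snps[tril].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for fid, iid in grm.ids:
            fh.write(f"{fid}\t{iid}\n")


def read_grm(prefix: str | Path) -> GRM:
    prefix = Path(prefix)
    id_df = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None, dtype=str)
    ids = list(zip(id_df[0], id_df[1]))
    n = len(ids)
    n_tri = n * (n + 1) // 2
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if len(vals) != n_tri:
        raise ValueError(
            f"{prefix}.grm.bin holds {len(vals)} values, expected {n_tri} for N={n}"
        )
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if len(counts) != n_tri:
        raise ValueError(f"{prefix}.grm.N.bin size inconsistent with N={n}")
    A = np.zeros((n, n))
    nm = np.zeros((n, n))
    tril = np.tril_indices(n)
    A[tril] = vals
    nm[tril] = counts
    A = A + np.tril(A, -1).T
    nm = nm + np.tril(nm, -1).T
    return GRM(ids=ids, A=A, n_snps=nm)
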