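import struct

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mvgreml.genotype_grm import (
    MISSING,
    GRM,
    GenotypeMatrix,
    SnpWeights,
    compute_grm,
    ldak_thin_weights,
    maf_filter,
    prune_relatedness,
    read_grm,
    read_plink,
    standardize,
    write_grm,
    write_plink,
)
from mvgreml.simulate import SimulationSpec, simulate_genotypes


def _geno(counts, pos=None, chrom=None):
    counts = np.asarray(counts, dtype=np.int8)
    n, m = counts.shape
    snp_ids = pd.DataFrame({
        "snp": [f"s{i}" for i in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "a1": "A", "a2": "G",
    })
    return GenotypeMatrix(
        ids=[("F", f"I{j}") for j in range(n)],
        snp_ids=snp_ids, counts=counts,
        freqs=GenotypeMatrix.empirical_freqs(counts),
    )


def _hw_spec(N, M, seed=0, freq_range=(0.05, 0.5)):
    t = 1
    return SimulationSpec(N=N, M=M, T=t, V_G_true=np.eye(t) * 0.4,
                          V_E_true=np.eye(t) * 0.6, freq_range=freq_range,
                          seed=seed)


class TestPlinkIO:
    def test_roundtrip_identity(self, tmp_path):
        g = simulate_genotypes(_hw_spec(13, 7, seed=3))
        write_plink(g, tmp_path / "x")
        g2 = read_plink(tmp_path / "x")
        assert np.array_equal(g.counts, g2.counts)
        assert g2.ids == g.ids
        assert list(g2.snp_ids["snp"]) == list(g.snp_ids["snp"])

    def test_missing_call_frequency_hand_count(self, tmp_path):
        # 5 individuals x 3 SNPs, one missing call in SNP 1
        counts = np.array([
            [0, 2, 1],
            [1, MISSING, 0],
            [2, 1, 0],
            [0, 0, 2],
            [1, 2, 1],
        ], dtype=np.int8)
        g = _geno(counts)
        write_plink(g, tmp_path / "m")
        g2 = read_plink(tmp_path / "m")
        assert np.array_equal(g2.counts, counts)
        # SNP 1: non-missing calls 2,1,0,2 over 4 individuals -> f = 5/8
        assert g2.freqs[1] == pytest.approx(5 / 8, abs=1e-12)
        assert (g2.counts[:, 1] != MISSING).sum() == 4

    def test_all_missing_snp_flagged_and_removed(self):
        counts = np.array([[MISSING, 1], [MISSING, 2], [MISSING, 0]], dtype=np.int8)
        g = _geno(counts)
        assert np.isnan(g.freqs[0])
        kept = maf_filter(g, 0.0)
        assert list(kept.snp_ids["snp"]) == ["s1"]

    def test_bad_magic_rejected(self, tmp_path):
        g = simulate_genotypes(_hw_spec(5, 3))
        write_plink(g, tmp_path / "y")
        bed = tmp_path / "y.bed"
        data = bytearray(bed.read_bytes())
        data[0] = 0x00
        bed.write_bytes(bytes(data))
        with pytest.raises(ValueError, match="magic"):
            read_plink(tmp_path / "y")

    def test_individual_major_rejected(self, tmp_path):
        g = simulate_genotypes(_hw_spec(5, 3))
        write_plink(g, tmp_path / "z")
        bed = tmp_path / "z.bed"
        data = bytearray(bed.read_bytes())
        data[2] = 0x00
        bed.write_bytes(bytes(data))
        with pytest.raises(ValueError, match="individual-major"):
            read_plink(tmp_path / "z")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_plink(tmp_path / "nope")


class TestMafFilter:
    def test_boundary_inclusive(self):
        # f = 0.005, 0.01, 0.5 at min_maf = 0.01: boundary SNP retained
        counts = np.zeros((100, 3), dtype=np.int8)
        counts[0, 0] = 1                        # f = 0.005
        counts[:2, 1] = 1                       # f = 0.01
        counts[:50, 2] = 2                      # f = 0.5
        kept = maf_filter(_geno(counts), 0.01)
        assert list(kept.snp_ids["snp"]) == ["s1", "s2"]

    def test_zero_maf_drops_only_monomorphic(self):
        counts = np.array([[0, 1, 2], [0, 0, 2], [0, 2, 2]], dtype=np.int8)
        kept = maf_filter(_geno(counts), 0.0)
        assert list(kept.snp_ids["snp"]) == ["s1"]

    def test_matches_brute_force_scan(self):
        g = simulate_genotypes(_hw_spec(80, 100, seed=9, freq_range=(0.001, 0.5)))
        kept = maf_filter(g, 0.05)
        expected = [
            i for i, f in enumerate(g.freqs)
            if min(f, 1 - f) >= 0.05
        ]
        assert list(kept.snp_ids["snp"]) == [f"snp{m:05d}" for m in expected]

    def test_all_removed_errors(self):
        counts = np.array([[0, 0], [0, 0], [1, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="every SNP"):
            maf_filter(_geno(counts), 0.4)

    def test_invalid_threshold(self):
        g = _geno(np.array([[0, 1], [1, 2]], dtype=np.int8))
        with pytest.raises(ValueError):
            maf_filter(g, 0.5)


class TestStandardize:
    def test_symmetric_case_f_half(self):
        counts = np.array([[0], [1], [2], [1]], dtype=np.int8)  # f = 0.5
        std = standardize(_geno(counts))
        np.testing.assert_allclose(
            std[:, 0], [-1.41421356, 0.0, 1.41421356, 0.0], atol=1e-8
        )

    def test_hand_value_f_quarter(self):
        # f = 0.25: carrier of two copies -> (2 - 0.5)/sqrt(0.375)
        counts = np.array([[2], [0], [0], [0]], dtype=np.int8)
        g = _geno(counts)
        assert g.freqs[0] == pytest.approx(0.25)
        std = standardize(g)
        assert std[0, 0] == pytest.approx(1.5 / np.sqrt(0.375), abs=1e-6)
        assert std[0, 0] == pytest.approx(2.44949, abs=1e-5)

    def test_columns_centered(self):
        g = simulate_genotypes(_hw_spec(200, 50, seed=1))
        std = standardize(g)
        assert np.abs(std.mean(axis=0)).max() < 1e-10

    def test_missing_imputed_to_zero(self):
        counts = np.array([[0], [1], [2], [MISSING]], dtype=np.int8)
        std = standardize(_geno(counts))
        assert std[3, 0] == 0.0

    def test_monomorphic_errors_naming_snp(self):
        counts = np.array([[0, 1], [0, 2]], dtype=np.int8)
        with pytest.raises(ZeroDivisionError, match="s0"):
            standardize(_geno(counts))


class TestComputeGrm:
    def test_two_individual_single_snp(self):
        A = compute_grm(np.array([[-1.0], [1.0]])).A
        np.testing.assert_allclose(A, [[1, -1], [-1, 1]], atol=1e-12)

    def test_duplicate_rows(self):
        std = np.vstack([np.ones(5), np.ones(5), -np.ones(5)])
        A = compute_grm(std).A
        assert A[0, 1] == pytest.approx(A[0, 0], abs=1e-12)

    def test_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        std = rng.standard_normal((20, 50))
        w = rng.uniform(0.1, 2.0, 50)
        A = compute_grm(std, SnpWeights(w)).A
        expected = np.zeros((20, 20))
        for j in range(20):
            for k in range(20):
                for m in range(50):
                    expected[j, k] += std[j, m] * w[m] * std[k, m]
        expected /= w.sum()
        np.testing.assert_allclose(A, expected, atol=1e-12)

    def test_unit_weights_reduce_to_mean_crossproduct(self):
        rng = np.random.default_rng(6)
        std = rng.standard_normal((10, 30))
        A = compute_grm(std).A
        np.testing.assert_allclose(A, std @ std.T / 30, atol=1e-12)

    def test_zero_weight_sum_rejected(self):
        with pytest.raises(ValueError):
            SnpWeights(np.zeros(4))

    def test_trace_near_n_for_hw_genotypes(self):
        # unit-weight GRM from many independent HW SNPs: mean diagonal -> 1
        g = simulate_genotypes(_hw_spec(200, 5000, seed=2))
        grm = compute_grm(standardize(maf_filter(g, 0.01)))
        assert abs(np.trace(grm.A) / 200 - 1.0) < 0.05

    def test_psd_on_random_fixtures(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            A = compute_grm(rng.standard_normal((15, 40))).A
            w = np.linalg.eigvalsh(A)
            assert w.min() >= -1e-8 * w.max()

    def test_allele_flip_invariance(self):
        g = simulate_genotypes(_hw_spec(50, 30, seed=4))
        g = maf_filter(g, 0.01)
        flipped = _geno(2 - g.counts, pos=g.snp_ids["pos"].to_numpy())
        A1 = compute_grm(standardize(g)).A
        A2 = compute_grm(standardize(flipped)).A
        np.testing.assert_allclose(A1, A2, atol=1e-12)


class TestLdakThin:
    def test_perfectly_correlated_pair_thinned(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.3, size=60).astype(np.int8)
        g = _geno(np.column_stack([col, col]), pos=[1000, 2000])
        w = ldak_thin_weights(g, r2_max=0.98, window_bp=100_000)
        assert (w.w > 0).sum() == 1
        assert w.w[0] > 0                       # first in file order kept

    def test_alpha_minus_one_gives_unit_weights(self):
        g = simulate_genotypes(_hw_spec(100, 10, seed=7))
        w = ldak_thin_weights(g, alpha=-1.0)
        kept = w.w[w.w > 0]
        np.testing.assert_allclose(kept, 1.0, atol=1e-12)

    def test_matches_exhaustive_greedy_scan(self):
        rng = np.random.default_rng(11)
        base = rng.binomial(2, 0.4, size=(80, 10)).astype(np.int8)
        # plant an LD block: SNPs 10-19 are noisy copies of SNP 0
        block = base[:, [0]].repeat(10, axis=1)
        flip = rng.random((80, 10)) < 0.02
        block = np.clip(block + flip * rng.integers(-1, 2, (80, 10)), 0, 2)
        counts = np.column_stack([base, block.astype(np.int8),
                                  rng.binomial(2, 0.3, (80, 10)).astype(np.int8)])
        pos = np.arange(30) * 10_000
        g = maf_filter(_geno(counts, pos=pos), 0.01)
        w = ldak_thin_weights(g, r2_max=0.5, window_bp=100_000, alpha=-0.25)

        # independent greedy scan on the full correlation matrix
        std = standardize(g)
        C2 = np.corrcoef(std, rowvar=False) ** 2
        posk = g.snp_ids["pos"].to_numpy()
        kept = []
        for i in range(g.n_snps):
            if all(C2[i, k] <= 0.5 or abs(posk[i] - posk[k]) > 100_000 for k in kept):
                kept.append(i)
        expected = np.zeros(g.n_snps, dtype=bool)
        expected[kept] = True
        np.testing.assert_array_equal(w.w > 0, expected)


class TestPruneRelatedness:
    @staticmethod
    def _grm(A):
        A = np.asarray(A, float)
        n = A.shape[0]
        return GRM(ids=[("F", f"I{j}") for j in range(n)], A=A,
                   n_snps=np.full((n, n), 10.0))

    def test_single_related_pair(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.5
        pruned, removed = prune_relatedness(self._grm(A), 0.025)
        assert len(removed) == 1 and pruned.n_individuals == 2
        assert removed[0] == ("F", "I1")        # tie broken by later file order

    def test_identity_when_all_below_cutoff(self):
        A = np.eye(4) + 0.01 * (1 - np.eye(4))
        pruned, removed = prune_relatedness(self._grm(A), 0.025)
        assert removed == [] and pruned.n_individuals == 4

    def test_planted_clique_matches_greedy_replay(self):
        rng = np.random.default_rng(3)
        A = np.eye(10) + rng.normal(0, 0.002, (10, 10))
        A = (A + A.T) / 2
        for i, j in [(2, 5), (2, 7), (5, 7)]:   # 3-clique at relatedness 0.3
            A[i, j] = A[j, i] = 0.3
        pruned, removed = prune_relatedness(self._grm(A), 0.025)

        # brute-force replay of the documented greedy rule
        alive = set(range(10))
        expected_removed = []
        while True:
            deg = {
                j: sum(1 for k in alive if k != j and A[j, k] >= 0.025)
                for j in alive
            }
            worst = max(deg.values())
            if worst == 0:
                break
            drop = max(j for j in alive if deg[j] == worst)
            alive.discard(drop)
            expected_removed.append(drop)
        assert removed == [("F", f"I{j}") for j in sorted(expected_removed)]
        off = pruned.A - np.diag(np.diag(pruned.A))
        assert off.max() < 0.025

    def test_mutually_related_pair_leaves_survivor(self):
        # greedy removal always keeps at least one individual
        pruned, removed = prune_relatedness(self._grm(np.ones((2, 2))), 1e-9)
        assert pruned.n_individuals == 1
        assert removed == [("F", "I1")]


class TestGrmIO:
    def test_roundtrip_within_float32(self, tmp_path):
        rng = np.random.default_rng(8)
        B = rng.standard_normal((10, 40))
        grm = compute_grm(B)
        write_grm(grm, tmp_path / "g")
        back = read_grm(tmp_path / "g")
        assert np.abs(back.A - grm.A).max() <= 1e-6
        assert back.ids == grm.ids

    def test_bin_holds_triangle_count(self, tmp_path):
        grm = compute_grm(np.random.default_rng(1).standard_normal((3, 9)))
        write_grm(grm, tmp_path / "g3")
        assert (tmp_path / "g3.grm.bin").stat().st_size == 6 * 4

    def test_hand_encoded_two_individuals(self, tmp_path):
        (tmp_path / "h.grm.bin").write_bytes(struct.pack("<3f", 1.0, 0.2, 1.0))
        (tmp_path / "h.grm.N.bin").write_bytes(struct.pack("<3f", 5.0, 5.0, 5.0))
        (tmp_path / "h.grm.id").write_text("F\tA\nF\tB\n")
        grm = read_grm(tmp_path / "h")
        np.testing.assert_allclose(grm.A, [[1.0, 0.2], [0.2, 1.0]], atol=1e-7)

    def test_size_mismatch_rejected(self, tmp_path):
        (tmp_path / "b.grm.bin").write_bytes(struct.pack("<4f", 1, 0, 1, 0))
        (tmp_path / "b.grm.N.bin").write_bytes(struct.pack("<3f", 1, 1, 1))
        (tmp_path / "b.grm.id").write_text("F\tA\nF\tB\n")
        with pytest.raises(ValueError, match="grm.bin"):
            read_grm(tmp_path / "b")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_grm_roundtrip_property(seed, tmp_path_factory):
    grm = compute_grm(np.random.default_rng(seed).standard_normal((6, 12)))
    path = tmp_path_factory.mktemp("grm") / "p"
    write_grm(grm, path)
    assert np.abs(read_grm(path).A - grm.A).max() <= 1e-6
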