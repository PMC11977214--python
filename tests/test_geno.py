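import inspect

import numpy as np
import pandas as pd
import pytest

from megblup.geno import (
    GenotypeMatrix,
    GenomicRelationshipMatrix,
    compute_grm,
    filter_variants,
    mean_impute,
    pairwise_ld,
    read_genotype_matrix,
    verify_pedigree,
)
from megblup.simulate import SimulationConfig, simulate_population


def make_geno(calls, missing=None, tree_ids=None, snp_ids=None, imputed=False):
    calls = np.asarray(calls, dtype=np.float64)
    n, m = calls.shape
    return GenotypeMatrix(
        tree_ids=tree_ids if tree_ids is not None else [f"t{i}" for i in range(n)],
        snp_ids=snp_ids if snp_ids is not None else [f"s{j}" for j in range(m)],
        calls=calls,
        missing_mask=missing if missing is not None else np.zeros((n, m), bool),
        imputed=imputed,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestReadGenotypes:
    def test_tsv012_with_missing_cell(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("tree_id\tsnpA\tsnpB\tsnpC\nt1\t0\t1\t2\nt2\t2\tNA\t0\n")
        g = read_genotype_matrix(path, format="tsv012")
        assert g.calls.shape == (2, 3)
        assert g.missing_mask.sum() == 1
        assert g.missing_mask[1, 1]
        assert g.calls[0].tolist() == [0, 1, 2]

    def test_invalid_code_raises(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("tree_id\tsnpA\nt1\t3\n")
        with pytest.raises(ValueError, match="invalid genotype code"):
            read_genotype_matrix(path, format="tsv012")

    def test_duplicate_tree_ids_raise(self):
        with pytest.raises(ValueError, match="duplicate tree ids"):
            make_geno([[0], [1]], tree_ids=["t1", "t1"])

    def test_vcf_biallelic_with_missing_genotype(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "1\t200\tv2\tC\tT\t.\tPASS\t.\tGT\t1/1\t./.\n"
            "1\t300\tv3\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        )
        g = read_genotype_matrix(vcf, format="vcf")
        assert g.calls.shape == (2, 3)
        assert g.missing_mask.sum() == 1
        assert g.missing_mask[1, 1]
        assert g.calls[0].tolist() == [0, 2, 1]
        assert g.calls[1, 0] == 1 and g.calls[1, 2] == 0

    def test_vcf_multiallelic_strict_vs_lenient(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\tv1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
            "1\t200\tv2\tC\tT\t.\tPASS\t.\tGT\t1/1\n"
        )
        with pytest.raises(ValueError, match="biallelic"):
            read_genotype_matrix(vcf, format="vcf", strict=True)
        g = read_genotype_matrix(vcf, format="vcf", strict=False)
        assert list(g.snp_ids) == ["v2"]


# ---------------------------------------------------------------------------
# Filtering and imputation
# ---------------------------------------------------------------------------

class TestFilterVariants:
    def test_missingness_and_mac_rules(self):
        n = 20
        calls = np.zeros((n, 4))
        miss = np.zeros((n, 4), bool)
        calls[:5, 0] = 1        # MAC 5, no missing        -> keep
        miss[:5, 1] = True      # rate 0.25
        calls[5:8, 1] = 1       # MAC 3 among observed     -> keep
        miss[:8, 2] = True      # rate 0.40                -> drop (missing)
        calls[8:10, 2] = 1
        # column 3: all zero, MAC 0                        -> drop (mac)
        g = make_geno(calls, miss)
        out, log = filter_variants(g, max_missing_rate=0.30, min_mac=1)
        assert list(out.snp_ids) == ["s0", "s1"]
        assert log.n_dropped_missing == 1
        assert log.n_dropped_mac == 1
        assert log.n_retained == 2

    def test_no_op_thresholds_keep_everything(self):
        g = make_geno([[0, 1], [2, 0]])
        out, log = filter_variants(g, max_missing_rate=1.0, min_mac=0)
        assert out.n_snps == 2 and log.n_retained == 2

    def test_defaults_are_30pct_and_mac1(self):
        sig = inspect.signature(filter_variants)
        assert sig.parameters["max_missing_rate"].default == 0.30
        assert sig.parameters["min_mac"].default == 1

    def test_empty_result_warns(self):
        g = make_geno([[0], [0]])  # monomorphic
        with pytest.warns(UserWarning, match="all SNPs removed"):
            filter_variants(g)


class TestMeanImpute:
    @pytest.mark.parametrize("col,expected_fill,expected_p", [
        ([0, 2, None], 1.0, 0.5),
        ([1, 1, None], 1.0, 0.5),
    ])
    def test_missing_replaced_by_observed_mean(self, col, expected_fill, expected_p):
        vals = [v if v is not None else 0 for v in col]
        miss = np.array([[v is None] for v in col])
        g = make_geno(np.array(vals)[:, None], miss)
        out, p = mean_impute(g)
        assert out.calls[2, 0] == pytest.approx(expected_fill)
        assert p[0] == pytest.approx(expected_p)
        assert not out.missing_mask.any()
        # observed cells untouched
        assert out.calls[0, 0] == vals[0] and out.calls[1, 0] == vals[1]

    def test_all_missing_column_raises(self):
        g = make_geno([[0], [0]], missing=np.ones((2, 1), bool))
        with pytest.raises(ValueError, match="zero non-missing"):
            mean_impute(g)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

class TestComputeGrm:
    def test_single_snp_hand_example(self):
        g = make_geno([[0], [1], [2]], imputed=True)
        grm = compute_grm(g, p=np.array([0.5]), blend_weight=0.0)
        expected = np.array([[2, 0, -2], [0, 0, 0], [-2, 0, 2]], dtype=float)
        np.testing.assert_allclose(grm.values, expected)
        assert grm.denom == pytest.approx(0.5)

    def test_tree_at_population_mean_has_zero_row(self):
        calls = np.array([[0, 2, 0], [2, 0, 2], [1, 1, 1]], dtype=float)
        g = make_geno(calls, imputed=True)
        grm = compute_grm(g, p=np.array([0.5, 0.5, 0.5]), blend_weight=0.0)
        np.testing.assert_allclose(grm.values[2], 0.0, atol=1e-12)

    def test_matches_bruteforce_double_loop(self, rng):
        calls = rng.integers(0, 3, size=(5, 20)).astype(float)
        g = make_geno(calls, imputed=True)
        p = g.allele_frequencies()
        grm = compute_grm(g, p, blend_weight=0.0)
        W = calls - 2 * p
        poly = (p > 0) & (p < 1)
        denom = 2 * np.sum(p[poly] * (1 - p[poly]))
        brute = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                brute[i, j] = sum(W[i, k] * W[j, k] for k in range(20)) / denom
        np.testing.assert_allclose(grm.values, brute, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        calls = rng.integers(0, 3, size=(6, 40)).astype(float)
        g = make_geno(calls, imputed=True)
        perm = rng.permutation(6)
        gp = make_geno(calls[perm], tree_ids=[f"t{i}" for i in perm], imputed=True)
        p = g.allele_frequencies()
        G1 = compute_grm(g, p, blend_weight=0.0).values
        G2 = compute_grm(gp, p, blend_weight=0.0).values
        np.testing.assert_allclose(G2, G1[np.ix_(perm, perm)], atol=1e-12)

    def test_blending_raises_smallest_eigenvalue(self, rng):
        calls = rng.integers(0, 3, size=(30, 10)).astype(float)  # n > rank: singular raw G
        g = make_geno(calls, imputed=True)
        p = g.allele_frequencies()
        raw = compute_grm(g, p, blend_weight=0.0)
        blended = compute_grm(g, p, blend_weight=0.05)
        lo_raw = np.linalg.eigvalsh(raw.values).min()
        lo_blend = np.linalg.eigvalsh(blended.values).min()
        assert lo_blend >= lo_raw + 0.05 * (1 - 1e-6) * (1 - abs(lo_raw))
        assert lo_blend > 1e-4  # invertible

    def test_hwe_population_diagonal_mean_near_one(self):
        # 400 unrelated trees (families of one offspring each)
        cfg = SimulationConfig(seed=5, n_families=400, n_sites=1,
                               offspring_per_family_per_site=(1,), n_snps=1500,
                               sigma2_a=(0.5,), sigma2_e=(0.5,), r_g=0.0)
        geno, _ = simulate_population(cfg)
        grm = compute_grm(geno, blend_weight=0.0)
        assert np.mean(np.diag(grm.values)) == pytest.approx(1.0, abs=0.05)

    def test_all_monomorphic_raises(self):
        g = make_geno([[2, 2], [2, 2]], imputed=True)
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(g, blend_weight=0.0)

    def test_pipeline_deterministic(self, tmp_path, rng):
        calls = rng.integers(0, 3, size=(8, 30)).astype(float)
        miss = rng.random((8, 30)) < 0.1
        g = make_geno(calls, miss)
        results = []
        for _ in range(2):
            f, _log = filter_variants(g)
            imp, p = mean_impute(f)
            results.append(compute_grm(imp, p).values)
        assert (results[0] == results[1]).all()


def test_halfsib_families_average_quarter_relatedness(sim600):
    """Mean within-family off-diagonal GRM entry ~ 0.25, cross-family ~ 0."""
    cfg, geno, ped, pheno, truth, _ = sim600
    grm = compute_grm(geno, blend_weight=0.0)
    fam = ped.set_index("tree_id").loc[grm.tree_ids, "family_id"].to_numpy()
    iu, ju = np.triu_indices(grm.n_trees, k=1)
    same = fam[iu] == fam[ju]
    within = grm.values[iu, ju][same].mean()
    across = grm.values[iu, ju][~same].mean()
    assert within == pytest.approx(0.25, abs=0.03)
    assert across == pytest.approx(0.0, abs=0.02)


# ---------------------------------------------------------------------------
# Pedigree conflicts
# ---------------------------------------------------------------------------

class TestVerifyPedigree:
    @staticmethod
    def _grm_from(values, ids):
        return GenomicRelationshipMatrix(
            tree_ids=ids, values=np.asarray(values, float), blend_weight=0.0, denom=1.0
        )

    def _ped(self, fam_of):
        return pd.DataFrame(
            {"tree_id": list(fam_of), "family_id": [fam_of[t] for t in fam_of]}
        )

    def test_small_deviation_not_flagged_large_flagged(self):
        G = np.array([[1.0, 0.26, 0.60], [0.26, 1.0, 0.0], [0.60, 0.0, 1.0]])
        grm = self._grm_from(G, ["a", "b", "c"])
        ped = self._ped({"a": "F1", "b": "F1", "c": "F2"})
        rep = verify_pedigree(grm, ped, deviation_tol=0.15)
        tab = rep.pairs.set_index(["tree_a", "tree_b"])
        assert not tab.loc[("a", "b"), "flag"]  # same family, g=0.26, dev 0.01
        assert tab.loc[("a", "c"), "flag"]      # cross family, g=0.60
        assert rep.removed_tree_ids  # greedy removal resolves the conflict

    def test_mislabeled_tree_is_the_removal_set(self):
        # trees a1-a3 family F1, b1-b3 family F2; b3 is genomically an F1 tree
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        G = np.eye(6)
        for i in range(3):
            for j in range(3):
                if i != j:
                    G[i, j] = 0.25
        G[3, 4] = G[4, 3] = 0.25
        for i in range(3):           # b3 related to all of F1
            G[5, i] = G[i, 5] = 0.25
        # b3 unrelated to its recorded sibs b1, b2 (0 vs expected 0.25): deviation 0.25
        grm = self._grm_from(G, ids)
        ped = self._ped({"a1": "F1", "a2": "F1", "a3": "F1",
                         "b1": "F2", "b2": "F2", "b3": "F2"})
        rep = verify_pedigree(grm, ped, deviation_tol=0.15)
        assert rep.removed_tree_ids == ["b3"]
        assert rep.n_flagged == 5
        assert rep.retained_ids(ids) == ["a1", "a2", "a3", "b1", "b2"]

    def test_tree_missing_from_pedigree_raises(self):
        grm = self._grm_from(np.eye(2), ["a", "b"])
        ped = self._ped({"a": "F1"})
        with pytest.raises(ValueError, match="absent from pedigree"):
            verify_pedigree(grm, ped)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

class TestPairwiseLd:
    def test_duplicated_column_r2_one(self):
        calls = np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1], [1, 1, 2]], dtype=float)
        g = make_geno(calls, imputed=True)
        res = pairwise_ld(g)
        dup = res.pairs.set_index(["snp_a", "snp_b"]).loc[("s0", "s1"), "r2"]
        assert dup == pytest.approx(1.0)

    def test_matches_bruteforce_correlations(self):
        calls = np.array([[0, 2, 1], [1, 1, 2], [2, 0, 0], [1, 2, 1], [0, 1, 2]], dtype=float)
        g = make_geno(calls, imputed=True)
        res = pairwise_ld(g)
        for _, row in res.pairs.iterrows():
            a = calls[:, int(row["snp_a"][1:])]
            b = calls[:, int(row["snp_b"][1:])]
            assert row["r2"] == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2, abs=1e-12)

    def test_pair_count_is_choose_2(self, rng):
        k = 25
        calls = rng.integers(0, 3, size=(10, k)).astype(float)
        g = make_geno(calls, imputed=True)
        res = pairwise_ld(g, keep_pairs=False)
        assert res.count_pairs == k * (k - 1) // 2

    def test_zero_variance_snp_reported_missing(self):
        calls = np.array([[1, 0], [1, 1], [1, 2]], dtype=float)
        g = make_geno(calls, imputed=True)
        res = pairwise_ld(g)
        assert np.isnan(res.pairs["r2"]).all()
        assert res.count_pairs == 1 and res.count_above == 0
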