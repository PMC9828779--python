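"""Variant filtering, genotype PCA, and hybrid-index classification."""

import numpy as np
import pytest

from contactzone import popgen
from contactzone.io_formats import GenotypeMatrix


def six_site_fixture():
    """Six sites engineered so exactly one fails each rule and one passes.

    10 samples.  Sites:
      0 pass       biallelic, clean, MAF 0.3
      1 non-biallelic
      2 fails missingness directly (7/10 "./.")
      3 fails missingness after GQ masking (8 entries GQ <= 20)
      4 fails missingness after depth masking (8 entries DP = 2)
      5 fails MAF (singleton het: MAF 0.05 < 0.04? no -> monomorphic)
    """
    n = 10
    dos = np.zeros((n, 6))
    dos[:, 0] = [0, 0, 1, 1, 2, 0, 1, 0, 1, 0]       # MAF 0.35
    dos[:, 1] = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]       # flagged non-biallelic
    dos[:7, 2] = np.nan                               # 70% missing
    dos[:, 3] = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
    dos[:, 4] = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
    dos[:, 5] = 0.0                                   # monomorphic, MAF 0
    gq = np.full((n, 6), 99.0)
    gq[:8, 3] = 10.0                                  # masked -> 80% missing
    depth = np.full((n, 6), 15.0)
    depth[:8, 4] = 2.0                                # masked -> 80% missing
    bial = np.array([True, False, True, True, True, True])
    # non-biallelic entries are missing at read time
    dos[:, 1] = np.nan
    return GenotypeMatrix(dos, [f"i{i}" for i in range(n)],
                          [f"s{j}" for j in range(6)], depth=depth, gq=gq,
                          is_biallelic=bial)


def brute_force_filter(G, maf_min=0.04, max_missing=0.60, gq_min=20,
                       dp_min=5, dp_max=30):
    """Independent per-rule oracle: loops over sites and entries."""
    losses = {"non_biallelic": 0, "missing": 0, "maf": 0}
    survivors = []
    for j in range(G.n_sites):
        if not G.is_biallelic[j]:
            losses["non_biallelic"] += 1
            continue
        col = []
        for i in range(G.n_samples):
            v = G.dosages[i, j]
            if np.isnan(v):
                col.append(np.nan)
                continue
            if G.gq is not None and G.gq[i, j] <= gq_min:
                col.append(np.nan)
                continue
            if G.depth is not None and not (dp_min <= G.depth[i, j] <= dp_max):
                col.append(np.nan)
                continue
            col.append(v)
        col = np.array(col)
        if np.mean(np.isnan(col)) > max_missing:
            losses["missing"] += 1
            continue
        p = np.nanmean(col) / 2.0
        if np.isnan(p) or min(p, 1 - p) < maf_min:
            losses["maf"] += 1
            continue
        survivors.append(j)
    return survivors, losses


class TestFilterVariants:
    def test_fixture_matches_oracle(self):
        G = six_site_fixture()
        out, losses = popgen.filter_variants(G)
        surv, oracle_losses = brute_force_filter(G)
        assert out.site_ids == [G.site_ids[j] for j in surv]
        assert out.n_sites == 1
        for rule in ("non_biallelic", "missing", "maf"):
            assert losses[rule] == oracle_losses[rule], rule

    def test_loss_counts_sum_to_sites_removed(self):
        G = six_site_fixture()
        out, losses = popgen.filter_variants(G)
        removed = sum(losses[k] for k in ("non_biallelic", "missing", "maf"))
        assert removed == G.n_sites - out.n_sites

    def test_vacuous_thresholds_keep_everything(self, rng):
        dos = rng.integers(0, 3, size=(8, 5)).astype(float)
        G = GenotypeMatrix(dos, [f"i{i}" for i in range(8)],
                           [f"s{j}" for j in range(5)])
        out, _ = popgen.filter_variants(G, maf_min=0.0, max_missing=1.0,
                                        gq_min=0, dp_min=0, dp_max=10 ** 9,
                                        biallelic_only=False)
        np.testing.assert_array_equal(out.dosages, dos)

    def test_monomorphic_removed_by_maf(self):
        dos = np.zeros((6, 1))
        G = GenotypeMatrix(dos, [f"i{i}" for i in range(6)], ["s0"])
        out, losses = popgen.filter_variants(G)
        assert out.n_sites == 0
        assert losses["maf"] == 1

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(5):
            n, m = 12, 25
            dos = rng.integers(0, 3, size=(n, m)).astype(float)
            dos[rng.uniform(size=(n, m)) < 0.3] = np.nan
            depth = rng.integers(1, 40, size=(n, m)).astype(float)
            gq = rng.integers(5, 99, size=(n, m)).astype(float)
            bial = rng.uniform(size=m) > 0.1
            dos[:, ~bial] = np.nan
            G = GenotypeMatrix(dos, [f"i{i}" for i in range(n)],
                               [f"s{j}" for j in range(m)], depth=depth,
                               gq=gq, is_biallelic=bial)
            out, losses = popgen.filter_variants(G)
            surv, oracle_losses = brute_force_filter(G)
            assert out.site_ids == [G.site_ids[j] for j in surv]
            for rule in oracle_losses:
                assert losses[rule] == oracle_losses[rule]


class TestGenotypePCA:
    def two_cluster_matrix(self, rng, n=20, m=30):
        dos = np.zeros((2 * n, m))
        dos[n:, :] = 2.0
        noise = rng.uniform(size=dos.shape) < 0.02
        dos[noise] = 1.0
        return GenotypeMatrix(dos, [f"i{i}" for i in range(2 * n)],
                              [f"s{j}" for j in range(m)])

    def test_pc1_separates_fixed_clusters(self, rng):
        G = self.two_cluster_matrix(rng)
        s = popgen.genotype_pca(G)
        assert s.var_fraction[0] > 0.9
        pc1 = s.scores[:, 0]
        assert (pc1[:20].mean() < 0 < pc1[20:].mean()) \
            or (pc1[20:].mean() < 0 < pc1[:20].mean())

    def test_f1_row_is_intermediate(self):
        dos = np.vstack([np.zeros((10, 20)), np.full((10, 20), 2.0),
                         np.full((1, 20), 1.0)])
        G = GenotypeMatrix(dos, [f"i{i}" for i in range(21)],
                           [f"s{j}" for j in range(20)])
        s = popgen.genotype_pca(G)
        pc1 = s.scores[:, 0]
        lo, hi = sorted([pc1[:10].mean(), pc1[10:20].mean()])
        assert lo < pc1[20] < hi

    def test_mirrored_dosages_mirror_pc1(self, rng):
        dos = rng.integers(0, 3, size=(15, 40)).astype(float)
        ids = [f"i{i}" for i in range(15)]
        sites = [f"s{j}" for j in range(40)]
        a = popgen.genotype_pca(GenotypeMatrix(dos, ids, sites))
        b = popgen.genotype_pca(GenotypeMatrix(2.0 - dos, ids, sites))
        np.testing.assert_allclose(np.abs(a.scores[:, 0]),
                                   np.abs(b.scores[:, 0]), atol=1e-8)

    def test_matches_direct_eigendecomposition(self, rng):
        dos = rng.integers(0, 3, size=(30, 50)).astype(float)
        G = GenotypeMatrix(dos, [f"i{i}" for i in range(30)],
                           [f"s{j}" for j in range(50)])
        s = popgen.genotype_pca(G)
        evals = np.sort(np.linalg.eigvalsh(
            np.cov(dos, rowvar=False, ddof=1)))[::-1]
        np.testing.assert_allclose(s.var_fraction[0],
                                   evals[0] / evals.sum(), rtol=1e-8)

    def test_orientation_anchor(self, rng):
        G = self.two_cluster_matrix(rng)
        s = popgen.genotype_pca(G, orient_negative_ids=[f"i{i}"
                                                        for i in range(20)])
        assert s.scores[:20, 0].mean() < 0

    def test_all_missing_site_dropped(self, rng):
        dos = rng.integers(0, 3, size=(10, 3)).astype(float)
        dos[:, 1] = np.nan
        G = GenotypeMatrix(dos, [f"i{i}" for i in range(10)],
                           ["a", "b", "c"])
        s = popgen.genotype_pca(G)
        assert s.loadings.shape[1] == 2


class TestHybridIndex:
    def panel_matrix(self, rng, n_diag=40, het_fraction=None, extra=None):
        """10 pure A, 10 pure B, plus optional query rows."""
        rows = [np.zeros(n_diag)] * 10 + [np.full(n_diag, 2.0)] * 10
        if extra is not None:
            rows += list(extra)
        dos = np.array(rows, dtype=float)
        ids = ([f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
               + [f"q{i}" for i in range(len(dos) - 20)])
        return GenotypeMatrix(dos, ids, [f"s{j}" for j in range(n_diag)]), ids

    def test_pure_and_f1_calls(self, rng):
        extra = [np.zeros(40), np.full(40, 2.0), np.full(40, 1.0)]
        G, ids = self.panel_matrix(rng, extra=extra)
        reports = popgen.hybrid_index(G, ids[:10], ids[10:20])
        calls = {r.sample_id: r for r in reports}
        assert calls["q0"].call == "pure_A" and calls["q0"].hybrid_index == 0.0
        assert calls["q1"].call == "pure_B" and calls["q1"].hybrid_index == 1.0
        f1 = calls["q2"]
        assert f1.call == "F1_candidate"
        assert f1.hybrid_index == 0.5
        assert f1.interspecific_het == 1.0

    def test_backcross_called_other(self, rng):
        """A backcross (F1 x pure A) has expected index 0.25 and het 0.5 at
        diagnostic sites; it must not be mistaken for an F1."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            # gametes: pure A contributes allele 0; F1 contributes 0 or 1
            bc = (r.integers(0, 2, size=40)).astype(float)
            G, ids = self.panel_matrix(r, extra=[bc])
            (rep_out,) = popgen.hybrid_index(G, ids[:10], ids[10:20])
            hits += rep_out.call == "other"
        assert hits >= 95

    def test_site_permutation_invariance(self, rng):
        q = rng.integers(0, 3, size=40).astype(float)
        G, ids = self.panel_matrix(rng, extra=[q])
        (a,) = popgen.hybrid_index(G, ids[:10], ids[10:20])
        perm = rng.permutation(40)
        G2 = GenotypeMatrix(G.dosages[:, perm], G.sample_ids,
                            [G.site_ids[j] for j in perm])
        (b,) = popgen.hybrid_index(G2, ids[:10], ids[10:20])
        assert a.hybrid_index == pytest.approx(b.hybrid_index)
        assert a.interspecific_het == pytest.approx(b.interspecific_het)

    def test_no_diagnostic_sites_raises(self, rng):
        dos = rng.integers(0, 3, size=(21, 10)).astype(float)
        ids = [f"x{i}" for i in range(21)]
        G = GenotypeMatrix(dos, ids, [f"s{j}" for j in range(10)])
        with pytest.raises(ValueError, match="diagnostic"):
            popgen.hybrid_index(G, ids[:10], ids[10:20],
                                diagnostic_delta=0.999)
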