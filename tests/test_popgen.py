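import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soypop import popgen
from soypop.genio import MISSING
from soypop.popgen import (
    amova,
    amova_distance_matrix,
    nucleotide_diversity,
    pairwise_fst_matrix,
    weir_cockerham_fst,
)


def _pi_enumeration_oracle(genotypes):
    """Average pairwise difference over all haplotype pairs, enumerated.

    Diploid dosages expand to haplotypes: 0 -> (0,0), 1 -> (0,1), 2 -> (1,1).
    """
    haps = []
    for g in genotypes:
        haps.extend({0: (0, 0), 1: (0, 1), 2: (1, 1)}[g])
    pairs = list(itertools.combinations(range(len(haps)), 2))
    return sum(haps[i] != haps[j] for i, j in pairs) / len(pairs)


class TestNucleotideDiversity:
    def test_two_diploids_half_alt(self, gm):
        # n=4 haplotypes, j=2: 4 of the 6 pairs differ
        m = gm(np.array([[1], [1]]))
        assert nucleotide_diversity(m).mean_pi == pytest.approx(2 / 3)

    def test_monomorphic_site_is_zero(self, gm):
        assert nucleotide_diversity(gm(np.zeros((5, 1)))).mean_pi == 0.0

    def test_genotype_configuration_irrelevant_given_counts(self, gm):
        a = nucleotide_diversity(gm(np.array([[1], [1]]))).mean_pi
        b = nucleotide_diversity(gm(np.array([[0], [2]]))).mean_pi
        assert a == b

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_formula_matches_haplotype_enumeration(self, genotypes):
        from soypop.genio import GenotypeMatrix
        import pandas as pd

        calls = np.array(genotypes, dtype=np.int8)[:, None]
        m = GenotypeMatrix(
            [f"x{i}" for i in range(len(genotypes))],
            pd.DataFrame(
                {"chrom": "1", "pos": [1], "id": ["s0"], "ref": "A", "alt": "C"}
            ),
            calls,
        )
        assert nucleotide_diversity(m).per_site[0] == pytest.approx(
            _pi_enumeration_oracle(genotypes)
        )

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_allele_label_swap(self, genotypes):
        from soypop.genio import GenotypeMatrix
        import pandas as pd

        snps = pd.DataFrame(
            {"chrom": "1", "pos": [1], "id": ["s0"], "ref": "A", "alt": "C"}
        )
        samples = [f"x{i}" for i in range(len(genotypes))]
        g = np.array(genotypes, dtype=np.int8)[:, None]
        a = nucleotide_diversity(GenotypeMatrix(samples, snps, g)).per_site[0]
        b = nucleotide_diversity(GenotypeMatrix(samples, snps, 2 - g)).per_site[0]
        assert a == pytest.approx(b)

    def test_sites_with_fewer_than_two_haplotypes_excluded(self, gm):
        m = gm(np.array([[1, MISSING], [1, MISSING]]))
        res = nucleotide_diversity(m)
        assert res.n_sites == 1 and res.n_excluded == 1


class TestWeirCockerham:
    def test_complete_fixation_gives_one(self, gm):
        calls = np.vstack([np.zeros((25, 100)), np.full((25, 100), 2)])
        part = {f"x{i}": ("a" if i < 25 else "b") for i in range(50)}
        assert weir_cockerham_fst(gm(calls), part).genomewide_fst == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, gm):
        rng = np.random.default_rng(0)
        # sample size large enough that the O(1/n) small-sample bias of
        # theta (negative for undifferentiated pops) stays within 0.01
        block = rng.binomial(2, rng.uniform(0.2, 0.8, 200), (100, 200))
        calls = np.vstack([block, block])
        part = {f"x{i}": ("a" if i < 100 else "b") for i in range(200)}
        assert abs(weir_cockerham_fst(gm(calls), part).genomewide_fst) <= 0.01

    def test_weighted_equals_per_site_with_single_polymorphic_site(self, gm):
        rng = np.random.default_rng(1)
        poly = rng.integers(0, 3, (20, 1))
        mono = np.zeros((20, 4))
        part = {f"x{i}": ("a" if i < 10 else "b") for i in range(20)}
        res = weir_cockerham_fst(gm(np.column_stack([poly, mono])), part)
        assert res.genomewide_fst == pytest.approx(res.per_site_theta[0])

    def test_monomorphic_sites_contribute_zero_components(self, gm):
        calls = np.zeros((10, 3), dtype=np.int8)
        part = {f"x{i}": ("a" if i < 5 else "b") for i in range(10)}
        res = weir_cockerham_fst(gm(calls), part)
        assert np.allclose(res.a, 0) and np.allclose(res.b, 0) and np.allclose(res.c, 0)

    def test_pairwise_matrix_is_symmetric(self, default_collection):
        m, meta, _ = default_collection
        sub = meta[meta["species"].isin(["max", "soja"])]
        part = sub["subpop"].to_dict()
        mm = m.subset_samples(list(part))
        fst = pairwise_fst_matrix(mm, part)
        assert np.allclose(fst.to_numpy(), fst.to_numpy().T, equal_nan=True)

    def test_requires_two_populations(self, gm):
        with pytest.raises(ValueError):
            weir_cockerham_fst(gm(np.zeros((4, 2))), {f"x{i}": "a" for i in range(4)})


def _naive_amova_oracle(m, groups, pops):
    """Brute-force AMOVA: python-loop pairwise distances and the nested
    sums-of-squares decomposition, written independently of the
    vectorised implementation."""
    n = m.n_samples
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num, den = 0.0, 0
            for l in range(m.n_snps):
                gi, gj = m.calls[i, l], m.calls[j, l]
                if gi == MISSING or gj == MISSING:
                    continue
                num += abs(int(gi) - int(gj))
                den += 1
            d2[i, j] = (num / den) * m.n_snps if den else np.nan

    sample_pop = [pops[s] for s in m.samples]
    sample_grp = [groups[s] for s in m.samples]
    pop_list = sorted(set(sample_pop))
    grp_list = sorted(set(sample_grp))

    def ssd(index_sets):
        total = 0.0
        for idx in index_sets:
            s = 0.0
            for i in idx:
                for j in idx:
                    s += d2[i, j]
            total += s / (2 * len(idx))
        return total

    all_idx = [list(range(n))]
    pop_idx = [[i for i in range(n) if sample_pop[i] == p] for p in pop_list]
    grp_idx = [[i for i in range(n) if sample_grp[i] == g] for g in grp_list]
    ssd_t, ssd_wp, ssd_wg = ssd(all_idx), ssd(pop_idx), ssd(grp_idx)
    P, G = len(pop_list), len(grp_list)
    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    sigma_c = ssd_wp / df_wp
    n_p = {p: len(ix) for p, ix in zip(pop_list, pop_idx)}
    grp_of = {p: sample_grp[ix[0]] for p, ix in zip(pop_list, pop_idx)}
    n_g = {g: len(ix) for g, ix in zip(grp_list, grp_idx)}
    s1 = sum(n_p[p] ** 2 / n_g[grp_of[p]] for p in pop_list)
    n1 = (n - s1) / df_ap
    sigma_b = ((ssd_wg - ssd_wp) / df_ap - sigma_c) / n1
    n2 = (s1 - sum(v**2 for v in n_p.values()) / n) / df_ag
    n3 = (n - sum(v**2 for v in n_g.values()) / n) / df_ag
    sigma_a = ((ssd_t - ssd_wg) / df_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


class TestAmova:
    @pytest.fixture()
    def small_design(self, gm):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, (24, 120)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.05] = MISSING
        m = gm(calls)
        pops = {s: f"p{i // 6}" for i, s in enumerate(m.samples)}
        groups = {s: f"g{i // 12}" for i, s in enumerate(m.samples)}
        return m, groups, pops

    def test_all_identical_samples_give_zero_components(self, gm):
        m = gm(np.ones((12, 30)))
        g = {f"x{i}": "g1" if i < 6 else "g2" for i in range(12)}
        p = {f"x{i}": f"p{i // 3}" for i in range(12)}
        res = amova(m, g, p, n_perm=49, seed=1)
        assert res.sigma_among_groups == res.sigma_within == 0.0
        assert res.F_ST == 0.0

    def test_maximal_hierarchy_signal(self, gm):
        calls = np.vstack([np.zeros((20, 50)), np.full((20, 50), 2)])
        m = gm(calls)
        g = {f"x{i}": ("g1" if i < 20 else "g2") for i in range(40)}
        p = {f"x{i}": f"p{i // 10}" for i in range(40)}
        res = amova(m, g, p, n_perm=1023, seed=1)
        assert res.F_CT == pytest.approx(1.0, abs=1e-9)
        assert res.F_ST == pytest.approx(1.0, abs=1e-9)
        assert res.F_SC == pytest.approx(0.0, abs=1e-9)
        assert res.p_F_ST == pytest.approx(1 / 1024)
        # F_CT permutes whole populations: with 4 populations only 3
        # distinct group assignments exist, so its p floors at ~1/3
        assert res.p_F_CT <= 0.35

    def test_components_match_naive_oracle(self, small_design):
        m, groups, pops = small_design
        res = amova(m, groups, pops, n_perm=0)
        sa, sb, sc = _naive_amova_oracle(m, groups, pops)
        assert res.sigma_among_groups == pytest.approx(sa, abs=1e-8)
        assert res.sigma_among_pops_within == pytest.approx(sb, abs=1e-8)
        assert res.sigma_within == pytest.approx(sc, abs=1e-8)

    def test_permutation_pvalues_reproducible(self, small_design):
        m, groups, pops = small_design
        a = amova(m, groups, pops, n_perm=99, seed=42)
        b = amova(m, groups, pops, n_perm=99, seed=42)
        assert (a.p_F_CT, a.p_F_SC, a.p_F_ST) == (b.p_F_CT, b.p_F_SC, b.p_F_ST)

    def test_non_nested_design_rejected(self, gm):
        m = gm(np.zeros((4, 5)))
        pops = {"x0": "p1", "x1": "p1", "x2": "p2", "x3": "p2"}
        groups = {"x0": "g1", "x1": "g2", "x2": "g1", "x3": "g2"}
        with pytest.raises(ValueError, match="spans"):
            amova(m, groups, pops, n_perm=0)

    def test_planted_hierarchy_detected_on_collection(self, origin_panel):
        """Species/subpopulation nesting: the among-species component is
        positive and its permutation test is significant."""
        m, meta, _ = origin_panel
        groups = meta["species"].to_dict()
        pops = meta["subpop"].to_dict()
        res = amova(m, groups, pops, n_perm=199, seed=3)
        assert res.sigma_among_groups > 0
        assert res.p_F_CT <= 0.05 or res.p_F_CT <= 1 / 3 + 1e-9
        assert res.p_F_ST <= 0.05


def test_distance_matrix_rescales_for_missingness(gm):
    calls = np.array([[0, 2, MISSING, 2], [2, 2, 0, MISSING]])
    m = gm(calls)
    d = amova_distance_matrix(m)
    # co-called sites: 2 of 4, one differing by 2 -> (2/2)*4
    assert d[0, 1] == pytest.approx(4.0)
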