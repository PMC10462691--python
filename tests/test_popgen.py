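import itertools

import numpy as np
import pytest
from scipy.special import comb

from seascapegen import popgen

from conftest import make_gm, make_loc, two_deme_gm


# ---------------------------------------------------------------------------
# independent literal-formula oracles

def wc_theta_oracle(pop_calls):
    """Direct transcription of the WC (1984) variance components, locus by
    locus, for complete biallelic diploid data."""
    L = pop_calls[0].shape[1]
    A = B = C = 0.0
    r = len(pop_calls)
    for l in range(L):
        ns = [p.shape[0] for p in pop_calls]
        ps = [p[:, l].sum() / (2 * n) for p, n in zip(pop_calls, ns)]
        hs = [(p[:, l] == 1).mean() for p in pop_calls]
        nbar = sum(ns) / r
        nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = nbar / nc * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        if a + b + c != 0:
            A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


def jost_d_oracle(pop_calls):
    """Direct transcription of Jost's D with Nei–Chesser H_S / H_T."""
    k = len(pop_calls)
    L = pop_calls[0].shape[1]
    ds = []
    for l in range(L):
        ns = [p.shape[0] for p in pop_calls]
        ps = [p[:, l].sum() / (2 * n) for p, n in zip(pop_calls, ns)]
        hos = [(p[:, l] == 1).mean() for p in pop_calls]
        ntilde = k / sum(1 / n for n in ns)
        sum_p2 = np.mean([p * p + (1 - p) ** 2 for p in ps])
        ho = np.mean(hos)
        hs = ntilde / (ntilde - 1) * (1 - sum_p2 - ho / (2 * ntilde))
        pbar = np.mean(ps)
        ht = (1 - pbar**2 - (1 - pbar) ** 2 + hs / (ntilde * k)
              - ho / (2 * ntilde * k))
        if 1 - hs != 0:
            ds.append((k / (k - 1)) * (ht - hs) / (1 - hs))
    return float(np.mean(ds))


def bh_oracle(p):
    """Brute-force step-up definition of Benjamini–Hochberg."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adj[i] = running_min
    return np.array(adj)


# ---------------------------------------------------------------------------

class TestDiversity:
    def test_fixed_locus_contributes_unit_richness_zero_het(self):
        gm = make_gm(np.zeros((5, 1)))
        loc = make_loc(gm, ["a"] * 5)
        t = popgen.diversity(gm, loc, rarefaction_g=4).table
        assert t.loc["a", "A_R"] == 1.0
        assert t.loc["a", "H_O"] == 0.0
        assert t.loc["a", "H_E"] == 0.0
        assert t.loc["a", "F_IS"] == 0.0

    def test_all_heterozygous_gives_unit_ho(self):
        gm = make_gm(np.ones((6, 1)))
        loc = make_loc(gm, ["a"] * 6)
        t = popgen.diversity(gm, loc, rarefaction_g=4).table
        assert t.loc["a", "H_O"] == 1.0

    def test_rarefied_richness_matches_hypergeometric_enumeration(self):
        # 5 diploids with allele counts (9, 1); draw g = 2 gene copies:
        # A_R = 2 - [C(9,2) + C(1,2)] / C(10,2)
        calls = np.array([[1.0], [0.0], [0.0], [0.0], [0.0]])
        gm = make_gm(calls)
        loc = make_loc(gm, ["a"] * 5)
        t = popgen.diversity(gm, loc, rarefaction_g=2).table
        expected = 2 - (comb(9, 2) + comb(1, 2)) / comb(10, 2)
        assert t.loc["a", "A_R"] == pytest.approx(expected)

    def test_unbiased_he_small_sample_factor(self):
        # p = 0.5, n = 2 diploids: H_E = 2pq * 4/3
        gm = make_gm(np.array([[0.0], [2.0]]))
        loc = make_loc(gm, ["a"] * 2)
        t = popgen.diversity(gm, loc, rarefaction_g=2).table
        assert t.loc["a", "H_E"] == pytest.approx(0.5 * 4 / 3)


class TestWCFst:
    def test_fixed_difference_gives_theta_one(self):
        calls = np.vstack([np.zeros((10, 3)), np.full((10, 3), 2.0)])
        gm = make_gm(calls)
        loc = make_loc(gm, ["a"] * 10 + ["b"] * 10)
        assert popgen.wc_fst(gm, loc) == pytest.approx(1.0)

    def test_identical_demes_give_nonpositive_theta(self, rng):
        block = rng.integers(0, 3, (8, 50)).astype(float)
        gm = make_gm(np.vstack([block, block]))
        loc = make_loc(gm, ["a"] * 8 + ["b"] * 8)
        assert popgen.wc_fst(gm, loc) <= 0.0

    def test_matches_literal_formula_oracle(self, rng):
        calls = rng.integers(0, 3, (17, 3)).astype(float)
        gm = make_gm(calls)
        labels = ["a"] * 9 + ["b"] * 8
        loc = make_loc(gm, labels)
        oracle = wc_theta_oracle([calls[:9], calls[9:]])
        assert popgen.wc_fst(gm, loc) == pytest.approx(oracle, abs=1e-12)

    def test_allele_label_flip_invariant(self, rng):
        gm, loc = two_deme_gm(rng, n_per=10, n_loci=40)
        flipped = make_gm(2.0 - gm.calls)
        assert popgen.wc_fst(flipped, make_loc(flipped, loc.location_of(gm))) == \
            pytest.approx(popgen.wc_fst(gm, loc))

    def test_increases_with_divergence(self, rng):
        thetas = []
        for spread in (0.2, 1.0, 2.5):
            gm, loc = two_deme_gm(rng, n_per=25, n_loci=400, spread=spread)
            thetas.append(popgen.wc_fst(gm, loc))
        assert thetas[0] < thetas[1] < thetas[2]


class TestJostD:
    def test_fixed_difference_gives_d_one(self):
        calls = np.vstack([np.zeros((10, 2)), np.full((10, 2), 2.0)])
        gm = make_gm(calls)
        loc = make_loc(gm, ["a"] * 10 + ["b"] * 10)
        assert popgen.jost_d(gm, loc) == pytest.approx(1.0)

    def test_identical_frequencies_give_d_near_zero(self):
        # identical genotype arrays, equal n: the Nei–Chesser-corrected D is
        # zero in expectation, with per-sample deviation of order 1/n
        block = np.tile([0.0, 1.0, 2.0, 1.0], 125)[:, None] * np.ones((1, 5))
        gm = make_gm(np.vstack([block, block]))
        loc = make_loc(gm, ["a"] * 500 + ["b"] * 500)
        assert popgen.jost_d(gm, loc) == pytest.approx(0.0, abs=0.01)

    def test_matches_literal_formula_oracle(self, rng):
        calls = rng.integers(0, 3, (15, 4)).astype(float)
        gm = make_gm(calls)
        loc = make_loc(gm, ["a"] * 7 + ["b"] * 8)
        oracle = jost_d_oracle([calls[:7], calls[7:]])
        assert popgen.jost_d(gm, loc) == pytest.approx(oracle, abs=1e-12)

    def test_harmonic_variant_defined(self, rng):
        gm, loc = two_deme_gm(rng, n_per=12, n_loci=60)
        d_h = popgen.jost_d(gm, loc, aggregate="harmonic")
        assert np.isfinite(d_h)


class TestBHAdjust:
    def test_two_value_example(self):
        assert np.allclose(popgen.bh_adjust(np.array([0.01, 0.04])), [0.02, 0.04])

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_matches_brute_force_on_small_grids(self, n, rng):
        grid = np.array([0.001, 0.01, 0.04, 0.2, 0.5, 0.9])
        for _ in range(30):
            p = rng.choice(grid, size=n, replace=True)
            assert np.allclose(popgen.bh_adjust(p), bh_oracle(p))

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(0, 1, 40)
        adj = popgen.bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestPairwiseBootstrap:
    def test_fixed_demes_give_minimal_p(self, rng):
        calls = np.vstack([np.zeros((10, 60)), np.full((10, 60), 2.0)])
        gm = make_gm(calls)
        loc = make_loc(gm, ["a"] * 10 + ["b"] * 10)
        pm = popgen.pairwise_with_bootstrap(gm, loc, "fst", n_boot=200, seed=1)
        assert pm.values[0, 1] == pytest.approx(1.0)
        assert pm.p_values[0, 1] <= 1.0 / 201.0 + 1e-12

    def test_inclusion_rule_excludes_small_locations(self, rng):
        gm, loc = two_deme_gm(rng, n_per=10, n_loci=30)
        extra = make_gm(
            np.vstack([gm.calls, rng.integers(0, 3, (3, 30))]), prefix="s"
        )
        labels = list(loc.location_of(gm)) + ["tiny"] * 3
        loc2 = make_loc(extra, labels)
        pm = popgen.pairwise_with_bootstrap(extra, loc2, "fst", n_boot=50, seed=0)
        assert "tiny" not in pm.location_ids

    def test_seed_reproducible(self, rng):
        gm, loc = two_deme_gm(rng, n_per=10, n_loci=40)
        a = popgen.pairwise_with_bootstrap(gm, loc, "jost_d", n_boot=99, seed=5)
        b = popgen.pairwise_with_bootstrap(gm, loc, "jost_d", n_boot=99, seed=5)
        assert np.array_equal(a.p_values, b.p_values, equal_nan=True)

    def test_bad_n_boot_rejected(self, rng):
        gm, loc = two_deme_gm(rng, n_per=10, n_loci=20)
        with pytest.raises(ValueError):
            popgen.pairwise_with_bootstrap(gm, loc, "fst", n_boot=0, seed=0)


class TestLinearize:
    def test_anchor_values(self):
        assert popgen.linearize(0.0) == 0.0
        assert popgen.linearize(0.5) == pytest.approx(1.0)
        assert popgen.linearize(-0.02) == 0.0  # clamped

    def test_monotone_on_unit_interval(self):
        xs = np.linspace(0, 0.99, 50)
        ys = [popgen.linearize(x) for x in xs]
        assert (np.diff(ys) > 0).all()

    def test_unit_fst_gives_infinity(self):
        with pytest.warns(UserWarning):
            assert popgen.linearize(1.0) == np.inf
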