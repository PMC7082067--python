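import numpy as np
import pytest

from imtracer.io_msmc import MultihetsepRecord
from imtracer.msmc2_lite import (
    HMMConfig,
    _HMMachinery,
    _interval_times,
    _pair_observations,
    _prior_marginal,
    block_bootstrap,
    estimate_rates,
    expand_pair_spec,
    smc_prime_transition,
)
from imtracer.scenarios import ScenarioSpec, clean_split, simulate_sequences
from imtracer.timegrid import make_time_grid

CROSS_16 = ("0-4,0-5,0-6,0-7,1-4,1-5,1-6,1-7,"
            "2-4,2-5,2-6,2-7,3-4,3-5,3-6,3-7")


class TestPairSpec:
    def test_within_form_expands_all_pairs(self):
        assert len(expand_pair_spec("0,1,2,3")) == 6
        assert expand_pair_spec("0,1").pairs == ((0, 1),)

    def test_cross_form_verbatim(self):
        sel = expand_pair_spec(CROSS_16)
        assert len(sel) == 16
        assert sel.pairs[0] == (0, 4) and sel.pairs[-1] == (3, 7)

    @pytest.mark.parametrize("bad", ["", "0", "0,0", "0-1,2", "a,b",
                                     "0-0"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            expand_pair_spec(bad)

    def test_out_of_range_index(self):
        with pytest.raises(ValueError, match="range"):
            expand_pair_spec("0,9").validate(4)


@pytest.fixture(scope="module")
def grid():
    return make_time_grid(n_ref=10_000)


@pytest.fixture(scope="module")
def sim_chroms():
    return simulate_sequences(clean_split(75.0), seed=11, n_chrom=2,
                              chrom_length=2e6)


class TestTransitionKernel:
    def test_rows_are_distributions(self, grid):
        lam0 = 2.5e-5
        b, t_rep = _interval_times(grid, lam0)
        T = smc_prime_transition(b, t_rep, np.full(grid.n_atomic, lam0),
                                 1e-8)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert T.min() >= 0.0

    def test_prior_is_stationary(self, grid, rng):
        # the SMC' kernel leaves the coalescent tMRCA prior invariant
        lam0 = 2.5e-5
        b, t_rep = _interval_times(grid, lam0)
        lam_at = np.exp(rng.uniform(np.log(5e-6), np.log(1e-4),
                                    grid.n_atomic))
        T = smc_prime_transition(b, t_rep, lam_at, 1e-8)
        q = _prior_marginal(b, lam_at)
        np.testing.assert_allclose(q @ T, q, rtol=2e-4)


class TestForwardBackward:
    def _machine(self, grid):
        lam0 = 2.5e-5
        b, t_rep = _interval_times(grid, lam0)
        T = smc_prime_transition(b, t_rep, np.full(grid.n_atomic, lam0),
                                 1e-8)
        p_het = -np.expm1(-2 * 1.25e-8 * t_rep)
        return _HMMachinery(T, p_het, _prior_marginal(
            b, np.full(grid.n_atomic, lam0)))

    def test_forward_backward_likelihood_agreement(self, grid, sim_chroms):
        pairs = expand_pair_spec("0,1,2,3")
        d, het = _pair_observations(sim_chroms[0][:400], pairs)
        mach = self._machine(grid)
        ll_f, _ = mach.forward(d, het)
        ll_b = mach.backward_loglik(d, het)
        np.testing.assert_allclose(ll_f, ll_b, rtol=1e-8)

    def test_posterior_sums_normalized(self, grid, sim_chroms):
        pairs = expand_pair_spec("0,1")
        d, het = _pair_observations(sim_chroms[0][:300], pairs)
        mach = self._machine(grid)
        gamma, ll = mach.posterior_sums(d, het)
        # gamma is weighted by called sites: total mass equals the total
        # number of called sites times the number of pairs
        assert gamma.sum() == pytest.approx(float(d.sum()) * len(pairs),
                                            rel=1e-9)

    def test_phase_ambiguous_emissions_are_averaged(self, grid):
        recs = [MultihetsepRecord("c", 100, 100, "01,10"),
                MultihetsepRecord("c", 500, 400, "00,11")]
        d, het = _pair_observations(recs, expand_pair_spec("0,1"))
        # first record is het under both phasings; second is hom in both
        np.testing.assert_array_equal(het[:, 0], [1.0, 0.0])
        recs2 = [MultihetsepRecord("c", 100, 100, "01,00")]
        _, het2 = _pair_observations(recs2, expand_pair_spec("0,1"))
        assert het2[0, 0] == pytest.approx(0.5)


class TestEstimation:
    def test_em_loglik_nondecreasing(self, grid, sim_chroms):
        cfg = HMMConfig(grid=grid, max_iterations=5)
        _, trace = estimate_rates(sim_chroms, expand_pair_spec("0,1,2,3"),
                                  cfg)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-9)

    def test_duplicating_input_leaves_fixed_point(self, grid, sim_chroms):
        cfg = HMMConfig(grid=grid, max_iterations=3)
        t1, _ = estimate_rates(sim_chroms, expand_pair_spec("0,1,2,3"), cfg)
        t2, _ = estimate_rates(sim_chroms + sim_chroms,
                               expand_pair_spec("0,1,2,3"), cfg)
        np.testing.assert_allclose(t1.lambdas, t2.lambdas, rtol=1e-9)

    def test_constant_size_recovery_within_flatness_band(self, grid,
                                                         sim_chroms):
        # within-population pairs of the split scenario coalesce in a
        # constant-size population; inferred sizes should be flat within
        # a modest band over the well-resolved middle range
        cfg = HMMConfig(grid=grid, max_iterations=8)
        tab, _ = estimate_rates(sim_chroms, expand_pair_spec("0,1,2,3"),
                                cfg)
        N_hat = 1.0 / (2.0 * tab.lambdas[:, 0] * grid.mu)
        mid = N_hat[4:22]
        assert mid.max() / mid.min() < 1.3
        assert np.median(mid) == pytest.approx(20_000, rel=0.15)

    def test_cross_rates_vanish_before_split(self, grid, sim_chroms):
        cfg = HMMConfig(grid=grid, max_iterations=8)
        tab, _ = estimate_rates(sim_chroms, expand_pair_spec(CROSS_16), cfg)
        lam = tab.lambdas[:, 0] * grid.mu
        # segment 0 lies entirely before the 75 kya split
        assert lam[0] < 0.2 * lam[-1]
        assert lam[-1] == pytest.approx(2.5e-5, rel=0.25)

    def test_zigzag_oscillation_tracked(self, grid):
        # oscillating size history: inferred sizes must alternate in phase
        # with the simulated zigzag over the resolvable range
        from imtracer.scenarios import zigzag

        chroms = simulate_sequences(zigzag(), seed=19, n_chrom=2,
                                    chrom_length=3e6)
        cfg = HMMConfig(grid=grid, rho=0.3e-8, max_iterations=10)
        tab, _ = estimate_rates(chroms,
                                expand_pair_spec("0,1,2,3,4,5,6,7"), cfg)
        N = 1.0 / (2.0 * tab.lambdas[:, 0] * grid.mu)
        bounds = grid.segment_boundaries_gens

        def n_at(t):
            seg = np.searchsorted(bounds[:-1], t, side="right") - 1
            return N[seg]

        # phase midpoints of the simulated low/high/low/high/low episodes
        low1, high1, low2, high2, low3 = (n_at(t) for t in
                                          (2200, 4600, 9000, 18000, 35000))
        assert low1 < high1 > low2 < high2 > low3
        assert high1 / low2 > 2 and high2 / low2 > 2
        assert np.all((N > 1_500) & (N < 45_000))

    def test_no_heterozygous_sites_is_an_error(self, grid):
        recs = [MultihetsepRecord("c", 100 * (i + 1), 100, "0000")
                for i in range(50)]
        with pytest.raises(ValueError, match="heterozygous"):
            estimate_rates([recs], expand_pair_spec("0,1,2,3"),
                           HMMConfig(grid=grid))

    def test_empty_input_is_an_error(self, grid):
        with pytest.raises(ValueError, match="records"):
            estimate_rates([[]], expand_pair_spec("0,1"),
                           HMMConfig(grid=grid))


class TestBootstrap:
    def test_reproducible_given_seed(self, sim_chroms):
        a = block_bootstrap(sim_chroms, 5e5, n_blocks=6, n_reps=20, seed=3)
        b = block_bootstrap(sim_chroms, 5e5, n_blocks=6, n_reps=20, seed=3)
        assert len(a) == 20
        assert a == b
        c = block_bootstrap(sim_chroms, 5e5, n_blocks=6, n_reps=20, seed=4)
        assert a != c

    def test_block_structure_preserved(self, sim_chroms):
        reps = block_bootstrap(sim_chroms, 5e5, n_blocks=4, n_reps=2,
                               seed=1)
        for rep in reps:
            assert len(rep) == 4
            for block in rep:
                pos = [r.pos for r in block]
                assert pos == sorted(pos)
                assert pos[-1] <= 5e5 + 1
                assert all(r.called_since_last >= 1 for r in block)

    def test_fraction_of_absent_blocks_near_inverse_e(self, sim_chroms):
        # classical bootstrap: P(block absent from a replicate) -> e^-1
        blocks_per_chrom = 20
        reps = block_bootstrap(sim_chroms, 1e5, n_blocks=40, n_reps=50,
                               seed=7)
        # identify source blocks by their sequence of allele strings,
        # which the bootstrap preserves verbatim
        def key(block):
            return tuple(r.alleles for r in block)
        pool_keys = set()
        for chrom in sim_chroms:
            for start in range(0, 2_000_001, 100_000):
                blk = [r for r in chrom if start < r.pos <= start + 100_000]
                if blk:
                    pool_keys.add(key(blk))
        absent = []
        for rep in reps:
            seen = {key(b) for b in rep}
            absent.append(1 - len(seen & pool_keys) / len(pool_keys))
        assert np.mean(absent) == pytest.approx(np.exp(-1), abs=0.08)
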