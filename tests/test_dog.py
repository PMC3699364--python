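import math
import statistics

import numpy as np
import pytest
from scipy.stats import norm

from dogstat import (
    DogHyper,
    ExpressionDataset,
    GenePair,
    dog_detect,
    dog_statistics,
    max_gene_variance,
    run_dog_dataset,
    split_candidates,
    update_tight_cluster,
)
from dogstat.datamodel import CONTROL, EXPERIMENTAL

# ---------------------------------------------------------------------------
# Independent oracle: a literal, slow replay of the sequential procedure
# using plain Python lists and the statistics module.  It shares no helper
# code with the implementation under test.
# ---------------------------------------------------------------------------


def oracle_dog(x, y, alpha, a, b, beta0_init=0.1, tol=1e-12, sweeps=5000):
    cutoff = max(x)
    z = list(x) + list(y)
    z_plus = sorted(v for v in z if v > cutoff)
    z_minus = [v for v in z if v <= cutoff]
    beta0 = beta0_init
    while z_plus:
        mu0 = statistics.median(z_minus)
        mu = mu0
        prev = None
        for _ in range(sweeps):
            inv_beta = (sum((v - mu) ** 2 for v in z_minus) + 2 * b) / (
                len(z_minus) + 2 * a + 2
            )
            beta = 1.0 / inv_beta
            mu = (beta * sum(z_minus) + beta0 * mu0) / (beta * len(z_minus) + beta0)
            beta0 = (a + 1.0) / ((mu - mu0) ** 2 / 2.0 + b)
            if prev and max(abs(mu - prev[0]), abs(beta - prev[1]),
                            abs(beta0 - prev[2])) < tol:
                break
            prev = (mu, beta, beta0)
        t = (z_plus[0] - mu) / math.sqrt(inv_beta)
        t_alpha = norm.ppf((1.0 - alpha) ** (1.0 / len(z_minus)))
        if t > t_alpha:
            ts = [(v - mu) / math.sqrt(inv_beta) for v in z_plus]
            return len(z_plus), sum(ts) / len(ts)
        z_minus.append(z_plus.pop(0))
    return 0, 0.0


class TestSplitCandidates:
    def test_max_control_mode(self):
        pair = GenePair([9.0, 10.0, 11.0], [10.0, 15.0])
        z_minus, z_plus, idx = split_candidates(pair, DogHyper())
        assert sorted(z_minus) == [9.0, 10.0, 10.0, 11.0]
        np.testing.assert_array_equal(z_plus, [15.0])
        np.testing.assert_array_equal(idx, [4])

    def test_no_candidates(self):
        pair = GenePair([9.0, 10.0, 11.0], [8.0, 9.0])
        z_minus, z_plus, _ = split_candidates(pair, DogHyper())
        assert z_plus.size == 0
        assert z_minus.size == 5

    def test_control_percentile_mode_flags_control_value(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 20.0])
        pair = GenePair(x, np.array([3.0, 4.0]))
        hyper = DogHyper(mode="control_percentile", control_percentile=90)
        z_minus, z_plus, _ = split_candidates(pair, hyper)
        # q90 of x by linear interpolation = 10.1 < 20, so 20 is a candidate
        assert 20.0 in z_plus
        assert z_minus.size + z_plus.size == 12

    def test_partition_is_conserved(self, rng):
        for mode in ("max_control", "control_percentile"):
            pair = GenePair(rng.normal(10, 1, 12), rng.normal(11, 2, 15))
            z_minus, z_plus, _ = split_candidates(pair, DogHyper(mode=mode))
            assert z_minus.size + z_plus.size == 27
            np.testing.assert_array_equal(z_plus, np.sort(z_plus))


class TestTightClusterUpdate:
    def test_symmetric_fixed_point(self):
        st = update_tight_cluster(np.array([9.0, 10.0, 11.0, 10.0]),
                                  DogHyper(b=5.5))
        assert st.mu == pytest.approx(10.0)
        assert 1 / st.beta == pytest.approx(1.625)  # (2 + 11)/8
        assert 1 / st.beta0 == pytest.approx(2.75)  # (0 + 5.5)/2

    def test_constant_cluster_limit(self):
        n, b = 6, 2.0
        st = update_tight_cluster(np.full(n, 3.0), DogHyper(a=1.0, b=b))
        assert st.mu == pytest.approx(3.0)
        assert 1 / st.beta == pytest.approx(2 * b / (n + 4))

    def test_posterior_tracks_sample_mean_with_n(self, rng):
        """With more data the posterior mean approaches the sample mean."""
        hyper = DogHyper(b=1.0)
        gaps = []
        for n in (10, 1000):
            z = rng.normal(5.0, 1.0, n)
            st = update_tight_cluster(z, hyper)
            gaps.append(abs(st.mu - z.mean()))
        assert gaps[1] < gaps[0]


class TestDogDetect:
    def test_hand_trace_single_outlier(self):
        res = dog_detect(GenePair([9.0, 10.0, 11.0], [10.0, 15.0]),
                         DogHyper(alpha=0.05), b=5.5)
        assert res.M == 1
        assert res.is_hdeg
        assert res.statistic == pytest.approx(5.0 / math.sqrt(1.625))
        assert res.trace[-1][2] == "detect"

    def test_no_candidates_is_non_hdeg(self):
        res = dog_detect(GenePair([9.0, 10.0, 11.0], [10.0, 9.0]), DogHyper())
        assert res.M == 0 and res.statistic == 0.0 and not res.is_hdeg

    @pytest.mark.parametrize("case", range(40))
    def test_oracle_equivalence_small_instances(self, case):
        """The implementation reproduces a literal replay of the sequential
        detect/absorb procedure on instances with up to 6 candidates."""
        rng = np.random.default_rng(1000 + case)
        x = rng.normal(10, 1, rng.integers(4, 12))
        n_out = int(rng.integers(0, 4))
        y = np.concatenate([
            rng.normal(10, 1, rng.integers(4, 12)),
            x.max() + rng.uniform(0.2, 4.0, n_out),
        ])
        b = float(np.var(np.concatenate([x, y]), ddof=1))
        res = dog_detect(GenePair(x, y), DogHyper(alpha=0.05), b=b)
        m_expect, stat_expect = oracle_dog(list(x), list(y), 0.05, 1.0, b)
        assert res.M == m_expect
        assert res.statistic == pytest.approx(stat_expect, rel=1e-6)

    def test_partition_conservation(self, rng):
        x = rng.normal(10, 1, 15)
        y = np.concatenate([rng.normal(10, 1, 12), [14.0, 15.0, 16.0]])
        res = dog_detect(GenePair(x, y), DogHyper(), b=2.0)
        assert res.z_minus_size + res.M == x.size + y.size

    def test_detected_t_values_exceed_threshold(self, rng):
        """Whenever M ≥ 1, every reported standardized outlier exceeds t_α:
        the first detection fires on the smallest remaining candidate."""
        hyper = DogHyper()
        found = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            x = r.normal(10, 1, 20)
            y = np.concatenate([r.normal(10, 1, 17),
                                x.max() + r.normal(2.0, 0.2, 3)])
            res = dog_detect(GenePair(x, y), hyper, b=1.5)
            if res.M >= 1:
                found += 1
                assert res.t_values.min() > hyper.threshold(res.z_minus_size)
                assert res.statistic == pytest.approx(res.t_values.mean())
        assert found > 0

    def test_m_monotone_in_alpha(self, rng):
        """A stricter threshold (smaller α) cannot detect more outliers."""
        x = rng.normal(10, 1, 20)
        y = np.concatenate([rng.normal(10, 1, 15),
                            x.max() + np.array([0.5, 1.0, 2.0, 3.0, 4.0])])
        pair = GenePair(x, y)
        ms = [dog_detect(pair, DogHyper(alpha=al), b=1.5).M
              for al in (0.2, 0.1, 0.05, 0.01, 0.001)]
        assert ms == sorted(ms, reverse=True)

    def test_absorption_moves_shrink_with_cluster_size(self, rng):
        """Absorbing the same candidate perturbs (μ, σ²) less as the i.i.d.
        Gaussian cluster grows — the empirical convergence behaviour."""
        hyper = DogHyper(b=1.5)
        cand = 12.0
        mu_moves, var_moves = [], []
        for n in (20, 80, 320, 1280):
            z = rng.normal(10, 1, n)
            before = update_tight_cluster(z, hyper)
            after = update_tight_cluster(np.append(z, cand), hyper, before)
            mu_moves.append(abs(after.mu - before.mu))
            var_moves.append(abs(after.sigma2 - before.sigma2))
        assert mu_moves == sorted(mu_moves, reverse=True)
        assert var_moves[-1] < var_moves[0]


class TestRunDogDataset:
    def test_shared_b_inflates_single_gene_variance(self):
        """A high-variance gene in the dataset raises b and hence the
        variance estimate used for every other gene."""
        rng = np.random.default_rng(7)
        quiet = rng.normal(10, 1, 60)
        noisy = rng.normal(10, 6, 60)
        labels = [CONTROL] * 30 + [EXPERIMENTAL] * 30
        ds = ExpressionDataset(["quiet", "noisy"],
                               np.vstack([quiet, noisy]), labels)
        b_shared = max_gene_variance(ds)
        b_alone = float(np.var(quiet, ddof=1))
        assert b_shared > b_alone
        hyper = DogHyper()
        pair = ds.gene(0)
        z_minus, _, _ = split_candidates(pair, hyper)
        st_shared = update_tight_cluster(z_minus, hyper, b=b_shared)
        st_alone = update_tight_cluster(z_minus, hyper, b=b_alone)
        assert 1 / st_shared.beta > 1 / st_alone.beta

    def test_identical_genes_identical_results(self, rng):
        row = rng.normal(10, 1, 20)
        row[-1] = row[:10].max() + 3
        values = np.tile(row, (4, 1))
        labels = [CONTROL] * 10 + [EXPERIMENTAL] * 10
        ds = ExpressionDataset([f"g{i}" for i in range(4)], values, labels)
        stat, m = dog_statistics(ds, DogHyper())
        assert len(set(np.round(stat, 12))) == 1
        assert len(set(m)) == 1

    def test_gene_order_permutation_equivariance(self, rng):
        values = rng.normal(10, 1, (6, 20))
        values[2, -1] += 5
        labels = [CONTROL] * 10 + [EXPERIMENTAL] * 10
        ids = [f"g{i}" for i in range(6)]
        ds = ExpressionDataset(ids, values, labels)
        perm = [3, 1, 5, 0, 2, 4]
        ds_p = ExpressionDataset([ids[i] for i in perm], values[perm], labels)
        s1, _ = dog_statistics(ds, DogHyper())
        s2, _ = dog_statistics(ds_p, DogHyper())
        np.testing.assert_allclose(s2, s1[perm], rtol=1e-12)

    def test_result_table_ranks(self, rng):
        values = rng.normal(10, 1, (5, 12))
        values[0, -1] += 6
        labels = [CONTROL] * 6 + [EXPERIMENTAL] * 6
        ds = ExpressionDataset([f"g{i}" for i in range(5)], values, labels)
        rt = run_dog_dataset(ds)
        assert sorted(rt.frame["rank"]) == [1, 2, 3, 4, 5]
        top = rt.sorted().iloc[0]
        assert top.gene_id == "g0"


class TestHyperOptions:
    def test_threshold_rules_ordered_at_moderate_n(self):
        """The max-of-n threshold is far stricter than the plain quantiles."""
        assert DogHyper(t_dist="normal").threshold(60) < \
            DogHyper(t_dist="student").threshold(60) < \
            DogHyper(t_dist="max_normal").threshold(60)

    def test_max_normal_grows_with_cluster_size(self):
        h = DogHyper()
        ts = [h.threshold(n) for n in (5, 20, 60, 200)]
        assert ts == sorted(ts)

    @pytest.mark.parametrize(
        "kwargs", [dict(alpha=0.0), dict(alpha=1.5), dict(a=-1.0),
                   dict(beta0_init=0.0), dict(mode="median"),
                   dict(t_dist="gumbel"),
                   dict(mode="control_percentile", control_percentile=100.0)],
    )
    def test_invalid_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DogHyper(**kwargs)
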