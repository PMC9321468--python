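"""Gaussian entropy / mutual information closed forms, mismatched
information against a fine beta-grid oracle, and MIP search against an
independent brute-force recomputation."""
import numpy as np
import pytest

from vpckit import (bipartitions, find_mip, gaussian_entropy,
                    lagged_covariances, mip_association, mip_type_code,
                    mismatched_information, mutual_information, phi_from_data,
                    phi_timecourse, shrinkage_cov)

LOG_2PIE = np.log(2 * np.pi * np.e)


def stationary_var1(A, noise=None):
    """Lagged covariances of a stationary VAR(1) process X_t = A X_{t-1} + e."""
    n = A.shape[0]
    noise = np.eye(n) if noise is None else noise
    S = np.eye(n)
    for _ in range(2000):
        S = A @ S @ A.T + noise
    return S, A @ S, S          # cov_t, cov_cross, cov_lag


def grid_istar(cov_t, cov_cross, cov_lag, partition, betas):
    """Independent fine-grid oracle for the mismatched information."""
    from vpckit.integration import _mismatched_objective
    n = cov_t.shape[0]
    A = np.zeros((n, n))
    Dinv = np.zeros((n, n))
    for p in partition:
        ix = np.ix_(p, p)
        a_k = cov_cross[ix] @ np.linalg.inv(cov_lag[ix])
        A[ix] = a_k
        Dinv[ix] = np.linalg.inv(cov_t[ix] - a_k @ cov_cross[ix].T)
    S = cov_t - A @ cov_cross.T - cov_cross @ A.T + A @ cov_lag @ A.T
    lag_inv = np.linalg.inv(cov_lag)
    vals = [_mismatched_objective(b, A, Dinv, S, cov_t, cov_lag, lag_inv)
            for b in betas]
    return max(vals)


class TestEntropy:
    def test_closed_forms(self):
        assert gaussian_entropy(np.array([[1.0]])) == pytest.approx(0.5 * LOG_2PIE,
                                                                    abs=1e-12)
        assert gaussian_entropy(np.eye(2)) == pytest.approx(LOG_2PIE, abs=1e-12)

    def test_monte_carlo_oracle(self, rng):
        a = rng.standard_normal((3, 3))
        cov = a @ a.T + 0.5 * np.eye(3)
        h = gaussian_entropy(cov)
        x = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        inv = np.linalg.inv(cov)
        logp = (-0.5 * np.einsum("ij,jk,ik->i", x, inv, x)
                - 0.5 * np.linalg.slogdet(2 * np.pi * cov)[1])
        assert h == pytest.approx(-logp.mean(), rel=0.01)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            gaussian_entropy(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestMutualInformation:
    def test_independence_gives_zero(self):
        assert mutual_information(np.eye(3), np.zeros((3, 3)), np.eye(3)) \
            == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("a,tau", [(0.9, 1), (0.9, 3), (0.5, 2)])
    def test_ar1_closed_form(self, a, tau):
        i = mutual_information(np.array([[1.0]]), np.array([[a ** tau]]),
                               np.array([[1.0]]))
        assert i == pytest.approx(-0.5 * np.log(1 - a ** (2 * tau)), abs=1e-3)

    def test_scale_invariance(self, rng):
        A = 0.4 * np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        cov_t, cov_x, cov_l = stationary_var1(A)
        i0 = mutual_information(cov_t, cov_x, cov_l)
        d = np.diag([3.0, 0.2, 7.0])
        i1 = mutual_information(d @ cov_t @ d, d @ cov_x @ d, d @ cov_l @ d)
        assert i1 == pytest.approx(i0, abs=1e-9)


class TestMismatchedInformation:
    def test_trivial_partition_recovers_full_information(self, rng):
        A = 0.5 * np.eye(4) + 0.15 * rng.standard_normal((4, 4))
        cov_t, cov_x, cov_l = stationary_var1(A)
        i = mutual_information(cov_t, cov_x, cov_l)
        i_star, beta = mismatched_information(cov_t, cov_x, cov_l,
                                              [list(range(4))])
        assert i_star == pytest.approx(i, abs=1e-8)
        assert beta == pytest.approx(1.0, abs=1e-3)

    def test_disconnected_system_gives_zero_phi(self):
        A = np.zeros((4, 4))
        A[:2, :2] = [[0.5, 0.2], [0.1, 0.4]]
        A[2:, 2:] = [[0.3, 0.1], [0.2, 0.6]]
        cov_t, cov_x, cov_l = stationary_var1(A)
        i = mutual_information(cov_t, cov_x, cov_l)
        i_star, _ = mismatched_information(cov_t, cov_x, cov_l, [[0, 1], [2, 3]])
        assert i - i_star == pytest.approx(0.0, abs=1e-6)

    def test_istar_bounded_by_i(self, rng):
        for _ in range(10):
            A = 0.3 * np.eye(4) + 0.2 * rng.standard_normal((4, 4))
            if np.max(np.abs(np.linalg.eigvals(A))) >= 0.95:
                continue
            cov_t, cov_x, cov_l = stationary_var1(A)
            i = mutual_information(cov_t, cov_x, cov_l)
            i_star, _ = mismatched_information(cov_t, cov_x, cov_l,
                                               [[0, 1], [2, 3]])
            assert -1e-9 <= i_star <= i + 1e-9

    def test_optimizer_matches_fine_grid(self, rng):
        betas = np.arange(0.0, 2.0 + 1e-12, 1e-4)
        for trial in range(3):
            A = np.array([[0.6, 0.25], [0.15, 0.5]]) \
                + 0.05 * rng.standard_normal((2, 2))
            cov_t, cov_x, cov_l = stationary_var1(A)
            i_star, _ = mismatched_information(cov_t, cov_x, cov_l, [[0], [1]])
            oracle = grid_istar(cov_t, cov_x, cov_l, [[0], [1]], betas)
            assert i_star == pytest.approx(oracle, abs=1e-4)

    def test_bad_partition_rejected(self):
        with pytest.raises(ValueError):
            mismatched_information(np.eye(2), np.zeros((2, 2)), np.eye(2),
                                   [[0], [0, 1]])


class TestShrinkageCov:
    def test_large_sample_identity(self, rng):
        x = rng.standard_normal((5, 1000))
        cov = shrinkage_cov(x)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 0.1
        assert np.allclose(np.diag(cov), 1.0, atol=0.15)

    def test_more_channels_than_samples_still_pd(self, rng):
        x = rng.standard_normal((20, 10))
        cov = shrinkage_cov(x)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_duplicated_channel_invertible(self, rng):
        base = rng.standard_normal((1, 200))
        x = np.vstack([base, base, rng.standard_normal((1, 200))])
        cov = shrinkage_cov(x)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_zero_variance_channel_named(self, rng):
        x = rng.standard_normal((3, 100))
        x[1] = 4.2
        with pytest.raises(ValueError, match="1"):
            shrinkage_cov(x)


class TestMipSearch:
    def test_bipartition_count(self):
        assert len(bipartitions(list("abcdefg"))) == 63
        assert len(bipartitions(list("abc"))) == 3

    def test_independent_groups_found_and_phi_zero(self):
        A = np.zeros((4, 4))
        A[:2, :2] = [[0.5, 0.3], [0.2, 0.4]]
        A[2:, 2:] = [[0.6, 0.1], [0.3, 0.5]]
        cov_t, cov_x, cov_l = stationary_var1(A)
        res = find_mip(cov_t, cov_x, cov_l,
                       {"p": [0], "q": [1], "r": [2], "s": [3]})
        assert set(res.mip[0]) in ({"p", "q"}, {"r", "s"})
        assert res.phi_star == pytest.approx(0.0, abs=1e-6)

    def test_normalization_is_min_part_entropy(self, rng):
        A = 0.4 * np.eye(2) + np.array([[0, 0.2], [0.1, 0]])
        cov_t, cov_x, cov_l = stationary_var1(A)
        res = find_mip(cov_t, cov_x, cov_l, {"a": [0], "b": [1]})
        h = [gaussian_entropy(cov_t[i:i + 1, i:i + 1]) for i in (0, 1)]
        assert res.normalization == pytest.approx(min(h), abs=1e-10)

    @pytest.mark.parametrize("n_parts", [3, 4])
    def test_matches_brute_force_oracle(self, n_parts, rng):
        betas = np.arange(0.0, 3.0 + 1e-12, 5e-4)
        n = n_parts  # one channel per part
        A = 0.45 * np.eye(n) + 0.12 * rng.standard_normal((n, n))
        cov_t, cov_x, cov_l = stationary_var1(A)
        parts = {chr(97 + i): [i] for i in range(n)}
        res = find_mip(cov_t, cov_x, cov_l, parts)
        i_full = mutual_information(cov_t, cov_x, cov_l)
        best = None
        for side_a, side_b in bipartitions(sorted(parts)):
            ch = [[parts[l][0] for l in side_a], [parts[l][0] for l in side_b]]
            phi = i_full - grid_istar(cov_t, cov_x, cov_l, ch, betas)
            norm = min(gaussian_entropy(cov_t[np.ix_(c, c)]) for c in ch)
            if best is None or phi / norm < best[0]:
                best = (phi / norm, (side_a, side_b), phi)
        assert res.mip == best[1]
        assert res.phi_star == pytest.approx(best[2], abs=1e-4)

    def test_lagged_covariances_from_data(self, rng):
        # VAR(1) sample: estimated MI at lag 1 approximates the analytic value
        A = np.array([[0.6, 0.2], [0.1, 0.5]])
        n = 60_000
        x = np.zeros((2, n))
        for t in range(1, n):
            x[:, t] = A @ x[:, t - 1] + rng.standard_normal(2)
        cov_t, cov_x, cov_l = lagged_covariances(x, 1)
        S, cross, _ = stationary_var1(A)
        i_est = mutual_information(cov_t, cov_x, cov_l)
        i_true = mutual_information(S, cross, S)
        assert i_est == pytest.approx(i_true, rel=0.1)


class TestTimecourseAndAssociation:
    def test_coupling_drop_recovered_in_time(self, rng):
        # two 2-channel parts; cross-part coupling vanishes during [-2, 2] s
        fs = 200.0
        t_range = (-6.0, 6.0)
        n = int((t_range[1] - t_range[0]) * fs)
        tax = np.linspace(*t_range, n)
        events = []
        for _ in range(4):
            x = np.zeros((4, n))
            for t in range(1, n):
                cross = 0.0 if -2.0 <= tax[t] <= 2.0 else 0.25
                A = np.array([[0.5, 0.2, cross, 0], [0.1, 0.5, 0, cross],
                              [cross, 0, 0.5, 0.2], [0, cross, 0.15, 0.5]])
                x[:, t] = A @ x[:, t - 1] + rng.standard_normal(4)
            events.append(x)
        times, phi_z, _ = phi_timecourse(events, fs, {"a": [0, 1], "b": [2, 3]},
                                         tau=1, window=1.0, stride=0.25,
                                         t_range=t_range)
        t_min = times[np.argmin(phi_z)]
        assert -2.5 <= t_min <= 2.5

    def test_constant_signals_rejected(self):
        arr = np.ones((2, 4000))
        with pytest.raises(ValueError, match="no usable events"):
            phi_timecourse([arr], 200.0, {"a": [0], "b": [1]}, tau=1,
                           t_range=(-6.0, 6.0))

    def test_association_probabilities(self):
        labels = ["a", "b", "c", "d"]
        mips = bipartitions(labels)           # uniform over the 7 bipartitions
        out = mip_association({"wake": mips})["wake"]
        assert out.loc["a", "a"] == 1.0
        assert out.loc["a", "b"] == pytest.approx(3 / 7)
        fixed = mip_association({"x": [mips[0]] * 5})["x"]
        assert set(np.unique(fixed.to_numpy())) <= {0.0, 1.0}

    def test_mip_type_code_is_a_bijection(self):
        labels = ["a", "b", "c", "d"]
        codes = {mip_type_code(m, labels) for m in bipartitions(labels)}
        assert codes == set(range(7))
        # order of sides is irrelevant
        m = (("b", "c"), ("a", "d"))
        assert mip_type_code(m, labels) == mip_type_code((m[1], m[0]), labels)
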