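"""Hidden-cause detection, clustering and latent series reconstruction."""

import math

import numpy as np
import pytest

from hcc_clinde.grn_data import DelayedEdge, DelayedGRN, InferenceParams
from hcc_clinde.hidden_cause import (
    HiddenCluster,
    LatentEstimationError,
    cluster_candidates,
    detect_candidates,
    estimate_hidden_series,
    estimate_sigma2,
    max_abs_shifted_corr,
    residual_variances,
)
from hcc_clinde.reinference import hcc_clinde
from hcc_clinde.synthetic_gen import gen_small_hidden_grn, simulate_expression

from conftest import make_segments


def hidden_motif_data(rng, m, var_h=1.0, c=1.0, d=1.0, var_e=1.0):
    """X, Y independent; H = X(t-1) + Y(t-1) + eh; Z = c*H(t-1) + ez; W = d*H(t-1) + ew.

    Returns observed columns [X, Y, Z, W] and the hidden series H.
    """
    n = m + 2
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    eh = math.sqrt(var_h) * rng.standard_normal(n)
    ez = math.sqrt(var_e) * rng.standard_normal(n)
    ew = math.sqrt(var_e) * rng.standard_normal(n)
    h = np.zeros(n)
    z = np.zeros(n)
    w = np.zeros(n)
    for t in range(1, n):
        h[t] = x[t - 1] + y[t - 1] + eh[t]
        z[t] = c * h[t - 1] + ez[t]
        w[t] = d * h[t - 1] + ew[t]
    cols = np.column_stack([x, y, z, w])[2:]
    return make_segments([cols], genes=["X", "Y", "Z", "W"]), h[2:]


class TestResidualVariances:
    def test_wrong_parents_inflate_variance(self, rng):
        # regressing Z on {X, Y} instead of the hidden H leaves the hidden
        # noise in the residual: Var(e) -> c^2 Var(eh) + Var(ez) = 2
        data, _ = hidden_motif_data(rng, m=2000)
        grn = DelayedGRN(n_observed=4, labels=["X", "Y", "Z", "W"])
        grn.add_edge(DelayedEdge(0, 2, 2, 1.0))  # X -> Z, composed delay
        grn.add_edge(DelayedEdge(1, 2, 2, 1.0))
        var = residual_variances(grn, data)
        assert var[2] == pytest.approx(2.0, abs=0.15)

    def test_true_parents_recover_noise_floor(self, rng):
        g = DelayedGRN(n_observed=2)
        g.add_edge(DelayedEdge(0, 1, 2, 0.9))
        data = simulate_expression(g, 2000, 0.5, 1.0, rng)
        grn = DelayedGRN(n_observed=2, labels=list(data.genes))
        grn.add_edge(DelayedEdge(0, 1, 2, 0.9))
        var = residual_variances(grn, data)
        assert var[1] == pytest.approx(0.5, rel=0.1)

    def test_parentless_gene_reports_raw_variance(self, rng):
        data = make_segments([rng.standard_normal((300, 2)) * 3.0])
        grn = DelayedGRN(n_observed=2, labels=list(data.genes))
        var = residual_variances(grn, data)
        np.testing.assert_allclose(var, data.stacked().var(axis=0))


class TestCandidates:
    @pytest.mark.parametrize(
        "values, expected",
        [([1, 1, 1, 5, 1], 1.0), ([2, 4, 6], 4.0), ([3.3, 3.3, 3.3], 3.3)],
    )
    def test_sigma2_is_median(self, values, expected):
        assert estimate_sigma2(np.array(values)) == expected

    @pytest.mark.parametrize(
        "var, flagged",
        [(2.0, True), (1.05, False), (1.1, False)],  # threshold is strict >
    )
    def test_threshold_rule(self, var, flagged):
        cs = detect_candidates(np.array([var]), sigma2=1.0, tolerance=0.1)
        assert bool(cs.flags[0]) is flagged

    def test_monotone_in_tolerance(self, rng):
        var = rng.uniform(0.5, 3.0, size=50)
        prev = None
        for rho in (0.0, 0.1, 0.3, 0.6):
            cur = set(detect_candidates(var, 1.0, rho).candidates)
            if prev is not None:
                assert cur <= prev
            prev = cur

    @pytest.mark.parametrize("p,c", [(0, 2), (0, 3)])
    def test_candidates_are_hidden_children_with_high_probability(self, p, c):
        # with known sigma^2 the flagged genes should be exactly the hidden
        # node's children in at least 80% of replicates
        hits = 0
        seeds = 20
        for seed in range(seeds):
            rng = np.random.default_rng(seed)
            grn = gen_small_hidden_grn(p, c, rng=rng)
            data = simulate_expression(grn, 200, 1.0, 1.0, rng)
            true_children = {e.dst for e in grn.edge_list() if e.src == grn.n_observed}
            params = InferenceParams(st=2.0, sigma2=1.0)
            _, details = hcc_clinde(data, params, return_details=True)
            if set(details.candidates) == true_children:
                hits += 1
        assert hits / seeds >= 0.8


class TestShiftedCorrelation:
    def test_pure_shift_recovered(self, rng):
        x = rng.standard_normal(200)
        # y(t) = x(t-3): y lags x by three steps
        data = make_segments([np.column_stack([x[3:], x[:-3]])])
        d, s = max_abs_shifted_corr(data, 0, 1, 4)
        assert d == pytest.approx(1.0)
        assert s == 3

    def test_scale_and_sign_invariance(self, rng):
        x = rng.standard_normal(100)
        data = make_segments([np.column_stack([x, -2 * x])])
        d, s = max_abs_shifted_corr(data, 0, 1, 4)
        assert d == pytest.approx(1.0)
        assert s == 0

    def test_independent_noise_low_similarity(self, rng):
        data = make_segments([rng.standard_normal((200, 2))])
        d, _ = max_abs_shifted_corr(data, 0, 1, 4)
        assert d < 0.3


class TestClustering:
    def test_model_derived_threshold_worked_example(self, rng):
        # two children of one hidden cause with unit coefficients and unit
        # error variance on top of a variance-3 cause: Var(Z) = Var(W) = 4,
        # threshold sqrt((1 - 1.1/4)^2) = 0.725 < theoretical corr 0.75
        rho0 = (1 + 0.1) * 1.0
        threshold = math.sqrt((1 - rho0 / 4.0) * (1 - rho0 / 4.0))
        assert threshold == pytest.approx(0.725)
        beta = 1.0 / 4.0
        assert math.sqrt((1 - beta) * (1 - beta)) == pytest.approx(0.75)
        m = 4000
        h = math.sqrt(3.0) * rng.standard_normal(m)
        z = h + rng.standard_normal(m)
        w = h + rng.standard_normal(m)
        data = make_segments([np.column_stack([z, w])])
        clusters = cluster_candidates([0, 1], data, 1.0, 0.1, 4)
        assert len(clusters) == 1
        assert clusters[0].members == [0, 1]

    def test_unrelated_causes_stay_apart(self, rng):
        m = 200
        h1 = rng.standard_normal(m) * 2
        h2 = rng.standard_normal(m) * 2
        cols = np.column_stack(
            [h1 + rng.standard_normal(m), h1 + rng.standard_normal(m),
             h2 + rng.standard_normal(m), h2 + rng.standard_normal(m)]
        )
        data = make_segments([cols])
        clusters = cluster_candidates([0, 1, 2, 3], data, 1.0, 0.1, 4)
        assert sorted(sorted(c.members) for c in clusters) == [[0, 1], [2, 3]]

    def test_single_candidate_singleton(self, rng):
        data = make_segments([rng.standard_normal((50, 2))])
        clusters = cluster_candidates([1], data, 1.0, 0.1, 4)
        assert len(clusters) == 1
        assert clusters[0].members == [1]
        assert clusters[0].shifts == [0]

    def test_noise_floor_variance_never_merges(self, rng):
        x = rng.standard_normal(100)
        data = make_segments([np.column_stack([x, x])])
        # both variances ~1 are below rho0 = 2.2: threshold is imaginary
        clusters = cluster_candidates([0, 1], data, 2.0, 0.1, 4)
        assert len(clusters) == 2


class TestLatentEstimation:
    def test_noiseless_rank_one_is_exact(self, rng):
        h = rng.standard_normal(60)
        a_true = np.array([1.5, -0.7, 0.4])
        cols = np.outer(h, a_true)
        data = make_segments([cols])
        cl = HiddenCluster(members=[0, 1, 2], shifts=[0, 0, 0])
        cl = estimate_hidden_series(cl, data, 4)
        # with all shifts 0 the output is the exact latent advanced by one
        # step, so a (x) h' reproduces the centred members shifted by one row
        centred = cols - cols.mean(axis=0)
        hp = cl.series[0]
        np.testing.assert_allclose(np.outer(hp[:-1], cl.coeffs), centred[1:], atol=1e-8)
        # sign convention: largest-|a| coefficient is positive
        assert cl.coeffs[np.argmax(np.abs(cl.coeffs))] > 0

    def test_scale_sign_indeterminacy_and_svd_optimality(self, rng):
        h = rng.standard_normal(40)
        cols = np.outer(h, [1.0, 2.0]) + 0.1 * rng.standard_normal((40, 2))
        data = make_segments([cols])
        cl = estimate_hidden_series(HiddenCluster([0, 1], [0, 0]), data, 4)
        centred = cols - cols.mean(axis=0)
        Y = centred.T
        resid = np.linalg.norm(Y - np.outer(cl.coeffs, np.linalg.lstsq(
            cl.coeffs[:, None], Y, rcond=None)[0]))
        # any random rank-1 alternative does no better in Frobenius norm
        for _ in range(20):
            a = rng.standard_normal(2)
            hh = np.linalg.lstsq(a[:, None], Y, rcond=None)[0]
            assert np.linalg.norm(Y - np.outer(a, hh)) >= resid - 1e-9

    def test_out_of_overlap_least_squares_formula(self, rng):
        # member 1 leads the latent by two steps, so with shifts [0, 2] the
        # last latent points rest on member 1 alone and must equal the
        # closed-form least squares a_k x'_k / a_k^2, evaluated independently
        m = 30
        h = rng.standard_normal(m + 2)
        cols = np.column_stack([2.0 * h[:m], 0.5 * h[2:]])
        data = make_segments([cols])
        cl = estimate_hidden_series(HiddenCluster([0, 1], [0, 2]), data, 4)
        centred = cols - cols.mean(axis=0)
        a = cl.coeffs
        # h'(m-1) = h_full(m+2), a suffix point seen only by member 1:
        # h_full(m+2) = a_1 x'_1(m) / a_1^2
        assert cl.series[0][m - 2] == pytest.approx(centred[m - 1, 1] / a[1])

    def test_latent_matches_true_hidden_series(self):
        # three children at sigma^2 = 0.5 carry a combined signal-to-noise
        # of S = sum a_k^2, so no estimator can correlate with the true
        # latent beyond ~sqrt(S/(S+1)); the SVD estimate should come close
        # and, for ordinary coefficient draws, exceed 0.9
        rng = np.random.default_rng(4)
        grn = gen_small_hidden_grn(0, 3, rng=rng)
        complete = simulate_expression(grn, 200, 0.5, 1.0, rng, complete=True)
        observed = complete.select(range(3), complete.genes[:3])
        params = InferenceParams(st=2.0, sigma2=0.5)
        _, details = hcc_clinde(observed, params, return_details=True)
        multi = [c for c in details.clusters if len(c.members) > 1 and c.series]
        assert multi, "expected one estimated cluster"
        est = multi[0].series[0][:-1]  # last point is padding
        true_h = complete.segments[0][:, 3]
        best = 0.0
        for s in range(-8, 9):
            if s >= 0:
                a, b = est[: len(est) - s], true_h[s: s + len(est) - s]
            else:
                a, b = est[-s:], true_h[: len(est) + s]
            best = max(best, abs(np.corrcoef(a, b)[0, 1]))
        snr = sum(e.effect**2 for e in grn.edge_list())  # Var(H) = sigma^2
        ceiling = np.sqrt(snr / (snr + 1.0))
        assert best > 0.9
        assert best > 0.9 * ceiling

    def test_singleton_cluster_rejected(self, rng):
        data = make_segments([rng.standard_normal((20, 1))])
        with pytest.raises(LatentEstimationError):
            estimate_hidden_series(HiddenCluster([0], [0]), data, 4)

    def test_too_short_overlap_rejected(self, rng):
        data = make_segments([rng.standard_normal((4, 2))])
        with pytest.raises(LatentEstimationError):
            estimate_hidden_series(HiddenCluster([0, 1], [0, 4]), data, 4)
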