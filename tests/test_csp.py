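import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import tacsim
from tacsim import build_montage, simulate_subject
from tacsim.csp import (CovariancePair, LotoComponents, average_pattern,
                        component_alpha_power, csp_fit, loto_components,
                        shrink, trial_covariance)
from tacsim.power import (TrialEpochs, aggregate_sources, timebin_windows,
                          window_alpha_power)


def _random_spd(d, rng):
    A = rng.standard_normal((d, d))
    return A @ A.T / d + 0.1 * np.eye(d)


class TestTrialCovariance:
    def test_white_noise_off_diagonal_small(self, rng):
        C = trial_covariance(rng.standard_normal((4, 100_000)))
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 0.02

    def test_single_active_channel(self):
        X = np.zeros((3, 100))
        X[1] = np.sin(np.arange(100))
        C = trial_covariance(X)
        assert C[1, 1] == pytest.approx(1.0)
        assert np.sum(np.abs(C)) == pytest.approx(1.0)

    def test_symmetric_and_unit_trace(self, rng):
        C = trial_covariance(rng.standard_normal((5, 300)))
        np.testing.assert_allclose(C, C.T, atol=1e-15)
        assert np.trace(C) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            trial_covariance(np.zeros((3, 100)))


class TestCovariancePair:
    def test_from_epochs_traces_and_count(self, rng):
        pre, post = _epoch_pair(rng, n_trials=8)
        pair = CovariancePair.from_epochs(pre, post)
        assert pair.n_trials_used == 8
        assert np.trace(pair.C_pre) == pytest.approx(1.0)
        assert np.trace(pair.C_post) == pytest.approx(1.0)
        np.testing.assert_allclose(pair.C_pre, pair.C_pre.T, atol=1e-14)

    def test_asymmetric_input_rejected(self):
        C = np.eye(3)
        bad = C.copy()
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            CovariancePair(C_pre=bad, C_post=C, n_trials_used=1)


class TestCspFit:
    def test_diagonal_analytic_solution(self):
        C_pre = np.diag([2.0, 1.0]) / 3
        C_post = np.diag([1.0, 2.0]) / 3
        f = csp_fit(C_pre, C_post, gamma=0.0)
        assert f.eigenvalues[0] == pytest.approx(2.0 / 3)
        w = f.csp_pre / np.linalg.norm(f.csp_pre)
        assert abs(w[0]) == pytest.approx(1.0)
        ratio = (w @ C_pre @ w) / (w @ C_post @ w)
        assert ratio == pytest.approx(2.0)

    def test_swap_reverses_order(self, rng):
        C1, C2 = _random_spd(5, rng), _random_spd(5, rng)
        a = csp_fit(C1, C2, gamma=0.0)
        b = csp_fit(C2, C1, gamma=0.0)
        cos = abs(a.csp_pre @ b.csp_post) / (
            np.linalg.norm(a.csp_pre) * np.linalg.norm(b.csp_post))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_rayleigh_optimality_vs_random_search(self, rng):
        """Top filter beats 1e5 random unit vectors on the pre/post ratio."""
        C_pre, C_post = _random_spd(8, rng), _random_spd(8, rng)
        f = csp_fit(C_pre, C_post, gamma=0.0)
        w = f.csp_pre
        best = (w @ C_pre @ w) / (w @ C_post @ w)
        V = rng.standard_normal((100_000, 8))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        ratios = np.einsum("ij,jk,ik->i", V, C_pre, V) / \
            np.einsum("ij,jk,ik->i", V, C_post, V)
        assert best >= ratios.max()

    def test_generalized_eigen_residual(self, rng):
        C_pre, C_post = _random_spd(8, rng), _random_spd(8, rng)
        f = csp_fit(C_pre, C_post, gamma=0.0)
        comp = C_pre + C_post
        for w, lam in zip(f.W, f.eigenvalues):
            assert np.linalg.norm(C_pre @ w - lam * comp @ w) < 1e-8

    def test_eigenvalues_in_unit_interval_descending(self, rng):
        f = csp_fit(_random_spd(6, rng), _random_spd(6, rng))
        assert np.all(np.diff(f.eigenvalues) <= 0)
        assert f.eigenvalues[0] <= 1 + 1e-12
        assert f.eigenvalues[-1] >= -1e-12

    def test_patterns_inverse_of_filters(self, rng):
        f = csp_fit(_random_spd(6, rng), _random_spd(6, rng))
        np.testing.assert_allclose(f.W @ f.patterns, np.eye(6), atol=1e-8)

    def test_shrinkage_preserves_trace(self, rng):
        C = _random_spd(5, rng)
        np.testing.assert_allclose(np.trace(shrink(C, 0.3)), np.trace(C))


def _epoch_pair(rng, n_trials=20, n_ch=6, n_samp=100):
    pre = TrialEpochs(rng.standard_normal((n_trials, n_ch, n_samp)), 500.0,
                      "pre", (-600, -100), "onset")
    post = TrialEpochs(rng.standard_normal((n_trials, n_ch, n_samp)), 500.0,
                       "post", (100, 600), "offset")
    return pre, post


def _naive_loto_oracle(pre, post, gamma=1e-6):
    """Refit-per-fold reference implementation, written independently."""
    n = pre.n_trials
    cp, cq = [], []
    for i in range(n):
        X, Y = pre.data[i], post.data[i]
        Cp = X @ X.T / X.shape[1]
        Cq = Y @ Y.T / Y.shape[1]
        s = (np.trace(Cp) + np.trace(Cq)) / 2.0
        cp.append(Cp / s)
        cq.append(Cq / s)
    filters = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        Cp = np.mean([cp[j] for j in others], axis=0)
        Cq = np.mean([cq[j] for j in others], axis=0)
        d = Cp.shape[0]
        Cp = (1 - gamma) * Cp + gamma * np.trace(Cp) / d * np.eye(d)
        Cq = (1 - gamma) * Cq + gamma * np.trace(Cq) / d * np.eye(d)
        evals, evecs = linalg.eigh(Cp, Cp + Cq)
        order = np.argsort(evals)[::-1]
        filters.append(evecs[:, order].T)
    return filters


class TestLoto:
    def test_exclusion_mutation(self, rng):
        """Changing trial i's data changes only trial i's components."""
        pre, post = _epoch_pair(rng)
        base = loto_components(pre, post)
        i = 7
        pre2 = TrialEpochs(pre.data.copy(), pre.srate, "pre", pre.window_def,
                           "onset")
        pre2.data[i] += 3.0 * rng.standard_normal(pre.data[i].shape)
        mutated = loto_components(pre2, post)
        for source in ("CSPpre", "CSPpost"):
            fa = base.filters[source]
            fb = mutated.filters[source]
            # fold i excludes trial i: identical covariances -> identical
            # filter, up to the global sign-alignment convention
            sign = 1.0 if fa[i] @ fb[i] > 0 else -1.0
            np.testing.assert_array_equal(fa[i], sign * fb[i])
            # every other fold includes the mutated trial
            for j in range(pre.n_trials):
                if j != i:
                    assert not (np.array_equal(fa[j], fb[j])
                                or np.array_equal(fa[j], -fb[j]))

    def test_matches_naive_oracle(self, rng):
        pre, post = _epoch_pair(rng)
        result = loto_components(pre, post)
        oracle = _naive_loto_oracle(pre, post)
        n = pre.n_trials
        for i in range(n):
            w_pre = oracle[i][0]
            w_post = oracle[i][-1]
            # production filters are sign-aligned across folds
            for mine, ref in ((result.filters["CSPpre"][i], w_pre),
                              (result.filters["CSPpost"][i], w_post)):
                sign = 1.0 if mine @ ref > 0 else -1.0
                np.testing.assert_array_equal(mine, sign * ref)

    def test_identical_trials_identical_filters(self, rng):
        one = rng.standard_normal((1, 5, 200))
        pre = TrialEpochs(np.repeat(one, 10, axis=0), 500.0, "pre",
                          (-600, -100), "onset")
        post = TrialEpochs(np.repeat(rng.standard_normal((1, 5, 200)), 10, 0),
                           500.0, "post", (100, 600), "offset")
        res = loto_components(pre, post)
        F = res.filters["CSPpre"]
        for i in range(1, 10):
            cos = abs(F[0] @ F[i]) / (np.linalg.norm(F[0]) * np.linalg.norm(F[i]))
            assert np.arccos(min(cos, 1.0)) < 1e-6

    def test_too_few_trials_rejected(self, rng):
        pre, post = _epoch_pair(rng, n_trials=2)
        with pytest.raises(ValueError, match="3 trials"):
            loto_components(pre, post)

    def test_scale_invariance_of_power_ratio(self, rng):
        """Scaling all epochs by c > 0 leaves post/pre power ratios unchanged."""
        pre, post = _epoch_pair(rng)
        r1 = loto_components(pre, post)
        c = 3.7
        pre2 = TrialEpochs(c * pre.data, pre.srate, "pre", pre.window_def, "onset")
        post2 = TrialEpochs(c * post.data, post.srate, "post", post.window_def,
                            "offset")
        r2 = loto_components(pre2, post2)
        iaf = 10.0
        p1_pre = window_alpha_power(r1.components["CSPpre"]["pre"], iaf, 500.0)
        p1_post = window_alpha_power(r1.components["CSPpre"]["post"], iaf, 500.0)
        p2_pre = window_alpha_power(r2.components["CSPpre"]["pre"], iaf, 500.0)
        p2_post = window_alpha_power(r2.components["CSPpre"]["post"], iaf, 500.0)
        np.testing.assert_allclose(p1_post / p1_pre, p2_post / p2_pre, rtol=1e-6)


class TestComponentPower:
    def test_delta_filter_equals_poz_rows(self, tiny_session):
        """A unit filter on POz reproduces the POz source rows."""
        layout = tiny_session.recording.layout
        w = timebin_windows(tiny_session.recording, tiny_session.events)
        pre, post = w["pre"], w["post_bin1"]
        delta = np.zeros(len(layout))
        delta[layout.index("POz")] = 1.0
        n = pre.n_trials
        loto = LotoComponents(
            components={"CSPpre": {
                "pre": np.stack([delta @ pre.data[i] for i in range(n)]),
                "post": np.stack([delta @ post.data[i] for i in range(n)]),
            }},
            filters={"CSPpre": np.tile(delta, (n, 1))},
            patterns={"CSPpre": delta},
        )
        iaf = tiny_session.ground_truth.iaf
        got = component_alpha_power(loto, tiny_session.events, iaf,
                                    tiny_session.recording.srate)
        post_named = TrialEpochs(post.data, post.srate, "post",
                                 post.window_def, "offset")
        ref = aggregate_sources({"pre": pre, "post": post_named}, layout, iaf,
                                tiny_session.events)
        ref_poz = ref[ref["source"] == "POz"].sort_values(["window", "trial"])
        got = got.sort_values(["window", "trial"])
        np.testing.assert_allclose(got["alpha_power"].to_numpy(),
                                   ref_poz["alpha_power"].to_numpy(), rtol=1e-12)

    def test_power_nonnegative(self, rng):
        pre, post = _epoch_pair(rng, n_ch=31)
        loto = loto_components(pre, post)
        events = pd.DataFrame({
            "trial_id": range(20), "block": 0, "stim_onset": 0,
            "stim_offset": 1, "state": ["EO"] * 20,
            "stimulation": ["in", "anti"] * 10})
        table = component_alpha_power(loto, events, 10.0, 500.0)
        assert (table["alpha_power"] >= 0).all()


@pytest.fixture(scope="module")
def recovered(suppression_config):
    """CSP patterns and modulations for a 12-subject suppression cohort."""
    from dataclasses import replace
    cfg = replace(suppression_config, suppression_depth=0.5)
    out = []
    for k in range(12):
        s = simulate_subject(cfg, k, np.random.default_rng(400 + k))
        w = timebin_windows(s.recording, s.events)
        loto = loto_components(w["pre"], w["post_bin1"], gamma=0.05)
        iaf = s.ground_truth.iaf
        a = window_alpha_power(loto.components["CSPpre"]["pre"], iaf,
                               cfg.srate).mean()
        b = window_alpha_power(loto.components["CSPpre"]["post"], iaf,
                               cfg.srate).mean()
        poz = s.recording.layout.index("POz")
        pa = window_alpha_power(w["pre"].data[:, poz], iaf, cfg.srate).mean()
        pb = window_alpha_power(w["post_bin1"].data[:, poz], iaf,
                                cfg.srate).mean()
        out.append({
            "pattern": loto.patterns["CSPpre"],
            "truth": s.ground_truth.source_pattern,
            "csp_mod": (b - a) / a * 100,
            "poz_mod": (pb - pa) / pa * 100,
        })
    return out


class TestGroundTruthRecovery:
    def test_pattern_cosine_similarity(self, recovered):
        cos = [abs(r["pattern"] @ r["truth"]) / np.linalg.norm(r["pattern"])
               for r in recovered]
        assert np.median(cos) >= 0.9

    def test_csp_modulation_stronger_than_poz(self, recovered):
        csp = np.mean([r["csp_mod"] for r in recovered])
        poz = np.mean([r["poz_mod"] for r in recovered])
        assert csp < poz < 0

    def test_average_pattern_peaks_in_poc(self, recovered):
        layout = build_montage()
        topo = average_pattern([r["pattern"] for r in recovered], layout)
        peak = topo.loc[topo["weight"].abs().idxmax(), "channel"]
        assert peak in tacsim.POC_CHANNELS


class TestAveragePattern:
    def test_single_subject_identity(self, rng):
        layout = build_montage()
        p = rng.standard_normal(31)
        topo = average_pattern([p], layout)
        np.testing.assert_allclose(topo["weight"].to_numpy(), p)

    def test_sign_flip_invariance(self, rng):
        layout = build_montage()
        base = rng.standard_normal(31)
        pats = [base + 0.1 * rng.standard_normal(31) for _ in range(5)]
        a = average_pattern(pats, layout)
        pats[2] = -pats[2]
        b = average_pattern(pats, layout)
        np.testing.assert_allclose(a["weight"].to_numpy(),
                                   b["weight"].to_numpy(), atol=1e-12)
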