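"""Dual-algorithm refitting, reconstruction, and the consensus rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lacsig import (
    ConsensusReport,
    FitResult,
    ForwardSelectionSignatureFitter,
    NNLSSignatureFitter,
    Profile96,
    SignatureSet,
    consensus_filter,
    cosine_similarity,
    fit_forward_selection,
    fit_nnls,
    reconstruct,
    stringency_sweep,
)


def simplex_grid_oracle(m, sigs, step=0.05):
    """Exhaustive search over the contribution simplex at a fixed grid step.

    Independent of the solvers: enumerates every non-negative weight vector
    with the given resolution summing to 1 and returns the SSE minimiser.
    """
    k = len(sigs)
    n_steps = int(round(1 / step))
    best, best_sse = None, np.inf
    for combo in itertools.product(range(n_steps + 1), repeat=k - 1):
        if sum(combo) > n_steps:
            continue
        c = np.array(list(combo) + [n_steps - sum(combo)], dtype=float) * step
        recon = c @ sigs.weights
        sse = float(np.sum((recon - m) ** 2))
        if sse < best_sse:
            best, best_sse = c, sse
    return best, best_sse


def mix_profile(sigs, weights, n=None, seed=0):
    """Profile equal to (or multinomially sampled from) a signature mixture."""
    m = np.zeros(96)
    for name, w in weights.items():
        m += w * sigs.row(name)
    if n is None:
        return Profile96(m * 1000, name="mix")
    rng = np.random.default_rng(seed)
    return Profile96(rng.multinomial(n, m / m.sum()).astype(float), name="mix")


@pytest.fixture(scope="module")
def three_sigs(norm_sigs):
    return norm_sigs.subset(["SBSsim2", "SBSsim4", "SBSsim6"])


class TestExactMixtures:
    @pytest.mark.parametrize("fit", [fit_nnls, fit_forward_selection])
    def test_single_signature_profile(self, norm_sigs, fit):
        profile = Profile96(norm_sigs.row("SBSsim4") * 500)
        result = fit(profile, norm_sigs)
        assert result.contributions["SBSsim4"] == pytest.approx(1.0, abs=0.01)
        assert result.residual == pytest.approx(0.0, abs=0.01)
        assert result.reconstruction_cosine > 0.999

    @pytest.mark.parametrize("fit", [fit_nnls, fit_forward_selection])
    def test_two_signature_exact_mixture(self, three_sigs, fit):
        profile = mix_profile(three_sigs, {"SBSsim4": 0.7, "SBSsim6": 0.3})
        result = fit(profile, three_sigs)
        assert result.contributions["SBSsim4"] == pytest.approx(0.7, abs=0.02)
        assert result.contributions["SBSsim6"] == pytest.approx(0.3, abs=0.02)
        assert result.residual == pytest.approx(0.0, abs=0.02)

    def test_degenerate_profile_rejected(self, norm_sigs):
        with pytest.raises(ValueError):
            fit_nnls(np.zeros(96), norm_sigs)


class TestNNLSAgainstGridOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_simplex_grid(self, three_sigs, seed):
        rng = np.random.default_rng(seed)
        true_w = rng.dirichlet([2, 2, 2])
        weights = dict(zip(three_sigs.names, true_w))
        profile = mix_profile(three_sigs, weights, n=500, seed=seed)
        result = fit_nnls(profile, three_sigs)
        grid_c, grid_sse = simplex_grid_oracle(profile.freqs, three_sigs, step=0.05)
        fitted = result.contributions.to_numpy()
        assert np.max(np.abs(fitted - grid_c)) <= 0.05 + 1e-9
        recon = fitted @ three_sigs.weights
        sse = float(np.sum((recon / recon.sum() - profile.freqs) ** 2))
        assert sse <= grid_sse + 1e-12

    def test_two_candidates(self, norm_sigs):
        pair = norm_sigs.subset(["SBSsim4", "SBSsim6"])
        profile = mix_profile(pair, {"SBSsim4": 0.35, "SBSsim6": 0.65}, n=800, seed=4)
        result = fit_nnls(profile, pair)
        grid_c, _ = simplex_grid_oracle(profile.freqs, pair, step=0.05)
        assert np.max(np.abs(result.contributions.to_numpy() - grid_c)) <= 0.05 + 1e-9


class TestForwardSelection:
    def test_three_signature_mixture_vs_fine_grid(self, three_sigs):
        truth = {"SBSsim2": 0.5, "SBSsim4": 0.3, "SBSsim6": 0.2}
        profile = mix_profile(three_sigs, truth)
        result = fit_forward_selection(profile, three_sigs)
        grid_c, _ = simplex_grid_oracle(profile.freqs, three_sigs, step=0.01)
        for i, name in enumerate(three_sigs.names):
            assert result.contributions[name] == pytest.approx(truth[name], abs=0.02)
            assert result.contributions[name] == pytest.approx(grid_c[i], abs=0.02)

    def test_weight_cutoff_feeds_residual(self, three_sigs):
        profile = mix_profile(three_sigs, {"SBSsim4": 0.97, "SBSsim6": 0.03})
        result = fit_forward_selection(profile, three_sigs, weight_cutoff=0.06)
        assert result.contributions["SBSsim6"] == 0.0
        assert result.residual == pytest.approx(
            1.0 - result.contributions.sum(), abs=1e-12
        )

    def test_estimator_api(self, three_sigs):
        X = np.vstack(
            [
                mix_profile(three_sigs, {"SBSsim4": 1.0}).freqs,
                mix_profile(three_sigs, {"SBSsim6": 1.0}).freqs,
            ]
        )
        est = ForwardSelectionSignatureFitter(signatures=three_sigs).fit(X)
        assert est.contributions_.shape == (2, 3)
        assert est.contributions_[0, list(three_sigs.names).index("SBSsim4")] > 0.9
        params = est.get_params()
        assert params["weight_cutoff"] == 0.06
        clone = ForwardSelectionSignatureFitter(**params)
        assert np.allclose(clone.fit(X).contributions_, est.contributions_)


class TestReconstruct:
    def test_weighted_sum(self, three_sigs):
        a, b = three_sigs.row("SBSsim4"), three_sigs.row("SBSsim6")
        recon = reconstruct({"SBSsim4": 0.4, "SBSsim6": 0.6}, three_sigs)
        assert np.allclose(recon, 0.4 * a + 0.6 * b)

    def test_unit_weight_returns_row(self, three_sigs):
        recon = reconstruct({"SBSsim2": 1.0}, three_sigs)
        assert np.allclose(recon, three_sigs.row("SBSsim2"))

    def test_all_zero_rejected(self, three_sigs):
        with pytest.raises(ValueError, match="all-zero"):
            reconstruct({"SBSsim2": 0.0}, three_sigs)

    def test_fit_reconstruction_beats_any_single_signature(self, norm_sigs):
        profile = mix_profile(norm_sigs, {"SBSsim4": 0.5, "SBSsim6": 0.5}, n=400, seed=9)
        result = fit_nnls(profile, norm_sigs)
        recon = reconstruct(result.contributions[result.contributions > 0], norm_sigs)
        best_single = max(
            cosine_similarity(norm_sigs.row(n), profile.freqs) for n in norm_sigs.names
        )
        assert cosine_similarity(recon, profile.freqs) >= best_single - 1e-9


def manual_fit(method, names, contributions, residual=None):
    s = pd.Series(0.0, index=list(names))
    for k, v in contributions.items():
        s[k] = v
    return FitResult(
        method=method,
        contributions=s,
        residual=residual if residual is not None else 1 - s.sum(),
        reconstructed=np.full(96, 1 / 96),
        reconstruction_cosine=0.9,
    )


def point_mass_set(n):
    w = np.zeros((n, 96))
    for i in range(n):
        w[i, i] = 1.0
    return SignatureSet(tuple(f"S{i+1}" for i in range(n)), w)


class TestConsensus:
    def test_three_criteria_example(self):
        sigs = point_mass_set(4)
        m = np.zeros(96)
        m[0], m[1] = 0.6, 0.4  # cosines: S1 0.83, S2 0.55, S3/S4 0
        fit_a = manual_fit("forward_selection", sigs.names, {"S1": 0.5, "S2": 0.25, "S3": 0.10})
        fit_b = manual_fit("nnls", sigs.names, {"S1": 0.45, "S2": 0.22, "S4": 0.30})
        report = consensus_filter(fit_a, fit_b, m, sigs)
        assert report.accepted == ("S1", "S2")
        assert report.rejections["S3"] == "ii"  # only ever seen below 20%
        assert report.rejections["S4"] == "i"  # reportable in one method only

    def test_zero_thresholds_give_intersection_of_detections(self):
        sigs = point_mass_set(3)
        m = np.zeros(96)
        m[:3] = [0.5, 0.3, 0.2]
        fit_a = manual_fit("forward_selection", sigs.names, {"S1": 0.6, "S2": 0.4})
        fit_b = manual_fit("nnls", sigs.names, {"S1": 0.5, "S3": 0.5})
        report = consensus_filter(fit_a, fit_b, m, sigs, min_contrib=0.0, min_cos=0.0)
        assert report.accepted == ("S1",)

    def test_accepted_subset_of_both_detections(self, norm_sigs, ref):
        from lacsig.simulate import recovery_config, simulate_catalog
        from lacsig import build_profile96

        catalog, _ = simulate_catalog(recovery_config(seed=2), norm_sigs, ref)
        profile = build_profile96(catalog, ref)
        fa = fit_forward_selection(profile, norm_sigs)
        fb = fit_nnls(profile, norm_sigs)
        report = consensus_filter(fa, fb, profile, norm_sigs)
        assert set(report.accepted) <= set(fa.detected) & set(fb.detected)

    def test_monotone_in_thresholds(self):
        sigs = point_mass_set(4)
        m = np.zeros(96)
        m[:4] = [0.4, 0.3, 0.2, 0.1]
        fit_a = manual_fit("forward_selection", sigs.names, {"S1": 0.4, "S2": 0.3, "S3": 0.2, "S4": 0.1})
        fit_b = manual_fit("nnls", sigs.names, {"S1": 0.35, "S2": 0.3, "S3": 0.25, "S4": 0.1})
        grid = {
            (mc, cos): set(
                consensus_filter(fit_a, fit_b, m, sigs, min_contrib=mc, min_cos=cos).accepted
            )
            for mc in [0.0, 0.1, 0.2, 0.3]
            for cos in [0.0, 0.3, 0.5, 0.7]
        }
        for (mc1, cos1), acc1 in grid.items():
            for (mc2, cos2), acc2 in grid.items():
                if mc2 >= mc1 and cos2 >= cos1:
                    assert acc2 <= acc1

    def test_mismatched_sets_rejected(self, three_sigs, norm_sigs):
        profile = mix_profile(three_sigs, {"SBSsim4": 1.0})
        fa = fit_forward_selection(profile, three_sigs)
        fb = fit_nnls(profile, norm_sigs)
        with pytest.raises(ValueError, match="same signature set"):
            consensus_filter(fa, fb, profile, three_sigs)


class TestStringencySweep:
    def test_survival_depends_on_cosine(self):
        # S1 has cosine ~0.99 with the profile, S2 ~0.57: S1 survives every
        # threshold, S2 only the 0.5 floor
        w = np.zeros((2, 96))
        w[0, 0] = 1.0
        w[1, 0], w[1, 1] = 0.35, 0.65
        sigs = SignatureSet(("S1", "S2"), w)
        m = np.zeros(96)
        m[0], m[1] = 0.9, 0.1
        fit_a = manual_fit("forward_selection", sigs.names, {"S1": 0.6, "S2": 0.4})
        fit_b = manual_fit("nnls", sigs.names, {"S1": 0.55, "S2": 0.45})
        table = stringency_sweep(fit_a, fit_b, m, sigs)
        assert table.loc["S1"].all()
        assert table.loc["S2", 0.5] and not table.loc["S2", [0.6, 0.7, 0.8]].any()

    def test_strong_signal_constant_across_thresholds(self, norm_sigs, ref):
        from lacsig.simulate import recovery_config, simulate_catalog
        from lacsig import build_profile96

        cfg = recovery_config(seed=1, n_mutations=400, mixture={"SBSsim4": 1.0})
        catalog, _ = simulate_catalog(cfg, norm_sigs, ref)
        profile = build_profile96(catalog, ref)
        fa = fit_forward_selection(profile, norm_sigs)
        fb = fit_nnls(profile, norm_sigs)
        table = stringency_sweep(fa, fb, profile, norm_sigs)
        assert table.loc["SBSsim4"].all()
        surviving = table.any(axis=0)
        assert (table[0.8] == table[0.5]).loc["SBSsim4"]
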