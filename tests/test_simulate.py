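"""Generator correctness: channel sampling, depth simulation, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lacsig import (
    ReferenceSequence,
    SignatureSet,
    SimulationConfig,
    build_profile96,
    call_mutations,
    consensus_filter,
    fit_forward_selection,
    fit_nnls,
    score_calls,
    simulate_catalog,
    simulate_pool_depths,
)
from lacsig.channels import CHANNEL_INDEX, channel_for
from lacsig.simulate import (
    DEFAULT_RECOVERY_MIXTURE,
    mixture_channel_distribution,
    pool_config,
    recovery_config,
    recovery_report,
)


def point_mass_sigs(channel):
    w = np.zeros((1, 96))
    w[0, CHANNEL_INDEX[channel]] = 1.0
    return SignatureSet(("PM",), w)


class TestSimulateCatalog:
    def test_point_mass_mixture_single_channel(self, ref):
        sigs = point_mass_sigs("A[C>A]A")
        cfg = SimulationConfig(mixture={"PM": 1.0}, n_mutations=50, seed=1)
        catalog, truth = simulate_catalog(cfg, sigs, ref)
        assert (truth.mutations["channel"] == "A[C>A]A").all()
        for row in catalog.records.itertuples(index=False):
            ctx = ref.context(row.position)
            assert channel_for(ctx, row.ref, row.alt) == "A[C>A]A"

    def test_channel_distribution_matches_truth(self, ref, norm_sigs):
        cfg = recovery_config(seed=13, n_mutations=10_000, mixture={"SBSsim4": 0.7, "SBSsim6": 0.3})
        catalog, _ = simulate_catalog(cfg, norm_sigs, ref)
        profile = build_profile96(catalog, ref)
        p = mixture_channel_distribution(cfg.mixture, norm_sigs)
        # chi-square goodness of fit over channels with adequate expectation
        expected = p * profile.n
        keep = expected >= 5
        chi2 = ((profile.counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 1e-3

    def test_seed_contract(self, ref, norm_sigs):
        cfg = recovery_config(seed=5)
        a, _ = simulate_catalog(cfg, norm_sigs, ref)
        b, _ = simulate_catalog(cfg, norm_sigs, ref)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_missing_context_errors(self):
        ref = ReferenceSequence("tiny", "TTTTTTTT")  # only TTT contexts
        with pytest.raises(ValueError, match="ACA"):
            simulate_catalog(
                SimulationConfig(mixture={"PM": 1.0}, n_mutations=5),
                point_mass_sigs("A[C>A]A"),
                ref,
            )

    def test_animals_round_robin(self, ref, norm_sigs):
        cfg = recovery_config(seed=2, n_mutations=60, n_animals=6)
        catalog, _ = simulate_catalog(cfg, norm_sigs, ref)
        assert (catalog.records["animal"].value_counts() == 10).all()


class TestSimulatePoolDepths:
    def test_noise_free_exact_recovery(self, ref, norm_sigs):
        cfg = pool_config(seed=11, noisy=False)
        catalog, truth = simulate_catalog(cfg, norm_sigs, ref)
        pools, truth = simulate_pool_depths(catalog, cfg, truth=truth, ref=ref)
        calls = [c for p in pools for c in call_mutations(p)]
        score = score_calls(calls, truth)
        assert score["sensitivity"] == 1.0
        assert score["precision"] == 1.0

    def test_noisy_fixture_precision_and_clonal_recovery(self, ref, norm_sigs):
        cfg = pool_config(seed=11, noisy=True)
        catalog, truth = simulate_catalog(cfg, norm_sigs, ref)
        pools, truth = simulate_pool_depths(catalog, cfg, truth=truth, ref=ref)
        calls = [c for p in pools for c in call_mutations(p)]
        score = score_calls(calls, truth)
        assert score["precision"] >= 0.99
        # every clonally expanded mutation (allele fraction 2/P, twice the
        # calling threshold) must be recovered; singletons sit exactly at the
        # threshold where symmetric read noise censors them
        called = {(c.pool_id, c.position, c.ref, c.alt) for c in calls}
        multi = truth.mutations[truth.mutations["carriers"] >= 2]
        assert all(
            (f"pool_{r.animal}", r.position, r.ref, r.alt) in called
            for r in multi.itertuples(index=False)
        )

    def test_background_only_cells_not_called(self, ref, norm_sigs):
        # with the caller told the simulation's error rate, background-only
        # positions yield no calls
        cfg = pool_config(seed=3, noisy=True)
        catalog, truth = simulate_catalog(cfg, norm_sigs, ref)
        pools, truth = simulate_pool_depths(catalog, cfg, truth=truth, ref=ref)
        planted = {
            (r.pool_id, r.position, r.ref, r.alt)
            for r in truth.planted_calls.itertuples(index=False)
        }
        for pool in pools:
            for call in call_mutations(pool):
                assert (pool.pool_id, call.position, call.ref, call.alt) in planted

    def test_doubling_coverage_does_not_hurt_sensitivity(self, ref, norm_sigs):
        sens = {}
        for coverage in (5000, 10000):
            vals = []
            for seed in range(5):
                cfg = pool_config(seed=seed, noisy=True, coverage=coverage)
                catalog, truth = simulate_catalog(cfg, norm_sigs, ref)
                pools, truth = simulate_pool_depths(catalog, cfg, truth=truth, ref=ref)
                calls = [c for p in pools for c in call_mutations(p)]
                vals.append(score_calls(calls, truth)["sensitivity"])
            sens[coverage] = np.mean(vals)
        assert sens[10000] >= sens[5000] - 0.05

    def test_pool_overflow_rejected(self, ref, norm_sigs):
        cfg = pool_config(seed=1, n_mutations=300, n_animals=2)  # 150 > 20 plaques
        catalog, truth = simulate_catalog(cfg, norm_sigs, ref)
        with pytest.raises(ValueError, match="exceed pool"):
            simulate_pool_depths(catalog, cfg, truth=truth, ref=ref)


class TestRecovery:
    def test_recovery_report_arithmetic(self, norm_sigs):
        from lacsig.simulate import SimulationTruth
        from lacsig.fitting import FitResult

        truth = SimulationTruth(
            mixture=pd.Series({"SBSsim4": 0.7, "SBSsim6": 0.3}),
            mutations=pd.DataFrame(),
            seed=0,
        )
        fit = FitResult(
            method="nnls",
            contributions=pd.Series({"SBSsim4": 0.6, "SBSsim6": 0.4}),
            residual=0.0,
            reconstructed=np.full(96, 1 / 96),
            reconstruction_cosine=1.0,
        )
        report = recovery_report(truth, [fit])
        assert report["l1"]["nnls"] == pytest.approx(0.2)

    def test_mean_l1_under_point_one_over_20_seeds(self, ref, norm_sigs):
        l1_nnls, l1_fs, exact = [], [], []
        for seed in range(20):
            cfg = recovery_config(seed=seed, n_mutations=500)
            catalog, truth = simulate_catalog(cfg, norm_sigs, ref)
            profile = build_profile96(catalog, ref)
            fs = fit_forward_selection(profile, norm_sigs)
            mp = fit_nnls(profile, norm_sigs)
            consensus = consensus_filter(fs, mp, profile, norm_sigs)
            report = recovery_report(truth, [fs, mp], consensus)
            l1_nnls.append(report["l1"]["nnls"])
            l1_fs.append(report["l1"]["forward_selection"])
            exact.append(report["consensus"]["exact"])
        assert np.mean(l1_nnls) < 0.10
        assert np.mean(exact) >= 0.9

    def test_l1_shrinks_with_sample_size(self, ref, norm_sigs):
        means = []
        for n in (100, 1000, 10000):
            l1 = []
            for seed in range(10):
                cfg = recovery_config(seed=seed, n_mutations=n)
                catalog, truth = simulate_catalog(cfg, norm_sigs, ref)
                profile = build_profile96(catalog, ref)
                report = recovery_report(truth, [fit_nnls(profile, norm_sigs)])
                l1.append(report["l1"]["nnls"])
            means.append(np.mean(l1))
        assert means[0] > means[1] > means[2]
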