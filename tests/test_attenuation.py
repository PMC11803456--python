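import numpy as np
import pytest

from oracles import dunn_oracle, kruskal_wallis_oracle

from hgamap import (DataError, ParadigmSpec, SyntheticConfig, TrialSampleMatrix,
                    baseline_drift_test, classify_attenuation,
                    consecutive_position_test, dunn_posthoc,
                    extract_trial_samples, generate_recording, kruskal_wallis,
                    preprocess, temporal_dynamics)

TIED_FIXTURE = [
    np.array([1.0, 2.0, 2.0, 3.0, 5.0]),
    np.array([2.0, 4.0, 4.0, 6.0, 6.0]),
    np.array([3.0, 5.0, 6.0, 8.0, 9.0]),
]


class TestKruskalWallis:
    def test_identical_groups_give_h0_p1(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        assert kruskal_wallis(g) == (0.0, 1.0)

    def test_matches_rank_oracle_without_ties(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                  np.array([5.0, 6.0])]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kruskal_wallis_oracle(groups), abs=1e-10)

    def test_matches_rank_oracle_with_ties(self):
        h, _ = kruskal_wallis(TIED_FIXTURE)
        assert h == pytest.approx(kruskal_wallis_oracle(TIED_FIXTURE),
                                  abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=7), rng.normal(size=5), rng.normal(size=6)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_too_few_groups_rejected(self):
        with pytest.raises(DataError):
            kruskal_wallis([np.array([1.0, 2.0])])


class TestDunn:
    def test_identical_groups_give_z0_p1(self):
        pairs = dunn_posthoc([np.array([1.0, 2.0, 3.0])] * 2, [(1, 2)])
        assert pairs[0].z == pytest.approx(0.0, abs=1e-12)
        assert pairs[0].p_adjusted == 1.0

    def test_antisymmetry(self):
        res = dunn_posthoc(TIED_FIXTURE, [(1, 3), (3, 1)])
        assert res[0].z == pytest.approx(-res[1].z, abs=1e-12)
        assert res[0].p_raw == pytest.approx(res[1].p_raw, abs=1e-12)

    def test_matches_formula_oracle_with_ties(self):
        family = [(1, 2), (1, 3), (2, 3)]
        pairs = dunn_posthoc(TIED_FIXTURE, family)
        for pr in pairs:
            z, p, p_adj = dunn_oracle(TIED_FIXTURE, (pr.i, pr.j), len(family))
            assert pr.z == pytest.approx(z, abs=1e-10)
            assert pr.p_raw == pytest.approx(p, abs=1e-10)
            assert pr.p_adjusted == pytest.approx(p_adj, abs=1e-10)

    def test_adjustment_is_bonferroni_over_family(self, rng):
        groups = [rng.normal(size=6) for _ in range(4)]
        pairs = dunn_posthoc(groups, [(1, 2), (2, 3), (3, 4)])
        for pr in pairs:
            assert pr.p_adjusted == pytest.approx(min(1.0, 3 * pr.p_raw))

    def test_empty_group_in_pair_rejected(self):
        with pytest.raises(DataError):
            dunn_posthoc([np.array([1.0]), np.array([])], [(1, 2)])


class TestConsecutivePositions:
    def test_family_is_the_nine_consecutive_pairs(self, rng):
        pools = [rng.normal(size=20) for _ in range(10)]
        res = consecutive_position_test(pools)
        assert [(p.i, p.j) for p in res.pairs] == [(i, i + 1)
                                                   for i in range(1, 10)]
        assert res.group_n == [20] * 10

    def test_missing_position_rejected(self, rng):
        pools = [rng.normal(size=5)] * 4 + [np.array([])]
        with pytest.raises(DataError):
            consecutive_position_test(pools)


def synthetic_trials(rng, n_el=1, effect=None):
    """Trial matrices with iid noise plus an optional (block, trial) effect."""
    hga = rng.normal(scale=0.45, size=(n_el, 10, 10))
    if effect is not None:
        hga += effect[None, :, :]
    return TrialSampleMatrix(hga=hga, window_z=np.zeros((n_el, 10, 10, 6)),
                             channel_names=[f"c{i}" for i in range(n_el)])


class TestClassification:
    def test_group_sizes_are_30_and_27(self, rng):
        res = classify_attenuation(synthetic_trials(rng))
        row = res.table.iloc[0]
        assert [row[f"nr{g}_n"] for g in (1, 2, 3)] == [30, 30, 30]
        assert [row[f"r{g}_n"] for g in (1, 2, 3)] == [27, 27, 27]

    def test_planted_short_term_drop_detected(self, rng):
        effect = np.zeros((10, 10))
        effect[:, 0:3] = 1.2
        effect[:, 6:9] = 0.4  # strong NR3-vs-NR1 contrast
        res = classify_attenuation(synthetic_trials(rng, effect=effect))
        assert res.table["nr_class"].iloc[0] == "attenuated"
        assert res.table["r_class"].iloc[0] == "not"

    def test_rank_invariance_under_monotone_transform(self, rng):
        trials = synthetic_trials(rng, n_el=3)
        res1 = classify_attenuation(trials)
        trials2 = TrialSampleMatrix(hga=np.exp(trials.hga),
                                    window_z=trials.window_z,
                                    channel_names=trials.channel_names)
        res2 = classify_attenuation(trials2)
        assert list(res1.table["nr_class"]) == list(res2.table["nr_class"])
        assert list(res1.table["r_class"]) == list(res2.table["r_class"])
        assert np.allclose(res1.table["nr_p13_adjusted"],
                           res2.table["nr_p13_adjusted"], atol=1e-10)

    def test_degenerate_samples_flagged_not_attenuated(self):
        trials = TrialSampleMatrix(hga=np.zeros((1, 10, 10)),
                                   window_z=np.zeros((1, 10, 10, 6)),
                                   channel_names=["c0"])
        res = classify_attenuation(trials)
        assert res.table["nr_class"].iloc[0] == "not"
        assert bool(res.table["nr_degenerate"].iloc[0])

    def test_invariant_to_electrode_ordering(self, rng):
        trials = synthetic_trials(rng, n_el=4)
        res = classify_attenuation(trials)
        perm = [2, 0, 3, 1]
        permuted = TrialSampleMatrix(hga=trials.hga[perm],
                                     window_z=trials.window_z[perm],
                                     channel_names=[trials.channel_names[i]
                                                    for i in perm])
        res_p = classify_attenuation(permuted)
        lookup = dict(zip(res.table["channel"], res.table["nr_class"]))
        for _, row in res_p.table.iterrows():
            assert row["nr_class"] == lookup[row["channel"]]

    def test_short_term_power_exceeds_long_term_when_only_trials_degraded(
            self, rng):
        # matched simulations: identical contrast planted on trials only
        effect = np.zeros((10, 10))
        effect[:, 0:3] = 0.5
        effect[:, 6:9] = 0.1
        nr_hits = r_hits = 0
        for _ in range(30):
            res = classify_attenuation(synthetic_trials(rng, effect=effect))
            nr_hits += res.table["nr_class"].iloc[0] == "attenuated"
            r_hits += res.table["r_class"].iloc[0] == "attenuated"
        assert nr_hits > r_hits
        assert nr_hits >= 20


class TestDynamics:
    def test_constant_z_gives_flat_curve_with_zero_sem(self, default_session):
        z = default_session.z
        z0 = z.z.copy()
        try:
            z.z = np.full_like(z.z, 0.7)
            curves = temporal_dynamics(z, default_session.timeline, [0, 1])
            c = curves["trial_1"]
            assert np.allclose(c.mean, 0.7)
            assert np.allclose(c.sem2, 0.0)
            assert np.all(c.n == 2 * 10)  # channels x blocks
        finally:
            z.z = z0

    def test_sem2_definition(self, default_session):
        curves = temporal_dynamics(default_session.z,
                                   default_session.timeline, range(8))
        c = curves["nr1"]
        assert np.all(c.n == 8 * 30)  # 3 trials x 10 blocks x 8 channels
        assert np.all(c.sem2 >= 0)

    def test_first_trial_curve_peaks_at_700_ms(self, default_session):
        curves = temporal_dynamics(default_session.z,
                                   default_session.timeline, range(8))
        c = curves["trial_1"]
        peak = c.offsets_s[np.argmax(c.mean)]
        assert abs(peak - 0.7) <= 0.1 + 1e-9

    def test_nr3_below_nr1_in_window_when_attenuation_planted(
            self, default_session):
        curves = temporal_dynamics(default_session.z,
                                   default_session.timeline, range(8))
        offs = curves["nr1"].offsets_s
        window = (offs >= 0.4 - 1e-9) & (offs <= 0.9 + 1e-9)
        # evaluation-window average clearly attenuated ...
        assert (curves["nr3"].mean[window].mean()
                < curves["nr1"].mean[window].mean())
        # ... and pointwise around the response peak
        peak_region = (offs >= 0.6 - 1e-9) & (offs <= 0.8 + 1e-9)
        assert np.all(curves["nr3"].mean[peak_region]
                      < curves["nr1"].mean[peak_region])

    def test_single_sample_pool_rejected(self, default_session):
        with pytest.raises(DataError):
            temporal_dynamics(default_session.z, default_session.timeline, [])


class TestBaselineDrift:
    def test_u_identity_and_identical_pools(self, default_session):
        res = baseline_drift_test(default_session.z,
                                  default_session.timeline, range(8))
        # U + U' = n1 * n2
        assert res.n_early == res.n_late == 8 * 3 * 120
        assert 0 <= res.U <= res.n_early * res.n_late
        assert 0 <= res.p <= 1

    def test_planted_late_baseline_rise_detected(self):
        spec = ParadigmSpec()
        hits = 0
        for seed in range(3):
            cfg = SyntheticConfig(n_channels=4, responsive_channels=(0, 1),
                                  seed=seed,
                                  block_gain_profile=(1.0, 1.0, 1.0, 1.0, 1.0,
                                                      1.0, 1.3, 1.3, 1.3, 1.3))
            rec, tl, _ = generate_recording(cfg, spec)
            z = preprocess(rec, tl)
            res = baseline_drift_test(z, tl, [0, 1])
            assert res.median_blocks_7_9 > res.median_blocks_1_3
            hits += res.p < 0.05
        assert hits == 3
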