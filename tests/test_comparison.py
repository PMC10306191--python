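"""Model-human single-trial analytics: RR, predictivity, bootstraps,
noise ceilings, temporal correspondence and explanatory power."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rsvpsim import (
    ConfigError,
    NoiseCeiling,
    ObserverReports,
    PredictivityProfile,
    bootstrap_profile,
    explanatory_power,
    noise_ceilings,
    report_rate,
    spearman,
    temporal_correspondence,
    trial_predictivity,
)


def make_reports(reports, durations=None):
    reports = np.asarray(reports)
    if durations is None:
        durations = np.zeros(reports.shape[1], int)
    return ObserverReports(reports=reports, durations=durations)


def ppc_frame(ppc_by_steps, trial_ids=None):
    rows = []
    for s, vals in ppc_by_steps.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "trial_id": i if trial_ids is None else trial_ids[i],
                    "steps_per_image": s,
                    "ppc": v,
                    "target_present": 1,
                }
            )
    return pd.DataFrame(rows)


class TestReportRate:
    def test_unanimous_yes(self):
        rr = report_rate(make_reports(np.ones((4, 3), int)))
        np.testing.assert_array_equal(rr.values, [1, 1, 1])

    def test_three_of_four(self):
        rr = report_rate(make_reports([[1], [1], [1], [0]]))
        assert rr.iloc[0] == 0.75

    def test_subject_order_invariance(self, rng):
        R = rng.integers(0, 2, (6, 10))
        base = report_rate(make_reports(R))
        perm = report_rate(make_reports(R[rng.permutation(6)]))
        np.testing.assert_array_equal(base.values, perm.values)

    def test_duration_restriction(self):
        rep = make_reports([[1, 0], [1, 0]], durations=[13, 40])
        assert list(report_rate(rep, 13).values) == [1.0]


class TestPredictivity:
    def test_monotone_relationship_is_one(self):
        ppc = np.array([0.1, 0.3, 0.2, 0.9, 0.5])
        assert trial_predictivity(ppc, ppc**3) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        ppc = np.array([0.1, 0.3, 0.2, 0.9, 0.5])
        assert trial_predictivity(ppc, -ppc) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        from scipy.stats import rankdata

        ppc = rng.normal(0, 1, 6)
        rr = rng.uniform(0, 1, 6)
        oracle = np.corrcoef(rankdata(ppc), rankdata(rr))[0, 1]
        assert trial_predictivity(ppc, rr) == pytest.approx(oracle, abs=1e-12)
        assert trial_predictivity(ppc, rr) == pytest.approx(
            spearmanr(ppc, rr).statistic, abs=1e-12
        )

    def test_constant_input_gives_nan_sentinel(self):
        assert np.isnan(spearman(np.ones(5), np.arange(5)))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ConfigError):
            trial_predictivity([0.1, 0.2], [0.3, 0.4])

    def test_invariant_under_monotone_ppc_transform(self, rng):
        ppc = rng.normal(0, 1, 30)
        rr = rng.uniform(0, 1, 30)
        base = trial_predictivity(ppc, rr)
        for f in (np.tanh, np.exp, lambda v: v**3):
            assert trial_predictivity(f(ppc), rr) == pytest.approx(base,
                                                                   abs=1e-12)


class TestBootstrapProfile:
    def test_identical_subjects_zero_width_ci(self, rng):
        row = rng.integers(0, 2, 12)
        rep = make_reports(np.tile(row, (5, 1)))
        ppc = ppc_frame({1: rng.normal(0, 1, 12), 2: rng.normal(0, 1, 12)})
        prof = bootstrap_profile(ppc, rep, n_boot=50, seed=0)
        np.testing.assert_allclose(prof.ci_low, prof.rho, atol=1e-12)
        np.testing.assert_allclose(prof.ci_high, prof.rho, atol=1e-12)

    def test_single_resample_bounds_equal_it(self, rng):
        rep = make_reports(rng.integers(0, 2, (4, 10)))
        ppc = ppc_frame({1: rng.normal(0, 1, 10)})
        prof = bootstrap_profile(ppc, rep, n_boot=1, seed=3)
        np.testing.assert_allclose(prof.ci_low, prof.boot[0])
        np.testing.assert_allclose(prof.ci_high, prof.boot[0])

    def test_matches_independent_resample_oracle(self, rng):
        """Replay the same subject draws and recompute rho via scipy."""
        R = rng.integers(0, 2, (3, 9))
        R[0, 0] = 1 - R[1, 0]  # ensure non-constant rows are likely
        rep = make_reports(R)
        ppc_vals = rng.normal(0, 1, 9)
        ppc = ppc_frame({1: ppc_vals})
        n_boot = 4
        prof = bootstrap_profile(ppc, rep, n_boot=n_boot, seed=11)
        oracle_rng = np.random.default_rng(11)
        for b in range(n_boot):
            subj = oracle_rng.integers(0, 3, 3)
            rr = R[subj].mean(axis=0)
            expected = (
                np.nan if np.ptp(rr) == 0
                else spearmanr(ppc_vals, rr).statistic
            )
            got = prof.boot[b, 0, 0]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_bit_reproducible_given_seed(self, rng):
        rep = make_reports(rng.integers(0, 2, (6, 20)),
                           durations=np.resize([13, 40], 20))
        ppc = ppc_frame({1: rng.normal(0, 1, 20), 4: rng.normal(0, 1, 20)})
        p1 = bootstrap_profile(ppc, rep, n_boot=25, seed=9)
        p2 = bootstrap_profile(ppc, rep, n_boot=25, seed=9)
        np.testing.assert_array_equal(p1.boot, p2.boot)


class TestNoiseCeilings:
    def test_identical_subjects_ceiling_one(self, rng):
        row = rng.integers(0, 2, 20)
        row[0], row[1] = 0, 1  # non-constant
        nc = noise_ceilings(make_reports(np.tile(row, (6, 1))))
        assert nc.upper == pytest.approx(1.0)
        assert nc.lower == pytest.approx(1.0)

    def test_independent_null_lower_near_zero_upper_biased(self):
        """Leave-one-out removes the self-inclusion bias: for independent
        subjects the lower ceiling is ~0 while the upper sits near
        1/sqrt(S) because each subject contributes to the group mean."""
        rng = np.random.default_rng(2024)
        S = 12
        nc = noise_ceilings(make_reports(rng.integers(0, 2, (S, 400))))
        assert abs(nc.lower) < 3 / np.sqrt(400)
        assert nc.upper == pytest.approx(1 / np.sqrt(S), abs=0.1)

    def test_lower_below_upper_on_average(self):
        rng = np.random.default_rng(99)
        diffs = []
        for _ in range(12):
            latent = rng.normal(0, 1, 60)
            prob = 1 / (1 + np.exp(-(latent + rng.normal(0, 1.0, (8, 60)))))
            R = (rng.random((8, 60)) < prob).astype(int)
            nc = noise_ceilings(make_reports(R))
            diffs.append(nc.upper - nc.lower)
        assert np.mean(diffs) > 0

    def test_requires_two_subjects(self, rng):
        with pytest.raises(ConfigError):
            noise_ceilings(make_reports(rng.integers(0, 2, (1, 10))))


def planted_profile(boot=True):
    """Predictivity profile with peaks planted at steps 2, 6, 8 for
    durations 13, 40, 80."""
    steps = np.array([1, 2, 4, 6, 8])
    durations = np.array([13, 40, 80])
    peaks = {13: 2, 40: 6, 80: 8}
    rho = np.zeros((5, 3))
    for j, d in enumerate(durations):
        rho[:, j] = 0.3 - 0.02 * np.abs(steps - peaks[d])
    B = 20
    boot_arr = np.repeat(rho[None], B, axis=0) if boot else None
    return PredictivityProfile(steps, durations, rho, rho.copy(), rho.copy(),
                               boot_arr)


class TestTemporalCorrespondence:
    def test_recovers_planted_peaks(self):
        tc = temporal_correspondence(planted_profile())
        assert dict(zip(tc["duration"], tc["best_step"])) == {13: 2, 40: 6,
                                                              80: 8}
        assert (tc["best_step_ci_low"] == tc["best_step"]).all()
        assert (tc["best_step_ci_high"] == tc["best_step"]).all()

    def test_monotone_rho_picks_largest_step(self):
        steps = np.array([1, 2, 4])
        rho = np.array([[0.1], [0.2], [0.3]])
        prof = PredictivityProfile(steps, np.array([13]), rho, rho, rho)
        tc = temporal_correspondence(prof)
        assert tc["best_step"].item() == 4

    def test_ties_resolve_to_smallest_step(self):
        steps = np.array([1, 2, 4])
        rho = np.array([[0.3], [0.3], [0.1]])
        prof = PredictivityProfile(steps, np.array([13]), rho, rho, rho)
        assert temporal_correspondence(prof)["best_step"].item() == 1

    def test_all_nan_column_excluded(self):
        steps = np.array([1, 2])
        rho = np.array([[np.nan, 0.2], [np.nan, 0.4]])
        prof = PredictivityProfile(steps, np.array([13, 40]), rho, rho, rho)
        tc = temporal_correspondence(prof)
        assert list(tc["duration"]) == [40]


class TestExplanatoryPower:
    def _profile(self, rhos):
        steps = np.array([1, 2])
        durations = np.array(sorted(rhos))
        rho = np.array([[rhos[d] for d in durations],
                        [0.5 * rhos[d] for d in durations]])
        return PredictivityProfile(steps, durations, rho, rho, rho)

    def test_matching_ceiling_gives_one(self):
        prof = self._profile({13: 0.4, 40: 0.4})
        ceilings = {d: NoiseCeiling(0.4, 0.5) for d in (13, 40)}
        assert explanatory_power(prof, ceilings) == pytest.approx(1.0)

    def test_half_ceiling_gives_half(self):
        prof = self._profile({13: 0.3, 40: 0.3})
        ceilings = {d: NoiseCeiling(0.6, 0.7) for d in (13, 40)}
        assert explanatory_power(prof, ceilings) == pytest.approx(0.5)

    def test_two_duration_arithmetic(self):
        prof = self._profile({13: 0.3, 40: 0.6})
        ceilings = {d: NoiseCeiling(0.6, 0.7) for d in (13, 40)}
        assert explanatory_power(prof, ceilings) == pytest.approx(0.75)

    def test_nonpositive_ceiling_excluded(self):
        prof = self._profile({13: 0.3, 40: 0.6})
        ceilings = {13: NoiseCeiling(-0.1, 0.2), 40: NoiseCeiling(0.6, 0.7)}
        assert explanatory_power(prof, ceilings) == pytest.approx(1.0)

    def test_values_above_one_are_legal(self):
        prof = self._profile({13: 0.8})
        assert explanatory_power(prof, {13: NoiseCeiling(0.4, 0.5)}) == \
            pytest.approx(2.0)


class TestReportsIO:
    def test_frame_round_trip(self, rng):
        rep = make_reports(rng.integers(0, 2, (4, 6)),
                           durations=np.resize([13, 40, 80], 6))
        back = ObserverReports.from_frame(rep.to_frame())
        np.testing.assert_array_equal(back.reports, rep.reports)
        np.testing.assert_array_equal(back.durations, rep.durations)
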