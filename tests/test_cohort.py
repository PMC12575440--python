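"""Synthetic cohort generator: determinism, calibration, kinetics and effect plumbing."""

import dataclasses

import numpy as np
import pytest

import cyclephys as cp
from cyclephys import cohort as syn
from cyclephys.lactate import po_at_lactate


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a = syn.generate_cohort(4, 7)
        b = syn.generate_cohort(4, 7)
        assert a == b

    def test_adding_riders_preserves_existing_ones(self):
        small = syn.generate_cohort(3, 5)
        large = syn.generate_cohort(8, 5)
        assert small == large[:3]

    def test_cohort_size_and_uniqueness(self):
        cohort = syn.generate_cohort(22, 1)
        ids = [p.id for p, _ in cohort]
        assert len(set(ids)) == 22
        mean_vo2 = np.mean([ph.vo2max_rel for _, ph in cohort])
        assert abs(mean_vo2 - 69.5) < 2 * 6.0 / np.sqrt(22) + 1.0

    def test_large_cohort_mean_matches_configured_value(self):
        cohort = syn.generate_cohort(1000, 3)
        assert np.mean([ph.vo2max_rel for _, ph in cohort]) == pytest.approx(69.5, abs=0.5)
        assert np.mean([p.body_mass for p, _ in cohort]) == pytest.approx(70.8, abs=0.8)

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            syn.generate_cohort(0, 1)

    def test_physiological_ordering(self):
        """Threshold power < 15-min power < ramp-maximum power for every rider."""
        for _, ph in syn.generate_cohort(50, 13):
            assert ph.po_4mmol_true < ph.po_15min_true < ph.po_vo2max_true


class TestStepTest:
    def test_deterministic_under_fixed_seed(self, rider):
        part, phys = rider
        a = syn.simulate_step_test(phys, part, rng=np.random.default_rng(7))
        b = syn.simulate_step_test(phys, part, rng=np.random.default_rng(7))
        assert a.steps == b.steps

    def test_noise_free_root_recovery(self, small_cohort):
        for part, phys in small_cohort:
            prof = syn.simulate_step_test(phys, part, rng=np.random.default_rng(0))
            root = syn.true_po_at_lactate(phys, 4.0)
            assert root == pytest.approx(phys.po_4mmol_true)  # by construction
            assert abs(po_at_lactate(prof, 4.0) - root) < 25.0

    def test_flat_curve_never_terminates(self, rider):
        part, phys = rider
        flat = dataclasses.replace(phys, la_basal=0.8, la_amp=1e-9, la_rate=1e-4)
        prof = syn.simulate_step_test(flat, part, rng=np.random.default_rng(0))
        assert not prof.terminated

    def test_high_start_power_for_strong_riders(self, rider):
        part, phys = rider
        strong = dataclasses.replace(
            phys, po_4mmol_true=360.0, po_40min_true=370.0, po_vo2max_true=520.0,
            po_15min_true=380.0,
        )
        prof = syn.simulate_step_test(strong, part, rng=np.random.default_rng(0))
        assert prof.steps[0].power == 175.0


class TestKinetics:
    def test_square_wave_matches_analytic_exponential(self):
        tau, dt = 30.0, 10.0
        demand = np.full(60, 4.0)
        v0 = 1.0
        out = syn.first_order_response(demand, dt, tau, v0=v0)
        t = (np.arange(60) + 1) * dt
        analytic = 4.0 + (v0 - 4.0) * np.exp(-t / tau)
        np.testing.assert_allclose(out, analytic, rtol=1e-12)

    def test_convergence_within_five_time_constants(self):
        tau, dt = 40.0, 10.0
        n = int(5 * tau / dt) + 1
        out = syn.first_order_response(np.full(n, 3.5), dt, tau, v0=0.3)
        assert abs(out[-1] - 3.5) / 3.5 < 0.01


class TestSessions:
    def test_unknown_prescription_rejected(self):
        with pytest.raises(ValueError, match="unknown prescription"):
            syn.prescription("4x16")

    def test_hit_exceeds_mit_in_vo2_fraction_and_time_above_90(self, rider):
        part, phys = rider
        cfg = syn.default_effect_config(0)
        mit, _, _ = syn.simulate_session(phys, part, "7x10", np.random.default_rng(1), cfg)
        hit, _, _ = syn.simulate_session(phys, part, "5x8.75", np.random.default_rng(2), cfg)
        vm = phys.vo2max_abs * 1000.0
        pct_mit = np.nanmean(mit.vo2[mit.work_mask()]) / vm
        pct_hit = np.nanmean(hit.vo2[hit.work_mask()]) / vm
        assert pct_hit > pct_mit
        assert cp.time_at_or_above(hit, vm, 0.9) > cp.time_at_or_above(mit, vm, 0.9)

    def test_rpe_targets(self, rider):
        part, phys = rider
        cfg = syn.default_effect_config(0)
        _, rpe, _ = syn.simulate_session(phys, part, "7x10", np.random.default_rng(3), cfg)
        assert 14.0 <= np.mean(rpe) <= 15.0

    def test_block_work_durations(self):
        assert syn.block_work_minutes("MIT") == pytest.approx(424.0)
        assert syn.block_work_minutes("HIT") == pytest.approx(218.75)


class TestBlockEffects:
    def test_null_effect_is_identity(self, rider):
        _, phys = rider
        cfg = syn.EffectConfig(blocks={"MIT": {k: (0.0, 0.0) for k in
                                               ("po_4mmol", "po_vo2max", "po_15min",
                                                "po_10sec", "vo2max", "ge_pp", "body_mass")}})
        post = syn.apply_block_effects(phys, cfg, "MIT", np.random.default_rng(0))
        assert post == phys

    def test_missing_block_rejected(self, rider):
        _, phys = rider
        cfg = syn.EffectConfig(blocks={"MIT": {"po_4mmol": (4.5, 4.5)}})
        with pytest.raises(ValueError, match="not configured"):
            syn.apply_block_effects(phys, cfg, "HIT", np.random.default_rng(0))

    def test_total_loss_effect_rejected(self):
        with pytest.raises(ValueError, match="exceed -100"):
            syn.EffectConfig(blocks={"MIT": {"po_4mmol": (-100.0, 1.0)}})

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            syn.EffectConfig(blocks={"MIT": {}}, vo2_pct=-1.0)

    def test_mean_effect_recovery_at_n200(self, rider):
        """+4.5 (4.5)% threshold-power effect: latent change recovers the mean within 1 pp."""
        _, phys = rider
        cfg = syn.EffectConfig(blocks={"B": {"po_4mmol": (4.5, 4.5)}})
        changes = []
        for i in range(200):
            post = syn.apply_block_effects(phys, cfg, "B", syn.rng_for(0, 1, i))
            changes.append(100 * (post.po_4mmol_true / phys.po_4mmol_true - 1))
        assert np.mean(changes) == pytest.approx(4.5, abs=1.0)

    def test_study_determinism(self):
        a = syn.simulate_study(3, 21)
        b = syn.simulate_study(3, 21)
        assert a == b


class TestBatteryRecovery:
    def test_noise_free_battery_recovers_latent_state(self, rider):
        part, phys = rider
        raw = syn.simulate_battery(phys, part, np.random.default_rng(0), noise=None)
        br = cp.assemble_battery(
            participant_id=part.id, block="MIT", timepoint="pre",
            body_mass=phys.body_mass, profile=raw.profile, tired_steps=raw.tired_steps,
            sprint_power=raw.sprint_power, sprint_period=1.0,
            vo2max_series=raw.vo2max_series, time_trial=raw.time_trial,
        )
        m = phys.body_mass
        assert br.po_15min == pytest.approx(phys.po_15min_true / m, rel=1e-3)
        assert br.po_10sec == pytest.approx(phys.po_10sec_true / m, rel=1e-3)
        assert br.po_vo2max == pytest.approx(phys.po_vo2max_true / m, rel=0.02)
        assert br.vo2max_rel == pytest.approx(phys.vo2max_rel, rel=0.02)
        assert abs(br.po_4mmol * m - phys.po_4mmol_true) < 25.0
        # gross efficiency recovered to < 0.05 %-points in the fresh state
        assert br.ge_fresh_3rd == pytest.approx(100 * phys.ge_true, abs=0.05)
        assert br.ge_fresh_2nd == pytest.approx(100 * phys.ge_true, abs=0.05)
        # semi-fatigued efficiency is lower by construction
        assert br.ge_tired_3rd < br.ge_fresh_3rd
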