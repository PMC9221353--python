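"""Generative screen model: closed forms, determinism, drift, recovery."""

import math

import numpy as np
import pytest

import nkscreen as nk
from nkscreen import Condition, HitStatus, Role, WellRole


def zero_noise_config(**kw):
    defaults = dict(
        seed=1, n_compounds=160, noise_cv=0.0, plate_gain_cv=0.0,
        drift_rate_per_min=0.0, spontaneous_drift_per_min=0.0,
    )
    defaults.update(kw)
    return nk.SimulationConfig(**defaults)


def screen_fold_changes(sim):
    cc, ta = [], []
    for read in sim.reads:
        plate = sim.layout.plate(read.plate_id, read.condition)
        records = nk.fold_change_plate(read, plate)
        (cc if read.condition is Condition.COCULTURE else ta).extend(records)
    return cc, ta


class TestKillFraction:
    def test_zero_ratio_kills_nothing(self):
        config = zero_noise_config()
        assert nk.kill_fraction(0.0, config=config) == 0.0

    def test_saturates_at_fmax(self):
        config = zero_noise_config()
        assert nk.kill_fraction(1e9, config=config) == pytest.approx(0.9)

    def test_half_saturation_at_k(self):
        config = zero_noise_config()
        assert nk.kill_fraction(3.0, config=config) == pytest.approx(0.45)

    def test_monotone_in_ratio_and_effect(self):
        config = zero_noise_config()
        f = [nk.kill_fraction(r, config=config) for r in (0.5, 1, 3, 9, 81)]
        assert f == sorted(f)
        assert nk.kill_fraction(1.0, effect=2.0, config=config) > nk.kill_fraction(
            1.0, effect=1.0, config=config
        )

    def test_screen_ratio_minimal_saturating_ratio_near_max(self):
        # calibration: E:T=1 on the rising limb, E:T=81 near the plateau
        config = zero_noise_config()
        assert nk.kill_fraction(1.0, config=config) < 0.3
        assert nk.kill_fraction(81.0, config=config) > 0.85


class TestWellModel:
    def test_target_alone_dmso_is_spontaneous(self):
        config = zero_noise_config()
        rlu = nk.expected_rlu(
            WellRole(Role.NEGATIVE_CONTROL), Condition.TARGET_ALONE, config=config
        )
        assert rlu == config.base_spontaneous

    def test_digitonin_well_is_maximal(self):
        config = zero_noise_config()
        rlu = nk.expected_rlu(
            WellRole(Role.POSITIVE_CONTROL), Condition.TARGET_ALONE, config=config
        )
        assert rlu == config.base_maximal

    def test_fully_toxic_compound_reaches_maximal(self):
        config = zero_noise_config()
        rlu = nk.expected_rlu(
            WellRole(Role.COMPOUND, "x"),
            Condition.TARGET_ALONE,
            toxic_fraction=1.0,
            config=config,
        )
        assert rlu == pytest.approx(config.base_maximal)

    def test_closed_form_fold_change(self):
        config = zero_noise_config()
        # f(e) = fmax*e/(k+e) at E:T=1; fc = (s + f(e)*w) / (s + f(1)*w)
        s, w = config.base_spontaneous, config.base_maximal - config.base_spontaneous
        for effect in (1.0, 1.5630420280186785, 2.5, 4.0):
            f_e = 0.9 * effect / (3.0 + effect)
            f_1 = 0.9 / 4.0
            expected = (s + f_e * w) / (s + f_1 * w)
            assert nk.expected_fold_change(
                effect, config=config
            ) == pytest.approx(expected)

    def test_effect_for_fold_change_inverts_the_model(self):
        config = zero_noise_config()
        for fc in (1.1, 1.3, 1.8, 2.0):
            effect = nk.effect_for_fold_change(fc, config=config)
            assert nk.expected_fold_change(effect, config=config) == pytest.approx(fc)


class TestSimulateScreen:
    def test_zero_noise_wells_equal_expected_values(self):
        config = zero_noise_config()
        sim = nk.simulate_screen(config)
        for read in sim.reads[:4]:
            plate = sim.layout.plate(read.plate_id, read.condition)
            for well, rlu in read.values.items():
                wr = plate.roles[well]
                expected = nk.expected_rlu(wr, read.condition, config=config)
                assert rlu == pytest.approx(expected, rel=1e-12)

    def test_zero_noise_inactive_screen_has_unit_fold_changes(self):
        sim = nk.simulate_screen(zero_noise_config())
        cc, ta = screen_fold_changes(sim)
        assert all(r.fc == pytest.approx(1.0) for r in cc + ta)

    def test_same_seed_reproduces_byte_identical_reads(self):
        config = nk.SimulationConfig(seed=42, n_compounds=160)
        a = nk.simulate_screen(config)
        b = nk.simulate_screen(config)
        assert a.reads == b.reads

    def test_different_seeds_differ(self):
        a = nk.simulate_screen(nk.SimulationConfig(seed=1, n_compounds=80))
        b = nk.simulate_screen(nk.SimulationConfig(seed=2, n_compounds=80))
        assert a.reads != b.reads

    def test_truth_covers_all_compounds_and_plates(self):
        config = nk.planted_screen_config(3, n_compounds=160)
        sim = nk.simulate_screen(config)
        assert len(sim.truth.compounds) == 160
        assert sim.truth.compounds["is_enhancer"].sum() == 14
        assert sim.truth.compounds["is_toxic"].sum() == 1
        # 2 plates x 2 conditions x 2 replicates
        assert len(sim.truth.plates) == 8

    def test_unknown_planted_compound_rejected(self):
        with pytest.raises(ValueError, match="not in the manifest"):
            nk.simulate_screen(
                nk.SimulationConfig(
                    seed=1, n_compounds=10, enhancer_effects={"C9999": 2.0}
                )
            )

    def test_noise_cv_controls_well_dispersion(self):
        config = nk.SimulationConfig(
            seed=9, n_compounds=1200, noise_cv=0.1, plate_gain_cv=0.0
        )
        sim = nk.simulate_screen(config)
        read = sim.reads[0]
        values = np.array(list(read.values.values()))
        plate = sim.layout.plate(read.plate_id, read.condition)
        dmso = [v for w, v in read.values.items() if w.column == 1]
        cv = np.std(dmso, ddof=1) / np.mean(dmso)
        assert 0.03 < cv < 0.25  # 8 wells, loose band around 0.1


class TestDrift:
    def test_potency_flat_before_onset_then_declines(self):
        config = nk.SimulationConfig(seed=1, n_compounds=1200, seed_interval_min=30.0)
        sim = nk.simulate_screen(config)
        plates = sim.truth.plates.drop_duplicates("plate_id").sort_values(
            "wait_min"
        )
        potency = plates["potency"].to_numpy()
        wait = plates["wait_min"].to_numpy()
        assert np.all(potency[wait <= 120.0] == 1.0)
        late = potency[wait > 120.0]
        assert np.all(np.diff(late) <= 0) and late[0] < 1.0
        assert np.all(late >= 0.0)  # floored, never negative
        # default rate: 240 min of wait halves potency
        assert potency[wait == 240.0] == pytest.approx(0.5)

    def test_late_plates_lose_coculture_z_prime(self):
        zs = {"early": [], "late": []}
        for seed in range(5):
            config = nk.SimulationConfig(
                seed=seed, n_compounds=1200, seed_interval_min=30.0
            )
            sim = nk.simulate_screen(config)
            report = nk.screen_qc_report(sim.reads, sim.layout)
            for r in report.conditions[Condition.COCULTURE].results:
                (zs["early"] if r.plate_id <= "P04" else zs["late"]).append(
                    r.z_prime
                )
        assert np.mean(zs["late"]) < np.mean(zs["early"])

    def test_spontaneous_release_creeps_up_past_onset(self):
        config = zero_noise_config(
            n_compounds=1200,
            seed_interval_min=30.0,
            spontaneous_drift_per_min=5e-4,
        )
        sim = nk.simulate_screen(config)
        first, last = None, None
        for read in sim.reads:
            if read.condition is Condition.TARGET_ALONE and read.replicate_id == 1:
                dmso = [v for w, v in read.values.items() if w.column == 1]
                if read.plate_id == "P01":
                    first = np.mean(dmso)
                if read.plate_id == "P15":
                    last = np.mean(dmso)
        assert last > first == config.base_spontaneous


class TestRecovery:
    def test_zero_noise_recovery_is_exact(self):
        config = nk.planted_screen_config(
            17, noise_cv=0.0, plate_gain_cv=0.0
        )
        sim = nk.simulate_screen(config)
        table = nk.call_hits(*screen_fold_changes(sim))
        called = {c.compound_id for c in table.calls if c.status is HitStatus.HIT}
        assert called == set(config.enhancer_effects)
        toxic_status = {
            c.status for c in table.calls if c.compound_id in config.toxic_compounds
        }
        assert toxic_status == {HitStatus.EXCLUDED_TOXIC}

    def test_sensitivity_increases_with_effect_size(self):
        # Monte-Carlo over fixed seeds: recovery of a planted enhancer is
        # monotone in its killing multiplier near the decision boundary.
        hits_by_effect = []
        for effect in (1.6, 2.0, 3.0):
            recovered = 0
            for seed in range(30):
                config = nk.SimulationConfig(
                    seed=seed,
                    n_compounds=80,
                    enhancer_effects={"C0001": effect},
                )
                sim = nk.simulate_screen(config)
                table = nk.call_hits(*screen_fold_changes(sim))
                call = next(
                    c for c in table.calls if c.compound_id == "C0001"
                )
                recovered += call.status is HitStatus.HIT
            hits_by_effect.append(recovered)
        assert hits_by_effect == sorted(hits_by_effect)
        assert hits_by_effect[-1] >= 28


class TestSimulateDoseResponse:
    def test_monotone_effect_gives_monotone_lysis_at_zero_noise(self):
        config = zero_noise_config()
        df = nk.simulate_dose_response(
            config, "drug", {0.0: 1.0, 1.0: 1.2, 5.0: 1.8, 10.0: 2.6, 20.0: 3.5}
        )
        table = nk.dose_response_lysis(df)
        for ratio in table.e_t_ratios:
            means = [float(np.mean(table.cell(d, ratio))) for d in table.doses]
            assert means == sorted(means)

    def test_vehicle_must_have_unit_effect(self):
        config = zero_noise_config()
        with pytest.raises(ValueError):
            nk.simulate_dose_response(config, "drug", {0.0: 1.5, 5.0: 2.0})
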