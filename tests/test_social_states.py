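import numpy as np
import pytest
from scipy import stats as sps

from socialspike.social_states import (
    SocialEvent,
    StateConfig,
    classify_all,
    detect_alone,
    detect_contacts,
    detect_walking_onset,
    movement_flags,
    sample_random_windows,
)

CFG = StateConfig()
FPS = 10.0


def flags_from_speed(speed):
    return movement_flags(np.asarray(speed, dtype=float), FPS, CFG)


class TestMovementFlags:
    def test_zero_speed_still_everywhere(self):
        f = flags_from_speed(np.zeros(100))
        assert not f["moving"].any()
        assert f["still_end"].iloc[20:].all()

    def test_steady_walk_moving_everywhere(self):
        f = flags_from_speed(np.full(100, 2.0))
        assert f["moving"].all()
        assert not f["still_end"].iloc[25:].any()

    def test_sub_millimeter_drift_counts_as_still(self):
        # 0.4 mm over 2 s: below the 1 mm stillness criterion
        f = flags_from_speed(np.full(100, 0.02))
        assert f["still_end"].iloc[30:].all()
        assert not f["moving"].any()

    def test_one_millimeter_in_two_seconds_not_still(self):
        f = flags_from_speed(np.full(100, 0.06))  # 1.2 mm per 2 s
        assert not f["still_end"].iloc[30:].any()


class TestDetectAlone:
    def test_lone_bee_sixty_seconds_tiles_fifteen(self):
        events = detect_alone(np.full(600, np.nan), FPS, CFG)
        assert len(events) == 15
        assert events[0].t_sync_s == 2.0

    def test_partner_at_five_cm_blocks_all(self):
        assert detect_alone(np.full(600, 5.0), FPS, CFG) == []

    def test_strictly_greater_boundary(self):
        # 10.5 cm is clear; exactly 10.0 cm is not (strict > rule)
        assert len(detect_alone(np.full(600, 10.5), FPS, CFG)) == 15
        assert detect_alone(np.full(600, 10.0), FPS, CFG) == []

    def test_shrinking_radius_never_loses_events(self, main_behavior):
        d = main_behavior["distance_cm"].to_numpy(dtype=float)
        wide = detect_alone(d, FPS, StateConfig(alone_radius_cm=10.0))
        narrow = detect_alone(d, FPS, StateConfig(alone_radius_cm=8.0))
        assert len(narrow) >= len(wide)


class TestDetectWalkingOnset:
    def _speed_trace(self, still_s, walk_s, walk_speed=2.0, pad_s=3.0):
        return np.concatenate(
            [
                np.zeros(int(pad_s * FPS)),
                np.zeros(int(still_s * FPS)),
                np.full(int(walk_s * FPS), walk_speed),
                np.zeros(int(pad_s * FPS)),
            ]
        )

    def test_crafted_stop_then_walk_yields_one_event(self):
        speed = self._speed_trace(2.5, 3.0)
        events = detect_walking_onset(flags_from_speed(speed), len(speed), FPS, CFG)
        assert len(events) == 1
        assert events[0].t_sync_s == pytest.approx(5.5)  # the transition frame

    def test_continuous_walking_no_event(self):
        speed = np.full(200, 2.0)
        assert detect_walking_onset(flags_from_speed(speed), 200, FPS, CFG) == []

    def test_too_short_still_span_no_event(self):
        speed = np.concatenate([np.full(50, 2.0), np.zeros(19), np.full(60, 2.0)])
        assert detect_walking_onset(flags_from_speed(speed), len(speed), FPS, CFG) == []

    def test_too_short_walk_no_event(self):
        speed = self._speed_trace(2.5, 1.5)
        assert detect_walking_onset(flags_from_speed(speed), len(speed), FPS, CFG) == []


class TestDetectContacts:
    def _approach(self, n=100, contact_f=60, focal_speed=None):
        """Distance trace: far, then linear approach crossing 1 cm at contact_f."""
        d = np.full(n, 30.0)
        d[contact_f - 20 : contact_f + 1] = np.linspace(10.8, 0.85, 21)
        d[contact_f + 1 :] = 0.85
        speed = np.zeros(n) if focal_speed is None else focal_speed
        flags = flags_from_speed(speed)
        n_within = (d < 1.0).astype(int)
        partner = np.array(["beeA"] * n, dtype=object)
        return detect_contacts(d, partner, n_within, flags, FPS, CFG)

    def test_approach_to_still_focal_is_passive(self):
        passive, active, uncls = self._approach()
        assert len(passive) == 1 and len(active) == 0 and uncls == 0
        assert passive[0].t_sync_s == pytest.approx(6.0)
        assert passive[0].partner_id == "beeA"

    def test_focal_walks_just_before_contact_is_active(self):
        speed = np.zeros(100)
        speed[54:70] = 1.5  # onset 0.6 s before the contact at frame 60
        passive, active, _ = self._approach(focal_speed=speed)
        assert len(active) == 1 and len(passive) == 0

    def test_two_bees_at_contact_rejected(self):
        n = 100
        d = np.full(n, 30.0)
        d[40:61] = np.linspace(10.8, 0.85, 21)
        d[61:] = 0.85
        n_within = (d < 1.0).astype(int) * 2  # two bees inside 1 cm
        flags = flags_from_speed(np.zeros(n))
        passive, active, _ = detect_contacts(
            d, np.array(["beeA"] * n, dtype=object), n_within, flags, FPS, CFG
        )
        assert passive == [] and active == []

    def test_not_alone_at_window_start_rejected(self):
        n = 100
        d = np.full(n, 8.0)  # inside the alone radius already
        d[40:61] = np.linspace(9.5, 0.85, 21)
        d[61:] = 0.85
        n_within = (d < 1.0).astype(int)
        flags = flags_from_speed(np.zeros(n))
        passive, active, _ = detect_contacts(
            d, np.array(["beeA"] * n, dtype=object), n_within, flags, FPS, CFG
        )
        assert passive == [] and active == []


class TestRandomWindows:
    def test_zero_requested_zero_returned(self):
        assert sample_random_windows(1000, 0, FPS, CFG, 1) == []

    def test_seed_reproducibility(self):
        a = sample_random_windows(5000, 20, FPS, CFG, 42)
        b = sample_random_windows(5000, 20, FPS, CFG, 42)
        assert [e.t_start_s for e in a] == [e.t_start_s for e in b]

    def test_starts_uniform_ks(self):
        events = sample_random_windows(100_000, 10_000, FPS, CFG, 7)
        starts = np.array([e.t_start_s for e in events])
        span = (100_000 - 40) / FPS
        stat, p = sps.kstest(starts / span, "uniform")
        assert p > 0.01


class TestClassifyAll:
    def test_planted_events_recovered_exactly(self, fidelity_sim, fidelity_behavior):
        """Precision and recall are 1.0 for every detector on the noise-free
        planted fixture (the focal bee moves only when scripted)."""
        _, _, truth = fidelity_sim
        catalog = classify_all(fidelity_behavior, FPS, CFG, seed=11)
        for state in ("alone", "walking_onset", "passive_contact", "active_contact"):
            detected = sorted(e.t_sync_s for e in catalog.by_state(state))
            planted = sorted(e.t_sync_s for e in truth.by_state(state))
            assert detected == planted, state
        assert catalog.n_unclassified_contacts == 0

    def test_random_count_matches_passive(self, fidelity_behavior):
        catalog = classify_all(fidelity_behavior, FPS, CFG, seed=11)
        assert len(catalog.by_state("random")) == len(catalog.by_state("passive_contact"))

    def test_contacts_never_both_passive_and_active(self, main_behavior):
        catalog = classify_all(main_behavior, FPS, CFG, seed=3)
        p = {e.t_sync_s for e in catalog.by_state("passive_contact")}
        a = {e.t_sync_s for e in catalog.by_state("active_contact")}
        assert not (p & a)

    def test_catalog_stable_under_rerun(self, main_behavior):
        a = classify_all(main_behavior, FPS, CFG, seed=5).to_frame()
        b = classify_all(main_behavior, FPS, CFG, seed=5).to_frame()
        assert a.equals(b)


def test_state_config_validation():
    with pytest.raises(ValueError):
        StateConfig(sync_mark_s=5.0)
    with pytest.raises(ValueError):
        StateConfig(contact_radius_cm=12.0)
    with pytest.raises(ValueError):
        SocialEvent("unknown_state", 0.0, 2.0)
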