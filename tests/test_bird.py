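"""Decision rules: site choice, stress-driven re-caching, safety risk."""

import numpy as np
import pytest

from jaysim.bird import (RELOCATION_FLOOR, BirdParams, OnlookerContext,
                         PRIVATE, cache_attractiveness, cache_relocation,
                         choose_cache_site, choose_recovery_site,
                         decide_recache, immediate_recache_odds,
                         maybe_immediate_recache, onlooker_aversion,
                         recovery_attractiveness, safety_risk)
from jaysim.memory import CACHE, RECOVERY, MemoryStore

WATCHED = OnlookerContext(watched=True, rank="peer")
DOMINANT = OnlookerContext(watched=True, rank="dominant", near_tray_id=0)
SUBORDINATE = OnlookerContext(watched=True, rank="subordinate", near_tray_id=0)


def tray_of(site):
    """Two 8-site trays: sites 0-7 near (tray 0), 8-15 far (tray 1)."""
    return 0 if site < 8 else 1


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"d": 0.0}, {"d": 1.0}, {"n": -0.1}, {"st": 1.2},
        {"oa_d": -0.1, "oa_s": -0.5},   # dominant aversion weaker
        {"oa_s": 0.2}, {"cr_w": 1.5},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BirdParams(**kwargs)

    def test_context_rank_consistency(self):
        with pytest.raises(ValueError):
            OnlookerContext(watched=True, rank="none")
        with pytest.raises(ValueError):
            OnlookerContext(watched=False, rank="dominant")


class TestOnlookerAversion:
    def test_near_tray_penalties(self, params):
        assert onlooker_aversion(3, DOMINANT, params, tray_of) == -1.25
        assert onlooker_aversion(3, SUBORDINATE, params, tray_of) == -0.5

    def test_far_tray_and_private_are_neutral(self, params):
        assert onlooker_aversion(12, DOMINANT, params, tray_of) == 0.0
        assert onlooker_aversion(3, PRIVATE, params, tray_of) == 0.0
        assert onlooker_aversion(3, WATCHED, params, tray_of) == 0.0


class TestImmediateRecache:
    def test_odds_by_condition(self, params):
        assert immediate_recache_odds(DOMINANT, params) == params.cr_d
        assert immediate_recache_odds(SUBORDINATE, params) == params.cr_s
        assert immediate_recache_odds(WATCHED, params) == params.cr_w
        assert immediate_recache_odds(PRIVATE, params) == 0.0

    def test_private_never_recaches(self, params, rng):
        assert not any(maybe_immediate_recache(PRIVATE, params, rng)
                       for _ in range(500))

    def test_long_run_frequency(self, params, rng):
        hits = sum(maybe_immediate_recache(WATCHED, params, rng)
                   for _ in range(20_000))
        assert hits / 20_000 == pytest.approx(params.cr_w, abs=0.02)


class TestCacheChoice:
    def test_fresh_store_all_zero_without_noise(self, rng):
        p = BirdParams(n=0.0)
        store = MemoryStore(16)
        scores = cache_attractiveness(np.arange(16), store, PRIVATE, p,
                                      rng, tray_of)
        assert np.all(scores == 0.0)

    def test_previous_cache_inhibits(self, rng):
        p = BirdParams(n=0.0)
        store = MemoryStore(16)
        store.encode_event(CACHE, 5)
        scores = cache_attractiveness(np.arange(16), store, PRIVATE, p,
                                      rng, tray_of)
        assert scores[5] < 0.0 and np.all(scores[np.arange(16) != 5] == 0.0)

    def test_dominant_onlooker_pushes_to_far_tray(self, params, rng):
        p = params.with_overrides(n=0.0)
        store = MemoryStore(16)
        site = choose_cache_site(np.arange(16), store, DOMINANT, p, rng, tray_of)
        assert tray_of(site) == 1

    def test_single_offered_site(self, params, rng):
        store = MemoryStore(16)
        assert choose_cache_site(np.array([7]), store, PRIVATE, params,
                                 rng, tray_of) == 7

    def test_empty_offer_rejected(self, params, rng):
        with pytest.raises(ValueError):
            choose_cache_site(np.array([], dtype=int), MemoryStore(16),
                              PRIVATE, params, rng, tray_of)

    def test_inhibition_spreads_caches(self, rng):
        # with noise off, repeated caching never stacks on one site
        p = BirdParams(n=0.0)
        store = MemoryStore(16)
        chosen = []
        for _ in range(8):
            site = choose_cache_site(np.arange(16), store, PRIVATE, p,
                                     rng, tray_of)
            store.encode_event(CACHE, site)
            chosen.append(site)
        assert len(set(chosen)) == 8

    def test_argmax_matches_brute_force(self, params, rng):
        p = params.with_overrides(n=0.0)
        store = MemoryStore(16)
        for s in (1, 1, 4, 9):
            store.encode_event(CACHE, s)
        scores = cache_attractiveness(np.arange(16), store, SUBORDINATE, p,
                                      rng, tray_of)
        site = choose_cache_site(np.arange(16), store, SUBORDINATE, p,
                                 rng, tray_of)
        assert scores[site] == scores.max()


class TestRecovery:
    def test_never_cached_site_sits_at_floor(self, params):
        store = MemoryStore(16)
        assert cache_relocation(3, store, None, params) == RELOCATION_FLOOR

    def test_unit_lag_cache_has_zero_activation(self, params):
        store = MemoryStore(16)
        store.encode_event(CACHE, 3)
        assert cache_relocation(3, store, None, params) == pytest.approx(0.0)

    def test_frequency_beats_single_use(self, params):
        store = MemoryStore(16)
        store.encode_event(CACHE, 3)
        store.encode_event(CACHE, 5)
        store.encode_event(CACHE, 5)
        now = store.clock + 3
        assert cache_relocation(5, store, now, params) > \
            cache_relocation(3, store, now, params)

    def test_cached_site_wins_over_empty_memory(self, rng):
        p = BirdParams(n=0.0)
        store = MemoryStore(16)
        store.encode_event(CACHE, 11)
        assert choose_recovery_site(np.arange(16), store, p, rng) == 11

    def test_recovered_site_suppressed(self, rng):
        p = BirdParams(n=0.0)
        store = MemoryStore(16)
        store.encode_event(CACHE, 4)
        store.encode_event(CACHE, 9)
        store.encode_event(RECOVERY, 4, success=True)
        scores = recovery_attractiveness(np.arange(16), store, p, rng)
        assert scores[9] > scores[4]


class TestSafetyRisk:
    def test_no_evidence_is_safe(self, params):
        store = MemoryStore(16)
        assert safety_risk(np.arange(8), store, set(range(8)), params) == 0.0

    def test_only_successes_is_safe(self, params):
        store = MemoryStore(16)
        store.encode_event(RECOVERY, 1, success=True)
        store.encode_event(RECOVERY, 2, success=True)
        assert safety_risk(np.arange(8), store, set(range(8)), params) == 0.0

    def test_balanced_evidence_is_half(self, params):
        store = MemoryStore(16)
        store.encode_event(RECOVERY, 1, success=True)
        store.encode_event(RECOVERY, 2, success=False)
        assert safety_risk(np.arange(8), store, set(range(8)),
                           params) == pytest.approx(0.5)

    def test_qualifying_filter_excludes_far_failures(self, params):
        store = MemoryStore(16)
        store.encode_event(RECOVERY, 1, success=True)
        store.encode_event(RECOVERY, 7, success=False)   # not qualifying
        assert safety_risk(np.arange(8), store, {1, 2}, params) == 0.0

    def test_self_emptied_site_is_not_a_missing_cache(self, params):
        store = MemoryStore(16)
        store.encode_event(RECOVERY, 1, success=True)
        store.encode_event(RECOVERY, 1, success=False)   # re-probe of own site
        assert safety_risk(np.arange(8), store, set(range(8)), params) == 0.0

    def test_bounded_for_random_stores(self, params, rng):
        for _ in range(50):
            store = MemoryStore(16)
            for _ in range(int(rng.integers(0, 40))):
                store.encode_event(RECOVERY, int(rng.integers(16)),
                                   success=bool(rng.integers(2)))
            s = safety_risk(np.arange(8), store, set(range(16)), params,
                            since=int(rng.integers(0, 3)))
            assert 0.0 <= s <= 1.0


class TestRecacheDecision:
    @pytest.mark.parametrize("s,st,expected", [
        (0.7, 0.6, True),
        (0.6, 0.6, False),      # strictly greater than the threshold
        (0.0, 0.0, False),
        (1.0, 1.0, False),      # st = 1 never re-caches
        (1.0, 0.999, True),
    ])
    def test_threshold_is_strict(self, s, st, expected):
        assert decide_recache(s, st) is expected

    def test_rejects_invalid_risk(self):
        with pytest.raises(ValueError):
            decide_recache(1.2, 0.6)
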