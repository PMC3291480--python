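"""Ground-truth physical state and the session engines.

The world keeps track of what is actually true — which tray sites hold
worms, how many worms were re-cached out of reach — while the bird acts
only on its memory.  The divergence between the two is the engine of
the model: it is the sole source of recovery failures, and recovery
failures are the source of stress at recovery.

Two session engines couple bird and world: a caching session places a
fixed number of worms (with stress-driven immediate re-caching when
watched), and a recovery session probes sites until every worm left in
the offered trays has been recovered, re-caching recovered worms to an
out-of-tray sink whenever the safety risk of their tray exceeds the
bird's stress threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple

import numpy as np

from .bird import (MAX_RECACHE_CHAIN, RELOCATION_FLOOR, BirdParams,
                   OnlookerContext, PRIVATE, decide_recache,
                   maybe_immediate_recache, onlooker_aversion,
                   safety_risk_masked)
from .memory import CACHE, IOR_STRENGTH, RECOVERY, MemoryStore, NoiseStream

__all__ = [
    "Tray", "World", "SessionConfig", "Event", "DesignPlan", "TrialPlan",
    "CachingPhase", "build_world", "make_world", "run_caching_session",
    "run_recovery_session", "DESIGNS",
]

#: recovery-session circuit breaker: offered sites x this many probes
RECOVERY_STEP_FACTOR = 50


@dataclass(frozen=True)
class Tray:
    """An ice-cube tray: a rows x cols grid of discrete cache sites."""

    tray_id: int
    sites: np.ndarray          # (rows, cols) array of global site ids
    distance_class: str = "neutral"   # near / far / neutral

    @property
    def site_ids(self) -> np.ndarray:
        return self.sites.ravel()


@lru_cache(maxsize=None)
def _grid_neighbors(layout: tuple) -> dict[int, frozenset]:
    """Within-tray grid adjacency, Chebyshev distance <= 1 (incl. self).

    ``layout`` is a tuple of (first site id, (rows, cols)) per tray;
    cached because worlds of the same design share their geometry.
    """
    out = {}
    for first, (rows, cols) in layout:
        sites = np.arange(first, first + rows * cols).reshape(rows, cols)
        for r in range(rows):
            for c in range(cols):
                near = sites[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
                out[int(sites[r, c])] = frozenset(int(s) for s in near.ravel())
    return out


class Event(NamedTuple):
    step: int
    session: str               # caching / recovery
    action: str                # cache / recover_success / recover_fail /
                               # recache_immediate / recache_recovery
    tray: int
    site: int


class World:
    """Trays, worm positions, and the out-of-tray sink."""

    def __init__(self, trays: list[Tray]):
        self.trays = trays
        self.n_sites = int(sum(t.site_ids.size for t in trays))
        self.site_tray = np.empty(self.n_sites, dtype=int)
        for t in trays:
            self.site_tray[t.site_ids] = t.tray_id
        self.worms_at = np.zeros(self.n_sites, dtype=int)
        self.out_of_tray = 0
        self.consumed = 0
        self.given = 0
        #: every site that has actually held a worm (the bird's real
        #: cache sites, used by the safety-risk filter)
        self.ever_cached: set[int] = set()
        key = tuple((int(t.sites[0, 0]), t.sites.shape) for t in trays)
        self._neighbors = _grid_neighbors(key)

    def neighbors(self, site_id: int) -> frozenset:
        """The site itself plus its laterally/diagonally adjacent sites."""
        return self._neighbors[site_id]

    def tray_of(self, site_id: int) -> int:
        return int(self.site_tray[site_id])

    def sites_of(self, tray_ids) -> np.ndarray:
        return np.concatenate([self.trays[t].site_ids for t in tray_ids])

    def free_sites(self, tray_ids) -> np.ndarray:
        sites = self.sites_of(tray_ids)
        return sites[self.worms_at[sites] == 0]

    def place_worm(self, site_id: int, new: bool = False):
        if self.worms_at[site_id] != 0:
            raise ValueError(f"site {site_id} already holds a worm")
        if new:
            self.given += 1
        self.worms_at[site_id] = 1
        self.ever_cached.add(int(site_id))

    def remove_worm(self, site_id: int):
        if self.worms_at[site_id] != 1:
            raise ValueError(f"no worm at site {site_id}")
        self.worms_at[site_id] = 0

    def qualifying_sites(self) -> set[int]:
        """Actual cache sites and their neighbors (safety-risk filter)."""
        out: set[int] = set()
        for s in self.ever_cached:
            out |= self._neighbors[s]
        return out

    def check_conservation(self):
        total = int(self.worms_at.sum()) + self.out_of_tray + self.consumed
        if total != self.given:
            raise AssertionError(
                f"worm conservation violated: {total} accounted, {self.given} given")


@dataclass(frozen=True)
class SessionConfig:
    session_type: str                  # caching / recovery
    offered_trays: tuple[int, ...]
    n_caches: int | None = None        # caching sessions only
    context: OnlookerContext = PRIVATE

    def __post_init__(self):
        if self.session_type == "caching" and (self.n_caches is None
                                               or self.n_caches < 1):
            raise ValueError("caching sessions need n_caches >= 1")


def _pick(scores: np.ndarray, noisy: bool, rng: np.random.Generator) -> int:
    """Argmax with uniform tie-breaking (ties only arise when n = 0)."""
    best = int(np.argmax(scores))
    if noisy:
        return best
    ties = np.flatnonzero(scores == scores[best])
    return best if ties.size == 1 else int(rng.choice(ties))


def run_caching_session(store: MemoryStore, world: World, cfg: SessionConfig,
                        params: BirdParams, rng: np.random.Generator) -> list[Event]:
    """Cache ``n_caches`` worms; watched birds may immediately re-cache.

    Each worm is placed at the free offered site with the highest cache
    attractiveness (onlooker aversion + inhibition of return + noise,
    evaluated for the whole candidate set in one vectorised pass).
    After every cache event a watched bird re-caches the fresh cache
    with its condition's odds: it recovers the worm (encoded as a
    successful recovery) and caches it anew, and the replacement cache
    is itself eligible, up to a hard chain cap.
    """
    if cfg.session_type != "caching":
        raise ValueError("not a caching session config")
    ctx, events = cfg.context, []
    start = store.clock
    noisy = params.n > 0.0
    aversion = np.array([onlooker_aversion(s, ctx, params, world.tray_of)
                         for s in range(world.n_sites)])
    offered = np.zeros(world.n_sites, dtype=bool)
    offered[world.sites_of(cfg.offered_trays)] = True

    noise = NoiseStream(params.n, world.n_sites, rng)

    def cache_once() -> tuple[int, int]:
        free = offered & (world.worms_at == 0)
        if not free.any():
            raise ValueError("no free cache site offered")
        scores = (aversion
                  - IOR_STRENGTH * store.site_traces(CACHE, None, params.d,
                                                     since=start)
                  + noise.next_row())
        scores[~free] = -np.inf
        site = _pick(scores, noisy, rng)
        step = store.clock
        store.encode_event(CACHE, site)
        return site, step

    for _ in range(cfg.n_caches):
        site, step = cache_once()
        world.place_worm(site, new=True)
        events.append(Event(step, "caching", "cache", world.tray_of(site), site))
        chain = 0
        while chain < MAX_RECACHE_CHAIN and maybe_immediate_recache(ctx, params, rng):
            store.encode_event(RECOVERY, site, success=True)
            world.remove_worm(site)
            site, step = cache_once()
            world.place_worm(site)
            events.append(Event(step, "caching", "recache_immediate",
                                world.tray_of(site), site))
            chain += 1
    world.check_conservation()
    return events


def run_recovery_session(store: MemoryStore, world: World, cfg: SessionConfig,
                         params: BirdParams,
                         rng: np.random.Generator) -> tuple[list[Event], bool]:
    """Probe sites until every worm in the offered trays is recovered.

    Each probe targets the offered site with the highest recovery
    attractiveness.  A probe at an empty site is a recovery failure; a
    probe that finds a worm triggers the safety-risk check of that
    worm's tray, and the worm is re-cached out of tray (never recovered
    again) when the risk exceeds the stress threshold, eaten otherwise.

    Returns (events, completed); ``completed`` is False when the
    step-count circuit breaker tripped before the trays were empty.
    """
    if cfg.session_type != "recovery":
        raise ValueError("not a recovery session config")
    offered_sites = world.sites_of(cfg.offered_trays)
    offered = np.zeros(world.n_sites, dtype=bool)
    offered[offered_sites] = True
    qualifying = np.fromiter(world.qualifying_sites(), dtype=int)
    tray_masks = {t: np.intersect1d(world.trays[t].site_ids, qualifying)
                  for t in cfg.offered_trays}
    limit = offered_sites.size * RECOVERY_STEP_FACTOR
    start = store.clock
    noisy = params.n > 0.0
    remaining = int(world.worms_at[offered_sites].sum())
    noise = NoiseStream(params.n, world.n_sites, rng)
    events: list[Event] = []

    while remaining > 0:
        if len(events) >= limit:
            return events, False
        cache_tr = store.site_traces(CACHE, None, params.d)
        relocation = np.full(world.n_sites, RELOCATION_FLOOR)
        np.log(cache_tr, out=relocation, where=cache_tr > 0.0)
        scores = (relocation
                  - IOR_STRENGTH * store.site_traces(RECOVERY, "any", params.d,
                                                     since=start)
                  + noise.next_row())
        scores[~offered] = -np.inf
        site = _pick(scores, noisy, rng)
        step = store.clock
        tray = world.tray_of(site)
        if world.worms_at[site] > 0:
            # the safety risk reflects previous recovery experiences:
            # the recovery that just found this worm does not count
            risk = safety_risk_masked(tray_masks[tray], store, params,
                                      since=start)
            store.encode_event(RECOVERY, site, success=True)
            world.remove_worm(site)
            remaining -= 1
            if decide_recache(risk, params.st):
                world.out_of_tray += 1
                events.append(Event(step, "recovery", "recache_recovery", tray, site))
            else:
                world.consumed += 1
                events.append(Event(step, "recovery", "recover_success", tray, site))
        else:
            store.encode_event(RECOVERY, site, success=False)
            events.append(Event(step, "recovery", "recover_fail", tray, site))
        world.check_conservation()
    return events, True


# ---------------------------------------------------------------------------
# experiment designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CachingPhase:
    offered_trays: tuple[int, ...]
    context: OnlookerContext
    n_caches: int


@dataclass(frozen=True)
class TrialPlan:
    trial_id: int
    condition: str
    caching_phases: tuple[CachingPhase, ...]
    recovery_trays: tuple[int, ...]
    #: tray id -> analysis label, for designs where the tray carries the
    #: contrast (watched vs private tray, near vs far tray)
    tray_labels: dict[int, str] = field(default_factory=dict)


@dataclass(frozen=True)
class DesignPlan:
    name: str
    n_birds: int
    trials: tuple[TrialPlan, ...]
    tray_specs: tuple[tuple[str, int, int], ...]   # (distance_class, rows, cols)

    def new_world(self) -> World:
        return make_world(self.tray_specs)


def make_world(tray_specs) -> World:
    trays, next_id = [], 0
    for i, (distance, rows, cols) in enumerate(tray_specs):
        ids = np.arange(next_id, next_id + rows * cols).reshape(rows, cols)
        trays.append(Tray(i, ids, distance))
        next_id += rows * cols
    return World(trays)


def build_world(design: str, tray_rows: int = 2, tray_cols: int = 8,
                n_caches: int = 8) -> DesignPlan:
    """Experiment design -> fresh-world factory plus per-trial session plan.

    ``exp1a``: six alternating watched / private trials, one tray each.
    ``exp1b``: two trials; the bird caches in a watched tray and a
    private tray one after the other, and recovers with both trays
    returned simultaneously.
    ``exp2``: dominant / subordinate / private conditions; two trays per
    trial, one near the adjacent bird's cage and one farther away.
    """
    shape = (tray_rows, tray_cols)
    watched = OnlookerContext(watched=True, rank="peer")

    if design == "exp1a":
        # six trials, alternating watched and private, one fresh tray each
        trials = tuple(
            TrialPlan(i, cond,
                      (CachingPhase((0,), ctx, n_caches),),
                      (0,))
            for i, (cond, ctx) in enumerate(
                3 * [("watched", watched), ("private", PRIVATE)])
        )
        return DesignPlan("exp1a", 7, trials, (("neutral", *shape),))

    if design == "exp1b":
        # two trials: cache in a watched tray then a private tray (order
        # counterbalanced across trials), recover with both trays at once
        def trial(i: int, watched_tray: int) -> TrialPlan:
            private_tray = 1 - watched_tray
            phases = [CachingPhase((watched_tray,), watched, n_caches),
                      CachingPhase((private_tray,), PRIVATE, n_caches)]
            if i % 2:
                phases.reverse()
            return TrialPlan(i, "both", tuple(phases), (0, 1),
                             {watched_tray: "watched", private_tray: "private"})

        trials = (trial(0, 0), trial(1, 1))
        return DesignPlan("exp1b", 7, trials,
                          (("neutral", *shape), ("neutral", *shape)))

    if design == "exp2":
        # one trial per condition; tray 0 is near the adjacent bird
        contexts = {
            "dominant": OnlookerContext(True, "dominant", near_tray_id=0),
            "subordinate": OnlookerContext(True, "subordinate", near_tray_id=0),
            "private": PRIVATE,
        }
        trials = tuple(
            TrialPlan(i, cond,
                      (CachingPhase((0, 1), ctx, n_caches),),
                      (0, 1), {0: "near", 1: "far"})
            for i, (cond, ctx) in enumerate(contexts.items())
        )
        return DesignPlan("exp2", 9, trials,
                          (("near", *shape), ("far", *shape)))

    raise ValueError(f"unknown design {design!r}; expected exp1a, exp1b or exp2")


DESIGNS = ("exp1a", "exp1b", "exp2")
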