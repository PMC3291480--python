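"""The virtual bird's decision rules.

Where to cache, where to recover, and when stress triggers re-caching.
All decisions are argmax choices over the discrete tray sites on offer,
scored by an attractiveness that combines at most three ingredients:
a deterministic pull or push (onlooker aversion when caching, the cache
relocation effect when recovering), inhibition of return, and logistic
transient noise.  Stress enters in two places: watched birds immediately
re-cache freshly made caches with condition-specific odds, and a
recovering bird re-caches a recovered worm when the activation-weighted
share of failed recovery attempts in that tray (the safety risk) exceeds
its stress threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .memory import CACHE, IOR_STRENGTH, RECOVERY, MemoryStore, draw_noise

__all__ = [
    "BirdParams",
    "OnlookerContext",
    "PRIVATE",
    "onlooker_aversion",
    "immediate_recache_odds",
    "maybe_immediate_recache",
    "cache_attractiveness",
    "choose_cache_site",
    "cache_relocation",
    "recovery_attractiveness",
    "choose_recovery_site",
    "safety_risk",
    "safety_risk_masked",
    "decide_recache",
]

#: hard cap on chained immediate re-caches of a single worm; guards
#: against nontermination at degenerate odds (cr = 1)
MAX_RECACHE_CHAIN = 10

#: relocation pull assigned to sites with no cache memory.  Finite but
#: far below any remembered site's activation, so the bird directs its
#: recovery attempts at remembered cache sites, and probes elsewhere
#: only when every remembered site is strongly inhibited (late in a
#: session) and noise tips the balance.
RELOCATION_FLOOR = -2.0


@dataclass(frozen=True)
class BirdParams:
    """All tunable quantities of the cognitive model.

    Defaults are the model's operating point: decay ``d`` and noise
    scale ``n`` of the memory equations; stress threshold ``st`` for
    re-caching at recovery; onlooker aversions ``oa_d`` / ``oa_s``
    (additive penalties on near-tray sites when watched by a dominant /
    subordinate bird); immediate-re-cache odds ``cr_w`` (watched,
    unranked onlooker), ``cr_d`` (dominant) and ``cr_s`` (subordinate).
    """

    d: float = 0.2
    n: float = 0.3
    st: float = 0.6
    oa_d: float = -1.25
    oa_s: float = -0.5
    cr_w: float = 0.6
    cr_d: float = 0.8
    cr_s: float = 0.4

    def __post_init__(self):
        if not 0.0 < self.d < 1.0:
            raise ValueError("decay d must be in (0, 1)")
        if self.n < 0.0:
            raise ValueError("noise scale n must be >= 0")
        if not 0.0 <= self.st <= 1.0:
            raise ValueError("stress threshold st must be in [0, 1]")
        if not self.oa_d <= self.oa_s <= 0.0:
            raise ValueError("onlooker aversions must satisfy oa_d <= oa_s <= 0")
        for name in ("cr_w", "cr_d", "cr_s"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def with_overrides(self, **kwargs) -> "BirdParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class OnlookerContext:
    """Social context of one caching session.

    ``rank`` is "dominant", "subordinate" or "peer" (an onlooker of
    unstated rank) when watched, "none" in private.  ``near_tray_id``
    identifies the tray adjacent to the onlooker in distance designs.
    """

    watched: bool = False
    rank: str = "none"
    near_tray_id: int | None = None

    def __post_init__(self):
        if self.rank not in ("dominant", "subordinate", "peer", "none"):
            raise ValueError(f"unknown rank {self.rank!r}")
        if (self.rank == "none") != (not self.watched):
            raise ValueError("rank is 'none' exactly when unwatched")


PRIVATE = OnlookerContext()


def onlooker_aversion(site_id: int, context: OnlookerContext,
                      params: BirdParams, tray_of) -> float:
    """O_k: additive penalty for caching near a watching conspecific.

    Equal to ``oa_d`` for near-tray sites under a dominant onlooker,
    ``oa_s`` for the same sites under a subordinate onlooker, and zero
    otherwise.  ``tray_of`` maps a site id to its tray id.
    """
    if context.near_tray_id is None or tray_of(site_id) != context.near_tray_id:
        return 0.0
    if context.rank == "dominant":
        return params.oa_d
    if context.rank == "subordinate":
        return params.oa_s
    return 0.0


def immediate_recache_odds(context: OnlookerContext, params: BirdParams) -> float:
    """Probability that a freshly made cache is immediately re-cached."""
    return {"dominant": params.cr_d, "subordinate": params.cr_s,
            "peer": params.cr_w, "none": 0.0}[context.rank]


def maybe_immediate_recache(context: OnlookerContext, params: BirdParams,
                            rng: np.random.Generator) -> bool:
    """Stress check after each cache event during a caching session."""
    p = immediate_recache_odds(context, params)
    return p > 0.0 and rng.random() < p


def _aversion_vector(sites: np.ndarray, context: OnlookerContext,
                     params: BirdParams, tray_of) -> np.ndarray:
    return np.array([onlooker_aversion(int(s), context, params, tray_of)
                     for s in sites])


def cache_attractiveness(sites, store: MemoryStore, context: OnlookerContext,
                         params: BirdParams, rng: np.random.Generator,
                         tray_of, since: int | None = None) -> np.ndarray:
    """C_k = O_k + I_k + noise for each candidate site.

    One fresh noise draw per site per decision; inhibition counts cache
    chunks only (the current session's type), scoped to the ongoing
    session via ``since``.
    """
    sites = np.asarray(sites)
    inhibition = -IOR_STRENGTH * store.site_traces(CACHE, None, params.d,
                                                   since=since)[sites]
    aversion = _aversion_vector(sites, context, params, tray_of)
    return aversion + inhibition + draw_noise(params.n, rng, sites.size)


def _argmax_tiebreak(values: np.ndarray, rng: np.random.Generator) -> int:
    best = int(np.argmax(values))
    ties = np.flatnonzero(values == values[best])
    return best if ties.size == 1 else int(rng.choice(ties))


def choose_cache_site(sites, store, context, params, rng, tray_of,
                      since: int | None = None) -> int:
    """Site with the highest cache attractiveness; ties broken uniformly."""
    sites = np.asarray(sites)
    if sites.size == 0:
        raise ValueError("no candidate cache sites offered")
    scores = cache_attractiveness(sites, store, context, params, rng,
                                  tray_of, since)
    return int(sites[_argmax_tiebreak(scores, rng)])


def cache_relocation(site_id: int, store: MemoryStore, now: int | None,
                     params: BirdParams) -> float:
    """F_k: the pull toward recovering where a cache memory exists.

    Equal to the current activation of the site's cache chunk; a site
    with no cache chunk falls to the relocation floor, far below any
    remembered site.  Recovery attempts are therefore directed at
    remembered cache sites, and with noise silenced (n = 0) failures
    can arise solely from memory/world divergence.
    """
    tr = store.site_traces(CACHE, None, params.d, now)[site_id]
    return math.log(tr) if tr > 0.0 else RELOCATION_FLOOR


def recovery_attractiveness(sites, store: MemoryStore, params: BirdParams,
                            rng: np.random.Generator,
                            since: int | None = None) -> np.ndarray:
    """R_k = F_k + I_k + noise.

    Inhibition counts recovery chunks only, scoped to the ongoing
    session via ``since``; the relocation pull F uses the full cache
    memory regardless of session.
    """
    sites = np.asarray(sites)
    cache_tr = store.site_traces(CACHE, None, params.d)[sites]
    relocation = np.where(cache_tr > 0.0,
                          np.log(np.maximum(cache_tr, 1e-300)),
                          RELOCATION_FLOOR)
    succ, fail = store.recovery_traces(params.d, since=since)
    inhibition = -IOR_STRENGTH * (succ[sites] + fail[sites])
    return relocation + inhibition + draw_noise(params.n, rng, sites.size)


def choose_recovery_site(sites, store, params, rng,
                         since: int | None = None) -> int:
    sites = np.asarray(sites)
    if sites.size == 0:
        raise ValueError("no candidate recovery sites offered")
    scores = recovery_attractiveness(sites, store, params, rng, since)
    return int(sites[_argmax_tiebreak(scores, rng)])


def safety_risk(tray_sites, store: MemoryStore, qualifying_sites,
                params: BirdParams, since: int | None = None) -> float:
    """S_k: the share of failed among all recovery attempts in a tray.

    Over the recovery experiences in the worm's tray that are directed
    at the bird's actual cache sites or their neighbors
    (``qualifying_sites``),

        S = A_u / (A_u + A_s)

    where A_u counts the tray sites whose recovery memory is an
    unresolved failure — the bird remembers probing there and finding
    no worm, with no memory of having emptied the site itself — and
    A_s counts the sites it remembers successfully recovering from.
    Each remembered site contributes one attempt however often it was
    re-probed, so S estimates the fraction of the tray's apparent
    caches that turned out to be missing.  ``since`` restricts the
    tally to experiences encoded from that step onward (the recovery
    session engine passes its own start step, so stress reflects the
    ongoing session rather than recoveries made while caching).  0
    when no qualifying recovery experience exists yet (no evidence of
    risk).  Always in [0, 1].
    """
    mask = np.intersect1d(np.asarray(tray_sites, dtype=int),
                          np.asarray(list(qualifying_sites), dtype=int))
    return safety_risk_masked(mask, store, params, since)


def safety_risk_masked(mask: np.ndarray, store: MemoryStore,
                       params: BirdParams, since: int | None = None) -> float:
    """``safety_risk`` with the tray/qualifying intersection precomputed."""
    if mask.size == 0:
        return 0.0
    succ = store.site_traces(RECOVERY, True, params.d, since=since)[mask]
    fail = store.site_traces(RECOVERY, False, params.d, since=since)[mask]
    a_s = float((succ > 0.0).sum())
    # a failed probe of a site the bird remembers emptying itself is
    # not a missing cache
    a_u = float(((fail > 0.0) & (succ == 0.0)).sum())
    total = a_u + a_s
    return a_u / total if total > 0.0 else 0.0


def decide_recache(s: float, st: float) -> bool:
    """Re-cache iff the safety risk strictly exceeds the stress threshold."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("safety risk must be in [0, 1]")
    return s > st
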