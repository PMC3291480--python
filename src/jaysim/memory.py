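"""Declarative memory for the virtual bird.

Every caching and recovery event is encoded as a *chunk*: one chunk per
kind of experience at a site (caching there, successfully recovering
there, unsuccessfully recovering there).  Re-experiencing an event adds a
*use* to the existing chunk rather than creating a duplicate.  A chunk's
memory strength is its base-level activation

    A_h = ln( sum_j t_j^(-d) )

where ``t_j`` is the number of model steps elapsed since use ``j`` and
``d`` is the decay rate.  Time is counted in discrete steps: every cache
or recovery event advances the clock by one, and time between sessions
does not pass.

The module also provides the two other quantities every site-choice is
built from: *inhibition of return* (a negative bias against revisiting a
site for the same purpose) and logistic *transient noise*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CACHE",
    "RECOVERY",
    "MemoryChunk",
    "MemoryStore",
    "activation",
    "trace",
    "inhibition_of_return",
    "transient_noise",
    "draw_noise",
]

CACHE = "cache"
RECOVERY = "recovery"

#: Elapsed times are clamped to >= 1 step so that an event evaluated on
#: the step it occurred contributes t^-d = 1 instead of a singularity.
MIN_ELAPSED = 1

#: Strength of inhibition of return relative to one fresh memory trace.
#: Set so that at the operating parameters roughly a quarter of all
#: caches land in the near tray under both onlooker conditions (the
#: calibration the onlooker-aversion settings were tuned against).
IOR_STRENGTH = 2.5


@dataclass
class MemoryChunk:
    """One remembered kind of experience at one site.

    ``success`` is ``None`` for cache chunks and a boolean for recovery
    chunks (was a worm actually found?).  ``use_steps`` is the strictly
    increasing list of clock steps at which the experience occurred.
    """

    event_type: str
    site_id: int
    success: bool | None
    use_steps: list[int] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.event_type, self.site_id, self.success)


class MemoryStore:
    """The bird's collection of chunks plus its step clock.

    The sole substrate of every decision the bird makes: the world is
    never consulted directly, so memory and world can diverge (which is
    exactly what produces recovery failures).

    Alongside the chunk mapping, flat per-event arrays are kept for each
    chunk class so the session engines can evaluate whole candidate sets
    of sites in single vectorised passes.
    """

    #: chunk classes, in the order used by the flat arrays; the "any"
    #: class mirrors every recovery event regardless of outcome so the
    #: recovery-session inhibition needs a single pass
    CLASSES = ((CACHE, None), (RECOVERY, True), (RECOVERY, False),
               (RECOVERY, "any"))

    def __init__(self, n_sites: int):
        self.n_sites = int(n_sites)
        self.chunks: dict[tuple, MemoryChunk] = {}
        self.clock: int = 0
        # flat (site, use_step) event buffers per chunk class, grown
        # geometrically so batch queries need no list conversion
        self._sites = {c: np.empty(32, dtype=np.intp) for c in self.CLASSES}
        self._steps = {c: np.empty(32, dtype=np.int64) for c in self.CLASSES}
        self._n = {c: 0 for c in self.CLASSES}
        self._pow_tables: dict[float, np.ndarray] = {}

    def _pow_table(self, d: float) -> np.ndarray:
        # table[t] = t^-d for every elapsed time reachable at the
        # current clock; avoids a float power per batch query
        tab = self._pow_tables.get(d)
        if tab is None or tab.size <= self.clock + 1:
            size = max(256, 2 * (self.clock + 2))
            tab = np.empty(size)
            tab[0] = 1.0
            tab[1:] = np.arange(1, size, dtype=float) ** (-d)
            self._pow_tables[d] = tab
        return tab

    # -- encoding ------------------------------------------------------

    def encode_event(self, event_type: str, site_id: int,
                     success: bool | None = None) -> MemoryChunk:
        """Encode one event at the current clock step; advance the clock.

        A new chunk is created only if no chunk with the same
        (type, site, success) key exists; otherwise the existing chunk
        receives an update (a new use step).
        """
        if event_type not in (CACHE, RECOVERY):
            raise ValueError(f"unknown event type {event_type!r}")
        if event_type == CACHE and success is not None:
            raise ValueError("cache events carry no success flag")
        if event_type == RECOVERY and success is None:
            raise ValueError("recovery events require a success flag")
        if not (0 <= site_id < self.n_sites):
            raise ValueError(f"site {site_id} outside world of {self.n_sites}")

        key = (event_type, site_id, success)
        chunk = self.chunks.get(key)
        if chunk is None:
            chunk = MemoryChunk(event_type, site_id, success)
            self.chunks[key] = chunk
        chunk.use_steps.append(self.clock)
        classes = ((event_type, success),)
        if event_type == RECOVERY:
            classes += ((RECOVERY, "any"),)
        for cls in classes:
            n = self._n[cls]
            if n == self._sites[cls].size:
                self._sites[cls] = np.concatenate([self._sites[cls]] * 2)
                self._steps[cls] = np.concatenate([self._steps[cls]] * 2)
            self._sites[cls][n] = site_id
            self._steps[cls][n] = self.clock
            self._n[cls] = n + 1
        self.clock += 1
        return chunk

    # -- vectorised queries -------------------------------------------

    def site_traces(self, event_type: str, success: bool | None,
                    d: float, now: int | None = None,
                    since: int | None = None) -> np.ndarray:
        """Total power-law trace per site for one chunk class.

        Returns the length-``n_sites`` vector whose entry for site k is
        ``sum_j t_j^(-d)`` over every use of the class's chunk at k
        (0.0 where no chunk exists).  ``exp(activation)`` of a chunk is
        exactly its entry's contribution, so ``log`` of a positive entry
        recovers the chunk activation.  ``since`` restricts the sum to
        uses encoded at step >= since.
        """
        now = self.clock if now is None else now
        cls = (event_type, success)
        n = self._n[cls]
        if n == 0:
            return np.zeros(self.n_sites)
        steps = self._steps[cls][:n]
        sites = self._sites[cls][:n]
        if since is not None:
            # events are appended in clock order, so a binary search
            # finds the first use inside the window
            lo = int(np.searchsorted(steps, since, side="left"))
            steps, sites = steps[lo:], sites[lo:]
        t = now - steps
        np.maximum(t, MIN_ELAPSED, out=t)
        w = self._pow_table(d)[t] if now <= self.clock else \
            np.asarray(t, dtype=float) ** (-d)
        return np.bincount(sites, weights=w, minlength=self.n_sites)

    def recovery_traces(self, d: float, now: int | None = None,
                        since: int | None = None):
        """(successful, unsuccessful) recovery trace vectors."""
        return (self.site_traces(RECOVERY, True, d, now, since),
                self.site_traces(RECOVERY, False, d, now, since))

    # -- debugging -----------------------------------------------------

    def to_json(self) -> str:
        """Chunk key -> use_steps, for inspection and debugging."""
        payload = {
            f"{t}:{s}:{'-' if ok is None else ok}": c.use_steps
            for (t, s, ok), c in sorted(self.chunks.items(),
                                        key=lambda kv: repr(kv[0]))
        }
        return json.dumps({"clock": self.clock, "chunks": payload})


def activation(chunk: MemoryChunk, now: int, d: float) -> float:
    """Base-level activation A_h = ln(sum_j t_j^-d) of a chunk.

    Elapsed times below one step are clamped to one, so the activation
    of a chunk used once on the previous step is exactly 0.
    """
    if not chunk.use_steps:
        raise ValueError("chunk has no uses")
    if not 0.0 < d < 1.0:
        raise ValueError("decay d must be in (0, 1)")
    return math.log(trace(chunk, now, d))


def trace(chunk: MemoryChunk, now: int, d: float,
          since: int | None = None) -> float:
    """Power-law memory trace sum_j t_j^-d (= exp(activation)).

    ``since`` restricts the sum to uses encoded at step >= since.
    """
    return sum(max(now - u, MIN_ELAPSED) ** (-d) for u in chunk.use_steps
               if since is None or u >= since)


def inhibition_of_return(store: MemoryStore, site_id: int, session_type: str,
                         now: int | None = None, d: float = 0.2,
                         since: int | None = None) -> float:
    """Inhibition of return I_k for a site within a session type.

    Only chunks of the current session's type count: during caching
    sessions a site is inhibited by memories of having cached there;
    during recovery sessions by memories of having recovered there
    (successfully or not).  The bias is the negated total power-law
    trace of those chunks,

        I_k = - c * sum_l exp(A_l),    c = IOR_STRENGTH

    which is 0 when no matching chunk exists and strictly more negative
    the stronger (more frequent, more recent) the matching memories.

    Inhibition of return is a short-term, task-scoped bias; the session
    engines pass their start step as ``since`` so only events of the
    ongoing session inhibit.
    """
    if session_type not in (CACHE, RECOVERY):
        raise ValueError(f"unknown session type {session_type!r}")
    now = store.clock if now is None else now
    total = 0.0
    if session_type == CACHE:
        chunk = store.chunks.get((CACHE, site_id, None))
        if chunk is not None:
            total += trace(chunk, now, d, since)
    else:
        for success in (True, False):
            chunk = store.chunks.get((RECOVERY, site_id, success))
            if chunk is not None:
                total += trace(chunk, now, d, since)
    return -IOR_STRENGTH * total


def transient_noise(n: float, r: float) -> float:
    """Logistic transient noise n * ln((1 - r) / r) for r in (0, 1).

    Symmetric about zero; scale parameter ``n`` (a scale of n gives a
    standard deviation of n * pi / sqrt(3)).  ``n = 0`` silences noise
    entirely.
    """
    if n < 0:
        raise ValueError("noise scale n must be >= 0")
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie strictly between 0 and 1")
    if n == 0.0:
        return 0.0
    return n * math.log((1.0 - r) / r)


def draw_noise(n: float, rng: np.random.Generator, size: int) -> np.ndarray:
    """Vector of independent transient-noise draws.

    Uniform draws that land exactly on 0 or 1 (possible only at floating
    point extremes) are resampled rather than mapped to +-infinity.
    """
    if n == 0.0:
        return np.zeros(size)
    r = rng.random(size)
    # rng.random() lies in [0, 1); resample exact zeros
    while True:
        bad = r == 0.0
        if not bad.any():
            break
        r[bad] = rng.random(int(bad.sum()))
    return n * np.log((1.0 - r) / r)


class NoiseStream:
    """Blocked source of per-site transient-noise vectors.

    Draws ``block`` decision rows at a time from one RNG, amortising
    generator overhead across a session's decisions; each row is a
    fresh independent noise draw for every site.
    """

    def __init__(self, n: float, width: int, rng: np.random.Generator,
                 block: int = 32):
        self.n, self.width, self.rng, self.block = n, width, rng, block
        self._zero = np.zeros(width)
        self._buf: np.ndarray | None = None
        self._i = 0

    def next_row(self) -> np.ndarray:
        if self.n == 0.0:
            return self._zero
        if self._buf is None or self._i >= self.block:
            r = self.rng.random((self.block, self.width))
            while True:
                bad = r == 0.0
                if not bad.any():
                    break
                r[bad] = self.rng.random(int(bad.sum()))
            self._buf = self.n * np.log((1.0 - r) / r)
            self._i = 0
        row = self._buf[self._i]
        self._i += 1
        return row
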