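# Methods

## Model overview

`jaysim` simulates an individual food-caching corvid as a memory
system plus a small set of behavioral rules.  The world is a set of
ice-cube trays, each a grid of discrete cache sites holding at most one
worm; the bird acts only on its memory, never on the world directly,
so the two can diverge — and that divergence is the engine of every
result.  A trial consists of one *caching session* (the bird places a
fixed number of worms) and one *recovery session* (the trays are
returned and the bird probes sites until every remaining worm is
recovered).  Time is counted in model steps: each cache or recovery
event is one step, and time between sessions does not pass — the decay
of memory over the intervening hours is neglected, which is reasonable
because recovery accuracy in these birds degrades over days, not
hours.

## Memory

Every event is encoded as a *chunk* keyed by (event kind, site,
outcome): caching at a site, successfully recovering there, or
unsuccessfully recovering there.  Re-experiencing a keyed event
appends a *use* to the existing chunk.  A chunk's base-level
activation is

    A_h = ln( Σ_j t_j^(-d) ),

summing a power-law trace `t^-d` over all uses, where `t_j` is the
number of steps since use `j` and `d` (default 0.2) is the decay rate.
Elapsed times are clamped to ≥ 1 step so an event is well defined on
the step it occurred.  Only base-level learning and transient noise
are taken from the parent cognitive-architecture tradition; spreading
activation, partial matching and retrieval latencies are out of scope.

## Decision rules

All choices are argmaxes of per-site attractiveness over the offered
sites, with ties (possible only when noise is off) broken uniformly at
random from the run's seeded RNG.

**Inhibition of return.**  `I_k = -c · Σ_l exp(A_l)` over the chunks
at site `k` *of the current session's type* (cache chunks in caching
sessions; recovery chunks of either outcome in recovery sessions),
counting only events of the ongoing session: inhibition of return is a
short-term bias against revisiting a site with the same purpose, not a
lifetime aversion.  `exp(A_l)` is the chunk's power-law trace, so the
bias is 0 with no matching chunk, strictly negative otherwise, and
grows with the frequency and recency of the memories.  A form built
directly on summed raw activations cannot satisfy these sign
constraints, because single-use activations go negative one step after
the event.  The strength constant `c = 2.5` is the one calibrated
quantity of the implementation: it is set (jointly with nothing else)
so that, at the default parameters, roughly a quarter of all caches
land in the near tray in *both* onlooker conditions — the same anchor
against which the onlooker-aversion settings themselves were
originally tuned.  This calibration is non-trivial: the dominant
condition pairs a stronger aversion (−1.25) with more re-cache churn
(odds 0.8, hence ≈ 37 cache events for 8 worms), while the subordinate
condition pairs −0.5 with odds 0.4 (≈ 13 events), and only an
inhibition that accumulates over repeated use of the far tray brings
both conditions to ≈ 25% (measured 27.3% / 22.1% at 100 runs).

**Transient noise.**  Every attractiveness includes one fresh draw of
`ε = n · ln((1 − r)/r)`, `r` uniform in (0, 1) — the standard logistic
transient noise of the parent architecture (scale `n = 0.3`, standard
deviation `n·π/√3 ≈ 0.54`).  Draws of exactly 0 or 1 are resampled.

**Caching.**  `C_k = O_k + I_k + ε` over the *free* offered sites.
`O_k` is `oa_d = −1.25` for near-tray sites under a dominant onlooker,
`oa_s = −0.5` under a subordinate one, 0 otherwise; the preference for
distance is assumed to have been learned before the experiment and is
built in.  While watched, each completed cache is immediately
recovered and re-cached with the condition's odds (`cr_w = 0.6`
unranked, `cr_d = 0.8`, `cr_s = 0.4`, 0 in private); the recovery is
encoded as a successful recovery event and the worm is cached anew by
the ordinary rule.  The replacement cache is itself eligible, so
chains are geometric; a hard cap of 10 re-caches per worm guards the
degenerate `cr = 1` case.  At `cr_w = 0.6` the expected chain length
is `Σ_{k=1..10} 0.6^k ≈ 1.49` re-caches per worm (measured 1.49–1.51),
which lies inside the calibration band around the published anchor of
roughly 1.3; the exact chain structure behind that printed value is
not recoverable, so it is deliberately not hard-coded.

**Recovery.**  `R_k = F_k + I_k + ε` over all offered sites.  The
cache-relocation pull `F_k` is the current activation of the site's
cache chunk (full memory, not session-scoped); a site with no cache
chunk falls to a floor of −2, far below any remembered site, so the
bird directs recovery attempts at sites it remembers caching in and
probes elsewhere only when every remembered site is strongly inhibited
and noise tips the balance.  With noise silenced, recovery visits
exactly the remembered cache sites and failures can arise only from
memory/world divergence.  A probe of an empty site is encoded as an
unsuccessful recovery; a found worm is removed and either eaten or, if
the safety check below fires, re-cached into an out-of-tray sink that
is invisible to further choice (re-cached worms are never recovered
again).  The session ends when the offered trays are empty; a circuit
breaker (50 probes per offered site) flags and excludes pathological
runs, none of which occur at the default parameters.

**Safety risk and re-caching.**  After finding a worm in tray `T` the
bird computes `S = A_u / (A_u + A_s)` over its *previous* recovery
experiences in `T` this session — the find being decided does not
count — restricted to attempts directed at its actual cache sites or
their within-tray neighbours (Chebyshev distance 1).  `A_u` counts the
sites remembered as unresolved failures, `A_s` the sites remembered as
successful recoveries; a failed probe of a site the bird itself
emptied earlier re-affirms a resolved recovery rather than signalling
a missing cache.  Counting each remembered site once (rather than
summing raw traces) makes `S` estimate the fraction of the tray's
apparent caches that turned out to be missing, which is what the
ratio-of-attempts definition describes; trace-weighted variants were
evaluated and let re-probed phantom sites dominate the tally, erasing
the near/far tray contrast.  The worm is re-cached iff `S > st`
(strict; `st = 0.6`), so with no evidence (`S = 0`) or `st = 1` the
bird never re-caches at recovery.

## Experiment harness

Designs: `exp1a` — six alternating watched/private trials, one 2×8
tray, 8 caches per session, 7 birds; `exp1b` — two trials in which the
bird caches 8 worms in a watched tray then 8 in a private tray (order
and tray roles counterbalanced across trials) and recovers with both
trays returned together, 7 birds; `exp2` — dominant / subordinate /
private conditions with a near and a far 2×8 tray, 8 caches, 9 birds.
Memory is reset between trials by default (empirically, trials used
distinct trays on different days; carrying memory across trials is
available behind a flag).  Each experiment is run 100 times; every
run, bird and session draws from named substreams of one master seed,
so all outputs are bit-identical under replay.

Per bird and condition (and per tray where the design contrasts
trays) the harness tallies initial caches, immediate re-caches,
recovery failures, and recovery re-caches, and reports the proportion
of worms present at recovery that were re-cached.  The
*representative run* is the one whose condition-level mean re-cache
proportions are closest (mean absolute difference) to the across-run
grand means, with ties broken by run id.  Matched-samples tests follow
the conventions of the original animal studies: a two-tailed Wilcoxon
matched-pairs test (zero differences dropped; the statistic is the
smaller signed-rank sum, so a unanimous direction gives V = 0; exact
p for small tie-free samples) and Friedman's tie-corrected rank
analysis of variance.

Five directional patterns summarise the replication: (1) more
re-caching after watched than private trials; (2) more from the
watched than the private tray; (3) dominant > subordinate; (4)
dominant > private; (5) within the watched conditions, the near tray
loses a larger share of its caches than the far tray.  Condition-level
comparisons average per-bird proportions; the tray-level comparison
(5) pools counts across birds and runs because a single bird holds
only one to three worms in the near tray, making per-bird ratios
nearly degenerate.  The parameter sweep re-runs the pattern suite over
a grid (defaults `d, n ∈ {0.1..0.5}`, `st ∈ {0.4..0.7}`) at 20 runs
per cell for desk-scale runtime.

## Numerical and design choices

* Per-site occupancy is binary; caching candidates are the free
  offered sites (offering fewer free sites than caches is a config
  error).
* The engines evaluate whole candidate sets in single vectorised
  passes (flat per-class event buffers, a `t^-d` lookup table, blocked
  noise draws); the per-site functions in `jaysim.bird` are the
  canonical scalar definitions and the tests hold the two paths to the
  same answers.
* Worm conservation (given = in trays + eaten + out-of-tray) is
  asserted after every event.
* Tray geometry (2×8), caches per session (8), and the sweep grid are
  configurable defaults chosen to keep near/far splits observable in a
  16-site tray; the original per-bird cache counts were never
  published.

## What the simulation does and does not show

The harness reproduces the *directional* re-caching patterns and the
two printed calibration anchors (≈ 1.3 immediate re-caches per watched
worm; ≈ 25% near-tray caching under onlookers), and the unanimity
behind the watched-vs-private V = 0.  Absolute re-cache proportions
depend on unpublished details (tray sizes, per-bird cache counts, the
exact inhibition and safety-risk equations) and are not calibration
targets.  Within the dominant condition alone the near/far contrast is
weaker than pooled across the watched conditions: the sparsely used
near tray yields occasional "free" first recoveries with no prior
evidence (S = 0), a small-sample effect of the tray-level safety
ratio.  The patterns are robust to one-step moves of (d, n, st) around
the operating point, with one genuine exception: at `st = 0.5` the
near/far contrast compresses toward zero, because far-tray finds with
middling risk also trigger re-caching.  All of this describes the
simulated protocol — real birds bring motivation, satiety and
individual history that the model deliberately omits, and the model's
birds always recover everything, which real birds do not.
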