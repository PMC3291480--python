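# jaysim

Agent-based simulation of food-caching corvid cognition: a "virtual
bird" with a human-memory-style declarative memory caches and recovers
worms in simulated cache-protection experiments, and re-caches its food
not because it reasons about what observers saw, but because *stress* —
from being watched while caching, and from failing to find caches it
remembers making — makes it want to cache more.

Western scrub jays re-cache food more after caching in front of a
conspecific, more when the onlooker was dominant, and preferentially
from the tray nearest the onlooker.  These patterns are usually read as
evidence for "theory of mind".  `jaysim` implements the cognitively
lean alternative: a single learned rule (cache far from onlookers) plus
stress-driven re-caching and ordinary memory errors reproduce all of
those directional patterns.  The package is for researchers in
comparative cognition and computational ethology who want to re-run,
probe, or extend that argument.

## The model

The bird stores one memory *chunk* per kind of experience at a site
(caching there; recovering there successfully; recovering there
unsuccessfully).  A chunk used at steps `j` (one step per cache or
recovery event) has base-level activation

    A_h = ln( Σ_j t_j^(-d) )

with elapsed times `t_j` and decay `d` — the standard power-law
recency/frequency law of human declarative memory.  Site choice is an
argmax of per-site attractiveness, always containing *inhibition of
return* `I_k = -c·Σ_l exp(A_l)` over same-purpose chunks at the site
(session-scoped; `c = 2.5`) and logistic transient noise
`ε = n·ln((1-r)/r)`:

* caching:  `C_k = O_k + I_k + ε`, where the onlooker aversion `O_k`
  penalises sites in the tray near a watching conspecific
  (`oa_d = -1.25` dominant, `oa_s = -0.5` subordinate);
* recovery: `R_k = F_k + I_k + ε`, where the cache-relocation pull
  `F_k` is the activation of the site's cache chunk.

Stress enters twice.  While watched, each fresh cache is immediately
recovered and re-cached with condition odds (`cr_w = 0.6`,
`cr_d = 0.8`, `cr_s = 0.4`), which litters memory with cache chunks at
sites that no longer hold worms.  At recovery, after finding a worm in
tray `T` the bird computes the safety risk

    S = A_u / (A_u + A_s)

the share of failed among all its recovery attempts in `T` (directed
at its actual cache sites or their neighbours), and re-caches the worm
out of reach when `S > st` (stress threshold, `st = 0.6`).  Memory
confusion → recovery failures → stress → re-caching is the entire
causal chain; the bird never remembers who watched it, or whether it
was watched at all.

Two experiment designs are built in: alternating watched/private
trials and a watched-tray/private-tray design (7 birds), and a
dominant/subordinate/private design with a near and a far tray
(9 birds).

## Worked example

```python
from jaysim import run_experiment
from jaysim.experiments import (grand_mean, immediate_recaches_per_worm,
                                representative_wilcoxon)

runs = run_experiment("exp1a", n_runs=100, seed=1)
print("immediate re-caches per watched worm:",
      round(immediate_recaches_per_worm(runs), 2))
print("mean re-cache proportion, watched:", round(grand_mean(runs, "watched"), 3))
print("mean re-cache proportion, private:", round(grand_mean(runs, "private"), 3))
v, p = representative_wilcoxon(runs)
print(f"Wilcoxon matched-pairs (n = 7): V = {v:.0f}, p = {p:.3f}")
```

prints

```
immediate re-caches per watched worm: 1.51
mean re-cache proportion, watched: 0.231
mean re-cache proportion, private: 0.0
Wilcoxon matched-pairs (n = 7): V = 0, p = 0.031
```

Watched virtual birds re-cache each worm about 1.5 times during the
caching session itself; at recovery they then re-cache about 23% of
their caches, while private birds — whose memories match the world —
re-cache essentially nothing.  Every one of the 7 birds shows the
watched > private direction, so the signed-rank statistic of the
representative run is V = 0.

The same is available from a shell:

```sh
jaysim reproduce --seed 1 --out results/     # all designs + report.json
jaysim run exp2 --st 1.0 --out results/      # never-stressed ablation
jaysim sweep --runs 20 --out results/        # (d, n, st) robustness grid
jaysim selftest                              # quick invariant checks
```

Every command writes a `manifest.json` (seed, parameters, version) and
is bit-identical when repeated with the same seed.

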