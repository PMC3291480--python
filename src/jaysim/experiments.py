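"""Replication harness for the two simulated experiments.

Each experiment is run many times (100 by default, matching the study
protocol) with as many virtual birds as there were real ones (7 in the
watched-vs-private experiment, 9 in the distance/dominance experiment).
Per run and bird the harness tallies caching-session and
recovery-session events into re-cache proportions, selects the
*representative run* (the one closest to the across-run average),
applies the matched-samples tests, checks the five directional
re-caching patterns, and can sweep the (d, n, st) parameter cube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bird import BirdParams
from .memory import MemoryStore
from .stats import wilcoxon_matched_pairs
from .world import DesignPlan, SessionConfig, build_world, run_caching_session, \
    run_recovery_session

__all__ = [
    "RunResult", "SweepCell", "run_experiment", "run_all_designs",
    "select_representative_run", "condition_means", "grand_mean",
    "pooled_proportion",
    "summarize_run", "summarize_runs", "check_patterns", "PATTERN_NAMES",
    "parameter_sweep", "sweep_to_frame", "immediate_recaches_per_worm",
    "near_tray_share", "representative_wilcoxon",
]

#: number of real birds in each original experiment
DESIGN_N_BIRDS = {"exp1a": 7, "exp1b": 7, "exp2": 9}


@dataclass
class RunResult:
    """Event tallies of one simulation run.

    ``table`` has one row per (bird, condition, tray) with the counts
    n_cached (initial cache placements), n_immediate (immediate
    re-caches while watched), n_failures (failed recovery probes),
    n_recached (worms re-cached out of tray at recovery), n_worms
    (worms present when the trays were returned) and the proportion
    ``prop_recached`` = n_recached / n_worms.  ``tray`` is "all" for
    condition-level rows, or a tray label (near/far) where the design
    contrasts trays.
    """

    run_id: int
    table: pd.DataFrame
    completed: bool = True


_COUNTS = ("n_cached", "n_immediate", "n_failures", "n_recached", "n_worms")


def _run_one(plan: DesignPlan, params: BirdParams, n_birds: int, run_id: int,
             rng_seeds, carry_memory: bool) -> RunResult:
    acc: dict[tuple, dict] = {}

    def bump(bird, condition, tray, **deltas):
        row = acc.setdefault((bird, condition, tray),
                             {k: 0 for k in _COUNTS})
        for k, v in deltas.items():
            row[k] += v

    completed = True
    for b in range(n_birds):
        rng = np.random.default_rng(rng_seeds[b])
        store = None
        for trial in plan.trials:
            world = plan.new_world()
            if store is None or not carry_memory:
                store = MemoryStore(world.n_sites)
            cache_events = []
            for phase in trial.caching_phases:
                cfg = SessionConfig("caching", phase.offered_trays,
                                    phase.n_caches, phase.context)
                cache_events += run_caching_session(store, world, cfg, params, rng)
            rec_cfg = SessionConfig("recovery", trial.recovery_trays)
            rec_events, ok = run_recovery_session(store, world, rec_cfg,
                                                  params, rng)
            completed = completed and ok

            def keys_for(tray: int):
                if plan.name == "exp1b":
                    # the tray carries the watched/private contrast
                    return [(trial.tray_labels[tray], "all")]
                out = [(trial.condition, "all")]
                if trial.tray_labels:
                    out.append((trial.condition, trial.tray_labels[tray]))
                return out

            for ev in cache_events:
                delta = ({"n_cached": 1} if ev.action == "cache"
                         else {"n_immediate": 1})
                for cond, tray in keys_for(ev.tray):
                    bump(b, cond, tray, **delta)
            for ev in rec_events:
                delta = {
                    "recover_fail": {"n_failures": 1},
                    "recover_success": {"n_worms": 1},
                    "recache_recovery": {"n_worms": 1, "n_recached": 1},
                }[ev.action]
                for cond, tray in keys_for(ev.tray):
                    bump(b, cond, tray, **delta)

    rows = []
    for (bird, cond, tray), c in acc.items():
        rows.append({"bird": bird, "condition": cond, "tray": tray, **c,
                     "prop_recached": (c["n_recached"] / c["n_worms"]
                                       if c["n_worms"] else np.nan)})
    table = pd.DataFrame(rows).sort_values(
        ["bird", "condition", "tray"]).reset_index(drop=True)
    return RunResult(run_id, table, completed)


def run_experiment(design: str, params: BirdParams | None = None,
                   n_birds: int | None = None, n_runs: int = 100,
                   seed: int = 0, carry_memory: bool = False,
                   tray_rows: int = 2, tray_cols: int = 8,
                   n_caches: int = 8) -> list[RunResult]:
    """Run one experiment design ``n_runs`` times.

    Each run draws an independent random substream from the master
    seed, so results are reproducible and runs are exchangeable.  Runs
    whose recovery circuit breaker tripped are excluded with a warning.
    """
    params = params or BirdParams()
    plan = build_world(design, tray_rows, tray_cols, n_caches)
    n_birds = n_birds or plan.n_birds
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    results = []
    for run_id, run_ss in enumerate(master.spawn(n_runs)):
        res = _run_one(plan, params, n_birds, run_id,
                       run_ss.spawn(n_birds), carry_memory)
        if res.completed:
            results.append(res)
        else:
            warnings.warn(f"{design} run {run_id}: recovery circuit breaker "
                          "tripped; run excluded")
    return results


def run_all_designs(params: BirdParams | None = None, n_runs: int = 100,
                    seed: int = 0, n_caches: int = 8) -> dict[str, list[RunResult]]:
    """All three designs under one master seed (one substream each)."""
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    out = {}
    for design, ss in zip(("exp1a", "exp1b", "exp2"), master.spawn(3)):
        out[design] = run_experiment(design, params, n_runs=n_runs,
                                     seed=ss, n_caches=n_caches)
    return out


# ---------------------------------------------------------------------------
# summaries and representative-run selection
# ---------------------------------------------------------------------------

def condition_means(run: RunResult, tray: str = "all") -> pd.Series:
    """Mean re-cache proportion per condition, averaged over birds."""
    t = run.table[run.table.tray == tray]
    return t.groupby("condition")["prop_recached"].mean().sort_index()


def grand_mean(runs: list[RunResult], condition: str, tray: str = "all") -> float:
    """Across-run mean of the per-run bird-average re-cache proportion."""
    vals = [condition_means(r, tray).get(condition, np.nan) for r in runs]
    return float(np.nanmean(vals))


def pooled_proportion(runs: list[RunResult], conditions, tray: str) -> float:
    """Re-cache proportion with worms pooled across birds and runs.

    Per-bird proportions are unstable for sparsely used trays (a bird
    may hold one or two worms in the near tray), so tray-level
    comparisons pool the counts instead of averaging bird ratios.
    """
    t = pd.concat([r.table for r in runs])
    t = t[t.condition.isin(conditions) & (t.tray == tray)]
    worms = int(t.n_worms.sum())
    return float(t.n_recached.sum() / worms) if worms else float("nan")


def select_representative_run(runs: list[RunResult]) -> RunResult:
    """The run closest to the across-run average.

    Distance is the mean absolute difference between a run's
    condition-level mean re-cache proportions and the across-run grand
    means of the same quantities; ties go to the lowest run id.
    """
    if not runs:
        raise ValueError("no runs to select from")
    mat = pd.DataFrame([condition_means(r) for r in runs])
    dist = (mat - mat.mean(axis=0)).abs().mean(axis=1).to_numpy()
    order = np.lexsort(([r.run_id for r in runs], dist))
    return runs[order[0]]


def summarize_run(run: RunResult) -> pd.DataFrame:
    """(condition, tray) -> mean and SE of prop_recached across birds."""
    g = run.table.groupby(["condition", "tray"])["prop_recached"]
    out = g.agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(v.notna().sum()),
                n_birds="count")
    return out.reset_index()


def summarize_runs(runs: list[RunResult]) -> pd.DataFrame:
    """(condition, tray) -> across-run mean and SE of the bird-average."""
    per_run = pd.concat(
        [r.table.groupby(["condition", "tray"])["prop_recached"].mean()
         for r in runs], axis=1)
    out = pd.DataFrame({
        "mean": per_run.mean(axis=1),
        "se": per_run.std(axis=1, ddof=1) / np.sqrt(per_run.notna().sum(axis=1)),
        "n_runs": per_run.notna().sum(axis=1),
    })
    return out.reset_index()


# ---------------------------------------------------------------------------
# headline quantities
# ---------------------------------------------------------------------------

def immediate_recaches_per_worm(runs: list[RunResult],
                                conditions=("watched",)) -> float:
    """Mean immediate re-caches per initially cached worm, pooled."""
    t = pd.concat([r.table for r in runs])
    t = t[(t.tray == "all") & t.condition.isin(conditions)]
    return float(t.n_immediate.sum() / t.n_cached.sum())


def near_tray_share(runs: list[RunResult], condition: str) -> float:
    """Fraction of initial cache placements landing in the near tray."""
    t = pd.concat([r.table for r in runs])
    t = t[t.condition == condition]
    near = t.loc[t.tray == "near", "n_cached"].sum()
    total = t.loc[t.tray == "all", "n_cached"].sum()
    return float(near / total)


def representative_wilcoxon(runs: list[RunResult], cond_a: str = "watched",
                            cond_b: str = "private") -> tuple[float, float]:
    """Wilcoxon matched-pairs test on the representative run's birds."""
    rep = select_representative_run(runs)
    t = rep.table[rep.table.tray == "all"]
    wide = t.pivot(index="bird", columns="condition", values="prop_recached")
    return wilcoxon_matched_pairs(wide[cond_a].to_numpy(),
                                  wide[cond_b].to_numpy())


# ---------------------------------------------------------------------------
# pattern suite and parameter sweep
# ---------------------------------------------------------------------------

PATTERN_NAMES = (
    "exp1a_watched_gt_private",
    "exp1b_watched_tray_gt_private_tray",
    "exp2_dominant_gt_subordinate",
    "exp2_dominant_gt_private",
    "exp2_near_gt_far_when_watched",
)


def check_patterns(results: dict[str, list[RunResult]]) -> dict[str, bool]:
    """The five directional re-caching patterns, on across-run means.

    (1) more re-caching after watched than private trials; (2) more
    from the watched tray than the private tray; (3) dominant onlooker
    beats subordinate; (4) dominant beats private; (5) within watched
    conditions, the near tray loses a larger share of its caches than
    the far tray.
    """
    e1a, e1b, e2 = results["exp1a"], results["exp1b"], results["exp2"]
    watched = ("dominant", "subordinate")
    near = pooled_proportion(e2, watched, "near")
    far = pooled_proportion(e2, watched, "far")
    flags = (
        grand_mean(e1a, "watched") > grand_mean(e1a, "private"),
        grand_mean(e1b, "watched") > grand_mean(e1b, "private"),
        grand_mean(e2, "dominant") > grand_mean(e2, "subordinate"),
        grand_mean(e2, "dominant") > grand_mean(e2, "private"),
        bool(near > far),
    )
    return dict(zip(PATTERN_NAMES, map(bool, flags)))


@dataclass(frozen=True)
class SweepCell:
    """Pattern flags of one (d, n, st) parameter combination."""

    d: float
    n: float
    st: float
    pattern_flags: tuple[bool, bool, bool, bool, bool]
    all_patterns: bool


#: default sweep grid (reconstruction of the published robustness sweep)
SWEEP_GRID = {
    "d": (0.1, 0.2, 0.3, 0.4, 0.5),
    "n": (0.1, 0.2, 0.3, 0.4, 0.5),
    "st": (0.4, 0.5, 0.6, 0.7),
}


def parameter_sweep(d_values=SWEEP_GRID["d"], n_values=SWEEP_GRID["n"],
                    st_values=SWEEP_GRID["st"],
                    base: BirdParams | None = None, n_runs: int = 20,
                    seed: int = 0, n_caches: int = 8,
                    progress=None) -> list[SweepCell]:
    """Re-run the pattern suite over a (d, n, st) grid.

    Uses a reduced number of runs per cell (20 by default) so a full
    5 x 5 x 4 grid stays desk-scale.  Each cell draws its own
    substream of the master seed, so the sweep is reproducible and
    cells are independent.
    """
    base = base or BirdParams()
    cells = [(d, n, st) for d in d_values for n in n_values for st in st_values]
    master = np.random.SeedSequence(seed)
    out = []
    for (d, n, st), ss in zip(cells, master.spawn(len(cells))):
        params = base.with_overrides(d=d, n=n, st=st)
        results = run_all_designs(params, n_runs=n_runs, seed=ss,
                                  n_caches=n_caches)
        flags = tuple(check_patterns(results).values())
        out.append(SweepCell(d, n, st, flags, all(flags)))
        if progress is not None:
            progress(out[-1])
    return out


def sweep_to_frame(cells: list[SweepCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append({"d": c.d, "n": c.n, "st": c.st,
                     **dict(zip(PATTERN_NAMES, c.pattern_flags)),
                     "all_patterns": c.all_patterns})
    return pd.DataFrame(rows)
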