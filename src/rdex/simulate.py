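"""Simulation of complete stop-signal datasets under the hybrid race model.

The default schedule reproduces the study design: two sessions (one with
blockwise and one with trialwise bias cuing), eight 60-trial experimental
blocks per session with exactly 15 pre-assigned stop trials each (960 trials,
240 stop, i.e. 25% stop trials), a 2 s response deadline, and a one-up
one-down staircase on the stop-signal delay starting at 0.2 s with 0.05 s
steps, which tracks the SSD at which inhibition succeeds about half the
time.

Design cells: difficulty is balanced and randomized within block; the bias
cue is fixed per block in blockwise sessions (balanced across blocks) and
randomized per trial in trialwise sessions; the stimulus matches the bias
cue with 70% probability (cue validity), and only the cue identity — not its
correctness — enters the parameter map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import (
    DESIGN_FACTORS,
    AccumulatorRole,
    DesignCell,
    ParameterMap,
    build_map,
)
from .distributions import DEFAULT_STOP_LOWER, StopRunnerParams, trunc_exg_sample
from .likelihood import RESPONSES, Trial

__all__ = [
    "StaircaseState",
    "staircase_update",
    "make_schedule",
    "simulate_dataset",
    "simulate_stop_outcomes",
    "generate_recovery_truths",
    "BASE_TRUTH",
    "DEFAULT_JITTER",
    "trials_from_table",
]

CUE_VALIDITY = 0.7
DEFAULT_DEADLINE = 2.0


@dataclass(frozen=True)
class StaircaseState:
    """One-up one-down SSD staircase: current SSD, step size and floor."""

    ssd: float = 0.2
    step: float = 0.05
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.ssd < self.floor:
            raise ValueError("ssd must not be below the floor")


def staircase_update(state: StaircaseState, outcome: str) -> StaircaseState:
    """Advance the staircase: SSD increases after a successful inhibition
    and decreases (clamped at the floor) after a failed one."""
    if outcome == "inhibited":
        return replace(state, ssd=state.ssd + state.step)
    if outcome == "responded":
        return replace(state, ssd=max(state.floor, state.ssd - state.step))
    raise ValueError(f"unknown staircase outcome {outcome!r}")


def make_schedule(
    n_sessions: int = 2,
    blocks_per_session: int = 8,
    trials_per_block: int = 60,
    stop_per_block: int = 15,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build a trial schedule: session, block, trial, design cell and stop
    flag per row. Deterministic given the seed."""
    if stop_per_block > trials_per_block:
        raise ValueError("stop_per_block must not exceed trials_per_block")
    if rng is None:
        rng = np.random.default_rng(seed)
    block_types = [
        DESIGN_FACTORS["block_type"][s % 2] for s in range(n_sessions)
    ]
    rows = []
    for s, block_type in enumerate(block_types, start=1):
        # blockwise sessions: bias fixed per block, balanced across blocks
        block_biases = np.array(
            [DESIGN_FACTORS["bias"][i % 2] for i in range(blocks_per_session)]
        )
        rng.shuffle(block_biases)
        for b in range(blocks_per_session):
            stop_pos = set(rng.choice(trials_per_block, size=stop_per_block, replace=False))
            # difficulty balanced within block
            difficulty = np.array(
                [DESIGN_FACTORS["difficulty"][i % 2] for i in range(trials_per_block)]
            )
            rng.shuffle(difficulty)
            if block_type == "block":
                bias = np.full(trials_per_block, block_biases[b], dtype=object)
            else:
                bias = rng.choice(DESIGN_FACTORS["bias"], size=trials_per_block)
            valid = rng.random(trials_per_block) < CUE_VALIDITY
            other = np.where(bias == "blue", "orange", "blue")
            stimulus = np.where(valid, bias, other)
            for t in range(trials_per_block):
                rows.append(
                    {
                        "session": s,
                        "block": b + 1,
                        "trial": t + 1,
                        "block_type": block_type,
                        "bias": bias[t],
                        "difficulty": difficulty[t],
                        "stimulus": stimulus[t],
                        "is_stop": t in stop_pos,
                    }
                )
    return pd.DataFrame(rows)


def _cell_of_row(row) -> DesignCell:
    return DesignCell(
        block_type=row.block_type,
        bias=row.bias,
        difficulty=row.difficulty,
        stimulus=row.stimulus,
    )


def simulate_dataset(
    schedule: pd.DataFrame,
    flat: np.ndarray,
    pmap: ParameterMap | None = None,
    deadline: float = DEFAULT_DEADLINE,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    staircase: StaircaseState | None = None,
    fixed_ssd: float | np.ndarray | None = None,
    stop_lower: float = DEFAULT_STOP_LOWER,
    stop_upper: float = math.inf,
    subject: str = "s1",
) -> pd.DataFrame:
    """Simulate responses for a schedule under the race model.

    Per trial: with probability ``pgf`` the go runners are not launched;
    otherwise both accumulators' finishing times are Wald draws plus t0. On
    stop trials, with probability ``ptf`` the stop runner is not launched;
    otherwise its finishing time is ``ssd`` plus a truncated ex-Gaussian
    draw. A response is emitted iff the fastest go finish precedes both the
    stop finish (if any) and the deadline. The staircase advances in
    schedule order after every stop trial; pass ``fixed_ssd`` (a scalar or a
    per-stop-trial array) to disable it.

    Returns a trial table with one row per trial (RT in seconds; empty
    response/SSD fields encoded as NaN / ``"none"``).
    """
    if pmap is None:
        pmap = build_map()
    if rng is None:
        rng = np.random.default_rng(seed)
    flat = np.asarray(flat, dtype=float)
    n = len(schedule)

    # gather per-trial parameters (cache per design cell)
    cache: dict[DesignCell, dict] = {}
    cells = [_cell_of_row(row) for row in schedule.itertuples()]
    for cell in cells:
        if cell not in cache:
            runners = {
                resp: pmap.go_params(flat, cell, AccumulatorRole(resp))
                for resp in RESPONSES
            }
            mix = pmap.mixture_params(flat, cell)
            stop = pmap.stop_params(flat, cell, lower=stop_lower, upper=stop_upper)
            cache[cell] = {"runners": runners, "mix": mix, "stop": stop}

    v = np.array([[cache[c]["runners"][r].v for r in RESPONSES] for c in cells])
    b = np.array([[cache[c]["runners"][r].b for r in RESPONSES] for c in cells])
    t0 = np.array([[cache[c]["runners"][r].t0 for r in RESPONSES] for c in cells])
    a_rng = np.array([[cache[c]["runners"][r].A for r in RESPONSES] for c in cells])
    pgf = np.array([cache[c]["mix"].pgf for c in cells])
    ptf = np.array([cache[c]["mix"].ptf for c in cells])

    dist = b - rng.uniform(0.0, 1.0, size=b.shape) * a_rng
    go_finish = t0 + rng.wald(dist / v, dist * dist)  # (n, 2)
    go_fail = rng.random(n) < pgf
    trig_fail = rng.random(n) < ptf
    # stop-runner draws, one per trial (used only on stop trials)
    stop_rel = np.empty(n)
    for cell, group in _groups(cells):
        stop_rel[group] = trunc_exg_sample(len(group), cache[cell]["stop"], rng)

    is_stop = schedule["is_stop"].to_numpy()
    if fixed_ssd is not None:
        fixed = np.broadcast_to(np.asarray(fixed_ssd, dtype=float), (int(is_stop.sum()),))
    if staircase is None:
        staircase = StaircaseState()

    ssd_out = np.full(n, np.nan)
    resp_out = np.full(n, "none", dtype=object)
    rt_out = np.full(n, np.nan)
    stop_counter = 0
    for i in range(n):
        winner = int(np.argmin(go_finish[i]))
        t_go = math.inf if go_fail[i] else go_finish[i, winner]
        if is_stop[i]:
            if fixed_ssd is not None:
                ssd = float(fixed[stop_counter])
            else:
                ssd = staircase.ssd
            stop_counter += 1
            t_stop = math.inf if trig_fail[i] else ssd + stop_rel[i]
            responded = t_go < t_stop and t_go <= deadline and math.isfinite(t_go)
            ssd_out[i] = ssd
            if responded:
                resp_out[i] = RESPONSES[winner]
                rt_out[i] = t_go
            if fixed_ssd is None:
                staircase = staircase_update(
                    staircase, "responded" if responded else "inhibited"
                )
        else:
            if t_go <= deadline and math.isfinite(t_go):
                resp_out[i] = RESPONSES[winner]
                rt_out[i] = t_go

    out = schedule.copy()
    out.insert(0, "subject", subject)
    out["trial_type"] = np.where(is_stop, "stop", "go")
    out["ssd"] = ssd_out
    out["response"] = resp_out
    out["rt"] = rt_out
    return out.drop(columns=["is_stop"])


def _groups(cells):
    by_cell: dict[DesignCell, list[int]] = {}
    for i, c in enumerate(cells):
        by_cell.setdefault(c, []).append(i)
    return by_cell.items()


def simulate_stop_outcomes(
    n: int,
    go_i,
    go_j,
    stop: StopRunnerParams,
    pgf: float,
    ptf: float,
    ssd: float,
    rng: np.random.Generator,
    deadline: float = math.inf,
):
    """Vectorized simulation of ``n`` stop trials at a fixed SSD.

    Returns ``(responded, rt)`` where ``responded`` is a boolean array and
    ``rt`` holds signal-respond RTs (NaN for inhibitions). The workhorse of
    the likelihood <-> simulation cross-checks.
    """
    runners = (go_i, go_j)
    finish = np.empty((n, 2))
    for k, p in enumerate(runners):
        dist = p.b - rng.uniform(0.0, 1.0, size=n) * p.A
        finish[:, k] = p.t0 + rng.wald(dist / p.v, dist * dist)
    t_go = finish.min(axis=1)
    t_go[rng.random(n) < pgf] = np.inf
    t_stop = ssd + trunc_exg_sample(n, stop, rng)
    t_stop[rng.random(n) < ptf] = np.inf
    responded = (t_go < t_stop) & (t_go <= deadline)
    rt = np.where(responded, t_go, np.nan)
    return responded, rt


# ---------------------------------------------------------------------------
# recovery truths
# ---------------------------------------------------------------------------

def _paper_base_truth(pmap: ParameterMap) -> np.ndarray:
    """Data-generating values anchored at the reported condition effects:
    match-mismatch rate differences of ~2.4 (easy) and ~1.37 (hard),
    congruent/incongruent thresholds ~1.69/1.92 with a larger bias effect
    under trialwise cuing, shared t0 of 0.25 s, a stop runner with mean
    SSRT ~0.28 s, and small go/trigger-failure probabilities."""
    flat = np.zeros(pmap.n_params)
    labels = pmap.labels()
    b_values = {
        ("block", True): 1.75,   # (block_type, congruent)
        ("block", False): 1.87,
        ("trial", True): 1.63,
        ("trial", False): 1.96,
    }
    v_values = {
        ("block", "easy", True): 3.54,
        ("block", "easy", False): 1.2,
        ("block", "hard", True): 2.63,
        ("block", "hard", False): 1.2,
        ("trial", "easy", True): 3.66,
        ("trial", "easy", False): 1.2,
        ("trial", "hard", True): 2.51,
        ("trial", "hard", False): 1.2,
    }
    for i, label in enumerate(labels):
        parts = label.split(".")
        ptype = parts[0]
        if ptype == "t0":
            flat[i] = 0.25
        elif ptype == "B":
            bt, bias, resp = parts[1:]
            flat[i] = b_values[(bt, bias == resp)]
        elif ptype == "v":
            bt, diff, match = parts[1:]
            flat[i] = v_values[(bt, diff, match == "True")]
        elif ptype == "mu":
            flat[i] = 0.2
        elif ptype == "sigma":
            flat[i] = 0.04
        elif ptype == "tau":
            flat[i] = 0.08
        elif ptype == "zgf":
            flat[i] = -2.054  # pgf ~ 0.02
        elif ptype == "ztf":
            flat[i] = -1.476  # ptf ~ 0.07
        else:
            raise ValueError(f"no base truth for parameter type {ptype!r}")
    return flat


BASE_TRUTH = _paper_base_truth

# between-set jitter SDs per parameter type (seconds / evidence units /
# probit units), chosen to mimic realistic between-participant variability
DEFAULT_JITTER: dict[str, float] = {
    "t0": 0.04,
    "B": 0.20,
    "v": 0.40,
    "mu": 0.04,
    "sigma": 0.015,
    "tau": 0.025,
    "zgf": 0.40,
    "ztf": 0.40,
}

# hard support bounds per type (the Table-style prior bounds), used to keep
# jittered truths inside the prior support
_TRUTH_BOUNDS: dict[str, tuple[float, float]] = {
    "t0": (0.1, 1.0),
    "B": (1e-6, math.inf),
    "v": (1e-6, math.inf),
    "mu": (1e-6, 4.0),
    "sigma": (1e-3, 4.0),
    "tau": (1e-3, 4.0),
    "zgf": (-math.inf, math.inf),
    "ztf": (-math.inf, math.inf),
}


def generate_recovery_truths(
    n_sets: int = 18,
    base_values: np.ndarray | None = None,
    jitter_spec: dict[str, float] | None = None,
    seed: int | None = None,
    pmap: ParameterMap | None = None,
) -> np.ndarray:
    """Generate ``n_sets`` data-generating parameter vectors by jittering
    the base values with independent truncated-normal noise per parameter
    type; every vector stays inside the prior support. Deterministic given
    the seed; zero jitter returns the base values exactly."""
    if pmap is None:
        pmap = build_map()
    if base_values is None:
        base_values = _paper_base_truth(pmap)
    base_values = np.asarray(base_values, dtype=float)
    if base_values.shape != (pmap.n_params,):
        raise ValueError("base_values length does not match the map")
    if jitter_spec is None:
        jitter_spec = DEFAULT_JITTER
    rng = np.random.default_rng(seed)
    labels = pmap.labels()
    out = np.empty((n_sets, pmap.n_params))
    for j, label in enumerate(labels):
        ptype = label.split(".")[0]
        sd = jitter_spec.get(ptype, 0.0)
        lo, hi = _TRUTH_BOUNDS.get(ptype, (-math.inf, math.inf))
        for s in range(n_sets):
            if sd == 0.0:
                val = base_values[j]
            else:
                val = base_values[j] + sd * rng.standard_normal()
                for _ in range(1000):
                    if lo <= val <= hi:
                        break
                    val = base_values[j] + sd * rng.standard_normal()
                else:  # pragma: no cover - pathological spec
                    raise ValueError(f"could not jitter {label} into support")
            out[s, j] = val
    return out


def trials_from_table(table: pd.DataFrame) -> list[Trial]:
    """Convert a trial table (as produced by :func:`simulate_dataset` or
    read from CSV) into :class:`~rdex.likelihood.Trial` objects."""
    trials = []
    for row in table.itertuples():
        cell = DesignCell(
            block_type=row.block_type,
            bias=row.bias,
            difficulty=row.difficulty,
            stimulus=row.stimulus,
        )
        is_stop = row.trial_type == "stop"
        response = None if row.response in ("none", None) or pd.isna(row.response) else row.response
        rt = None if pd.isna(row.rt) else float(row.rt)
        ssd = float(row.ssd) if is_stop else None
        trials.append(Trial(cell=cell, is_stop=is_stop, ssd=ssd, response=response, rt=rt))
    return trials
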