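"""Serially balanced carry-over trial sequences and per-trial change labels.

The carry-over design requires every condition to be preceded by every
condition (including itself) equally often, so that first-order history
effects are balanced. The target-trial order is an Euler circuit on the
complete directed graph with self-loops over the ``n`` conditions: the
circuit traverses each of the ``n**2`` ordered pairs exactly once and visits
``n**2 + 1`` trials. Shorter sequences truncate one seeded circuit, keeping
the ordered-pair count matrix maximally uniform (spread <= 1).

Each target trial is then labelled by its relation to the immediately
preceding target trial (all same / same place / same view / same heading /
all different), and the five pairwise change covariates (place, view and
heading change, texture change, landmark similarity) are attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .environment import (
    StimulusSet,
    RoomModel,
    heading_distance,
    landmark_similarity,
    place_distance,
    view_distance,
)

__all__ = [
    "TimingSpec",
    "Trial",
    "PairChange",
    "LabeledSequence",
    "euler_carryover_order",
    "generate_carryover_sequence",
    "pair_count_matrix",
    "pair_count_spread",
    "label_trials",
    "pair_regressors",
    "runs_to_events",
    "events_to_runs",
]

LABELS = ("all_same", "same_place", "same_view", "same_heading", "all_different", "excluded")


@dataclass(frozen=True)
class TimingSpec:
    """Trial timing in seconds (defaults follow the 1.914-s TR paradigm:
    one-volume stimulus, quarter-volume gap, four-volume fixation blocks)."""

    trial_duration: float = 1.913
    iti: float = 0.478
    fixation_duration: float = 7.656

    @property
    def soa(self) -> float:
        return self.trial_duration + self.iti


@dataclass(frozen=True)
class Trial:
    index: int
    kind: str  # target | catch | fixation
    condition_id: int | None
    onset: float
    duration: float
    response_valid: bool = True


@dataclass(frozen=True)
class PairChange:
    """Changes between a target trial and its predecessor."""

    place_change: float
    view_change: float
    heading_change: float
    texture_change: float
    landmark_similarity: float


@dataclass
class LabeledSequence:
    """Trial runs with per-target relation labels and pair regressors."""

    runs: list[list[Trial]]
    labels: list[dict[int, str]]  # per run: trial index -> label
    stimuli: StimulusSet = field(repr=False)
    pair_changes: list[dict[int, PairChange]] | None = None

    def label_of(self, run: int, trial_index: int) -> str:
        return self.labels[run][trial_index]


def euler_carryover_order(n_conditions: int, seed: int | np.random.Generator = 0) -> list[int]:
    """Closed Euler circuit over the complete digraph with self-loops.

    Returns a list of ``n_conditions**2 + 1`` condition ids (1-based) in
    which every ordered pair of conditions, including repeats, occurs as a
    consecutive pair exactly once. Hierholzer's algorithm with seeded
    shuffling of the outgoing-edge order makes the circuit reproducible.
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_conditions
    out_edges = []
    for u in range(n):
        targets = list(range(n))
        rng.shuffle(targets)
        out_edges.append(targets)
    ptr = [0] * n
    start = int(rng.integers(n))
    stack = [start]
    circuit: list[int] = []
    while stack:
        u = stack[-1]
        if ptr[u] < n:
            v = out_edges[u][ptr[u]]
            ptr[u] += 1
            stack.append(v)
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    assert len(circuit) == n * n + 1
    return [c + 1 for c in circuit]


def pair_count_matrix(condition_stream: Sequence[int], n_conditions: int) -> np.ndarray:
    """Counts of ordered (previous, current) condition pairs in a stream."""
    m = np.zeros((n_conditions, n_conditions), dtype=int)
    for a, b in zip(condition_stream[:-1], condition_stream[1:]):
        m[a - 1, b - 1] += 1
    return m


def pair_count_spread(condition_stream: Sequence[int], n_conditions: int) -> int:
    """Max minus min of the ordered-pair count matrix (0 = fully balanced)."""
    m = pair_count_matrix(condition_stream, n_conditions)
    return int(m.max() - m.min())


def generate_carryover_sequence(
    n_conditions: int,
    n_runs: int = 4,
    trials_per_run: int = 176,
    catch_rate: float = 25 / 176,
    n_fixation_blocks: int = 10,
    timing: TimingSpec | None = None,
    seed: int = 0,
    miss_rate: float = 0.01,
) -> list[list[Trial]]:
    """Generate carry-over trial runs with catch trials and fixation blocks.

    The concatenated target stream follows one seeded Euler circuit; when
    ``n_runs * trials_per_run`` is at least ``n_conditions**2 + 1`` the full
    circuit is used (pair counts exactly uniform), otherwise the circuit is
    truncated (pair-count spread <= 1). Catch trials (``catch_rate`` per
    target trial) and fixation blocks are inserted at seeded positions;
    ``miss_rate`` of target trials are flagged as missing a response.
    """
    if n_conditions < 2 or n_runs < 1 or trials_per_run < 1:
        raise ValueError("invalid counts")
    timing = timing or TimingSpec()
    rng = np.random.default_rng(seed)
    n_targets = n_runs * trials_per_run

    def draw_order() -> list[int]:
        out: list[int] = []
        while len(out) < n_targets:
            circuit = euler_carryover_order(n_conditions, rng)
            # chain circuits for very long sequences; each is internally balanced
            out.extend(circuit if not out else circuit[1:])
        return out[:n_targets]

    order = draw_order()
    if trials_per_run >= n_conditions:
        # condition-pattern estimation needs every condition in every run;
        # redraw the seeded circuit until the truncation covers them all
        best, best_missing = order, float("inf")
        for _ in range(200):
            chunks = [order[i * trials_per_run : (i + 1) * trials_per_run] for i in range(n_runs)]
            missing = sum(n_conditions - len(set(c)) for c in chunks)
            if missing < best_missing:
                best, best_missing = order, missing
            if missing == 0:
                break
            order = draw_order()
        else:
            import warnings

            warnings.warn(
                f"per-run condition coverage not achieved ({best_missing} gaps); "
                "per-run pattern estimation may be impossible at this run length",
                stacklevel=2,
            )
        order = best

    runs: list[list[Trial]] = []
    pos = 0
    for _ in range(n_runs):
        run_targets = order[pos : pos + trials_per_run]
        pos += trials_per_run
        n_catch = int(round(catch_rate * trials_per_run))
        kinds = ["target"] * trials_per_run + ["catch"] * n_catch + ["fixation"] * n_fixation_blocks
        slots = rng.permutation(len(kinds))
        events = [kinds[i] for i in np.argsort(slots)]
        # draw miss flags, redrawing if they would leave a condition with no
        # valid trial in the run (condition patterns need one per run)
        for _ in range(100):
            misses = rng.random(trials_per_run) < miss_rate
            valid_conds = {c for c, m in zip(run_targets, misses) if not m}
            if trials_per_run < n_conditions or len(valid_conds) == len(set(run_targets)):
                break
        trials: list[Trial] = []
        t = 0.0
        it = iter(enumerate(run_targets))
        for idx, kind in enumerate(events):
            if kind == "fixation":
                trials.append(Trial(idx, "fixation", None, t, timing.fixation_duration))
                t += timing.fixation_duration
            else:
                if kind == "target":
                    k, cond = next(it)
                    valid = not misses[k]
                else:
                    cond, valid = None, True
                trials.append(Trial(idx, kind, cond, t, timing.trial_duration, valid))
                t += timing.soa
        runs.append(trials)
    return runs


def _relation_label(prev_cond: int, cond: int, stimuli: StimulusSet) -> str:
    if prev_cond == cond:
        return "all_same"
    a, b = stimuli[prev_cond], stimuli[cond]
    same_p = a.place_id == b.place_id
    same_v = a.view_id == b.view_id
    same_h = a.heading == b.heading
    if same_p and not same_v and not same_h:
        return "same_place"
    if same_v and not same_p and not same_h:
        return "same_view"
    if same_h and not same_p and not same_v:
        return "same_heading"
    if not same_p and not same_v and not same_h:
        return "all_different"
    return "all_different"  # mixed repeats (e.g. same place and heading)


def label_trials(runs: list[list[Trial]], stimuli: StimulusSet) -> LabeledSequence:
    """Label each target trial by its relation to the preceding target trial.

    A target trial is ``excluded`` when it has no valid response, when it is
    the first target of a run, or when it follows a fixation block, a catch
    trial or a missed-response target.
    """
    labels: list[dict[int, str]] = []
    for run in runs:
        run_labels: dict[int, str] = {}
        prev: Trial | None = None  # previous event of any kind
        prev_target_ok = False
        prev_cond: int | None = None
        for tr in run:
            if tr.kind != "target":
                prev = tr
                continue
            follows_break = prev is None or prev.kind != "target" or not prev.response_valid
            if not tr.response_valid or follows_break or prev_cond is None:
                run_labels[tr.index] = "excluded"
            else:
                run_labels[tr.index] = _relation_label(prev_cond, tr.condition_id, stimuli)
            prev = tr
            prev_cond = tr.condition_id
        labels.append(run_labels)
    return LabeledSequence(runs=runs, labels=labels, stimuli=stimuli)


def pair_regressors(
    seq: LabeledSequence,
    room: RoomModel,
    texture_table: np.ndarray | None = None,
) -> list[dict[int, PairChange]]:
    """Pairwise change covariates for every included (non-excluded) target.

    ``texture_table`` is the condition-by-condition chi-square dissimilarity
    matrix; when omitted, texture change is reported as 0. The result is
    stored on the sequence and returned (one dict per run, keyed by trial
    index).
    """
    stimuli = seq.stimuli
    out: list[dict[int, PairChange]] = []
    for run, run_labels in zip(seq.runs, seq.labels):
        changes: dict[int, PairChange] = {}
        prev_cond: int | None = None
        for tr in run:
            if tr.kind != "target":
                continue
            label = run_labels[tr.index]
            if label != "excluded":
                assert prev_cond is not None
                a, b = stimuli[prev_cond], stimuli[tr.condition_id]
                if texture_table is not None:
                    tex = float(texture_table[prev_cond - 1, tr.condition_id - 1])
                else:
                    tex = 0.0
                changes[tr.index] = PairChange(
                    place_change=place_distance(a.place_id, b.place_id, room),
                    view_change=view_distance(a.view_id, b.view_id, room),
                    heading_change=heading_distance(a.heading, b.heading),
                    texture_change=tex,
                    landmark_similarity=landmark_similarity(a, b, "count"),
                )
            prev_cond = tr.condition_id
        out.append(changes)
    seq.pair_changes = out
    return out


def runs_to_events(runs: list[list[Trial]]) -> pd.DataFrame:
    """Flatten trial runs into a BIDS-style events table (TSV-ready)."""
    rows = []
    for r, run in enumerate(runs):
        for tr in run:
            rows.append(
                {
                    "run": r,
                    "onset": tr.onset,
                    "duration": tr.duration,
                    "trial_type": tr.condition_id if tr.condition_id is not None else "n/a",
                    "kind": tr.kind,
                    "response_valid": int(tr.response_valid),
                }
            )
    return pd.DataFrame(rows)


def events_to_runs(events: pd.DataFrame) -> list[list[Trial]]:
    """Inverse of :func:`runs_to_events`."""
    runs: list[list[Trial]] = []
    for _, df in events.groupby("run", sort=True):
        trials = []
        for i, row in enumerate(df.sort_values("onset").itertuples()):
            cond = None if str(row.trial_type) in ("n/a", "nan") else int(row.trial_type)
            trials.append(
                Trial(i, row.kind, cond, float(row.onset), float(row.duration), bool(row.response_valid))
            )
        runs.append(trials)
    return runs
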