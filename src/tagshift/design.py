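"""Deterministic construction of the four-arc cueing experiment schedule.

The experiment presents four arcs arranged around fixation, each
flickering at a fixed frequency (upper right 18 Hz, lower right 21 Hz,
lower left 24 Hz, upper left 27 Hz).  A central cue points at one arc;
at cue onset the arcs switch from a common baseline color to either a
*different*-color configuration (all four arcs uniquely colored) or a
*same*-color configuration (exactly one arc adjacent to the cued arc
shares the cued color).  Transient target events then appear at the
cued or an adjacent arc with fixed probabilities.

Trial classes are allocated with exact counts (the experiment reports
exact Ns: 360 post-cue-event trials, 640 without, 120 late-event
trials, 168 pre-cue-event trials on the default 1000-trial session)
and the trial order is then shuffled by the seed, so marginal counts
are deterministic and testable rather than binomial draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Arc positions in clockwise circular order starting at the upper right.
POSITIONS = ("upper_right", "lower_right", "lower_left", "upper_left")

#: Flicker frequency of each arc, in Hz.
FREQUENCIES_BY_POSITION = {
    "upper_right": 18.0,
    "lower_right": 21.0,
    "lower_left": 24.0,
    "upper_left": 27.0,
}

#: Event conditions.  ``val``/``val_match`` are events at the cued arc in
#: the different/same color configuration; ``inval*`` are events at an
#: adjacent uncued arc.
EVENT_CONDITIONS = ("val", "val_match", "inval", "inval_match", "inval_non_match")

#: Default palette: one baseline color plus four possible arc colors.
DEFAULT_PALETTE = ("orange", "cyan", "magenta", "purple", "lime")

_SAME_CONFIG_CONDITIONS = frozenset({"val_match", "inval_match", "inval_non_match"})


def adjacent_positions(pos_idx: int) -> tuple[int, int]:
    """Indices of the two arcs adjacent to ``pos_idx`` (clockwise order)."""
    return (pos_idx - 1) % 4, (pos_idx + 1) % 4


def diagonal_position(pos_idx: int) -> int:
    """Index of the arc diagonally opposite ``pos_idx``."""
    return (pos_idx + 2) % 4


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the trial schedule.

    The condition probabilities are expressed relative to the set of
    post-cue-event trials and follow a 3:1:1:1 validity ratio within
    each color configuration (valid events three times as likely as
    each invalid event type), which reproduces the stated per-condition
    rates of 33.34 % (valid) and 11.1 % (each invalid type).
    """

    n_trials: int = 1000
    p_postcue_event: float = 0.36
    p_late_given_event: float = 1.0 / 3.0
    p_precue_event: float = 0.168
    p_same_config: float = 0.5
    condition_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "val": 1.0 / 3.0,
            "val_match": 1.0 / 3.0,
            "inval": 1.0 / 9.0,
            "inval_match": 1.0 / 9.0,
            "inval_non_match": 1.0 / 9.0,
        }
    )
    event_bins_ms: Sequence[tuple[float, float]] = (
        (200.0, 300.0),
        (400.0, 500.0),
        (600.0, 700.0),
    )
    late_event_window_ms: tuple[float, float] = (800.0, 1850.0)
    late_event_min_gap_ms: float = 800.0
    precue_duration_ms: float = 1500.0
    precue_jitter_ms: float = 100.0
    postcue_duration_ms: float = 2000.0
    frequencies_by_position: Mapping[str, float] = field(
        default_factory=lambda: dict(FREQUENCIES_BY_POSITION)
    )
    palette: Sequence[str] = DEFAULT_PALETTE
    baseline_color: str = "orange"
    seed: int = 0

    # ------------------------------------------------------------------
    def _exact_count(self, p: float, n: int, what: str) -> int:
        c = p * n
        if abs(c - round(c)) > 1e-9:
            raise ValueError(
                f"{what}: {p} x {n} = {c} is not an integer; exact-count "
                "allocation requires integer trial counts"
            )
        return int(round(c))

    def counts(self) -> dict[str, int]:
        """Exact per-class trial counts implied by the proportions."""
        n = self.n_trials
        n_event = self._exact_count(self.p_postcue_event, n, "post-cue events")
        cond_counts = {
            c: self._exact_count(p, n_event, f"condition {c}")
            for c, p in self.condition_probs.items()
        }
        if sum(cond_counts.values()) != n_event:
            raise ValueError("condition probabilities do not sum to 1 over event trials")
        n_late = self._exact_count(self.p_late_given_event, n_event, "late events")
        n_precue = self._exact_count(self.p_precue_event, n, "pre-cue events")
        n_same = self._exact_count(self.p_same_config, n, "same-color configuration")
        n_event_same = sum(
            v for c, v in cond_counts.items() if c in _SAME_CONFIG_CONDITIONS
        )
        n_event_diff = n_event - n_event_same
        n_noevent_same = n_same - n_event_same
        n_noevent_diff = (n - n_same) - n_event_diff
        if n_noevent_same < 0 or n_noevent_diff < 0:
            raise ValueError("configuration split incompatible with condition counts")
        if n_event % len(self.event_bins_ms):
            raise ValueError("event trials must divide evenly across event bins")
        return {
            "n_event": n_event,
            "n_noevent": n - n_event,
            "n_late": n_late,
            "n_precue": n_precue,
            "n_noevent_same": n_noevent_same,
            "n_noevent_diff": n_noevent_diff,
            **{f"n_{c}": v for c, v in cond_counts.items()},
        }

    def validate(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if len(self.palette) != 5:
            raise ValueError("palette must contain exactly 5 colors")
        if self.baseline_color not in self.palette:
            raise ValueError("baseline color must be a member of the palette")
        if set(self.frequencies_by_position) != set(POSITIONS):
            raise ValueError("frequencies must map every arc position exactly once")
        if len(set(self.frequencies_by_position.values())) != 4:
            raise ValueError("each arc needs a distinct flicker frequency")
        lo, hi = 0.0, self.postcue_duration_ms
        flat = sorted(self.event_bins_ms)
        for (a0, a1), (b0, b1) in zip(flat, flat[1:]):
            if a1 > b0:
                raise ValueError("event bins must be disjoint")
        for a, b in flat:
            if a < lo or b > hi or a >= b:
                raise ValueError("event bins must lie inside the post-cue window")
        if self.n_trials:
            self.counts()


@dataclass
class TrialSchedule:
    """Per-trial experiment schedule.

    ``trials`` holds one row per trial with the cue position, color
    configuration, per-arc colors, event condition/time, late-event and
    pre-cue-event bookkeeping, and the jittered pre-cue duration.
    """

    trials: pd.DataFrame
    params: DesignParams

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def event_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["has_postcue_event"]]

    @property
    def no_event_trials(self) -> pd.DataFrame:
        """Trials without post-cue events (the only trials entering SSVEP analysis)."""
        return self.trials[~self.trials["has_postcue_event"]]

    # -- serialization --------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the schedule as tidy CSV plus a JSON parameter sidecar."""
        path = Path(path)
        self.trials.to_csv(path, index=False)
        params = asdict(self.params)
        params["condition_probs"] = dict(params["condition_probs"])
        params["frequencies_by_position"] = dict(params["frequencies_by_position"])
        params["event_bins_ms"] = [list(b) for b in params["event_bins_ms"]]
        params["palette"] = list(params["palette"])
        path.with_suffix(".params.json").write_text(json.dumps(params, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialSchedule":
        path = Path(path)
        trials = pd.read_csv(path)
        raw = json.loads(path.with_suffix(".params.json").read_text())
        raw["event_bins_ms"] = [tuple(b) for b in raw["event_bins_ms"]]
        raw["palette"] = tuple(raw["palette"])
        raw["late_event_window_ms"] = tuple(raw["late_event_window_ms"])
        params = DesignParams(**raw)
        return cls(trials=trials, params=params)


# ----------------------------------------------------------------------
def assign_colors(
    trial: Mapping,
    palette: Sequence[str],
    baseline_color: str,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Assign a post-cue color to each arc for one trial.

    The cued arc draws its color uniformly from the four non-baseline
    palette entries.  In the different-color configuration all four
    arcs receive distinct colors; in the same-color configuration the
    arc on the trial's ``match_side`` duplicates the cued color and the
    remaining two arcs receive distinct colors from the rest of the
    palette.
    """
    if len(palette) != 5:
        raise ValueError("palette must contain exactly 5 colors")
    arc_colors = [c for c in palette if c != baseline_color]
    if len(arc_colors) != 4:
        raise ValueError("baseline color must appear exactly once in the palette")
    cue = int(trial["cue_pos_idx"])
    cued_color = arc_colors[rng.integers(4)]
    rest = [c for c in arc_colors if c != cued_color]
    out = {}
    if trial["config"] == "different":
        perm = list(rng.permutation(rest))
        for idx in range(4):
            out[POSITIONS[idx]] = cued_color if idx == cue else perm.pop()
    else:
        ccw, cw = adjacent_positions(cue)
        match_idx = cw if trial["match_side"] == "cw" else ccw
        others = [i for i in range(4) if i not in (cue, match_idx)]
        picks = list(rng.choice(rest, size=2, replace=False))
        for idx in range(4):
            if idx in (cue, match_idx):
                out[POSITIONS[idx]] = cued_color
            else:
                out[POSITIONS[idx]] = picks[others.index(idx)]
    return out


def _cyclic_positions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n cue positions, balanced to within one count, random phase."""
    start = int(rng.integers(4))
    return (start + np.arange(n)) % 4


def build_schedule(params: DesignParams | None = None) -> TrialSchedule:
    """Construct the full randomized trial schedule.

    Allocation is exact-count: every trial class receives the integer
    number of trials its proportion implies, and the resulting list is
    shuffled by ``params.seed``.  Late events occur only in
    post-cue-event trials, between 800 and 1850 ms but at least 800 ms
    after the first event, uniformly at the cued or an adjacent arc.
    """
    params = params or DesignParams()
    params.validate()
    columns = [
        "trial", "cue_position", "cue_pos_idx", "config", "condition",
        "has_postcue_event", "event_time_ms", "event_position",
        "has_late_event", "late_time_ms", "late_position",
        "has_precue_event", "precue_time_ms", "precue_duration_ms",
        "match_side", "match_position",
        *[f"color_{p}" for p in POSITIONS],
    ]
    if params.n_trials == 0:
        return TrialSchedule(pd.DataFrame(columns=columns), params)

    rng = np.random.default_rng(params.seed)
    counts = params.counts()

    rows: list[dict] = []
    groups: list[tuple[str, str, int]] = [
        (c, "same" if c in _SAME_CONFIG_CONDITIONS else "different", counts[f"n_{c}"])
        for c in params.condition_probs
    ]
    groups.append(("none", "same", counts["n_noevent_same"]))
    groups.append(("none", "different", counts["n_noevent_diff"]))
    for condition, config, n in groups:
        cues = _cyclic_positions(n, rng)
        for cue in cues:
            rows.append(
                {
                    "cue_pos_idx": int(cue),
                    "config": config,
                    "condition": condition,
                    "has_postcue_event": condition != "none",
                }
            )

    # event-time bins: exactly one third of event trials per bin
    event_rows = [r for r in rows if r["has_postcue_event"]]
    n_event = len(event_rows)
    bins = np.repeat(np.arange(len(params.event_bins_ms)), n_event // len(params.event_bins_ms))
    bins = rng.permutation(bins)
    for r, b in zip(event_rows, bins):
        lo, hi = params.event_bins_ms[b]
        r["event_time_ms"] = float(rng.uniform(lo, hi))

    # late events in exactly n_late event trials
    late_idx = rng.choice(n_event, size=counts["n_late"], replace=False)
    for i in late_idx:
        r = event_rows[i]
        w0, w1 = params.late_event_window_ms
        lo = max(w0, r["event_time_ms"] + params.late_event_min_gap_ms)
        r["has_late_event"] = True
        r["late_time_ms"] = float(rng.uniform(lo, w1))
        ccw, cw = adjacent_positions(r["cue_pos_idx"])
        r["late_position"] = POSITIONS[
            int(rng.choice([r["cue_pos_idx"], ccw, cw]))
        ]

    # pre-cue events in exactly n_precue trials (any trial class)
    pre_idx = rng.choice(len(rows), size=counts["n_precue"], replace=False)
    for i in pre_idx:
        rows[i]["has_precue_event"] = True

    # balanced match-side allocation per (condition, cue position) so the
    # same-colored arc lands clockwise/counterclockwise in equal counts
    same_groups: dict[tuple, list[dict]] = {}
    for r in rows:
        if r["config"] == "same":
            same_groups.setdefault((r["condition"], r["cue_pos_idx"]), []).append(r)
    for lst in same_groups.values():
        sides = ["cw"] * (len(lst) // 2) + ["ccw"] * (len(lst) - len(lst) // 2)
        for r, s in zip(lst, rng.permutation(np.array(sides))):
            r["match_side"] = str(s)

    for r in rows:
        r.setdefault("has_late_event", False)
        r.setdefault("late_time_ms", np.nan)
        r.setdefault("late_position", None)
        r.setdefault("has_precue_event", False)
        r.setdefault("event_time_ms", np.nan)
        dur = params.precue_duration_ms + rng.uniform(
            -params.precue_jitter_ms, params.precue_jitter_ms
        )
        r["precue_duration_ms"] = float(dur)
        if r["has_precue_event"]:
            # the fixation-cross event must fit inside the pre-cue period
            r["precue_time_ms"] = float(rng.uniform(-(dur - 100.0), -150.0))
        else:
            r["precue_time_ms"] = np.nan

        cue = r["cue_pos_idx"]
        ccw, cw = adjacent_positions(cue)
        if r["config"] == "same":
            r["match_position"] = POSITIONS[cw if r["match_side"] == "cw" else ccw]
        else:
            r["match_side"] = None
            r["match_position"] = None
        colors = assign_colors(r, params.palette, params.baseline_color, rng)
        for p in POSITIONS:
            r[f"color_{p}"] = colors[p]

        cond = r["condition"]
        if cond in ("val", "val_match"):
            r["event_position"] = POSITIONS[cue]
        elif cond == "inval":
            r["event_position"] = POSITIONS[int(rng.choice([ccw, cw]))]
        elif cond == "inval_match":
            r["event_position"] = r["match_position"]
        elif cond == "inval_non_match":
            non_match = cw if r["match_side"] == "ccw" else ccw
            r["event_position"] = POSITIONS[non_match]
        else:
            r["event_position"] = None
        r["cue_position"] = POSITIONS[cue]

    order = rng.permutation(len(rows))
    trials = pd.DataFrame([rows[i] for i in order])
    trials["trial"] = np.arange(len(trials))
    trials = trials[columns]
    return TrialSchedule(trials=trials, params=params)
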