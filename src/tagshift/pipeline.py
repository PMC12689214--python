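"""End-to-end orchestration of synthetic studies.

Chains the full analysis for one subject (schedule -> synthetic EEG ->
cleaning -> electrode selection -> Gabor envelopes -> percent
modulation) and for a group of subjects, and bundles the group-level
statistics (cluster-permutation tests against baseline and between
conditions, the Bayes-factor time course for the cued vs uncued
same-colored contrast, jackknife onsets, window-averaged contrasts,
and the behavioral analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import inference
from .design import DesignParams, TrialSchedule, build_schedule
from .envelope import CONDITIONS, ModulationTimecourse, subject_modulation
from .montage import MontageLayout, default_montage
from .preprocess import clean_epochs
from .simulate import GroundTruthEnvelope, generate_subject, simulate_behavior


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_subject(
    seed: int,
    design_params: DesignParams | None = None,
    truth: GroundTruthEnvelope | None = None,
    montage: MontageLayout | None = None,
    noise: Mapping[str, float] | None = None,
    apply_csd: bool = True,
    z_threshold: float = 3.0,
    eog_threshold_uv: float = 25.0,
) -> tuple[ModulationTimecourse, pd.DataFrame]:
    """Simulate and analyze a single subject.

    EEG is generated for the trials without post-cue events only (the
    trials entering the SSVEP analysis); behavior is simulated from
    the full schedule.  Returns the per-condition percent-modulation
    time course and the behavior table.
    """
    montage = montage or default_montage()
    params = dc_replace(design_params or DesignParams(), seed=seed)
    s_rec, s_beh, s_pool = _child_seeds(seed, 3)
    schedule = build_schedule(params)

    no_event = TrialSchedule(
        schedule.no_event_trials.reset_index(drop=True), params
    )
    rec = generate_subject(no_event, truth, montage, noise, seed=s_rec)
    clean = clean_epochs(
        rec, z_threshold=z_threshold, eog_threshold_uv=eog_threshold_uv,
        apply_csd=apply_csd,
    )
    rows = no_event.trials.iloc[clean.retained].reset_index(drop=True)
    tc = subject_modulation(
        clean.data, rows, montage, clean.times, fs=rec.fs,
        frequencies_by_position=params.frequencies_by_position, seed=s_pool,
    )
    beh = simulate_behavior(schedule, seed=s_beh)
    return tc, beh


@dataclass
class StudyResult:
    """Group-level modulation traces and pooled behavior."""

    times: np.ndarray
    traces: dict[str, np.ndarray]  # condition -> (subjects, time)
    behavior: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return next(iter(self.traces.values())).shape[0]

    def traces_frame(self) -> pd.DataFrame:
        rows = []
        for cond, arr in self.traces.items():
            for s in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "subject": s, "condition": cond,
                    "time_ms": self.times * 1000.0, "modulation_pct": arr[s],
                }))
        return pd.concat(rows, ignore_index=True)


def run_study(
    n_subjects: int = 12,
    seed: int = 0,
    design_params: DesignParams | None = None,
    truth: GroundTruthEnvelope | None = None,
    noise: Mapping[str, float] | None = None,
    apply_csd: bool = True,
) -> StudyResult:
    """Simulate and analyze ``n_subjects`` subjects."""
    montage = default_montage()
    seeds = _child_seeds(seed, n_subjects)
    traces: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    behs = []
    times = None
    for s, sub_seed in enumerate(seeds):
        tc, beh = run_subject(
            sub_seed, design_params=design_params, truth=truth,
            montage=montage, noise=noise, apply_csd=apply_csd,
        )
        times = tc.times
        for c in CONDITIONS:
            traces[c].append(tc.traces[c])
        beh.insert(0, "subject", s)
        behs.append(beh)
    return StudyResult(
        times=times,
        traces={c: np.vstack(v) for c, v in traces.items()},
        behavior=pd.concat(behs, ignore_index=True),
    )


#: running-test condition contrasts (one-tailed, direction first > second)
STUDY_CONTRASTS = (
    ("cued_match", "uncued_match"),
    ("cued_match", "uncued_non_match"),
    ("uncued_match", "uncued_non_match"),
    ("cued", "uncued"),
)


def analyze_study(
    study: StudyResult,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    test_window: tuple[float, float] = (0.0, 1.5),
) -> dict:
    """Group statistics of a study: cluster tests, BFs, onsets, behavior."""
    times = study.times
    m = (times >= test_window[0] - 1e-9) & (times <= test_window[1] + 1e-9)
    t_win = times[m]

    vs_baseline = {
        c: inference.running_cluster_test(
            arr[:, m], times=t_win, tail="greater", alpha=alpha,
            n_perm=n_perm, seed=seed,
        )
        for c, arr in study.traces.items()
    }
    between = {
        f"{a}_vs_{b}": inference.running_cluster_test(
            study.traces[a][:, m], study.traces[b][:, m], times=t_win,
            tail="greater", alpha=alpha, n_perm=n_perm, seed=seed,
        )
        for a, b in STUDY_CONTRASTS
    }
    bf_tc = inference.running_bf(
        study.traces["cued_match"][:, m], study.traces["uncued_match"][:, m],
        times=t_win,
    )
    onsets = {
        c: inference.jackknife_onsets(study.traces[c][:, m], t_win)
        for c in ("uncued_match", "uncued")
    }
    onset_test = inference.compare_onsets(onsets["uncued_match"], onsets["uncued"])
    window = inference.window_contrasts(study.traces, times)
    beh = behavior_mod.rt_condition_analysis(
        behavior_mod.filter_rts(study.behavior)
    )
    rates = behavior_mod.performance_rates(study.behavior)
    return {
        "vs_baseline": vs_baseline,
        "between": between,
        "bf_timecourse": bf_tc,
        "onsets": onsets,
        "onset_test": onset_test,
        "window_contrasts": window,
        "behavior": beh,
        "rates": rates,
    }
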