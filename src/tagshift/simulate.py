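"""Synthetic frequency-tagged EEG and behavior with known ground truth.

Each trial superimposes four sinusoids at the arc flicker frequencies
(18/21/24/27 Hz), phase-locked to cue onset, with posterior-lateralized
scalp topographies contralateral to the arc's hemifield.  The amplitude
of each sinusoid follows a condition-specific envelope: constant at a
baseline level before the cue, then a logistic rise to a plateau gain
with an optional late linear decay, depending on whether the arc is
cued, shares the cued color, or is uncued.  1/f^alpha background noise
is added independently per trial and channel, so that single-trial SNR
at the tag frequencies is below one and trial averaging matters, as in
real recordings.

Behavioral responses (hits with condition-specific reaction times,
lapses, false alarms) are simulated per trial from the same schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import POSITIONS, TrialSchedule, diagonal_position
from .montage import MontageLayout, default_montage

#: channel on which each tag frequency's topography peaks (contralateral
#: posterior scalp: right-hemifield arcs drive the left hemisphere).
TOPO_CENTER = {
    "upper_right": "PO7",
    "lower_right": "O1",
    "lower_left": "O2",
    "upper_left": "PO8",
}


@dataclass(frozen=True)
class ConditionDynamics:
    """Amplitude dynamics of one attention condition.

    The envelope (in percent gain over ``baseline_uv``) rises
    logistically with half-rise time ``half_rise_ms`` and time constant
    ``rise_tau_ms`` to ``gain_pct``, then decays linearly at
    ``decay_rate_pct_s`` after ``decay_start_ms``.
    """

    baseline_uv: float = 1.0
    gain_pct: float = 0.0
    half_rise_ms: float = 400.0
    rise_tau_ms: float = 80.0
    decay_start_ms: float = 1600.0
    decay_rate_pct_s: float = 0.0

    def gain(self, t_ms: np.ndarray) -> np.ndarray:
        """Percent gain over baseline at times ``t_ms`` (cue at 0)."""
        t = np.asarray(t_ms, dtype=float)
        from scipy.special import expit

        g = self.gain_pct * expit((t - self.half_rise_ms) / self.rise_tau_ms)
        decay = np.clip(t - self.decay_start_ms, 0.0, None) / 1000.0
        g = g - self.decay_rate_pct_s * decay
        return np.where(t >= 0.0, g, 0.0)

    def amplitude(self, t_ms: np.ndarray) -> np.ndarray:
        """Envelope amplitude in microvolts."""
        a = self.baseline_uv * (1.0 + self.gain(t_ms) / 100.0)
        if np.any(a <= 0):
            raise ValueError("envelope must remain strictly positive")
        return a

    def onset_at_criterion(self, criterion: float = 0.85) -> float:
        """Time (ms) at which the rising gain reaches ``criterion`` x plateau.

        Closed form of the logistic rise, ignoring the late decay; used
        as ground truth for onset-recovery checks.
        """
        if not 0 < criterion < 1:
            raise ValueError("criterion must be in (0, 1)")
        return self.half_rise_ms + self.rise_tau_ms * np.log(criterion / (1 - criterion))


#: the five analyzed conditions plus the unanalyzed diagonal arc
ENVELOPE_CONDITIONS = (
    "cued_match", "cued", "uncued_match", "uncued_non_match", "uncued", "diagonal",
)


@dataclass(frozen=True)
class GroundTruthEnvelope:
    """Per-condition amplitude dynamics driving the generator.

    Defaults encode the qualitative pattern of the experiment's
    grand-average time courses: strong, early enhancement for the cued
    arc in both configurations, an early enhancement of the uncued arc
    sharing the cued color, a late and weak enhancement of uncued
    non-matching arcs, and a mild decay late in the trial.
    """

    conditions: Mapping[str, ConditionDynamics] = field(
        default_factory=lambda: {
            "cued_match": ConditionDynamics(1.0, 30.0, 350.0, 80.0, 1400.0, 10.0),
            "cued": ConditionDynamics(1.0, 30.0, 350.0, 80.0, 1400.0, 10.0),
            "uncued_match": ConditionDynamics(1.0, 18.0, 350.0, 80.0, 1400.0, 8.0),
            "uncued_non_match": ConditionDynamics(1.0, 10.0, 900.0, 100.0, 1600.0, 5.0),
            "uncued": ConditionDynamics(1.0, 14.0, 700.0, 100.0, 1600.0, 6.0),
            "diagonal": ConditionDynamics(1.0, 0.0),
        }
    )

    def __getitem__(self, condition: str) -> ConditionDynamics:
        return self.conditions[condition]

    def flat(self, baseline_uv: float = 1.0) -> "GroundTruthEnvelope":
        """A copy with all gains zeroed (constant envelopes)."""
        return GroundTruthEnvelope(
            {c: ConditionDynamics(baseline_uv=baseline_uv) for c in self.conditions}
        )


@dataclass
class SubjectRecording:
    """Epoched multichannel EEG for one subject.

    ``data`` is (trials, channels, samples) in microvolts at ``fs`` Hz;
    epochs run from ``tmin`` to ``tmax`` seconds around cue onset, with
    the cue at sample ``cue_index``.  Flicker phase is locked to cue
    onset in every trial.
    """

    data: np.ndarray
    fs: float
    tmin: float
    schedule: TrialSchedule
    montage: MontageLayout
    truth: GroundTruthEnvelope | None = None

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to cue onset."""
        return self.tmin + np.arange(self.data.shape[-1]) / self.fs

    @property
    def cue_index(self) -> int:
        return int(round(-self.tmin * self.fs))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def save_h5(self, path: str | Path) -> None:
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.attrs["fs"] = self.fs
            f.attrs["tmin"] = self.tmin
            f.attrs["channel_names"] = [n.encode() for n in self.montage.names]
        self.schedule.to_csv(path.with_suffix(".schedule.csv"))


def condition_of_arc(row: pd.Series, position: str) -> str:
    """Attention condition of the arc at ``position`` in one trial.

    The cued arc is *cued_match* (same-color configuration) or *cued*;
    adjacent arcs are *uncued_match* / *uncued_non_match* in the
    same-color configuration and *uncued* in the different-color one;
    the diagonal arc is tagged *diagonal* (excluded from analysis).
    """
    pos_idx = POSITIONS.index(position)
    cue = int(row["cue_pos_idx"])
    if pos_idx == cue:
        return "cued_match" if row["config"] == "same" else "cued"
    if pos_idx == diagonal_position(cue):
        return "diagonal"
    if row["config"] == "different":
        return "uncued"
    return "uncued_match" if row["match_position"] == position else "uncued_non_match"


def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                fs: float, exponent: float, rms: float) -> np.ndarray:
    """1/f^alpha noise with the requested RMS, shaped in the Fourier domain."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    std = out.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return out / std * rms


def generate_subject(
    schedule: TrialSchedule,
    truth: GroundTruthEnvelope | None = None,
    montage: MontageLayout | None = None,
    noise: Mapping[str, float] | None = None,
    fs: float = 256.0,
    tmin: float = -1.5,
    tmax: float = 2.2,
    topo_sigma: float = 0.45,
    seed: int = 0,
) -> SubjectRecording:
    """Generate one subject's epoched EEG from a trial schedule.

    ``noise`` keys: ``pink_exponent`` (default 1.0), ``pink_scale``
    (RMS uV of the 1/f background, default 4.0) and ``white_scale``
    (RMS uV of white sensor noise, default 0.5).  Set both scales to 0
    for noiseless data.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    truth = truth or GroundTruthEnvelope()
    montage = montage or default_montage()
    noise = dict(noise or {})
    pink_exp = noise.pop("pink_exponent", 1.0)
    pink_scale = noise.pop("pink_scale", 4.0)
    white_scale = noise.pop("white_scale", 0.5)
    # channel-to-channel spread of noise level (lognormal sigma); EOG
    # derivations are bipolar and carry less background EEG
    ch_sigma = noise.pop("channel_gain_sigma", 0.2)
    eog_scale = noise.pop("eog_noise_scale", 0.4)
    if noise:
        raise ValueError(f"unknown noise parameters: {sorted(noise)}")

    freqs = schedule.params.frequencies_by_position
    if set(freqs) != set(POSITIONS):
        raise ValueError("frequency map must cover exactly the four arc positions")
    for p in freqs:
        if p not in TOPO_CENTER:
            raise ValueError(f"no topography defined for position {p!r}")

    n_samples = int(round((tmax - tmin) * fs)) + 1
    times_s = tmin + np.arange(n_samples) / fs
    t_ms = times_s * 1000.0
    n_ch = len(montage.names)
    rng = np.random.default_rng(seed)

    # spatial weight of each tag frequency on each channel
    topo = np.zeros((len(POSITIONS), n_ch))
    for i, p in enumerate(POSITIONS):
        center = montage.positions[montage.index(TOPO_CENTER[p])]
        d = np.linalg.norm(montage.positions[: montage.n_scalp] - center, axis=1)
        topo[i, : montage.n_scalp] = np.exp(-((d / topo_sigma) ** 2))

    carriers = np.stack(
        [np.sin(2 * np.pi * freqs[p] * times_s) for p in POSITIONS]
    )  # (4, n_samples); phase locked to cue (t=0)

    # per-condition amplitude envelopes, precomputed once
    env = {c: truth[c].amplitude(t_ms) for c in truth.conditions}

    ch_gain = rng.lognormal(0.0, ch_sigma, size=n_ch) if ch_sigma > 0 else np.ones(n_ch)
    ch_gain[montage.n_scalp:] *= eog_scale

    trials = schedule.trials
    data = np.empty((len(trials), n_ch, n_samples))
    for ti, (_, row) in enumerate(trials.iterrows()):
        sig = np.zeros((n_ch, n_samples))
        for ai, p in enumerate(POSITIONS):
            cond = condition_of_arc(row, p)
            sig += np.outer(topo[ai], env[cond] * carriers[ai])
        nz = np.zeros((n_ch, n_samples))
        if pink_scale > 0:
            nz += _pink_noise(rng, (n_ch,), n_samples, fs, pink_exp, pink_scale)
        if white_scale > 0:
            nz += rng.standard_normal((n_ch, n_samples)) * white_scale
        data[ti] = sig + nz * ch_gain[:, None]
    return SubjectRecording(
        data=data, fs=fs, tmin=tmin, schedule=schedule, montage=montage, truth=truth
    )


# ----------------------------------------------------------------------
def inject_artifacts(
    recording: SubjectRecording,
    spec: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[SubjectRecording, dict[str, np.ndarray]]:
    """Add ocular artifacts to a copy of the recording, returning labels.

    ``spec`` keys: ``n_blink_trials``, ``n_saccade_trials``,
    ``blink_amp_uv`` (default 150), ``saccade_step_uv`` (default 40).
    Blinks are smooth pulses on the vertical EOG pair (opposite signs)
    leaking into frontal channels; saccades are step functions on the
    horizontal EOG pair.  Artifact times fall inside the -1000 to
    2000 ms analysis window.  Labels list the contaminated trial
    indices.
    """
    spec = dict(spec or {})
    n_blink = int(spec.pop("n_blink_trials", 0))
    n_sacc = int(spec.pop("n_saccade_trials", 0))
    blink_amp = float(spec.pop("blink_amp_uv", 150.0))
    sacc_step = float(spec.pop("saccade_step_uv", 40.0))
    if spec:
        raise ValueError(f"unknown artifact parameters: {sorted(spec)}")
    if n_blink + n_sacc > recording.n_trials:
        raise ValueError("requested more contaminated trials than available")

    data = recording.data.copy()
    mont = recording.montage
    times = recording.times
    rng = np.random.default_rng(seed)
    picks = rng.choice(recording.n_trials, size=n_blink + n_sacc, replace=False)
    blink_trials, sacc_trials = picks[:n_blink], picks[n_blink:]

    frontal = [n for n in ("Fp1", "Fp2", "AF3", "AF4", "AF7", "AF8") if n in mont.names]
    veog_u, veog_d = mont.index("VEOG_U"), mont.index("VEOG_D")
    heog_l, heog_r = mont.index("HEOG_L"), mont.index("HEOG_R")

    t_lo, t_hi = max(times[0], -0.9), min(times[-1], 1.85)
    for t in blink_trials:
        t0 = rng.uniform(t_lo, t_hi)
        pulse = blink_amp * np.exp(-(((times - t0) / 0.08) ** 2))
        data[t, veog_u] += pulse
        data[t, veog_d] -= 0.6 * pulse
        for name in frontal:
            data[t, mont.index(name)] += 0.4 * pulse
    for t in sacc_trials:
        t0 = rng.uniform(t_lo, t_hi)
        sign = rng.choice([-1.0, 1.0])
        step = sacc_step * sign * (times >= t0)
        data[t, heog_l] += step
        data[t, heog_r] -= step
    out = replace(recording, data=data)
    labels = {
        "blink_trials": np.sort(blink_trials),
        "saccade_trials": np.sort(sacc_trials),
    }
    return out, labels


# ----------------------------------------------------------------------
DEFAULT_RT_MODEL = {
    # base reaction times (ms) encode the observed ordering: valid events
    # fastest, invalid events on the same-colored arc faster than on the
    # differently colored arc.
    "base_ms": {
        "val": 430.0,
        "val_match": 432.0,
        "inval": 475.0,
        "inval_match": 462.0,
        "inval_non_match": 472.0,
    },
    "sd_ms": 60.0,
    "lapse_rate": 0.18,
    "fa_rate": 0.015,
    "precue_base_ms": 420.0,
    "precue_sd_ms": 60.0,
    "precue_lapse_rate": 0.03,
    "precue_fa_rate": 0.001,
}


def simulate_behavior(
    schedule: TrialSchedule,
    rt_model: Mapping | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-trial button presses from the schedule.

    Returns a behavior table with one row per scoreable trial segment:
    post-cue event trials (hit with probability ``1 - lapse_rate``, RT
    Gaussian around the condition base), post-cue no-event trials
    (false alarms at ``fa_rate``), and the pre-cue task (events and
    false alarms analogously).
    """
    model = {**DEFAULT_RT_MODEL, **dict(rt_model or {})}
    base = {**DEFAULT_RT_MODEL["base_ms"], **dict(model["base_ms"])}
    if min(base.values()) < 150.0:
        raise ValueError("base reaction times must be at least 150 ms")
    rng = np.random.default_rng(seed)
    rows = []
    for _, tr in schedule.trials.iterrows():
        # pre-cue task segment
        if tr["has_precue_event"]:
            hit = rng.random() >= model["precue_lapse_rate"]
            rt = float(rng.normal(model["precue_base_ms"], model["precue_sd_ms"])) if hit else np.nan
            rows.append(
                dict(trial=tr["trial"], trial_class="precue_event",
                     condition="precue", event_time_ms=tr["precue_time_ms"],
                     responded=bool(hit), rt_ms=rt)
            )
        else:
            fa = rng.random() < model["precue_fa_rate"]
            rows.append(
                dict(trial=tr["trial"], trial_class="precue_noevent",
                     condition="precue", event_time_ms=np.nan,
                     responded=bool(fa), rt_ms=np.nan)
            )
        # post-cue task segment
        if tr["has_postcue_event"]:
            hit = rng.random() >= model["lapse_rate"]
            rt = rng.normal(base[tr["condition"]], model["sd_ms"]) if hit else np.nan
            rows.append(
                dict(trial=tr["trial"], trial_class="postcue_event",
                     condition=tr["condition"], event_time_ms=tr["event_time_ms"],
                     responded=bool(hit), rt_ms=float(rt) if hit else np.nan)
            )
        else:
            fa = rng.random() < model["fa_rate"]
            rows.append(
                dict(trial=tr["trial"], trial_class="postcue_noevent",
                     condition="none", event_time_ms=np.nan,
                     responded=bool(fa), rt_ms=np.nan)
            )
    return pd.DataFrame(rows)
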