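"""Gabor-energy amplitude envelopes and percent modulation time courses.

The narrowband amplitude of each tag frequency is extracted with a
Gabor-energy filter: a complex Gaussian-windowed sinusoid whose
spectral half-width at half maximum is 1 Hz.  By the Gaussian Fourier
time-bandwidth identity (product of full widths = 4 ln 2 / pi s*Hz)
this implies a temporal half-FWHM of 220.636 ms.  The modulus of the
convolution gives the envelope, with unit gain at the center frequency.

Trials without post-cue events are averaged per cue position in the
time domain first, filtered, averaged across the five selected
electrodes, expressed as percent change from the pre-cue baseline
(-720 to -220 ms, leaving a margin of one temporal half-FWHM to cue
onset so no post-cue samples leak into the baseline), and finally
collapsed across the four tag frequencies per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .design import POSITIONS
from .simulate import condition_of_arc

#: full-width product of a Gaussian and its Fourier transform (s * Hz)
TIME_BANDWIDTH_FWHM = 4.0 * np.log(2.0) / np.pi

#: the five analyzed conditions
CONDITIONS = ("cued_match", "cued", "uncued_match", "uncued_non_match", "uncued")


@dataclass(frozen=True)
class GaborKernel:
    """Complex Gabor-energy kernel.

    ``spectral_half_fwhm_hz`` is the half width at half maximum of the
    Gaussian transfer function (the filter passes +-1 Hz around the
    center at half amplitude by default).
    """

    center_hz: float
    fs: float = 256.0
    spectral_half_fwhm_hz: float = 1.0
    support_sigmas: float = 5.0

    def __post_init__(self) -> None:
        if self.center_hz >= self.fs / 2:
            raise ValueError("center frequency must be below Nyquist")
        if self.center_hz <= 0 or self.spectral_half_fwhm_hz <= 0:
            raise ValueError("frequencies must be positive")

    @property
    def spectral_fwhm_hz(self) -> float:
        return 2.0 * self.spectral_half_fwhm_hz

    @property
    def temporal_fwhm_s(self) -> float:
        """Full temporal FWHM from the Gaussian time-bandwidth identity."""
        return TIME_BANDWIDTH_FWHM / self.spectral_fwhm_hz

    @property
    def temporal_half_fwhm_ms(self) -> float:
        return self.temporal_fwhm_s / 2.0 * 1000.0

    @property
    def sigma_t_s(self) -> float:
        return self.temporal_fwhm_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def samples(self) -> np.ndarray:
        """Complex kernel samples, normalized to unit envelope gain.

        Normalization makes the modulus of the convolution with a
        unit-amplitude real sinusoid at the center frequency equal 1.0
        in steady state.
        """
        half = int(np.ceil(self.support_sigmas * self.sigma_t_s * self.fs))
        t = np.arange(-half, half + 1) / self.fs
        gauss = np.exp(-(t**2) / (2.0 * self.sigma_t_s**2))
        gauss *= 2.0 / gauss.sum()
        return gauss * np.exp(2j * np.pi * self.center_hz * t)

    def transfer(self, freq_hz: np.ndarray) -> np.ndarray:
        """Closed-form Gaussian amplitude transfer at ``freq_hz``."""
        df = np.asarray(freq_hz, dtype=float) - self.center_hz
        return np.exp(-4.0 * np.log(2.0) * (df / self.spectral_fwhm_hz) ** 2)


def gabor_energy(signal: np.ndarray, kernel: GaborKernel) -> np.ndarray:
    """Amplitude envelope: modulus of the complex Gabor convolution.

    Works on the last axis; the signal must be at least as long as the
    kernel support.
    """
    signal = np.asarray(signal, dtype=float)
    k = kernel.samples()
    if signal.shape[-1] < len(k):
        raise ValueError("signal shorter than the kernel support")
    out = sp_signal.fftconvolve(signal, k.reshape((1,) * (signal.ndim - 1) + (-1,)),
                                mode="same", axes=-1)
    return np.abs(out)


# ----------------------------------------------------------------------
def pool_conditions(
    data: np.ndarray,
    schedule_rows: pd.DataFrame,
    frequencies_by_position: Mapping[str, float] | None = None,
    seed: int = 0,
) -> dict[float, dict[str, dict]]:
    """Average trials per tag frequency and attention condition.

    ``data`` is (trials, channels, samples) aligned row-for-row with
    ``schedule_rows``; only trials without post-cue events may be
    passed.  For each tag frequency the five analyzed conditions are
    formed from the cue position and color configuration of each trial
    (the diagonal arc never contributes).  Uncued conditions pool the
    clockwise and counterclockwise arrangements; the *uncued* condition
    of the different-color configuration is built from a seeded 50 %
    subsample without replacement to equalize trial counts (and hence
    SNR) across conditions.

    Returns ``{freq: {condition: {"mean": (channels, samples),
    "n_trials": int, "trials": indices}}}``.
    """
    from .design import FREQUENCIES_BY_POSITION

    freqs = dict(frequencies_by_position or FREQUENCIES_BY_POSITION)
    if schedule_rows["has_postcue_event"].any():
        raise ValueError("only trials without post-cue events may be pooled")
    rng = np.random.default_rng(seed)
    out: dict[float, dict[str, dict]] = {}
    rows = schedule_rows.reset_index(drop=True)
    for pos in POSITIONS:
        f = freqs[pos]
        groups: dict[str, list[int]] = {c: [] for c in CONDITIONS}
        for i, row in rows.iterrows():
            cond = condition_of_arc(row, pos)
            if cond in groups:
                groups[cond].append(i)
        # seeded 50 % subsample of the uncued pool (it is ~2x the others)
        unc = np.array(groups["uncued"], dtype=int)
        n_half = len(unc) // 2
        groups["uncued"] = list(np.sort(rng.choice(unc, size=n_half, replace=False)))
        out[f] = {}
        for cond, idx in groups.items():
            if not idx:
                raise ValueError(
                    f"condition {cond!r} has zero trials at {f} Hz"
                )
            out[f][cond] = {
                "mean": data[idx].mean(axis=0),
                "n_trials": len(idx),
                "trials": np.asarray(idx),
            }
    return out


def percent_modulation(
    envelope: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float] = (-0.72, -0.22),
) -> np.ndarray:
    """Percent change of an envelope versus its pre-cue baseline mean.

    ``100 * (A(t) - mean(A_baseline)) / mean(A_baseline)``, computed on
    the last axis.  The baseline window must end before cue onset.
    """
    lo, hi = baseline_window
    if hi > 0:
        raise ValueError("baseline window must end before cue onset")
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not mask.any():
        raise ValueError("baseline window not inside the epoch")
    base = np.asarray(envelope)[..., mask].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline envelope mean must be positive")
    return 100.0 * (envelope - base) / base


@dataclass
class ModulationTimecourse:
    """Per-condition percent-modulation traces for one subject."""

    times: np.ndarray
    traces: dict[str, np.ndarray]  # condition -> (samples,)
    baseline_window: tuple[float, float] = (-0.72, -0.22)
    selections: dict = field(default_factory=dict)

    def to_frame(self, subject: str | int = 0) -> pd.DataFrame:
        rows = []
        for cond, tr in self.traces.items():
            rows.append(pd.DataFrame({
                "subject": subject, "condition": cond,
                "time_ms": self.times * 1000.0, "modulation_pct": tr,
            }))
        return pd.concat(rows, ignore_index=True)


def subject_modulation(
    clean_data: np.ndarray,
    schedule_rows: pd.DataFrame,
    montage,
    times: np.ndarray,
    fs: float = 256.0,
    frequencies_by_position: Mapping[str, float] | None = None,
    baseline_window: tuple[float, float] = (-0.72, -0.22),
    spectrum_window: tuple[float, float] = (-1.0, 2.0),
    seed: int = 0,
    average_channels_after_filter: bool = True,
) -> ModulationTimecourse:
    """Full per-subject envelope pipeline.

    Pools trials into condition averages per tag frequency, selects the
    individual best posterior electrode (plus 4 neighbors) from the
    condition-averaged amplitude spectrum, Gabor-filters each condition
    average, averages the envelope across the selected channels
    (filtering precedes channel averaging by default), converts to
    percent change versus the pre-cue baseline per frequency, and
    collapses across the four frequencies per condition.
    """
    from .design import FREQUENCIES_BY_POSITION
    from .spectral import amplitude_spectrum, select_electrodes

    freqs = dict(frequencies_by_position or FREQUENCIES_BY_POSITION)
    pooled = pool_conditions(clean_data, schedule_rows, freqs, seed=seed)

    per_freq_pct: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    selections = {}
    for f, conds in pooled.items():
        # electrode selection from the all-condition average spectrum
        grand = np.mean([v["mean"] for v in conds.values()], axis=0)
        spec = amplitude_spectrum(
            grand, fs, times=times, window=spectrum_window,
            channel_names=montage.names,
        )
        sel = select_electrodes(spec, montage, f)
        selections[f] = sel
        ch_idx = [montage.index(c) for c in sel.channels]
        kernel = GaborKernel(center_hz=f, fs=fs)
        for cond, v in conds.items():
            if average_channels_after_filter:
                env = gabor_energy(v["mean"][ch_idx], kernel).mean(axis=0)
            else:
                env = gabor_energy(v["mean"][ch_idx].mean(axis=0), kernel)
            per_freq_pct[cond].append(
                percent_modulation(env, times, baseline_window)
            )
    traces = {c: np.mean(v, axis=0) for c, v in per_freq_pct.items()}
    return ModulationTimecourse(
        times=times, traces=traces, baseline_window=baseline_window,
        selections=selections,
    )
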