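"""Epoch cleaning: detrending, ocular rejection, bad channels, CSD.

The cleaning chain mirrors a standard SSVEP preprocessing pipeline:
per-trial linear detrending over the analysis window, rejection of
trials with blinks or eye movements exceeding 25 uV on the EOG
derivations, per-trial detection of noisy channels by z-scored channel
statistics (variance, maximal gradient, amplitude range) with
spherical-spline interpolation of the flagged channels, discarding of
trials with more than 15 interpolated channels, and finally the scalp
current density (surface Laplacian) transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import _sphspline
from .design import TrialSchedule
from .montage import MontageLayout
from .simulate import SubjectRecording

#: rejection-log reasons
REASONS = ("blink", "eye_movement", "too_many_bad_channels", "majority_bad_channels")


@dataclass
class CleanEpochSet:
    """Result of the cleaning chain.

    ``data`` holds the retained trials; ``retained`` maps them back to
    the original trial rows.  ``rejection_log`` has one row per removed
    trial with its reason; ``interpolated`` lists, per retained trial,
    the channels that were spline-interpolated.
    """

    data: np.ndarray  # (retained trials, channels, samples)
    times: np.ndarray
    fs: float
    retained: np.ndarray  # original trial indices
    rejection_log: pd.DataFrame  # columns: trial, reason
    interpolated: list[list[str]] = field(default_factory=list)
    csd_applied: bool = False

    @property
    def n_retained(self) -> int:
        return self.data.shape[0]


def _window_slice(times: np.ndarray, window: tuple[float, float]) -> slice:
    lo, hi = window
    idx = np.where((times >= lo - 1e-9) & (times <= hi + 1e-9))[0]
    if idx.size < 2:
        raise ValueError(f"window {window} not inside epoch")
    return slice(idx[0], idx[-1] + 1)


def detrend_epochs(epochs: np.ndarray, window: slice | None = None) -> np.ndarray:
    """Remove a least-squares line per trial and channel.

    If ``window`` is given, the line is fitted on that sample range but
    removed from the full epoch.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.shape[-1] < 2:
        raise ValueError("need at least 2 samples to detrend")
    if window is None:
        return sp_signal.detrend(epochs, axis=-1, type="linear")
    n = epochs.shape[-1]
    t = np.arange(n, dtype=float)
    tw = t[window]
    x = np.column_stack([np.ones_like(tw), tw])
    beta = np.linalg.lstsq(x, np.moveaxis(epochs[..., window], -1, 0).reshape(len(tw), -1),
                           rcond=None)[0]
    fit = np.column_stack([np.ones_like(t), t]) @ beta
    return epochs - np.moveaxis(fit.reshape(n, *epochs.shape[:-1]), 0, -1)


def _smooth(x: np.ndarray, fs: float, width_s: float = 0.05) -> np.ndarray:
    w = max(int(round(width_s * fs)), 1)
    kernel = np.ones(w) / w
    return np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), -1, x)


def reject_ocular(
    epochs: np.ndarray,
    times: np.ndarray,
    fs: float,
    montage: MontageLayout,
    threshold_uv: float = 25.0,
    window: tuple[float, float] = (-1.0, 2.0),
) -> pd.DataFrame:
    """Flag trials with blinks or eye movements on the EOG derivations.

    The vertical derivation (VEOG_U - VEOG_D) detects blinks, the
    horizontal derivation (HEOG_L - HEOG_R) eye movements; a trial is
    flagged when the smoothed peak-to-peak amplitude of the derivation
    exceeds ``threshold_uv`` inside ``window``.  Returns a DataFrame
    with per-trial ``blink`` / ``eye_movement`` flags; blink takes
    precedence in the combined ``reason`` column.
    """
    for ch in ("VEOG_U", "VEOG_D", "HEOG_L", "HEOG_R"):
        if ch not in montage.names:
            raise ValueError(f"EOG channel {ch} missing from montage")
    sl = _window_slice(times, window)
    veog = epochs[:, montage.index("VEOG_U"), sl] - epochs[:, montage.index("VEOG_D"), sl]
    heog = epochs[:, montage.index("HEOG_L"), sl] - epochs[:, montage.index("HEOG_R"), sl]
    veog = _smooth(veog, fs)
    heog = _smooth(heog, fs)
    blink = veog.max(axis=-1) - veog.min(axis=-1) > threshold_uv
    move = heog.max(axis=-1) - heog.min(axis=-1) > threshold_uv
    reason = np.where(blink, "blink", np.where(move, "eye_movement", ""))
    return pd.DataFrame(
        {"trial": np.arange(len(epochs)), "blink": blink, "eye_movement": move,
         "reason": reason}
    )


def _robust_z(stats: np.ndarray) -> np.ndarray:
    """z-scores versus the channel population (median / scaled MAD)."""
    med = np.median(stats, axis=-1, keepdims=True)
    mad = np.median(np.abs(stats - med), axis=-1, keepdims=True) * 1.4826
    dev = stats - med
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(mad > 0, dev / np.where(mad > 0, mad, 1.0), np.where(dev == 0, 0.0, np.inf))
    return z


def detect_and_interpolate_bad_channels(
    epochs: np.ndarray,
    montage: MontageLayout,
    z_threshold: float = 3.0,
    max_interpolated: int = 15,
    window: slice | None = None,
) -> tuple[np.ndarray, list[list[str]], np.ndarray]:
    """Per-trial detection and spline interpolation of noisy channels.

    Channel statistics (standard deviation, maximal absolute gradient,
    amplitude range) are z-scored against the scalp-channel population
    of the same trial; channels exceeding ``z_threshold`` on any
    statistic are replaced by spherical-spline interpolation from the
    remaining scalp channels.  Trials with more than
    ``max_interpolated`` bad channels are marked for discarding, with a
    distinct reason when the majority of channels is bad.

    Returns ``(cleaned, interpolated_names, discard_reason)`` where
    ``discard_reason`` is an object array with '' for retained trials.
    """
    epochs = np.asarray(epochs, dtype=float)
    n_trials, n_ch, _ = epochs.shape
    if n_ch != len(montage.names):
        raise ValueError("channel count does not match montage")
    scalp = montage.scalp_indices
    seg = epochs[:, scalp, :] if window is None else epochs[:, scalp, window]
    stats = np.stack(
        [
            seg.std(axis=-1),
            np.abs(np.diff(seg, axis=-1)).max(axis=-1),
            seg.max(axis=-1) - seg.min(axis=-1),
        ],
        axis=1,
    )  # (trials, 3, n_scalp)
    z = _robust_z(stats)
    bad = (z > z_threshold).any(axis=1)  # (trials, n_scalp)

    # Across-channel z-scores break down once most channels are corrupted
    # (the median moves into the artifact); a trial whose median channel
    # power is grossly deviant versus the other trials is discarded whole.
    med_std = np.median(seg.std(axis=-1), axis=-1)
    majority_bad = _robust_z(med_std) > 5.0 * z_threshold

    cleaned = epochs.copy()
    interpolated: list[list[str]] = []
    discard = np.full(n_trials, "", dtype=object)
    pos = montage.scalp_positions
    interp_cache: dict[tuple, np.ndarray] = {}
    for t in range(n_trials):
        bad_idx = np.where(bad[t])[0]
        interpolated.append([montage.scalp_names[i] for i in bad_idx])
        if majority_bad[t] or bad_idx.size > len(scalp) // 2:
            discard[t] = "majority_bad_channels"
            continue
        if bad_idx.size == 0:
            continue
        if bad_idx.size > max_interpolated:
            discard[t] = "too_many_bad_channels"
            continue
        key = tuple(bad_idx)
        if key not in interp_cache:
            good_idx = np.setdiff1d(np.arange(len(scalp)), bad_idx)
            m = _sphspline.interpolation_matrix(pos[good_idx], pos[bad_idx])
            interp_cache[key] = m
        good_idx = np.setdiff1d(np.arange(len(scalp)), bad_idx)
        cleaned[t, scalp[bad_idx], :] = interp_cache[key] @ epochs[t, scalp[good_idx], :]
    return cleaned, interpolated, discard


def csd_transform(
    epochs: np.ndarray,
    montage: MontageLayout,
    m: int = 4,
    lam: float = 1e-5,
    n_legendre: int = 50,
    head_radius_m: float = 0.095,
) -> np.ndarray:
    """Spherical-spline surface Laplacian of the scalp channels.

    Input in microvolts; scalp channels are returned in uV/m^2 while
    EOG channels are passed through unchanged.  The transform is linear
    and maps spatially uniform potentials to zero.
    """
    epochs = np.asarray(epochs, dtype=float)
    if montage.n_scalp < 32:
        raise ValueError("CSD requires at least 32 scalp channels")
    lap = _sphspline.csd_matrix(
        montage.scalp_positions, m=m, lam=lam, n_legendre=n_legendre,
        head_radius_m=head_radius_m,
    )
    out = epochs.copy()
    scalp = montage.scalp_indices
    out[..., scalp, :] = np.einsum("ij,...js->...is", lap, epochs[..., scalp, :])
    return out


# ----------------------------------------------------------------------
def clean_epochs(
    recording: SubjectRecording,
    z_threshold: float | None = 3.0,
    eog_threshold_uv: float = 25.0,
    apply_csd: bool = True,
    analysis_window: tuple[float, float] = (-1.0, 2.0),
    max_interpolated: int = 15,
) -> CleanEpochSet:
    """Run the full cleaning chain on a subject recording.

    ``z_threshold=None`` skips bad-channel detection (appropriate for
    noiseless synthetic data, where the across-channel statistics the
    detector compares are degenerate).
    """
    times = recording.times
    mont = recording.montage
    sl = _window_slice(times, analysis_window)
    data = detrend_epochs(recording.data, window=sl)

    ocular = reject_ocular(
        data, times, recording.fs, mont, threshold_uv=eog_threshold_uv,
        window=analysis_window,
    )
    keep = ocular["reason"].to_numpy() == ""
    log_rows = [
        {"trial": int(t), "reason": r}
        for t, r in zip(ocular["trial"], ocular["reason"]) if r
    ]

    kept_idx = np.where(keep)[0]
    if z_threshold is None:
        cleaned = data[kept_idx]
        interp = [[] for _ in kept_idx]
        discard = np.full(len(kept_idx), "", dtype=object)
    else:
        cleaned, interp, discard = detect_and_interpolate_bad_channels(
            data[kept_idx], mont, z_threshold=z_threshold,
            max_interpolated=max_interpolated, window=sl,
        )
    final_keep = discard == ""
    for t, r in zip(kept_idx[~final_keep], discard[~final_keep]):
        log_rows.append({"trial": int(t), "reason": r})
    retained = kept_idx[final_keep]
    out = cleaned[final_keep]
    interp = [lst for lst, k in zip(interp, final_keep) if k]

    if apply_csd:
        out = csd_transform(out, mont)
    log = pd.DataFrame(log_rows, columns=["trial", "reason"]).sort_values("trial")
    return CleanEpochSet(
        data=out, times=times, fs=recording.fs, retained=retained,
        rejection_log=log.reset_index(drop=True), interpolated=interp,
        csd_applied=apply_csd,
    )


def read_bdf_epochs(path, schedule: TrialSchedule = None, **kwargs):  # pragma: no cover
    """Optional ingestion of real BioSemi BDF recordings via MNE.

    Provided for completeness; the synthetic generator is the primary
    input path.  Returns the raw MNE object; epoching against a
    schedule is left to the caller's event codes.
    """
    import mne

    return mne.io.read_raw_bdf(path, **kwargs)
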