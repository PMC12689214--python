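"""FFT amplitude spectra, electrode selection, and peak-vs-sideband SNR.

Spectra are computed on the 3-s analysis window (-1000 to 2000 ms at
256 Hz, 768 samples), giving a frequency resolution of 1/3 Hz so that
all four tag frequencies (18/21/24/27 Hz) fall exactly on bin centers.
Amplitudes are calibrated so that a unit-amplitude sinusoid at a bin
center yields 1.0.

Electrode selection follows the individual-best-electrode scheme: per
subject and tag frequency, the channel with the maximum amplitude
within the predefined 17-channel parieto-occipital cluster, extended
by its four nearest scalp neighbors (which may lie outside the
cluster), for five channels per subject and frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .montage import MontageLayout, POSTERIOR_CLUSTER


@dataclass
class Spectrum:
    """Amplitude spectrum per channel.

    ``amplitudes`` has shape (n_channels, n_bins); bin spacing is the
    reciprocal of the analysis-window length.
    """

    amplitudes: np.ndarray
    freqs: np.ndarray
    channel_names: list[str]

    @property
    def bin_spacing_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def at(self, freq_hz: float) -> np.ndarray:
        """Amplitudes at the bin nearest ``freq_hz`` (must be bin-aligned)."""
        i = self.bin_index(freq_hz)
        return self.amplitudes[:, i]

    def bin_index(self, freq_hz: float) -> int:
        i = int(round(freq_hz / self.bin_spacing_hz))
        if not (0 <= i < len(self.freqs)) or abs(self.freqs[i] - freq_hz) > 1e-6:
            raise ValueError(f"{freq_hz} Hz is not a bin center of this spectrum")
        return i


@dataclass
class ElectrodeSelection:
    """Best posterior channel plus its four nearest neighbors."""

    tag_frequency: float
    best: str
    neighbors: tuple[str, ...]
    amplitude: float
    tied: bool = False

    @property
    def channels(self) -> tuple[str, ...]:
        return (self.best,) + self.neighbors


def amplitude_spectrum(
    epochs: np.ndarray,
    fs: float,
    times: np.ndarray | None = None,
    window: tuple[float, float] = (-1.0, 2.0),
    channel_names: list[str] | None = None,
    detrend: bool = True,
) -> Spectrum:
    """Amplitude spectrum of (condition-averaged) epochs.

    ``epochs`` is (channels, samples); if ``times`` is given the
    ``window`` (seconds) is cut out first and must lie fully inside the
    epoch.  The modulus of the discrete Fourier coefficients is scaled
    by 2/N (DC by 1/N) so a unit sinusoid at a bin center yields 1.0.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if times is not None:
        lo, hi = window
        idx = np.where((times >= lo - 1e-9) & (times < hi - 1e-9))[0]
        n_expected = int(round((hi - lo) * fs))
        if idx.size < n_expected:
            raise ValueError("analysis window not fully inside the epoch")
        epochs = epochs[:, idx[0]: idx[0] + n_expected]
    n = epochs.shape[-1]
    if detrend:
        epochs = sp_signal.detrend(epochs, axis=-1, type="linear")
    coeffs = np.fft.rfft(epochs, axis=-1)
    amps = np.abs(coeffs) * 2.0 / n
    amps[:, 0] /= 2.0
    if n % 2 == 0:
        amps[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    names = channel_names or [f"ch{i}" for i in range(epochs.shape[0])]
    return Spectrum(amplitudes=amps, freqs=freqs, channel_names=list(names))


def select_electrodes(
    spectrum: Spectrum,
    montage: MontageLayout,
    tag_frequency: float,
    n_neighbors: int = 4,
) -> ElectrodeSelection:
    """Pick the best posterior-cluster channel and its nearest neighbors.

    The argmax is taken over the predefined parieto-occipital cluster
    at the tag-frequency bin; ties resolve to the lowest channel index
    (flagged in the result).  Neighbors are the ``n_neighbors`` nearest
    scalp channels by Euclidean distance and may lie outside the
    cluster.
    """
    missing = [c for c in POSTERIOR_CLUSTER if c not in spectrum.channel_names]
    if missing:
        raise ValueError(f"posterior cluster channels missing from spectrum: {missing}")
    amps = spectrum.at(tag_frequency)
    cluster_idx = [spectrum.channel_names.index(c) for c in POSTERIOR_CLUSTER]
    cluster_amps = amps[cluster_idx]
    best_pos = int(np.argmax(cluster_amps))
    tied = int(np.sum(cluster_amps == cluster_amps[best_pos])) > 1
    # ties resolve to the lowest channel index in the spectrum ordering
    if tied:
        winners = [cluster_idx[i] for i in np.where(cluster_amps == cluster_amps[best_pos])[0]]
        best_idx = min(winners)
    else:
        best_idx = cluster_idx[best_pos]
    best = spectrum.channel_names[best_idx]
    neighbors = tuple(montage.k_nearest(best, n_neighbors))
    return ElectrodeSelection(
        tag_frequency=tag_frequency, best=best, neighbors=neighbors,
        amplitude=float(amps[best_idx]), tied=tied,
    )


def snr_table(
    spectrum: Spectrum,
    tag_frequencies: tuple[float, ...] = (18.0, 21.0, 24.0, 27.0),
    sideband_hz: float = 1.0,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Peak and mean-sideband amplitudes per tag frequency.

    The sideband value is the mean amplitude of the two bins exactly
    ``sideband_hz`` above and below the tag frequency.  Raises when a
    sideband bin would coincide with another tag (cannot happen with
    the >=3 Hz tag spacing).  Rows feed the 2 x 4 Band-by-Frequency
    repeated-measures ANOVA of SSVEP signal quality.
    """
    for f in tag_frequencies:
        for s in (f - sideband_hz, f + sideband_hz):
            others = [g for g in tag_frequencies if g != f]
            if any(abs(s - g) < spectrum.bin_spacing_hz / 2 for g in others):
                raise ValueError(
                    f"sideband of {f} Hz overlaps another tag frequency"
                )
    if channels is None:
        sel = np.arange(len(spectrum.channel_names))
    else:
        sel = np.array([spectrum.channel_names.index(c) for c in channels])
    rows = []
    for f in tag_frequencies:
        peak = float(spectrum.at(f)[sel].mean())
        side = float(
            np.mean([spectrum.at(f - sideband_hz)[sel].mean(),
                     spectrum.at(f + sideband_hz)[sel].mean()])
        )
        rows.append({"frequency_hz": f, "peak_amp": peak, "sideband_amp": side,
                     "snr": peak / side if side > 0 else np.inf})
    return pd.DataFrame(rows)
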