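"""Electrode montage: 64 scalp channels plus 4 EOG channels.

Coordinates come from the standard 10-10 template bundled with MNE,
re-centered and projected onto the unit sphere.  The scalp layout is a
64-channel cap arranged so that it contains the full predefined
parieto-occipital cluster used for electrode selection (I1, I2, Iz,
O1, O2, Oz, P10, P5, P6, P7, P8, P9, PO3, PO4, PO7, PO8, POz).  The
four EOG channels sit at the outer canthi (horizontal pair) and above/
below the right eye (vertical pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: The 17-channel parieto-occipital cluster used for electrode selection.
POSTERIOR_CLUSTER = (
    "I1", "I2", "Iz", "O1", "O2", "Oz", "P10", "P5", "P6", "P7", "P8",
    "P9", "PO3", "PO4", "PO7", "PO8", "POz",
)

#: 64 scalp channel names (10-10 layout covering the posterior cluster).
SCALP_64 = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3",
    "FC1", "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1",
    "P3", "P5", "P7", "P9", "PO7", "PO3", "O1", "I1", "Iz", "Oz",
    "POz", "Pz", "CPz", "Fz", "Fp2", "AF8", "AF4", "F2", "F4", "F6",
    "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6",
    "T8", "TP8", "CP6", "CP4", "CP2", "P2", "P4", "P6", "P8", "P10",
    "PO8", "PO4", "O2", "I2",
)

EOG_CHANNELS = ("HEOG_L", "HEOG_R", "VEOG_U", "VEOG_D")

# approximate face positions for the EOG electrodes (unit sphere)
_EOG_POS = {
    "HEOG_L": (-0.82, 0.55, -0.17),
    "HEOG_R": (0.82, 0.55, -0.17),
    "VEOG_U": (0.38, 0.90, -0.10),
    "VEOG_D": (0.38, 0.86, -0.35),
}


@dataclass
class MontageLayout:
    """Channel names, unit-sphere coordinates and neighborhood structure."""

    names: list[str]
    positions: np.ndarray  # (n_channels, 3), unit norm
    n_scalp: int = 64
    k_neighbors: int = 4
    neighbor_graph: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.neighbor_graph:
            self.neighbor_graph = self._build_neighbor_graph()

    # -- basic accessors ------------------------------------------------
    @property
    def scalp_names(self) -> list[str]:
        return self.names[: self.n_scalp]

    @property
    def eog_names(self) -> list[str]:
        return self.names[self.n_scalp:]

    @property
    def scalp_positions(self) -> np.ndarray:
        return self.positions[: self.n_scalp]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.arange(self.n_scalp)

    @property
    def eog_indices(self) -> np.ndarray:
        return np.arange(self.n_scalp, len(self.names))

    @property
    def posterior_indices(self) -> np.ndarray:
        return np.array([self.index(n) for n in POSTERIOR_CLUSTER])

    def is_posterior(self, name: str) -> bool:
        return name in POSTERIOR_CLUSTER

    # -- neighborhood ----------------------------------------------------
    def k_nearest(self, name: str, k: int | None = None) -> list[str]:
        """The ``k`` scalp channels nearest to ``name`` (Euclidean, excluding itself)."""
        k = k or self.k_neighbors
        i = self.index(name)
        d = np.linalg.norm(self.scalp_positions - self.positions[i], axis=1)
        order = np.argsort(d, kind="stable")
        out = [self.scalp_names[j] for j in order if j != i][:k]
        return out

    def _build_neighbor_graph(self) -> dict[str, tuple[str, ...]]:
        # symmetric closure of the k-nearest relation on scalp channels
        near = {n: set(self.k_nearest(n)) for n in self.scalp_names}
        for a in list(near):
            for b in near[a]:
                near[b].add(a)
        return {n: tuple(sorted(v)) for n, v in near.items()}


def default_montage(k_neighbors: int = 4) -> MontageLayout:
    """Build the 64+4 channel layout from the MNE 10-10 template."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    scalp = np.array([ch_pos[n] for n in SCALP_64])
    scalp = scalp - scalp.mean(axis=0)
    scalp /= np.linalg.norm(scalp, axis=1, keepdims=True)
    eog = np.array([_EOG_POS[n] for n in EOG_CHANNELS])
    eog /= np.linalg.norm(eog, axis=1, keepdims=True)
    names = list(SCALP_64) + list(EOG_CHANNELS)
    positions = np.vstack([scalp, eog])
    return MontageLayout(names=names, positions=positions, k_neighbors=k_neighbors)
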