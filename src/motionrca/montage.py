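"""128-channel HydroCel-style sensor layout.

The analysis addresses data recorded with a 128-electrode geodesic net
(vertex reference).  This module wraps the idealized GSN-HydroCel-128
coordinates bundled with :mod:`mne` into a small montage object that knows

* 3-D electrode positions (normalized to the unit sphere),
* an ordered nearest-neighbour map (used for bad-electrode interpolation),
* the electrooculogram role electrodes: the outer canthi (125 right,
  128 left) for the horizontal EOG, and the supra-orbital (8, 25) vs
  cheek (126, 127) electrodes for the vertical EOG,
* the fixed 9-electrode occipital region of interest around Oz (E75).

Custom coordinates (e.g. digitized positions) can be supplied directly to
:class:`Montage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Occipital region of interest: Oz (75) plus the four lateral electrodes
#: on either side, used by the traditional motion-onset VEP average.
OCCIPITAL_ROI: tuple[int, ...] = (50, 58, 65, 70, 75, 83, 90, 96, 101)

#: EOG role electrodes (1-based HydroCel numbering).
EOG_ROLES: dict[str, tuple[int, ...]] = {
    "heog_right": (125,),
    "heog_left": (128,),
    "veog_upper": (8, 25),
    "veog_lower": (126, 127),
}


@dataclass
class Montage:
    """Electrode layout with neighbour relations and EOG role tags."""

    positions: np.ndarray  # (n_channels, 3), unit vectors
    channels: np.ndarray = field(default=None)  # 1-based ids
    roles: dict = field(default_factory=lambda: dict(EOG_ROLES))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        norms = np.linalg.norm(self.positions, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("electrode at origin")
        self.positions = self.positions / norms
        if self.channels is None:
            self.channels = np.arange(1, len(self.positions) + 1)
        self.channels = np.asarray(self.channels, dtype=int)
        for role, chans in self.roles.items():
            missing = set(chans) - set(self.channels.tolist())
            if missing:
                raise ValueError(f"role {role!r} electrodes missing: {sorted(missing)}")
        # ordered nearest neighbours (self excluded)
        d = np.linalg.norm(self.positions[:, None, :] - self.positions[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        self._neighbour_order = np.argsort(d, axis=1)[:, : len(self.channels) - 1]
        self._distance = d

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: int | np.ndarray) -> np.ndarray:
        """0-based array index of 1-based channel number(s)."""
        lookup = {c: i for i, c in enumerate(self.channels.tolist())}
        if np.isscalar(channel):
            return lookup[int(channel)]
        return np.array([lookup[int(c)] for c in np.atleast_1d(channel)])

    def neighbours(self, channel: int, k: int = 6) -> np.ndarray:
        """The ``k`` nearest neighbouring channel numbers, nearest first."""
        i = self.index(channel)
        return self.channels[self._neighbour_order[i, :k]]

    def role_indices(self, role: str) -> np.ndarray:
        return self.index(np.array(self.roles[role]))


def hydrocel_128() -> Montage:
    """The idealized 128-channel GSN HydroCel layout shipped with mne."""
    import mne

    std = mne.channels.make_standard_montage("GSN-HydroCel-128")
    pos = std.get_positions()["ch_pos"]
    xyz = np.array([pos[f"E{i}"] for i in range(1, 129)])
    return Montage(positions=xyz)
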