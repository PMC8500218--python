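"""Epoched multi-channel data container.

:class:`EpochSet` is the lingua franca of the pipeline: a
``trials x channels x samples`` array of amplitudes in microvolts with a
boolean missing-value mask, a time axis in milliseconds (relative to the
locking event, stimulus onset by default), and a per-trial metadata table.

Masked samples are also set to NaN in ``data`` so that any accidental
unmasked arithmetic fails loudly rather than silently using garbage.

On disk the container is an HDF5 file with datasets ``/data``, ``/mask``,
``/time_ms``, ``/channels`` and a ``/trials`` JSON table, plus attributes
for the sampling rate, reference and locking event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd


@dataclass
class EpochSet:
    data: np.ndarray        # (n_trials, n_channels, n_samples), µV
    mask: np.ndarray        # bool, True = missing
    time_ms: np.ndarray     # (n_samples,)
    channels: np.ndarray    # 1-based channel (or component) ids
    trials: pd.DataFrame    # one row per trial
    sfreq: float = 500.0
    reference: str = "vertex"
    locking: str = "stimulus"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.data.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channels = np.asarray(self.channels)
        if self.data.shape != self.mask.shape:
            raise ValueError("data/mask shape mismatch")
        if self.data.shape[2] != len(self.time_ms):
            raise ValueError("time axis length mismatch")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis length mismatch")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial table length mismatch")
        self.data[self.mask] = np.nan

    # -- basic geometry ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def valid(self) -> np.ndarray:
        """Boolean array of available (non-missing) samples."""
        return ~self.mask

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            mask=self.mask.copy(),
            time_ms=self.time_ms.copy(),
            channels=self.channels.copy(),
            trials=self.trials.copy(),
        )

    def sample_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.time_ms - t_ms)))

    def window(self, t0_ms: float, t1_ms: float) -> "EpochSet":
        """Half-open time window ``[t0_ms, t1_ms)``."""
        sel = (self.time_ms >= t0_ms) & (self.time_ms < t1_ms)
        if not sel.any():
            raise ValueError("empty window")
        return replace(
            self,
            data=self.data[:, :, sel].copy(),
            mask=self.mask[:, :, sel].copy(),
            time_ms=self.time_ms[sel].copy(),
            channels=self.channels.copy(),
            trials=self.trials.copy(),
        )

    def select_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx].copy(),
            mask=self.mask[idx].copy(),
            time_ms=self.time_ms.copy(),
            channels=self.channels.copy(),
            trials=self.trials.iloc[idx].reset_index(drop=True),
        )

    def set_missing(self, where: np.ndarray) -> None:
        """Grow the missing mask in place (never shrinks it)."""
        self.mask |= where
        self.data[self.mask] = np.nan

    # -- I/O -----------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("mask", data=self.mask, compression="gzip")
            f.create_dataset("time_ms", data=self.time_ms)
            ch = self.channels
            if ch.dtype.kind in "US":
                ch = ch.astype(h5py.string_dtype())
            f.create_dataset("channels", data=ch)
            f.create_dataset(
                "trials", data=self.trials.to_json(orient="split", date_format="iso")
            )
            f.attrs["sampling_rate_hz"] = self.sfreq
            f.attrs["reference"] = self.reference
            f.attrs["locking"] = self.locking

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        import io

        with h5py.File(path, "r") as f:
            ch = f["channels"][()]
            if ch.dtype.kind in "OS":
                ch = np.array([c.decode() if isinstance(c, bytes) else c for c in ch])
            raw = f["trials"][()]
            if isinstance(raw, bytes):
                raw = raw.decode()
            trials = pd.read_json(io.StringIO(raw), orient="split")
            return cls(
                data=f["data"][()],
                mask=f["mask"][()],
                time_ms=f["time_ms"][()],
                channels=ch,
                trials=trials,
                sfreq=float(f.attrs["sampling_rate_hz"]),
                reference=str(f.attrs["reference"]),
                locking=str(f.attrs["locking"]),
            )
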