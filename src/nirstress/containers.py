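"""In-memory containers for multichannel fNIRS data.

The probe montage is the 15-channel prefrontal layout of the NIRSIT LITE
device: channels 1-7 over the right hemisphere, 9-15 over the left, channel
8 on the midline, 25 mm source-detector separation, two wavelengths
(780/850 nm), sampled at 8.138 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

DEFAULT_FS_HZ = 8.138
DEFAULT_WAVELENGTHS_NM = (780.0, 850.0)


@dataclass(frozen=True)
class ChannelLayout:
    """Optode montage: channel/hemisphere assignment and acquisition geometry.

    Channel ids are 1-based, matching the device numbering. ``right_channels``,
    ``left_channels`` and ``midline_channels`` must partition ``1..n_channels``.
    """

    n_channels: int = 15
    right_channels: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    left_channels: tuple[int, ...] = (9, 10, 11, 12, 13, 14, 15)
    midline_channels: tuple[int, ...] = (8,)
    source_detector_distance_mm: float = 25.0
    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    fs_hz: float = DEFAULT_FS_HZ

    def __post_init__(self) -> None:
        all_ids = sorted(self.right_channels + self.left_channels + self.midline_channels)
        if all_ids != list(range(1, self.n_channels + 1)):
            raise ValueError(
                "right/left/midline channel sets must partition "
                f"1..{self.n_channels}, got {all_ids}"
            )
        if self.source_detector_distance_mm <= 0:
            raise ValueError("source-detector distance must be positive")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    def channel_indices(self, channel_ids) -> np.ndarray:
        """0-based array indices for 1-based channel ids."""
        ids = np.asarray(list(channel_ids), dtype=int)
        if ids.size == 0:
            raise ValueError("channel set is empty")
        if ids.min() < 1 or ids.max() > self.n_channels:
            raise ValueError(f"channel ids out of range 1..{self.n_channels}: {ids}")
        return ids - 1


@dataclass
class OpticalRecording:
    """Optical-density changes: ``dod[channel, wavelength, sample]``.

    ``dod`` is dimensionless (-log of the intensity ratio to baseline);
    ``wavelengths_nm`` gives the order of axis 1.
    """

    dod: np.ndarray
    fs_hz: float
    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM

    def __post_init__(self) -> None:
        self.dod = np.asarray(self.dod, dtype=float)
        if self.dod.ndim != 3:
            raise ValueError("dod must be channels x wavelengths x samples")
        if self.dod.shape[1] != len(self.wavelengths_nm):
            raise ValueError("dod wavelength axis does not match wavelengths_nm")
        if not np.all(np.isfinite(self.dod)):
            raise ValueError("dod contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.dod.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dod.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class HemoTimeSeries:
    """Hemoglobin concentration changes per channel.

    ``dhbo``/``dhbr`` are ``channels x samples`` in uM (for the default DPF
    convention; with DPF = 1 they read as uM*mm path products -- the
    laterality index is invariant to this scale). ``dhbt``, when present,
    must equal ``dhbo + dhbr`` elementwise.
    """

    dhbo: np.ndarray
    dhbr: np.ndarray
    fs_hz: float
    dhbt: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dhbo = np.asarray(self.dhbo, dtype=float)
        self.dhbr = np.asarray(self.dhbr, dtype=float)
        if self.dhbo.shape != self.dhbr.shape or self.dhbo.ndim != 2:
            raise ValueError("dhbo and dhbr must be equal-shape channels x samples")
        if self.dhbt is not None:
            self.dhbt = np.asarray(self.dhbt, dtype=float)
            if not np.allclose(self.dhbt, self.dhbo + self.dhbr, atol=1e-9):
                raise ValueError("dhbt must equal dhbo + dhbr")

    @property
    def n_channels(self) -> int:
        return self.dhbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dhbo.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def with_dhbt(self) -> "HemoTimeSeries":
        return replace(self, dhbt=self.dhbo + self.dhbr)


@dataclass
class EpochSet:
    """Task-locked epochs: ``data[trial, channel, sample]`` on [-1, 60] s.

    ``onset_index`` is the sample index of t = 0 within each epoch. The
    baseline window is [-1, 0) (t = 0 belongs to the task). The fixed
    sampling convention uses floor(fs) pre-onset samples and floor(60*fs)
    post-onset samples inclusive, i.e. 8 + 1 + 488 = 497 samples at 8.138 Hz.
    """

    data: np.ndarray
    fs_hz: float
    onset_index: int
    window_s: tuple[float, float] = (-1.0, 60.0)
    baseline_window_s: tuple[float, float] = (-1.0, 0.0)
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if not 0 <= self.onset_index < self.data.shape[2]:
            raise ValueError("onset_index outside epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time of each epoch sample relative to task onset, in seconds."""
        return (np.arange(self.n_samples) - self.onset_index) / self.fs_hz
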