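"""Synthetic cohorts and event-locked lateralized hemodynamic recordings.

The generator reproduces the statistical structure the analysis assumes:

* cohorts whose sAA levels follow the reported per-group distributions
  (control 12.73 +/- 9.76, eustress 37.82 +/- 3.49, distress 61.82 +/- 18.07
  KU/L), sampled from truncated-at-zero normals and kept inside each group's
  defining interval by resampling, so sAA classification recovers the true
  group exactly;
* event-locked dHbO responses: the target-period stimulation boxcar
  convolved with a canonical double-gamma HRF (peak ~6 s, undershoot ~16 s),
  scaled per hemisphere by a group-specific right/left gain so the
  laterality index has a known closed form (g - 1)/(g + 1) in the noiseless
  case;
* dHbR as a scaled, sign-flipped copy of the noiseless dHbO shape (default
  ratio -1/3);
* additive nuisance: low-frequency drift, Mayer-wave (~0.1 Hz), respiratory
  (~0.25 Hz) and cardiac (~1.1 Hz) oscillations with random phases, plus
  white noise. Cardiac aliasing at the 8.138 Hz sampling rate is accepted
  as realistic.

Default per-group right gains (eustress 1.70, control 1.20, distress 1.01)
place the noiseless group LIS at ~0.26, ~0.09 and ~0.005 -- the
eustress > control > distress ordering the index is meant to detect. Gains
are configuration, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import DEFAULT_FS_HZ, ChannelLayout, HemoTimeSeries
from .paradigm import StimulusSchedule, target_boxcar
from .stats import classify_by_saa

# per-group sAA mean/SD in KU/L and defining interval (lo, hi)
SAA_DISTRIBUTIONS = {
    "control": (12.73, 9.76, (0.0, 28.0)),
    "eustress": (37.82, 3.49, (33.0, 44.0)),
    "distress": (61.82, 18.07, (44.0, np.inf)),
}

# accuracy (%) mean/SD; response time (ms) mean/SD follows the inverted-U:
# eustress fastest and most accurate, distress slowest
BEHAVIOR = {
    "control": {"accuracy": (95.5, 3.4), "rt_ms": (455.0, 50.0), "bpm": (19.7, 4.5)},
    "eustress": {"accuracy": (96.9, 0.8), "rt_ms": (420.0, 40.0), "bpm": (16.1, 4.7)},
    "distress": {"accuracy": (95.8, 2.0), "rt_ms": (490.0, 60.0), "bpm": (14.8, 4.2)},
}

DEFAULT_RIGHT_GAINS = {"control": 1.20, "eustress": 1.70, "distress": 1.01}


@dataclass(frozen=True)
class SyntheticParticipant:
    id: str
    saa_kul: float
    true_group: str  # control | eustress | distress
    right_gain: float
    accuracy_pct: float
    rt_ms: float
    bpm: float

    def __post_init__(self) -> None:
        if self.saa_kul < 0:
            raise ValueError("saa_kul must be non-negative")
        if self.right_gain <= 0:
            raise ValueError("right_gain must be positive")
        if not 0 <= self.accuracy_pct <= 100:
            raise ValueError("accuracy_pct must be in [0, 100]")


@dataclass(frozen=True)
class SimulationParams:
    """Forward-model parameters for one recording."""

    fs_hz: float = DEFAULT_FS_HZ
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    response_amplitude: float = 1.0  # uM; absolute scale is arbitrary, LIS is scale-free
    hbr_ratio: float = -1.0 / 3.0
    drift_amplitude: float = 2.0
    mayer_amplitude: float = 1.0
    respiration_amplitude: float = 0.5
    cardiac_amplitude: float = 0.5
    white_noise_sd: float = 6.0
    mayer_hz: float = 0.1
    respiration_hz: float = 0.25
    cardiac_hz: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drift_amplitude", "mayer_amplitude", "respiration_amplitude",
                     "cardiac_amplitude", "white_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hbr_ratio >= 0:
            raise ValueError("hbr_ratio must be negative (HbR opposes HbO)")

    def noiseless(self) -> "SimulationParams":
        return replace(self, drift_amplitude=0.0, mayer_amplitude=0.0,
                       respiration_amplitude=0.0, cardiac_amplitude=0.0,
                       white_noise_sd=0.0)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sample N(mean, sd) restricted to the open interval (lo, hi)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        ok = draw[(draw > lo) & (draw < hi)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def sample_cohort(
    n_per_group: int,
    seed: int,
    right_gains: dict | None = None,
) -> list[SyntheticParticipant]:
    """Draw a balanced cohort of control/eustress/distress participants.

    sAA levels are truncated-normal draws kept inside each group's defining
    interval, so :func:`nirstress.stats.classify_by_saa` recovers the true
    group for every participant by construction.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    rng = np.random.default_rng(seed)
    gains = dict(DEFAULT_RIGHT_GAINS)
    if right_gains:
        gains.update(right_gains)
    cohort = []
    for group in ("control", "eustress", "distress"):
        mean, sd, (lo, hi) = SAA_DISTRIBUTIONS[group]
        saa = _truncated_normal(rng, mean, sd, max(lo, 0.0), hi, n_per_group)
        beh = BEHAVIOR[group]
        acc = np.clip(rng.normal(*beh["accuracy"], n_per_group), 0.0, 100.0)
        rt = np.clip(rng.normal(*beh["rt_ms"], n_per_group), 150.0, None)
        bpm = np.clip(rng.normal(*beh["bpm"], n_per_group), 4.0, None)
        for i in range(n_per_group):
            p = SyntheticParticipant(
                id=f"{group[:4]}{i + 1:02d}",
                saa_kul=float(saa[i]),
                true_group=group,
                right_gain=float(gains[group]),
                accuracy_pct=float(acc[i]),
                rt_ms=float(rt[i]),
                bpm=float(bpm[i]),
            )
            assert classify_by_saa(p.saa_kul).three_group == group
            cohort.append(p)
    return cohort


def cohort_frame(cohort) -> pd.DataFrame:
    """Cohort as a table with columns id,saa_kul,group,accuracy_pct,rt_ms,bpm."""
    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "saa_kul": [p.saa_kul for p in cohort],
            "group": [p.true_group for p in cohort],
            "accuracy_pct": [p.accuracy_pct for p in cohort],
            "rt_ms": [p.rt_ms for p in cohort],
            "bpm": [p.bpm for p in cohort],
        }
    )


def double_gamma_hrf(t: np.ndarray, peak_s=6.0, undershoot_s=16.0,
                     undershoot_ratio=1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalised to 1."""
    from scipy.stats import gamma as _gamma

    h = _gamma.pdf(t, peak_s) - undershoot_ratio * _gamma.pdf(t, undershoot_s)
    peak = h.max()
    return h / peak if peak > 0 else h


def task_response(schedule: StimulusSchedule, params: SimulationParams,
                  n_samples: int) -> np.ndarray:
    """Noise-free unit-gain dHbO response: target boxcar (*) HRF, scaled."""
    box = target_boxcar(schedule, params.fs_hz, n_samples)
    t_hrf = np.arange(0, 32.0, 1.0 / params.fs_hz)
    hrf = double_gamma_hrf(t_hrf, params.hrf_peak_s, params.hrf_undershoot_s,
                           params.hrf_undershoot_ratio)
    resp = np.convolve(box, hrf)[:n_samples] / params.fs_hz
    return resp * params.response_amplitude


def record_n_samples(schedule: StimulusSchedule, fs_hz: float) -> int:
    # floor + 1 so the last epoch window (onset + 60 s) stays inside the record
    return int(np.floor(schedule.span_s * fs_hz)) + 1


def simulate_hemodynamics(
    schedule: StimulusSchedule,
    participant: SyntheticParticipant,
    params: SimulationParams,
    layout: ChannelLayout | None = None,
    base_response: np.ndarray | None = None,
) -> HemoTimeSeries:
    """Simulate a 15-channel dHbO/dHbR recording for one participant/session.

    Right-hemisphere channels carry ``right_gain`` times the unit response,
    left channels carry it unscaled, and the midline channel the mean of the
    two. dHbR is ``hbr_ratio`` times the noiseless dHbO component with its
    own noise. ``base_response`` allows reusing the schedule's unit-gain
    response across participants.
    """
    if not schedule.events:
        raise ValueError("schedule has no events")
    layout = layout or ChannelLayout(fs_hz=params.fs_hz)
    n = record_n_samples(schedule, params.fs_hz)
    if base_response is None:
        base_response = task_response(schedule, params, n)
    t = np.arange(n) / params.fs_hz

    gain = np.ones(layout.n_channels)
    gain[layout.channel_indices(layout.right_channels)] = participant.right_gain
    gain[layout.channel_indices(layout.midline_channels)] = (
        participant.right_gain + 1.0
    ) / 2.0

    signal_hbo = gain[:, None] * base_response[None, :]
    signal_hbr = params.hbr_ratio * signal_hbo

    rng = np.random.default_rng(params.seed)
    dhbo = signal_hbo + _nuisance(rng, t, layout.n_channels, params)
    dhbr = signal_hbr + 0.5 * _nuisance(rng, t, layout.n_channels, params)
    return HemoTimeSeries(dhbo=dhbo, dhbr=dhbr, fs_hz=params.fs_hz)


def _nuisance(rng, t, n_channels, params: SimulationParams) -> np.ndarray:
    """Drift + physiological oscillations + white noise, per channel."""
    out = np.zeros((n_channels, t.size))
    span = t[-1] - t[0] if t.size > 1 else 1.0
    for amp, freq in (
        (params.drift_amplitude, 0.5 / span),  # half-cycle drift over the record
        (params.mayer_amplitude, params.mayer_hz),
        (params.respiration_amplitude, params.respiration_hz),
        (params.cardiac_amplitude, params.cardiac_hz),
    ):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi, size=n_channels)
            f = freq * (1.0 + 0.05 * rng.standard_normal(n_channels))
            out += amp * np.sin(2 * np.pi * f[:, None] * t[None, :] + phase[:, None])
    if params.white_noise_sd > 0:
        out += params.white_noise_sd * rng.standard_normal((n_channels, t.size))
    return out
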