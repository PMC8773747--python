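"""Laterality index for stress (LIS).

LIS = (R - L) / (R + L), where R and L are the maximum absolute dHbO
amplitudes over the right-hemisphere (channels 1-7) and left-hemisphere
(channels 9-15) channel sets of the grand-averaged, baseline-corrected
epochs. The midline channel 8 belongs to neither set. Values lie in
[-1, 1]; positive means right-hemisphere dominance (the stress-typical
pattern), negative means left dominance.

Two channel-aggregation conventions are supported: ``max`` takes the single
most active channel per hemisphere (max over channels of the per-channel
absolute maximum; the default) and ``mean`` averages the per-channel
absolute maxima across the hemisphere. The index is invariant to any
common rescaling of the signals under both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ChannelLayout, EpochSet

AGGREGATION_MODES = ("max", "mean")
DEFAULT_AMPLITUDE_INTERVAL_S = (0.0, 60.0)


class UndefinedLaterality(ValueError):
    """Raised when R + L = 0, where the index is undefined (not zero)."""


@dataclass(frozen=True)
class LISResult:
    group: str
    session: int
    right_amplitude: float
    left_amplitude: float
    lis: float
    lis_se: Optional[float] = None  # standard error of per-participant indices
    aggregation: str = "max"
    n_participants: Optional[int] = None


def compute_lis(right: float, left: float) -> float:
    """(R - L) / (R + L) for non-negative amplitudes; antisymmetric in (R, L)."""
    if right < 0 or left < 0:
        raise ValueError("hemisphere amplitudes must be non-negative")
    total = right + left
    if total == 0:
        raise UndefinedLaterality("R + L = 0: laterality is undefined")
    return (right - left) / total


def hemisphere_amplitude(
    grand_avg: np.ndarray,
    channel_ids,
    layout: ChannelLayout,
    fs_hz: float,
    onset_index: int,
    interval_s=DEFAULT_AMPLITUDE_INTERVAL_S,
    aggregation: str = "max",
) -> float:
    """Absolute-amplitude summary of one hemisphere's grand average.

    ``grand_avg`` is channels x samples with t=0 at ``onset_index``. The
    per-channel statistic is max |x(t)| over the interval (default [0, 60] s);
    channels combine by ``max`` or ``mean``.
    """
    if aggregation not in AGGREGATION_MODES:
        raise ValueError(f"aggregation must be one of {AGGREGATION_MODES}")
    idx = layout.channel_indices(channel_ids)
    t = (np.arange(grand_avg.shape[1]) - onset_index) / fs_hz
    mask = (t >= interval_s[0]) & (t <= interval_s[1])
    if not mask.any():
        raise ValueError(f"interval {interval_s} selects no samples")
    per_channel = np.abs(grand_avg[np.ix_(idx, np.flatnonzero(mask))]).max(axis=1)
    return float(per_channel.max() if aggregation == "max" else per_channel.mean())


def lis_from_grand_average(
    grand_avg: np.ndarray,
    layout: ChannelLayout,
    fs_hz: float,
    onset_index: int,
    interval_s=DEFAULT_AMPLITUDE_INTERVAL_S,
    aggregation: str = "max",
) -> tuple[float, float, float]:
    """(R, L, LIS) of one grand-averaged epoch array."""
    r = hemisphere_amplitude(grand_avg, layout.right_channels, layout, fs_hz,
                             onset_index, interval_s, aggregation)
    l = hemisphere_amplitude(grand_avg, layout.left_channels, layout, fs_hz,
                             onset_index, interval_s, aggregation)
    return r, l, compute_lis(r, l)


def lis_by_group_session(
    epoch_sets_by_group_session: dict[tuple[str, int], list[EpochSet]],
    layout: ChannelLayout,
    interval_s=DEFAULT_AMPLITUDE_INTERVAL_S,
    aggregation: str = "max",
) -> list[LISResult]:
    """One LIS per (group, session) from participant epoch sets.

    Grand averaging pools trials within each participant and then
    participants within the group before the hemisphere amplitudes are
    taken. A per-participant LIS is also computed to supply the standard
    error across participants.
    """
    from .preprocess import average_trials, grand_average

    results = []
    for (group, session), epoch_sets in sorted(epoch_sets_by_group_session.items()):
        if not epoch_sets:
            raise ValueError(f"group {group!r} session {session} has no participants")
        fs = epoch_sets[0].fs_hz
        onset_index = epoch_sets[0].onset_index
        ga = grand_average(epoch_sets)
        r, l, lis = lis_from_grand_average(ga, layout, fs, onset_index,
                                           interval_s, aggregation)
        per_part = []
        for ep in epoch_sets:
            avg = average_trials(ep)
            try:
                per_part.append(
                    lis_from_grand_average(avg, layout, fs, ep.onset_index,
                                           interval_s, aggregation)[2]
                )
            except UndefinedLaterality:
                continue
        se = (
            float(np.std(per_part, ddof=1) / np.sqrt(len(per_part)))
            if len(per_part) > 1
            else None
        )
        results.append(
            LISResult(group=group, session=session, right_amplitude=r,
                      left_amplitude=l, lis=lis, lis_se=se, aggregation=aggregation,
                      n_participants=len(epoch_sets))
        )
    return results


def lis_table(results) -> pd.DataFrame:
    """LIS results as a table (group, session, R, L, lis, lis_se, aggregation_mode)."""
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "session": [r.session for r in results],
            "R": [r.right_amplitude for r in results],
            "L": [r.left_amplitude for r in results],
            "lis": [r.lis for r in results],
            "lis_se": [np.nan if r.lis_se is None else r.lis_se for r in results],
            "aggregation_mode": [r.aggregation for r in results],
            "n_participants": [r.n_participants for r in results],
        }
    )
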