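"""Calibration experiments: replicate studies of the pipeline's statistical behaviour.

These are the package's own checks that the analysis behaves as designed
under the simulated study conditions: laterality-ordering recovery across
seeded cohort replicates, type-I error calibration of the group tests, and
correlation recovery at the reported effect size. They are used by the test
suite and the reproduction script, and are importable for re-running at
other settings.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats as _sst

from .config import PipelineConfig
from .containers import ChannelLayout, HemoTimeSeries
from .laterality import lis_from_grand_average
from .paradigm import build_session_schedule, trial_onsets
from .pipeline import preprocess_recording
from .preprocess import average_trials
from .stats import compare_three_groups, compare_two_groups, correlate
from .synthetic import (
    DEFAULT_RIGHT_GAINS,
    SimulationParams,
    _nuisance,
    record_n_samples,
    task_response,
)


def group_mean_recording(
    n_participants: int,
    right_gain: float,
    schedule,
    params: SimulationParams,
    layout: ChannelLayout,
    rng: np.random.Generator,
    base_response: np.ndarray | None = None,
    seeds=None,
) -> HemoTimeSeries:
    """Participant-averaged recording of one group.

    Every linear stage of the pipeline (filter, epoching, baseline, trial
    and participant averaging) commutes with the participant mean, so the
    group grand average of per-participant processed epochs equals the
    processed mean recording. Averaging the raw recordings first and
    filtering once makes replicate studies tractable without changing the
    result.
    """
    n = record_n_samples(schedule, params.fs_hz)
    if base_response is None:
        base_response = task_response(schedule, params, n)
    t = np.arange(n) / params.fs_hz
    gain = np.ones(layout.n_channels)
    gain[layout.channel_indices(layout.right_channels)] = right_gain
    gain[layout.channel_indices(layout.midline_channels)] = (right_gain + 1.0) / 2.0
    signal = gain[:, None] * base_response[None, :]
    if seeds is None:
        seeds = [int(rng.integers(0, 2**31)) for _ in range(n_participants)]
    noise = np.zeros_like(signal)
    noise_r = np.zeros_like(signal)
    for s in seeds:
        p_i = replace(params, seed=int(s))
        r = np.random.default_rng(p_i.seed)
        noise += _nuisance(r, t, layout.n_channels, p_i)
        noise_r += 0.5 * _nuisance(r, t, layout.n_channels, p_i)
    noise /= n_participants
    noise_r /= n_participants
    return HemoTimeSeries(
        dhbo=signal + noise,
        dhbr=params.hbr_ratio * signal + noise_r,
        fs_hz=params.fs_hz,
    )


def ordering_recovery_rate(
    n_replicates: int,
    seed: int,
    n_per_group: int = 11,
    session: int = 1,
    config: PipelineConfig | None = None,
    sim_params: SimulationParams | None = None,
) -> float:
    """Fraction of replicate cohorts whose group LIS ordering is
    eustress > control > distress (the generator's designed ordering)."""
    config = (config or PipelineConfig()).validate()
    params = sim_params or SimulationParams(fs_hz=config.layout.fs_hz)
    rng = np.random.default_rng(seed)
    schedule = build_session_schedule(session, seed=seed)
    onsets = trial_onsets(schedule)
    n = record_n_samples(schedule, params.fs_hz)
    base = task_response(schedule, params, n)
    hits = 0
    for _ in range(n_replicates):
        lis = {}
        for group, gain in DEFAULT_RIGHT_GAINS.items():
            rec = group_mean_recording(n_per_group, gain, schedule, params,
                                       config.layout, rng, base)
            ep = preprocess_recording(rec, onsets, config)
            ga = average_trials(ep)
            lis[group] = lis_from_grand_average(
                ga, config.layout, params.fs_hz, ep.onset_index,
                config.lis.interval_s, config.lis.aggregation,
            )[2]
        hits += lis["eustress"] > lis["control"] > lis["distress"]
    return hits / n_replicates


def ttest_type_i_error(
    n_replicates: int, seed: int, n_per_group: int = 22, alpha: float = 0.05
) -> float:
    """Empirical rejection rate of the two-group t battery under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.standard_normal(n_per_group)
        b = rng.standard_normal(n_per_group)
        rejections += compare_two_groups({"a": a, "b": b}).p_value < alpha
    return rejections / n_replicates


def anova_type_i_error(
    n_replicates: int, seed: int, n_per_group: int = 11, alpha: float = 0.05
) -> float:
    """Empirical rejection rate of the three-group ANOVA under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        groups = {g: rng.standard_normal(n_per_group) for g in "abc"}
        rejections += compare_three_groups(groups, run_posthoc=False).p_value < alpha
    return rejections / n_replicates


def pearson_recovery(
    rho: float, n: int, n_replicates: int, seed: int
) -> tuple[float, float]:
    """(mean r, detection rate at p<0.05) over bivariate-normal replicates."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    rs, hits = [], 0
    for _ in range(n_replicates):
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        r, p = correlate(xy[:, 0], xy[:, 1])
        rs.append(r)
        hits += p < 0.05
    return float(np.mean(rs)), hits / n_replicates


def two_group_power(
    mean_a: float, sd_a: float, mean_b: float, sd_b: float,
    n_per_group: int, n_replicates: int, seed: int,
) -> tuple[float, float]:
    """(median p, rejection rate at 0.05) for normal groups at the given
    means/SDs -- a Monte-Carlo power check of the two-group comparison."""
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_replicates):
        a = rng.normal(mean_a, sd_a, n_per_group)
        b = rng.normal(mean_b, sd_b, n_per_group)
        ps.append(compare_two_groups({"a": a, "b": b}).p_value)
    ps = np.asarray(ps)
    return float(np.median(ps)), float(np.mean(ps < 0.05))
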