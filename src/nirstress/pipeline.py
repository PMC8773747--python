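"""End-to-end analysis: cohort -> recordings -> preprocessing -> LIS -> statistics.

`run_synthetic_pipeline` is the in-memory engine; `run_pipeline` wraps it
with on-disk artifacts (cohort table, grand averages, LIS tables, stats
reports, and a run manifest) so a run can be archived and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .containers import EpochSet, HemoTimeSeries
from .laterality import LISResult, lis_by_group_session, lis_table
from .mbll import forward_mbll, mbll_inverse
from .paradigm import build_session_schedule, trial_onsets
from .preprocess import bandpass, baseline_correct, epoch, grand_average
from .stats import compare_three_groups, compare_two_groups, correlate
from .synthetic import (
    SimulationParams,
    record_n_samples,
    sample_cohort,
    simulate_hemodynamics,
    task_response,
)

SESSIONS = (1, 2)


@dataclass
class PipelineResult:
    cohort: list
    lis_three_group: list[LISResult]
    lis_two_group: list[LISResult]
    stats: dict
    epoch_sets: dict = field(default_factory=dict)  # (group, session) -> [EpochSet]


def preprocess_recording(ts: HemoTimeSeries, onsets_s, config: PipelineConfig) -> EpochSet:
    """Filter -> epoch (dHbO only) -> baseline-correct one recording."""
    filtered = bandpass(ts, config.filter.low_hz, config.filter.high_hz,
                        config.filter.order, config.filter.ripple_db)
    ep = epoch(filtered, onsets_s, window_s=config.epoch.window_s)
    return baseline_correct(ep)


def run_synthetic_pipeline(
    config: PipelineConfig,
    sim_params: SimulationParams | None = None,
    sessions=SESSIONS,
    keep_epochs: bool = False,
    right_gains: dict | None = None,
) -> PipelineResult:
    """Simulate a cohort and run the full analysis on it, deterministically."""
    config.validate()
    sim_params = sim_params or SimulationParams(fs_hz=config.layout.fs_hz)
    cohort = sample_cohort(config.n_per_group, config.seed, right_gains=right_gains)
    seed_rng = np.random.default_rng(config.seed)
    part_seeds = seed_rng.integers(0, 2**31, size=(len(cohort), len(sessions)))

    by_group_session: dict[tuple[str, int], list[EpochSet]] = {}
    for s_idx, session in enumerate(sessions):
        schedule = build_session_schedule(session, seed=config.seed + session)
        onsets = trial_onsets(schedule)
        n = record_n_samples(schedule, sim_params.fs_hz)
        base = task_response(schedule, sim_params, n)
        for p_idx, part in enumerate(cohort):
            params_i = replace(sim_params, seed=int(part_seeds[p_idx, s_idx]))
            hemo = simulate_hemodynamics(schedule, part, params_i,
                                         layout=config.layout, base_response=base)
            if config.use_forward_model:
                rec = forward_mbll(hemo, config.layout, config.mbll.dpf)
                hemo = mbll_inverse(rec, config.layout, config.mbll.dpf)
            ep = preprocess_recording(hemo, onsets, config)
            by_group_session.setdefault((part.true_group, session), []).append(ep)

    lis3 = lis_by_group_session(by_group_session, config.layout,
                                config.lis.interval_s, config.lis.aggregation)

    two_group: dict[tuple[str, int], list[EpochSet]] = {}
    for (group, session), eps in by_group_session.items():
        label = "control" if group == "control" else "stress"
        two_group.setdefault((label, session), []).extend(eps)
    lis2 = lis_by_group_session(two_group, config.layout,
                                config.lis.interval_s, config.lis.aggregation)

    # group tests need >= 2 participants per group
    stats = _cohort_statistics(cohort) if config.n_per_group >= 2 else {}
    return PipelineResult(
        cohort=cohort,
        lis_three_group=lis3,
        lis_two_group=lis2,
        stats=stats,
        epoch_sets=by_group_session if keep_epochs else {},
    )


def _cohort_statistics(cohort) -> dict:
    saa3 = {g: [p.saa_kul for p in cohort if p.true_group == g]
            for g in ("control", "eustress", "distress")}
    saa2 = {
        "control": saa3["control"],
        "stress": saa3["eustress"] + saa3["distress"],
    }
    two = compare_two_groups(saa2)
    three = compare_three_groups(saa3)
    saa = [p.saa_kul for p in cohort]
    acc = [p.accuracy_pct for p in cohort]
    rt = [p.rt_ms for p in cohort]
    r_acc, p_acc = correlate(saa, acc)
    r_rt, p_rt = correlate(saa, rt)
    return {
        "saa_two_group": two,
        "saa_three_group": three,
        "corr_saa_accuracy": {"r": r_acc, "p": p_acc},
        "corr_saa_rt": {"r": r_rt, "p": p_rt},
    }


def _report_to_dict(report) -> dict:
    return {
        "test": report.test_name,
        "statistic": report.statistic,
        "p_value": report.p_value,
        "groups": {k: {"mean": m, "sd": s, "n": n}
                   for k, (m, s, n) in report.group_stats.items()},
        "levene": {"statistic": report.levene_statistic, "p": report.levene_p},
        "variant": report.variant,
        "posthoc": [
            {"pair": [c.group_a, c.group_b], "difference": c.mean_difference,
             "t": c.statistic, "df": c.df, "p": c.p_value}
            for c in report.posthoc
        ],
    }


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    sim_params: SimulationParams | None = None,
) -> PipelineResult:
    """Run the synthetic end-to-end analysis and write artifacts to ``out_dir``."""
    from .synthetic import cohort_frame

    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_synthetic_pipeline(config, sim_params, keep_epochs=True)

    cohort_frame(result.cohort).to_csv(out / "cohort.csv", index=False)
    lis_table(result.lis_three_group).to_csv(out / "lis_three_group.csv", index=False)
    lis_table(result.lis_two_group).to_csv(out / "lis_two_group.csv", index=False)
    for (group, session), eps in result.epoch_sets.items():
        ga = grand_average(eps)
        times = eps[0].times
        df = pd.DataFrame(ga.T, columns=[f"ch{c + 1:02d}_hbo" for c in range(ga.shape[0])])
        df.insert(0, "t", times)
        df.to_csv(out / f"grand_average_{group}_s{session}.csv", index=False)
    stats_json = {
        k: (_report_to_dict(v) if hasattr(v, "test_name") else v)
        for k, v in result.stats.items()
    }
    (out / "stats.json").write_text(json.dumps(stats_json, indent=2))

    cfg = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "package": f"nirstress {__version__}",
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": json.loads(cfg),
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
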