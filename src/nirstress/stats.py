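"""Group assignment by salivary alpha-amylase and group-comparison statistics.

sAA thresholds (KU/L): control < 28; stress > 33, subdivided into eustress
(33 < sAA < 44) and distress (sAA > 44). The 28-33 gap and the boundary
values are "unclassified" -- the study design enrolled nobody there, and
the strict inequalities of the definitions are kept.

Group comparisons follow the conventional battery: Levene's test for
homogeneity of variance, then a two-sample t-test (Welch when Levene
rejects at 0.05, pooled otherwise) or a one-way ANOVA with Dunnett's T3
post hoc. T3 refers each pairwise Welch statistic to the studentized
maximum modulus (SMM) distribution, appropriate for unequal variances.
Correlations are two-tailed Pearson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate
from scipy import stats as _sst

SAA_CONTROL_MAX_KUL = 28.0
SAA_STRESS_MIN_KUL = 33.0
SAA_DISTRESS_MIN_KUL = 44.0

LEVENE_ALPHA = 0.05


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined on the given data (zero variance)."""


@dataclass(frozen=True)
class GroupAssignment:
    participant_id: str
    saa_kul: float
    two_group: str  # control | stress | unclassified
    three_group: str  # control | eustress | distress | unclassified


@dataclass
class PosthocComparison:
    group_a: str
    group_b: str
    mean_difference: float
    statistic: float
    df: float
    p_value: float


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    group_stats: dict  # name -> (mean, sd, n)
    levene_statistic: Optional[float] = None
    levene_p: Optional[float] = None
    variant: Optional[str] = None  # "pooled" | "welch" for t-tests
    posthoc: list = field(default_factory=list)


def classify_by_saa(saa_kul: float, participant_id: str = "") -> GroupAssignment:
    """Assign two- and three-group labels from an sAA level in KU/L."""
    if saa_kul < 0:
        raise ValueError(f"sAA level must be non-negative, got {saa_kul}")
    if saa_kul < SAA_CONTROL_MAX_KUL:
        two, three = "control", "control"
    elif SAA_STRESS_MIN_KUL < saa_kul < SAA_DISTRESS_MIN_KUL:
        two, three = "stress", "eustress"
    elif saa_kul > SAA_DISTRESS_MIN_KUL:
        two, three = "stress", "distress"
    else:
        two, three = "unclassified", "unclassified"
    return GroupAssignment(participant_id=participant_id, saa_kul=float(saa_kul),
                           two_group=two, three_group=three)


def _group_stats(groups: dict) -> dict:
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values, has {v.size}")
        out[name] = (float(v.mean()), float(v.std(ddof=1)), int(v.size))
    return out


def compare_two_groups(groups: dict) -> TestReport:
    """Levene check followed by an independent two-sample t-test.

    ``groups`` maps two group names to value sequences. Welch's t is used
    when Levene rejects homogeneity at 0.05, the pooled t otherwise.
    """
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    gs = _group_stats(groups)
    a, b = (np.asarray(v, float) for v in groups.values())
    if a.var() == 0 and b.var() == 0:
        raise DegenerateDataError("both groups have zero variance; t is undefined")
    lev_stat, lev_p = _sst.levene(a, b)
    equal_var = lev_p >= LEVENE_ALPHA
    t, p = _sst.ttest_ind(a, b, equal_var=equal_var)
    return TestReport(
        test_name="independent t-test",
        statistic=float(t),
        p_value=float(p),
        group_stats=gs,
        levene_statistic=float(lev_stat),
        levene_p=float(lev_p),
        variant="pooled" if equal_var else "welch",
    )


def smm_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized maximum modulus: max of k independent |Z|,
    studentized by an independent chi(df)/sqrt(df) scale."""
    if q <= 0:
        return 0.0
    sqrt_df = np.sqrt(df)

    def integrand(u):
        return (2.0 * _sst.norm.cdf(q * u) - 1.0) ** k * _sst.chi.pdf(u * sqrt_df, df) * sqrt_df

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-9, epsrel=1e-9, limit=200)
    return float(min(1.0, max(0.0, val)))


def dunnett_t3(groups: dict) -> list[PosthocComparison]:
    """Dunnett T3 pairwise comparisons (unequal variances).

    Each pair uses the Welch statistic and degrees of freedom; the p-value
    refers |t| to the SMM distribution with k = number of pairs.
    """
    names = list(groups)
    arrays = {n: np.asarray(groups[n], float) for n in names}
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    k = len(pairs)
    out = []
    for a_name, b_name in pairs:
        a, b = arrays[a_name], arrays[b_name]
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0:
            raise DegenerateDataError(
                f"pair ({a_name}, {b_name}) has zero variance; T3 undefined"
            )
        diff = a.mean() - b.mean()
        se = np.sqrt(va + vb)
        t = diff / se
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = 1.0 - smm_cdf(abs(t), k, df)
        out.append(
            PosthocComparison(group_a=a_name, group_b=b_name, mean_difference=float(diff),
                              statistic=float(t), df=float(df), p_value=float(p))
        )
    return out


def compare_three_groups(groups: dict, run_posthoc: bool = True) -> TestReport:
    """One-way ANOVA across three groups with Dunnett T3 post hoc.

    ``run_posthoc=False`` skips the T3 comparisons (useful in replicate
    studies where only the omnibus test is of interest).
    """
    if len(groups) != 3:
        raise ValueError(f"expected exactly 3 groups, got {len(groups)}")
    gs = _group_stats(groups)
    arrays = [np.asarray(v, float) for v in groups.values()]
    if all(a.var() == 0 for a in arrays):
        raise DegenerateDataError("all groups have zero variance; F is undefined")
    lev_stat, lev_p = _sst.levene(*arrays)
    f, p = _sst.f_oneway(*arrays)
    return TestReport(
        test_name="one-way ANOVA",
        statistic=float(f),
        p_value=float(p),
        group_stats=gs,
        levene_statistic=float(lev_stat),
        levene_p=float(lev_p),
        posthoc=dunnett_t3(groups) if run_posthoc else [],
    )


def correlate(x, y) -> tuple[float, float]:
    """Two-tailed Pearson correlation; p from the t distribution with n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r, p = _sst.pearsonr(x, y)
    return float(r), float(p)
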