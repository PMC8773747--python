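"""sAA-based grouping and the group-comparison statistics.

Participants are assigned by salivary alpha-amylase: control < 28 KU/L,
eustress 33-44 KU/L, distress > 44 KU/L. Group contrasts use Levene +
t-test (two groups) or one-way ANOVA with Dunnett T3 post hoc (three
groups, unequal variances); correlations are two-tailed Pearson.
"""

from nirstress import (
    classify_by_saa,
    compare_three_groups,
    compare_two_groups,
    correlate,
    sample_cohort,
)

for saa in (12.7, 30.0, 37.8, 61.8):
    a = classify_by_saa(saa)
    print(f"sAA {saa:5.1f} KU/L -> two-group {a.two_group:<12} "
          f"three-group {a.three_group}")

cohort = sample_cohort(11, seed=1)
saa3 = {g: [p.saa_kul for p in cohort if p.true_group == g]
        for g in ("control", "eustress", "distress")}

rep2 = compare_two_groups(
    {"control": saa3["control"], "stress": saa3["eustress"] + saa3["distress"]}
)
print(f"\ntwo-group sAA t-test ({rep2.variant}): t = {rep2.statistic:.2f}, "
      f"p = {rep2.p_value:.2e}")

rep3 = compare_three_groups(saa3)
print(f"three-group ANOVA: F = {rep3.statistic:.2f}, p = {rep3.p_value:.2e}")
for c in rep3.posthoc:
    print(f"  Dunnett T3 {c.group_a} vs {c.group_b}: "
          f"t = {c.statistic:6.2f}, df = {c.df:5.1f}, p = {c.p_value:.4f}")

r, p = correlate([p.saa_kul for p in cohort], [p.accuracy_pct for p in cohort])
print(f"Pearson sAA vs accuracy: r = {r:.3f}, p = {p:.3f}")
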