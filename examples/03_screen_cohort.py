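"""Screen feature relevance against AHI on a synthetic cohort.

Simulates 60 subjects spanning 0-60 events/h, extracts ODI and sample entropy
at six timescales, computes Spearman correlations with the true AHI and
classifies each feature's scale-trend group (A decaying, B coarser-peak,
C polarity shift, D constant-high).
"""

from oxiscale import SimConfig, clean_spo2, coarse_grain, extract_all
from oxiscale.screening import build_feature_matrix, classify_trends, spearman_screen
from oxiscale.synthetic import simulate_cohort, uniform_rates

records, labels = simulate_cohort(60, uniform_rates(0, 60),
                                  SimConfig(duration_h=2.0), seed=11)
rows = []
for rec in records:
    s = clean_spo2(rec.series)
    for tau in (1, 2, 3, 5, 30, 60):
        rows.append((rec.series.subject_id, tau,
                     extract_all(coarse_grain(s, tau), include=["ODI", "SampEn"])))

report = spearman_screen(build_feature_matrix(rows), labels)
print(report.pivot(index="tau", columns="feature", values="rho").round(3))
print()
print(classify_trends(report)[["feature", "rho_best", "tau_best", "trend_group"]]
      .to_string(index=False))
# Expected: ODI correlates strongly at 1 s and collapses by 60 s (group A);
# SampEn stays above |rho| = 0.4 at every scale up to 60 s (group D).
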