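"""Relative sampling speed predicts preference; choice speed reveals mechanism.

Computes the two per-rat sampling statistics (latency ratio LR and winning
latency WL), their Spearman correlation with preference, and within-subject
sampling-vs-choice contrasts in each preference group.  Under the race
regime, recorded choice latencies are censored downward, so the rank-biserial
effect size is positive where the option laws overlap.
"""

import choicelat as cl

config = cl.CohortConfig(
    regime="SCM",
    n_rats={"SP": 30, "IND": 15, "CP": 15},
    n_sessions=5,
    seed=5,
)
summaries = cl.summarize_cohort(
    cl.select_analysis_window(cl.simulate_cohort(config), 3)
)

for statistic in ("LR", "WL"):
    rho, p = cl.preference_latency_correlation(summaries, statistic)
    print(f"{statistic} vs % cocaine choice: Spearman rho={rho:.2f}, p={p:.2g}")

for group, option in (("SP", "saccharin"), ("CP", "cocaine"), ("IND", "cocaine")):
    comp = cl.paired_latency_comparison(summaries, group, option)
    print(
        f"{group} x {option}: n={comp.n_rats}, "
        f"rank-biserial={comp.rank_biserial:+.2f}, p={comp.p_value:.2g}"
    )
# Positive correlations: the faster a rat samples cocaine relative to
# saccharin, the more it chooses cocaine.  Positive rank-biserial values mean
# choice latencies were *shorter* than sampling latencies (race censorship);
# the effect is strongest where option laws overlap (IND rats).
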