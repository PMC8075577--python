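"""Latency statistics and within-subject sampling-vs-choice contrasts.

Two per-rat summaries of relative sampling speed:

* **latency ratio** LR = mean(saccharin sampling) / (mean(saccharin) +
  mean(cocaine)); values near 1 mean cocaine is sampled faster;
* **winning latency** WL = proportion of (cocaine, saccharin) sampling-latency
  pairs, compared two by two, in which the cocaine latency is shorter ("wins
  the race"); ties count one half.

Both are correlated with preference (Spearman).  The mechanistic contrast is a
within-subject Wilcoxon signed-rank between each rat's mean sampling and mean
choice latency for an option, with the rank-biserial correlation
r = (W+ - W-) / (W+ + W-) as effect size: positive r means choice was faster
than sampling (the race-model censorship signature), negative r means choice
was slower (the deliberation signature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .trial_data import OPTIONS, PROFILES, RatSummary

GROUPS = PROFILES + ("ALL",)


def latency_ratio(
    saccharin_sampling: Sequence[float], cocaine_sampling: Sequence[float]
) -> float:
    """LR = mean(S) / (mean(S) + mean(C)), in [0, 1]."""
    if len(saccharin_sampling) == 0 or len(cocaine_sampling) == 0:
        raise ValueError("latency_ratio requires non-empty latency lists")
    mean_s = float(np.mean(saccharin_sampling))
    mean_c = float(np.mean(cocaine_sampling))
    if mean_s + mean_c == 0:
        raise ValueError("latency_ratio undefined when both means are zero")
    return mean_s / (mean_s + mean_c)


def winning_latency(
    cocaine_sampling: Sequence[float], saccharin_sampling: Sequence[float]
) -> float:
    """Pairwise win probability of cocaine over saccharin sampling latencies.

    All |C| x |S| pairs are compared; a strictly shorter cocaine latency is a
    win, an exact tie counts 0.5 (preserving WL(C,S) + WL(S,C) = 1).  0 means
    cocaine never wins the race, 1 means it always wins.
    """
    c = np.asarray(cocaine_sampling, dtype=float)
    s = np.asarray(saccharin_sampling, dtype=float)
    if c.size == 0 or s.size == 0:
        raise ValueError("winning_latency requires non-empty latency lists")
    wins = (c[:, None] < s[None, :]).sum()
    ties = (c[:, None] == s[None, :]).sum()
    return float((wins + 0.5 * ties) / (c.size * s.size))


def rank_biserial(
    sampling_means: Sequence[float], choice_means: Sequence[float]
) -> float:
    """Matched-pairs rank-biserial correlation, r = (W+ - W-)/(W+ + W-).

    Differences d_i = sampling_i - choice_i are signed-ranked by |d_i| with
    mid-ranks for ties; zero differences are discarded before ranking.  r > 0
    means choice latencies were shorter than sampling latencies.
    """
    d = np.asarray(sampling_means, dtype=float) - np.asarray(
        choice_means, dtype=float
    )
    if d.size != len(sampling_means) or len(sampling_means) != len(choice_means):
        raise ValueError("sampling and choice lists must have equal length")
    if d.size < 2:
        raise ValueError("rank_biserial requires at least 2 pairs")
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("rank_biserial undefined when all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return (w_plus - w_minus) / (w_plus + w_minus)


@dataclass(frozen=True)
class PairedComparison:
    """Within-subject sampling-vs-choice contrast for one group x option."""

    group: str
    option: str
    n_rats: int
    n_excluded: int
    sampling_means: tuple[float, ...]
    choice_means: tuple[float, ...]
    wilcoxon_stat: float
    p_value: float
    rank_biserial: float
    omission_mode: str


def paired_latency_comparison(
    summaries: Sequence[RatSummary],
    group: str,
    option: str,
    omission_mode: str = "include",
) -> PairedComparison:
    """Compare mean sampling vs mean choice latency for ``option`` within
    ``group`` (a preference profile, or "ALL").

    Rats whose choice-latency list for the option is empty (they never chose
    it in the window) cannot contribute a pair and are excluded but counted.
    The contrast is only meaningful for an option the group actually chooses;
    fewer than 2 eligible rats is an error.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if option not in OPTIONS:
        raise ValueError(f"unknown option {option!r}")
    members = [
        s for s in summaries if group == "ALL" or s.profile == group
    ]
    sampling, choice = [], []
    n_excluded = 0
    for s in members:
        samp = s.sampling_latencies(option)
        chos = s.choice_latencies(option)
        if len(samp) == 0 or len(chos) == 0:
            n_excluded += 1
            continue
        sampling.append(float(np.mean(samp)))
        choice.append(float(np.mean(chos)))
    if len(sampling) < 2:
        raise ValueError(
            f"group {group} x option {option}: only {len(sampling)} eligible "
            f"rats (need >= 2); comparison not computed"
        )
    res = stats.wilcoxon(sampling, choice, zero_method="wilcox", method="auto")
    return PairedComparison(
        group=group,
        option=option,
        n_rats=len(sampling),
        n_excluded=n_excluded,
        sampling_means=tuple(sampling),
        choice_means=tuple(choice),
        wilcoxon_stat=float(res.statistic),
        p_value=float(res.pvalue),
        rank_biserial=rank_biserial(sampling, choice),
        omission_mode=omission_mode,
    )


def preference_latency_correlation(
    summaries: Sequence[RatSummary], statistic: str = "WL"
) -> tuple[float, float]:
    """Spearman correlation between a per-rat sampling statistic (LR or WL)
    and preference (% cocaine choices).  Returns (rho, p)."""
    if statistic not in ("LR", "WL"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if len(summaries) < 5:
        raise ValueError("preference_latency_correlation requires >= 5 rats")
    values, prefs = [], []
    for s in summaries:
        if statistic == "LR":
            values.append(
                latency_ratio(
                    s.sampling_latencies_saccharin, s.sampling_latencies_cocaine
                )
            )
        else:
            values.append(
                winning_latency(
                    s.sampling_latencies_cocaine, s.sampling_latencies_saccharin
                )
            )
        prefs.append(s.preference_pct)
    res = stats.spearmanr(values, prefs)
    rho, p = float(res.statistic), float(res.pvalue)
    if np.isnan(rho):
        raise ValueError(
            "correlation undefined (constant statistic or preference vector)"
        )
    return rho, p


def rat_statistics(summaries: Sequence[RatSummary]) -> list[dict]:
    """Per-rat LR, WL, preference and profile rows for reporting."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "rat_id": s.rat_id,
                "LR": latency_ratio(
                    s.sampling_latencies_saccharin, s.sampling_latencies_cocaine
                ),
                "WL": winning_latency(
                    s.sampling_latencies_cocaine, s.sampling_latencies_saccharin
                ),
                "preference_pct": s.preference_pct,
                "profile": s.profile,
            }
        )
    return rows
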