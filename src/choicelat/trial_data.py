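"""Data model, I/O and per-rat summarization of discrete-trial choice sessions.

A daily session has 12 trials separated by 10 min inter-trial intervals: four
*sampling* trials in which each lever (cocaine or saccharin) is presented alone,
twice per option in alternation, followed by eight *choice* trials with both
levers available.  Latency is the time (s) from lever insertion to completion of
the FR2 requirement; a failure to respond within 5 min is an *omission* and is
recorded at the 300 s ceiling.

The on-disk format is a plain comma-delimited table with one row per trial and
header ``rat_id,session_index,trial_index,phase,option_presented,option_chosen,
latency_s,omission`` — hand-editable and diff-friendly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

OPTIONS = ("cocaine", "saccharin")
PHASES = ("sampling", "choice")
PROFILES = ("SP", "IND", "CP")

#: latency ceiling assigned to omitted trials, seconds
OMISSION_LATENCY_S = 300.0
TRIALS_PER_SESSION = 12
N_SAMPLING_TRIALS = 4
N_CHOICE_TRIALS = 8

#: profile boundaries in percent cocaine choices; exact thirds fall in IND
SP_UPPER = 100.0 / 3.0
CP_LOWER = 200.0 / 3.0

TRIAL_COLUMNS = (
    "rat_id",
    "session_index",
    "trial_index",
    "phase",
    "option_presented",
    "option_chosen",
    "latency_s",
    "omission",
)


class TrialParseError(ValueError):
    """A row of a trial table could not be parsed."""


class TrialValidationError(ValueError):
    """A trial record or session violates the protocol invariants."""


@dataclass(frozen=True)
class TrialRecord:
    """One trial of one rat."""

    rat_id: str
    session_index: int
    trial_index: int
    phase: str  # "sampling" | "choice"
    option_presented: str  # "cocaine" | "saccharin" | "both"
    option_chosen: str  # "cocaine" | "saccharin" | "none"
    latency_s: float
    omission: bool

    def validate(self) -> None:
        where = f"rat={self.rat_id} session={self.session_index} trial={self.trial_index}"
        if self.session_index < 1:
            raise TrialValidationError(f"{where}: session_index must be >= 1")
        if not 1 <= self.trial_index <= TRIALS_PER_SESSION:
            raise TrialValidationError(f"{where}: trial_index must be in 1..12")
        if self.phase not in PHASES:
            raise TrialValidationError(f"{where}: unknown phase {self.phase!r}")
        if self.phase == "sampling":
            if self.option_presented not in OPTIONS:
                raise TrialValidationError(
                    f"{where}: sampling trial must present a single option, "
                    f"got {self.option_presented!r}"
                )
            if self.option_chosen not in (self.option_presented, "none"):
                raise TrialValidationError(
                    f"{where}: sampling response {self.option_chosen!r} does not "
                    f"match presented option {self.option_presented!r}"
                )
        else:
            if self.option_presented != "both":
                raise TrialValidationError(
                    f"{where}: choice trial must present both options"
                )
            if self.option_chosen not in OPTIONS + ("none",):
                raise TrialValidationError(
                    f"{where}: unknown chosen option {self.option_chosen!r}"
                )
        if not 0.0 <= self.latency_s <= OMISSION_LATENCY_S:
            raise TrialValidationError(
                f"{where}: latency {self.latency_s} outside [0, {OMISSION_LATENCY_S}]"
            )
        is_ceiling = self.latency_s == OMISSION_LATENCY_S
        is_none = self.option_chosen == "none"
        if not (self.omission == is_ceiling == is_none):
            raise TrialValidationError(
                f"{where}: omission inconsistency (omission={self.omission}, "
                f"latency_s={self.latency_s}, option_chosen={self.option_chosen}); "
                f"omission=true <=> option_chosen=none <=> latency_s=300"
            )

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.rat_id, self.session_index, self.trial_index)


def validate_sessions(records: Sequence[TrialRecord]) -> None:
    """Check the 4-sampling + 8-choice structure of every complete session."""
    by_session: dict[tuple[str, int], list[TrialRecord]] = {}
    for rec in records:
        by_session.setdefault((rec.rat_id, rec.session_index), []).append(rec)
    for (rat, sess), recs in by_session.items():
        where = f"rat={rat} session={sess}"
        idx = sorted(r.trial_index for r in recs)
        if idx != list(range(1, TRIALS_PER_SESSION + 1)):
            raise TrialValidationError(
                f"{where}: expected trial indices 1..12, got {idx}"
            )
        recs = sorted(recs, key=lambda r: r.trial_index)
        sampling, choice = recs[:N_SAMPLING_TRIALS], recs[N_SAMPLING_TRIALS:]
        if any(r.phase != "sampling" for r in sampling):
            raise TrialValidationError(f"{where}: trials 1-4 must be sampling")
        if any(r.phase != "choice" for r in choice):
            raise TrialValidationError(f"{where}: trials 5-12 must be choice")
        pattern = tuple(r.option_presented for r in sampling)
        if pattern not in (
            ("cocaine", "saccharin", "cocaine", "saccharin"),
            ("saccharin", "cocaine", "saccharin", "cocaine"),
        ):
            raise TrialValidationError(
                f"{where}: sampling options must alternate, 2 per option; got {pattern}"
            )


def _parse_row(row: Mapping[str, str], lineno: int) -> TrialRecord:
    try:
        omission = row["omission"].strip().lower()
        if omission not in ("true", "false"):
            raise ValueError(f"omission must be true/false, got {row['omission']!r}")
        return TrialRecord(
            rat_id=row["rat_id"],
            session_index=int(row["session_index"]),
            trial_index=int(row["trial_index"]),
            phase=row["phase"],
            option_presented=row["option_presented"],
            option_chosen=row["option_chosen"],
            latency_s=float(row["latency_s"]),
            omission=omission == "true",
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise TrialParseError(f"line {lineno}: malformed trial row ({exc})") from exc


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read and validate a trial table; records are returned sorted by
    (rat_id, session_index, trial_index)."""
    path = Path(path)
    records: list[TrialRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(TRIAL_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise TrialParseError(
                f"{path}: header missing columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            records.append(_parse_row(row, lineno))
    for rec in records:
        rec.validate()
    validate_sessions(records)
    records.sort(key=lambda r: r.key)
    return records


def write_trials(records: Sequence[TrialRecord], path: str | Path) -> None:
    """Write a trial table readable by :func:`read_trials`.

    Latencies are written with Python's shortest round-tripping float
    representation, so write -> read is the identity.
    """
    seen: set[tuple[str, int, int]] = set()
    for rec in records:
        rec.validate()
        if rec.key in seen:
            raise TrialValidationError(
                f"duplicate trial key rat={rec.key[0]} session={rec.key[1]} "
                f"trial={rec.key[2]}"
            )
        seen.add(rec.key)
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.rat_id,
                    rec.session_index,
                    rec.trial_index,
                    rec.phase,
                    rec.option_presented,
                    rec.option_chosen,
                    repr(rec.latency_s),
                    "true" if rec.omission else "false",
                ]
            )


def select_analysis_window(
    records: Sequence[TrialRecord], n_sessions: int = 3
) -> list[TrialRecord]:
    """Keep, for each rat, only its final ``n_sessions`` sessions.

    The analysis window is the last sessions of a stable choice phase, where
    preference has settled and within-subject variability is low.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    sessions_by_rat: dict[str, set[int]] = {}
    for rec in records:
        sessions_by_rat.setdefault(rec.rat_id, set()).add(rec.session_index)
    keep: dict[str, set[int]] = {}
    for rat, sessions in sessions_by_rat.items():
        if len(sessions) < n_sessions:
            raise ValueError(
                f"rat {rat} has only {len(sessions)} sessions, needs {n_sessions}"
            )
        keep[rat] = set(sorted(sessions)[-n_sessions:])
    return [r for r in records if r.session_index in keep[r.rat_id]]


@dataclass
class RatSummary:
    """Per-rat latency aggregates over the analysis window.

    Over a 3-session window with no omissions there are 6 sampling latencies per
    option and 24 choice latencies split between options according to the rat's
    preference.  Choice-latency lists are keyed by the *chosen* option; omitted
    choice trials carry no chosen option and therefore never enter a choice
    list (they are counted in ``n_omissions_choice``).
    """

    rat_id: str
    sampling_latencies_cocaine: list[float] = field(default_factory=list)
    sampling_latencies_saccharin: list[float] = field(default_factory=list)
    choice_latencies_cocaine: list[float] = field(default_factory=list)
    choice_latencies_saccharin: list[float] = field(default_factory=list)
    n_omissions_sampling: int = 0
    n_omissions_choice: int = 0
    preference_pct: float = float("nan")
    profile: str = ""

    def sampling_latencies(self, option: str) -> list[float]:
        return getattr(self, f"sampling_latencies_{option}")

    def choice_latencies(self, option: str) -> list[float]:
        return getattr(self, f"choice_latencies_{option}")

    @property
    def mean_sampling_cocaine(self) -> float:
        return _mean_or_nan(self.sampling_latencies_cocaine)

    @property
    def mean_sampling_saccharin(self) -> float:
        return _mean_or_nan(self.sampling_latencies_saccharin)

    @property
    def mean_choice_cocaine(self) -> float:
        return _mean_or_nan(self.choice_latencies_cocaine)

    @property
    def mean_choice_saccharin(self) -> float:
        return _mean_or_nan(self.choice_latencies_saccharin)


def _mean_or_nan(values: Sequence[float]) -> float:
    return float(np.mean(values)) if len(values) else float("nan")


def preference_score(summary: RatSummary) -> float:
    """Percent cocaine choices among completed choice trials, in [0, 100]."""
    n_coc = len(summary.choice_latencies_cocaine)
    n_sac = len(summary.choice_latencies_saccharin)
    completed = n_coc + n_sac
    if completed == 0:
        raise ValueError(
            f"rat {summary.rat_id}: preference undefined with zero completed "
            "choice trials"
        )
    return 100.0 * n_coc / completed


def classify_profile(preference_pct: float) -> str:
    """SP below 33.3% cocaine choices, CP above 66.6%, IND in between."""
    if not 0.0 <= preference_pct <= 100.0:
        raise ValueError(f"preference_pct {preference_pct} outside [0, 100]")
    if preference_pct < SP_UPPER:
        return "SP"
    if preference_pct > CP_LOWER:
        return "CP"
    return "IND"


def summarize_rat(
    records: Sequence[TrialRecord], omission_mode: str = "include"
) -> RatSummary:
    """Aggregate one rat's analysis-window trials into a :class:`RatSummary`.

    ``omission_mode="include"`` keeps omitted sampling trials at the 300 s
    ceiling in the sampling lists; ``"exclude"`` drops omitted trials from all
    latency lists.  Omitted choice trials are never attributed to an option, so
    the preference denominator is the number of completed choice trials in both
    modes.
    """
    if omission_mode not in ("include", "exclude"):
        raise ValueError(f"unknown omission_mode {omission_mode!r}")
    if not records:
        raise ValueError("summarize_rat: empty record set")
    rat_ids = {r.rat_id for r in records}
    if len(rat_ids) != 1:
        raise ValueError(f"summarize_rat: records span multiple rats {sorted(rat_ids)}")
    summary = RatSummary(rat_id=records[0].rat_id)
    for rec in sorted(records, key=lambda r: r.key):
        if rec.phase == "sampling":
            if rec.omission:
                summary.n_omissions_sampling += 1
                if omission_mode == "include":
                    summary.sampling_latencies(rec.option_presented).append(
                        rec.latency_s
                    )
            else:
                summary.sampling_latencies(rec.option_presented).append(rec.latency_s)
        else:
            if rec.omission:
                summary.n_omissions_choice += 1
            else:
                summary.choice_latencies(rec.option_chosen).append(rec.latency_s)
    summary.preference_pct = preference_score(summary)
    summary.profile = classify_profile(summary.preference_pct)
    return summary


def summarize_cohort(
    records: Sequence[TrialRecord], omission_mode: str = "include"
) -> list[RatSummary]:
    """Summarize every rat present in ``records`` (sorted by rat id)."""
    by_rat: dict[str, list[TrialRecord]] = {}
    for rec in records:
        by_rat.setdefault(rec.rat_id, []).append(rec)
    return [
        summarize_rat(by_rat[rat], omission_mode) for rat in sorted(by_rat)
    ]


def session_preference_table(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-session preference (% cocaine of completed choices), rats x sessions."""
    rows: dict[str, dict[int, float]] = {}
    counts: dict[tuple[str, int], list[int]] = {}
    for rec in records:
        if rec.phase != "choice" or rec.omission:
            continue
        n = counts.setdefault((rec.rat_id, rec.session_index), [0, 0])
        n[0] += 1
        if rec.option_chosen == "cocaine":
            n[1] += 1
    for (rat, sess), (completed, coc) in counts.items():
        rows.setdefault(rat, {})[sess] = 100.0 * coc / completed
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return table[sorted(table.columns)]


@dataclass(frozen=True)
class StabilityReport:
    trend_ok: bool
    corr_ok: bool
    trend_p: float
    corr_ps: tuple[float, ...]


def stability_check(
    preference_table: pd.DataFrame, k: int = 3, alpha: float = 0.05
) -> StabilityReport:
    """Assess preference stability over the last ``k`` sessions.

    ``trend_ok``: no systematic drift — two-sided Wilcoxon signed-rank across
    rats between the first and last session of the window (all-zero differences
    count as no trend).  ``corr_ok``: per-rat preferences rank-correlate
    (Spearman, p < alpha) between every pair of consecutive window sessions.
    """
    if preference_table.shape[1] < k or k < 3:
        raise ValueError(f"need at least k={max(k, 3)} sessions")
    if preference_table.shape[0] < 5:
        raise ValueError("need at least 5 rats")
    window = preference_table[sorted(preference_table.columns)[-k:]].dropna()
    first = window.iloc[:, 0].to_numpy(float)
    last = window.iloc[:, -1].to_numpy(float)
    diffs = last - first
    if np.all(diffs == 0):
        trend_p = 1.0
    else:
        trend_p = float(stats.wilcoxon(last, first).pvalue)
    corr_ps = []
    for a, b in zip(range(k - 1), range(1, k)):
        res = stats.spearmanr(window.iloc[:, a], window.iloc[:, b])
        corr_ps.append(float(res.pvalue))
    return StabilityReport(
        trend_ok=trend_p >= alpha,
        corr_ok=all(p < alpha for p in corr_ps),
        trend_p=trend_p,
        corr_ps=tuple(corr_ps),
    )


def summaries_to_frame(summaries: Iterable[RatSummary]) -> pd.DataFrame:
    """Flatten summaries into the per-rat table the reports and the decoder use."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "rat_id": s.rat_id,
                "preference_pct": s.preference_pct,
                "profile": s.profile,
                "mean_sampling_cocaine": s.mean_sampling_cocaine,
                "mean_sampling_saccharin": s.mean_sampling_saccharin,
                "mean_choice_cocaine": s.mean_choice_cocaine,
                "mean_choice_saccharin": s.mean_choice_saccharin,
                "n_omissions_sampling": s.n_omissions_sampling,
                "n_omissions_choice": s.n_omissions_choice,
            }
        )
    return pd.DataFrame(rows)
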