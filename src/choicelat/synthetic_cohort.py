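"""Generative models of trial-level choice data under three latency regimes.

Three regimes span the mechanisms contrasted by the analysis:

* **SCM** (sequential choice model): each option independently elicits a
  response with some latency; on a choice trial the shorter latent latency wins
  the race and is the recorded latency.  Selection of one option censors the
  other's observable distribution, so recorded choice latencies are trimmed
  toward short values — the more the option laws overlap, the stronger the
  trimming.
* **DCM** (deliberative choice model): the options are valued and compared;
  choice follows a softmax on the value difference and deliberation adds an
  independent positive delay, so choice latencies exceed sampling latencies.
* **HABIT**: softmax choice with no deliberation cost; per-option choice
  latencies are distributed exactly like sampling latencies.

Latencies are a ~3 s reaction-time floor plus a right-skewed draw (lognormal by
default; a shifted-exponential special case is kept for closed-form oracles),
capped at the 300 s omission ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trial_data import OMISSION_LATENCY_S, TrialRecord

REGIMES = ("SCM", "DCM", "HABIT")

#: minimum attainable response latency, seconds (reaction time)
REACTION_FLOOR_S = 3.0


@dataclass(frozen=True)
class LatencyLaw:
    """Right-skewed law for the above-floor part of a response latency.

    ``family="lognormal"`` draws exp(N(log_mean, log_sd)); ``family=
    "exponential"`` draws Exp(rate) and exists so that race quantities have
    closed forms (min of exponentials) for testing.
    """

    family: str = "lognormal"
    log_mean: float = 0.0
    log_sd: float = 1.0
    rate: float = 1.0

    def validate(self) -> None:
        if self.family not in ("lognormal", "exponential"):
            raise ValueError(f"unknown latency family {self.family!r}")
        if self.family == "lognormal" and self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")
        if self.family == "exponential" and self.rate <= 0:
            raise ValueError("rate must be > 0")

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        self.validate()
        if self.family == "lognormal":
            return np.exp(rng.normal(self.log_mean, self.log_sd, size=size))
        return rng.exponential(1.0 / self.rate, size=size)

    def mean(self) -> float:
        """Closed-form mean of the above-floor component."""
        if self.family == "lognormal":
            return math.exp(self.log_mean + 0.5 * self.log_sd**2)
        return 1.0 / self.rate


@dataclass(frozen=True)
class RegimeParams:
    """Generative parameters for one rat under one regime.

    ``value_gap`` is the cocaine-minus-saccharin value difference driving the
    softmax choice rule of the DCM and HABIT regimes (the SCM race ignores it);
    ``deliberation_law`` is the extra delay added on DCM choice trials.
    """

    regime: str
    cocaine_law: LatencyLaw
    saccharin_law: LatencyLaw
    floor_s: float = REACTION_FLOOR_S
    cap_s: float = OMISSION_LATENCY_S
    deliberation_law: LatencyLaw | None = None
    value_gap: float = 0.0
    softmax_beta: float = 1.5

    def validate(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 <= self.floor_s < self.cap_s:
            raise ValueError("need 0 <= floor_s < cap_s")
        if self.softmax_beta <= 0:
            raise ValueError("softmax_beta must be > 0")
        self.cocaine_law.validate()
        self.saccharin_law.validate()
        if self.regime == "DCM":
            if self.deliberation_law is None:
                raise ValueError("DCM requires a deliberation_law")
            self.deliberation_law.validate()

    def law(self, option: str) -> LatencyLaw:
        if option == "cocaine":
            return self.cocaine_law
        if option == "saccharin":
            return self.saccharin_law
        raise ValueError(f"unknown option {option!r}")

    @property
    def p_choose_cocaine(self) -> float:
        """Softmax choice probability (DCM/HABIT)."""
        return 1.0 / (1.0 + math.exp(-self.softmax_beta * self.value_gap))


def sample_latency(
    params: RegimeParams, option: str, rng: np.random.Generator
) -> float:
    """One latency draw: min(cap, floor + law draw); cap flags an omission."""
    params.validate()
    raw = params.floor_s + float(params.law(option).sample(rng))
    return min(params.cap_s, raw)


def simulate_sampling_trial(
    params: RegimeParams,
    option: str,
    rng: np.random.Generator,
    rat_id: str = "rat",
    session_index: int = 1,
    trial_index: int = 1,
) -> TrialRecord:
    """One forced trial of ``option``; the regime plays no role here."""
    latency = sample_latency(params, option, rng)
    omission = latency >= params.cap_s
    return TrialRecord(
        rat_id=rat_id,
        session_index=session_index,
        trial_index=trial_index,
        phase="sampling",
        option_presented=option,
        option_chosen="none" if omission else option,
        latency_s=OMISSION_LATENCY_S if omission else latency,
        omission=omission,
    )


def simulate_choice_trial(
    params: RegimeParams,
    rng: np.random.Generator,
    rat_id: str = "rat",
    session_index: int = 1,
    trial_index: int = 5,
) -> TrialRecord:
    """One both-levers trial under the rat's regime."""
    params.validate()
    if params.regime == "SCM":
        lat_c = params.floor_s + float(params.cocaine_law.sample(rng))
        lat_s = params.floor_s + float(params.saccharin_law.sample(rng))
        if lat_c >= params.cap_s and lat_s >= params.cap_s:
            chosen, latency = "none", params.cap_s
        elif lat_c <= lat_s:
            chosen, latency = "cocaine", lat_c
        else:
            chosen, latency = "saccharin", lat_s
    else:
        chosen = "cocaine" if rng.random() < params.p_choose_cocaine else "saccharin"
        latency = params.floor_s + float(params.law(chosen).sample(rng))
        if params.regime == "DCM":
            latency += float(params.deliberation_law.sample(rng))
        if latency >= params.cap_s:
            chosen, latency = "none", params.cap_s
    omission = chosen == "none"
    return TrialRecord(
        rat_id=rat_id,
        session_index=session_index,
        trial_index=trial_index,
        phase="choice",
        option_presented="both",
        option_chosen=chosen,
        latency_s=OMISSION_LATENCY_S if omission else latency,
        omission=omission,
    )


def simulate_session(
    params: RegimeParams,
    rng: np.random.Generator,
    session_index: int = 1,
    rat_id: str = "rat",
) -> list[TrialRecord]:
    """One 12-trial session: 4 alternating sampling trials then 8 choice trials.

    The first sampled option alternates across sessions (cocaine first on odd
    session indices) so that neither lever systematically leads.
    """
    first = "cocaine" if session_index % 2 == 1 else "saccharin"
    second = "saccharin" if first == "cocaine" else "cocaine"
    records = []
    for i, option in enumerate((first, second, first, second), start=1):
        records.append(
            simulate_sampling_trial(params, option, rng, rat_id, session_index, i)
        )
    for i in range(5, 13):
        records.append(
            simulate_choice_trial(params, rng, rat_id, session_index, i)
        )
    return records


@dataclass(frozen=True)
class ArchetypeRanges:
    """Per-rat parameter ranges for one preference archetype.

    Lognormal log-means are drawn uniformly from the stated intervals; a lower
    log-mean for one option makes that option stochastically faster and (under
    every regime's defaults) more valued.
    """

    mu_cocaine: tuple[float, float]
    mu_saccharin: tuple[float, float]
    log_sd: float = 0.8
    value_gap: tuple[float, float] = (0.0, 0.0)


#: cohort mixture mirroring the saccharin-preferring majority with indifferent
#: and cocaine-preferring minorities.  The preferred option's lever is pressed
#: within a few seconds (floor + ~1-2 s) and the non-preferred option is
#: slower, but the per-option laws keep substantial overlap: even rats with a
#: clear preference show broad, overlapping latency distributions, with the
#: non-preferred option's sampling latencies long but far from the ceiling.
DEFAULT_ARCHETYPES: Mapping[str, ArchetypeRanges] = {
    "SP": ArchetypeRanges(
        mu_cocaine=(1.0, 1.8), mu_saccharin=(-0.1, 0.5), value_gap=(-2.5, -1.5)
    ),
    "IND": ArchetypeRanges(
        mu_cocaine=(0.5, 1.1), mu_saccharin=(0.5, 1.1), value_gap=(-0.3, 0.3)
    ),
    "CP": ArchetypeRanges(
        mu_cocaine=(-0.1, 0.5), mu_saccharin=(1.0, 1.8), value_gap=(1.5, 2.5)
    ),
}

#: archetype head-counts mirroring the large trained cohort's profile mix
DEFAULT_N_RATS: Mapping[str, int] = {"SP": 109, "IND": 23, "CP": 19}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative configuration.

    Defaults emulate the trained-cohort study conditions: a saccharin-
    preferring majority (109/23/19 archetype counts), 5 choice sessions of 12
    trials, 3 s reaction floor, 300 s omission cap, and a ~3 s mean
    deliberation delay when the regime is DCM.
    """

    regime: str = "SCM"
    n_rats: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_RATS)
    )
    n_sessions: int = 5
    floor_s: float = REACTION_FLOOR_S
    cap_s: float = OMISSION_LATENCY_S
    softmax_beta: float = 1.5
    deliberation_log_mean: float = 1.0
    deliberation_log_sd: float = 0.5
    archetypes: Mapping[str, ArchetypeRanges] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_sessions < 3:
            raise ValueError("n_sessions must be >= 3 (3-session analysis window)")
        for name, n in self.n_rats.items():
            if name not in self.archetypes:
                raise ValueError(f"no archetype ranges for {name!r}")
            if n < 0:
                raise ValueError(f"negative n_rats for {name!r}")


def draw_rat_params(
    config: CohortConfig, archetype: str, rng: np.random.Generator
) -> RegimeParams:
    """Draw one rat's regime parameters from its archetype's ranges."""
    ranges = config.archetypes[archetype]
    mu_c = rng.uniform(*ranges.mu_cocaine)
    mu_s = rng.uniform(*ranges.mu_saccharin)
    gap = rng.uniform(*ranges.value_gap)
    deliberation = None
    if config.regime == "DCM":
        deliberation = LatencyLaw(
            "lognormal", config.deliberation_log_mean, config.deliberation_log_sd
        )
    return RegimeParams(
        regime=config.regime,
        cocaine_law=LatencyLaw("lognormal", mu_c, ranges.log_sd),
        saccharin_law=LatencyLaw("lognormal", mu_s, ranges.log_sd),
        floor_s=config.floor_s,
        cap_s=config.cap_s,
        deliberation_law=deliberation,
        value_gap=gap,
        softmax_beta=config.softmax_beta,
    )


def simulate_cohort(config: CohortConfig) -> list[TrialRecord]:
    """Simulate a whole cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[TrialRecord] = []
    for archetype in config.n_rats:
        for i in range(config.n_rats[archetype]):
            rat_id = f"{archetype}{i + 1:03d}"
            params = draw_rat_params(config, archetype, rng)
            for session in range(1, config.n_sessions + 1):
                records.extend(
                    simulate_session(params, rng, session, rat_id)
                )
    return records


def scm_choice_probability(
    law_a: LatencyLaw,
    law_b: LatencyLaw,
    method: str = "montecarlo",
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """P(latency_A < latency_B) in a race between two option laws.

    The reaction floor shifts both racers equally and cancels.  ``analytic``
    is available for the exponential special case, where
    P = rate_A / (rate_A + rate_B).
    """
    law_a.validate()
    law_b.validate()
    if method == "analytic":
        if law_a.family == law_b.family == "exponential":
            return law_a.rate / (law_a.rate + law_b.rate)
        raise ValueError(
            "analytic race probability is only available for exponential laws"
        )
    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")
    rng = rng if rng is not None else np.random.default_rng()
    a = law_a.sample(rng, n_mc)
    b = law_b.sample(rng, n_mc)
    return float(np.mean(a < b) + 0.5 * np.mean(a == b))
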