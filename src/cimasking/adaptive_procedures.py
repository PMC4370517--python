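"""Adaptive psychophysical procedure engines.

Two engines drive any listener — simulated or a replay of recorded
responses — through the procedures used to measure cochlear-implant
thresholds and loudness matches:

* :func:`run_bekesy_tracking` — a modified Bekesy method: alternating
  ascending/descending tracking sequences whose endpoints are the levels at
  which the listener's audibility report changed. The first four sequences
  use a coarse 1 dB step, the final six a fine 0.5 dB step, and the
  threshold is the 20% trimmed mean of the final six sequence endpoints.

* :func:`run_double_staircase_balance` — two interleaved 1-up-1-down
  staircases (one starting above, one starting below the predicted match)
  converging on the level at which a comparison stimulus matches a fixed
  reference in loudness. Step size is 1 dB for the first four reversals and
  0.5 dB for the next six; the last six reversal levels of each staircase
  are pooled and averaged.

Both engines adapt in the dB domain (steps are defined in dB) and average
endpoint/reversal levels in dB before converting back to μA; μA-domain
averaging is available via the config. Listeners are plain callables bound
to their stimulus context, taking a level in μA:
``audible(level_ua) -> bool`` for tracking, and
``comparison_louder(level_ua) -> bool`` for balancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Literal, Optional, Sequence

import pandas as pd

from .errors import DomainError, SafetyLimitError
from .robust_stats import trimmed_mean
from .stimulus_space import db_to_ua, ua_to_db

__all__ = [
    "BekesyConfig",
    "TrackingSequenceLog",
    "ThresholdEstimate",
    "StaircaseConfig",
    "StaircaseLog",
    "BalancedLevel",
    "run_bekesy_tracking",
    "run_double_staircase_balance",
    "tracking_logs_to_frame",
    "staircase_logs_to_frame",
]


@dataclass(frozen=True)
class BekesyConfig:
    """Schedule and estimator settings for modified Bekesy tracking.

    ``start_level_ua`` must be below the listener's expected threshold so the
    initial ascending sequence starts inaudible. ``max_level_ua`` is a hard
    safety ceiling; ``min_level_ua`` bounds runaway descending sequences
    (e.g. a listener that reports every level audible).
    """

    start_level_ua: float
    n_sequences: int = 10
    coarse_step_db: float = 1.0
    fine_step_db: float = 0.5
    n_coarse_sequences: int = 4
    n_final_for_estimate: int = 6
    trim_proportion: float = 0.2
    max_level_ua: float = 4000.0
    min_level_ua: float = 0.5
    average_domain: Literal["db", "ua"] = "db"

    def __post_init__(self) -> None:
        if self.start_level_ua <= 0:
            raise DomainError("start_level_ua must be > 0")
        if not 0.0 <= self.trim_proportion < 0.5:
            raise DomainError("trim_proportion must lie in [0, 0.5)")
        if self.coarse_step_db <= 0 or self.fine_step_db <= 0:
            raise DomainError("step sizes must be > 0 dB")
        if self.n_final_for_estimate > self.n_sequences:
            raise DomainError("n_final_for_estimate cannot exceed n_sequences")


@dataclass
class TrackingSequenceLog:
    """One tracking sequence: every level visited and the response at each."""

    direction: Literal["ascending", "descending"]
    levels_visited: List[float] = field(default_factory=list)
    responses: List[bool] = field(default_factory=list)

    @property
    def endpoint_level(self) -> float:
        return self.levels_visited[-1]


@dataclass
class ThresholdEstimate:
    threshold_ua: float
    sequence_logs: List[TrackingSequenceLog]
    estimate_basis: List[float]  # endpoint levels (μA) of the final sequences


def run_bekesy_tracking(
    listener: Callable[[float], bool],
    config: BekesyConfig,
    rng=None,
) -> ThresholdEstimate:
    """Track a detection threshold with the modified Bekesy procedure.

    ``listener`` reports audibility for a presentation at a level in μA;
    it carries its own stimulus context (probe place/ear, optional masker)
    and randomness, so ``rng`` is accepted only for interface symmetry with
    stochastic listener factories.

    Ascending sequences raise the level one step at a time until the first
    audible response; the endpoint is that level, and the next (descending)
    sequence starts two of its own step sizes above it, ensuring audibility.
    Descending sequences mirror this. The estimate is the trimmed mean of
    the final ``n_final_for_estimate`` endpoints.
    """
    max_db = ua_to_db(config.max_level_ua)
    min_db = ua_to_db(config.min_level_ua)
    level_db = ua_to_db(config.start_level_ua)
    tol = 1e-9

    logs: List[TrackingSequenceLog] = []
    for seq_index in range(1, config.n_sequences + 1):
        step = (
            config.coarse_step_db
            if seq_index <= config.n_coarse_sequences
            else config.fine_step_db
        )
        ascending = seq_index % 2 == 1
        log = TrackingSequenceLog("ascending" if ascending else "descending")
        logs.append(log)
        while True:
            if level_db > max_db + tol:
                raise SafetyLimitError(
                    f"tracking level {db_to_ua(level_db):.1f} μA would exceed the "
                    f"{config.max_level_ua} μA safety ceiling in sequence {seq_index}",
                    partial_logs=logs,
                )
            if level_db < min_db - tol:
                raise SafetyLimitError(
                    f"tracking level fell below the {config.min_level_ua} μA floor in "
                    f"sequence {seq_index} (listener may report every level audible)",
                    partial_logs=logs,
                )
            level_ua = db_to_ua(level_db)
            audible = bool(listener(level_ua))
            log.levels_visited.append(level_ua)
            log.responses.append(audible)
            if audible == ascending:  # response changed: sequence endpoint
                break
            level_db += step if ascending else -step
        # Jump two step sizes of the sequence being entered, ensuring
        # audibility (before descending) or inaudibility (before ascending).
        if seq_index < config.n_sequences:
            next_step = (
                config.coarse_step_db
                if seq_index + 1 <= config.n_coarse_sequences
                else config.fine_step_db
            )
            level_db += 2 * next_step if ascending else -2 * next_step

    basis = [log.endpoint_level for log in logs[-config.n_final_for_estimate :]]
    if config.average_domain == "db":
        threshold = db_to_ua(
            trimmed_mean([ua_to_db(v) for v in basis], config.trim_proportion)
        )
    else:
        threshold = trimmed_mean(basis, config.trim_proportion)
    return ThresholdEstimate(threshold_ua=threshold, sequence_logs=logs, estimate_basis=basis)


@dataclass(frozen=True)
class StaircaseConfig:
    """Step/reversal schedule for the double-staircase loudness balance.

    ``start_offsets_db`` places one staircase above and one below the
    predicted match. Smaller steps than the defaults may be configured when
    the comparison ear's maximum acceptable loudness is close to the match.
    """

    coarse_step_db: float = 1.0
    fine_step_db: float = 0.5
    n_coarse_reversals: int = 4
    n_fine_reversals: int = 6
    n_reversals_for_estimate: int = 6
    start_offsets_db: tuple = (4.0, -4.0)
    max_level_ua: float = 4000.0
    min_level_ua: float = 0.5
    average_domain: Literal["db", "ua"] = "db"

    def __post_init__(self) -> None:
        if self.coarse_step_db <= 0 or self.fine_step_db <= 0:
            raise DomainError("step sizes must be > 0 dB")
        if min(self.n_coarse_reversals, self.n_fine_reversals, self.n_reversals_for_estimate) < 1:
            raise DomainError("reversal counts must be >= 1")
        if len(self.start_offsets_db) != 2:
            raise DomainError("start_offsets_db must be a pair (above, below)")


@dataclass
class StaircaseLog:
    """Trial history of one member of the interleaved pair."""

    start_level_ua: float
    levels_visited: List[float] = field(default_factory=list)
    responses: List[bool] = field(default_factory=list)  # True = comparison louder
    reversal_levels: List[float] = field(default_factory=list)


@dataclass
class BalancedLevel:
    level_ua: float
    reversal_levels: List[float]  # the pooled levels averaged for the estimate
    staircase_logs: List[StaircaseLog] = field(default_factory=list)


class _Staircase:
    def __init__(self, start_db: float, config: StaircaseConfig):
        self.cfg = config
        self.level_db = start_db
        self.prev_direction: Optional[str] = None
        self.log = StaircaseLog(start_level_ua=db_to_ua(start_db))

    @property
    def n_reversals(self) -> int:
        return len(self.log.reversal_levels)

    @property
    def done(self) -> bool:
        return self.n_reversals >= self.cfg.n_coarse_reversals + self.cfg.n_fine_reversals

    def step_size(self) -> float:
        return (
            self.cfg.coarse_step_db
            if self.n_reversals < self.cfg.n_coarse_reversals
            else self.cfg.fine_step_db
        )

    def run_trial(self, comparison_louder: Callable[[float], bool], all_logs) -> None:
        level_ua = db_to_ua(self.level_db)
        if level_ua > self.cfg.max_level_ua * (1 + 1e-12):
            raise SafetyLimitError(
                f"comparison level {level_ua:.1f} μA exceeds the maximum acceptable "
                f"loudness level of {self.cfg.max_level_ua} μA",
                partial_logs=all_logs,
            )
        louder = bool(comparison_louder(level_ua))
        self.log.levels_visited.append(level_ua)
        self.log.responses.append(louder)
        direction = "down" if louder else "up"
        if self.prev_direction is not None and direction != self.prev_direction:
            self.log.reversal_levels.append(level_ua)
        self.prev_direction = direction
        step = self.step_size()
        self.level_db += -step if direction == "down" else step
        if db_to_ua(self.level_db) < self.cfg.min_level_ua:
            self.level_db = ua_to_db(self.cfg.min_level_ua)


def run_double_staircase_balance(
    listener: Callable[[float], bool],
    predicted_match_ua: float,
    config: StaircaseConfig = StaircaseConfig(),
    rng=None,
) -> BalancedLevel:
    """Find the comparison level that matches the reference in loudness.

    ``listener(level_ua)`` answers whether the comparison stimulus at
    ``level_ua`` is louder than the fixed reference (reference context and
    response stochasticity live in the closure). One staircase starts above
    and one below ``predicted_match_ua``; trials alternate between the two,
    each adjusting its comparison level down after "comparison louder" and
    up otherwise (1-up-1-down). The estimate pools the last
    ``n_reversals_for_estimate`` reversal levels of each staircase and
    averages them in the configured domain.
    """
    if predicted_match_ua <= 0:
        raise DomainError("predicted_match_ua must be > 0")
    ref_db = ua_to_db(predicted_match_ua)
    pair = [_Staircase(ref_db + off, config) for off in config.start_offsets_db]
    logs = [s.log for s in pair]
    turn = 0
    while not all(s.done for s in pair):
        s = pair[turn % 2]
        if s.done:
            turn += 1
            continue
        s.run_trial(listener, logs)
        turn += 1

    pooled = [
        lvl
        for s in pair
        for lvl in s.log.reversal_levels[-config.n_reversals_for_estimate :]
    ]
    if config.average_domain == "db":
        level = db_to_ua(sum(ua_to_db(v) for v in pooled) / len(pooled))
    else:
        level = sum(pooled) / len(pooled)
    return BalancedLevel(level_ua=level, reversal_levels=pooled, staircase_logs=logs)


def tracking_logs_to_frame(
    estimate: ThresholdEstimate, subject: str = "", procedure: str = "bekesy"
) -> pd.DataFrame:
    """Tidy audit log: one row per presentation."""
    rows = []
    for i, log in enumerate(estimate.sequence_logs, start=1):
        for trial, (lvl, resp) in enumerate(zip(log.levels_visited, log.responses), start=1):
            rows.append(
                {
                    "subject": subject,
                    "procedure": procedure,
                    "sequence": i,
                    "direction": log.direction,
                    "trial": trial,
                    "level_uA": lvl,
                    "response": "audible" if resp else "inaudible",
                }
            )
    return pd.DataFrame(rows)


def staircase_logs_to_frame(
    balanced: BalancedLevel, subject: str = "", procedure: str = "loudness_balance"
) -> pd.DataFrame:
    rows = []
    for i, log in enumerate(balanced.staircase_logs, start=1):
        for trial, (lvl, resp) in enumerate(zip(log.levels_visited, log.responses), start=1):
            rows.append(
                {
                    "subject": subject,
                    "procedure": procedure,
                    "staircase": i,
                    "trial": trial,
                    "level_uA": lvl,
                    "response": "comparison_louder" if resp else "reference_louder",
                }
            )
    return pd.DataFrame(rows)
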