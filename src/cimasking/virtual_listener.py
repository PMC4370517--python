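"""Parametric simulated bilateral cochlear-implant listener.

The generator reproduces the statistical structure the masking analysis
assumes, so the whole pipeline can be exercised and validated without human
subjects:

* per-place unmasked thresholds (baseline μA plus a low-order polynomial in
  electrode place) and a most-comfortable level (MCL) a fixed number of dB
  above threshold;
* masking-induced threshold elevation with a peaked place profile — a
  two-sided (split-sigma) Gaussian, additive in μA — whose width and gain
  differ between ipsilateral and contralateral maskers (contralateral
  typically sharper and weaker) and whose apical/basal sigmas may differ;
* an interaural place offset: the contralateral masking peak sits at the
  masker place plus ``interaural_offset`` electrodes, emulating imperfect
  alignment of the two arrays;
* psychometric response noise: detection probability is a logistic function
  of level in dB re threshold with lapse/guess rates, and loudness
  comparisons are logistic in the dB loudness difference. Infinite slopes
  give fully deterministic listeners for exact-trace tests.

Masker level scales the masking gain linearly between the masker-place
threshold (scale 0) and MCL (scale 1); the study condition presents maskers
at MCL, i.e. scale 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import masking_analysis
from .adaptive_procedures import (
    BekesyConfig,
    StaircaseConfig,
    run_bekesy_tracking,
    run_double_staircase_balance,
)
from .errors import DomainError
from .stimulus_space import (
    ElectrodeArray,
    PulseTrainSpec,
    amplitude_after_db_step,
    db_to_ua,
    resolve_place,
    ua_to_db,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EarParams",
    "MaskingParams",
    "ListenerParams",
    "ExperimentDesign",
    "unmasked_threshold",
    "mcl",
    "true_masked_threshold",
    "audibility_probability",
    "respond_audible",
    "compare_loudness",
    "audibility_oracle",
    "loudness_oracle",
    "generate_experiment_dataset",
    "default_cohort_params",
    "null_cohort_params",
    "default_design",
]

PROBE_DURATION_MS = 20.0
MASKER_DURATION_MS = 500.0


@dataclass(frozen=True)
class EarParams:
    """One ear: threshold/MCL profiles, psychometrics, loudness offset.

    ``threshold_poly`` holds polynomial coefficients (μA per (place-center)^k,
    k starting at 1) added to ``threshold_baseline_ua``; ``poly_center`` is
    the place at which the polynomial vanishes.
    """

    threshold_baseline_ua: float = 200.0
    threshold_poly: Tuple[float, ...] = ()
    poly_center: float = 8.5
    mcl_headroom_db: float = 10.0
    psychometric_slope: float = 8.0  # logistic slope per dB; inf = deterministic
    lapse_rate: float = 0.0
    guess_rate: float = 0.0
    loudness_offset_db: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_rate < 0.5 and 0.0 <= self.guess_rate < 0.5):
            raise DomainError("lapse_rate and guess_rate must lie in [0, 0.5)")
        if self.mcl_headroom_db <= 0:
            raise DomainError("mcl_headroom_db must be > 0 so MCL exceeds threshold")

    def threshold_ua(self, place: float) -> float:
        x = place - self.poly_center
        value = self.threshold_baseline_ua
        for k, coeff in enumerate(self.threshold_poly, start=1):
            value += coeff * x**k
        if value <= 0:
            raise DomainError(
                f"threshold profile non-positive ({value:.1f} μA) at place {place}"
            )
        return value


@dataclass(frozen=True)
class MaskingParams:
    """Two-sided Gaussian masking profile parameters (electrode units, μA)."""

    ipsi_gain_ua: float = 80.0
    ipsi_sigma_apical: float = 2.0
    ipsi_sigma_basal: float = 2.0
    contra_gain_ua: float = 48.0
    contra_sigma_apical: float = 1.0
    contra_sigma_basal: float = 1.0
    interaural_offset: float = 0.0

    def __post_init__(self) -> None:
        sigmas = (
            self.ipsi_sigma_apical,
            self.ipsi_sigma_basal,
            self.contra_sigma_apical,
            self.contra_sigma_basal,
        )
        if any(s <= 0 for s in sigmas):
            raise DomainError("all masking sigmas must be > 0")
        if self.ipsi_gain_ua < 0 or self.contra_gain_ua < 0:
            raise DomainError("masking gains must be >= 0")


@dataclass(frozen=True)
class ListenerParams:
    subject: str = "S01"
    left: EarParams = field(default_factory=EarParams)
    right: EarParams = field(default_factory=EarParams)
    masking: MaskingParams = field(default_factory=MaskingParams)
    choice_slope: float = 4.0  # loudness-comparison logistic slope per dB

    def ear(self, which: str) -> EarParams:
        if which == "left":
            return self.left
        if which == "right":
            return self.right
        raise DomainError(f"ear must be 'left' or 'right', got {which!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """Probe grid, masker placement, and procedure settings for one run."""

    probe_places: Tuple[float, ...] = tuple(np.round(np.arange(1.0, 13.01, 0.5), 4))
    masker_places: Tuple[Tuple[str, float], ...] = (("apical", 3.0), ("middle", 9.0))
    probe_ear: Literal["left", "right"] = "left"
    conditions: Tuple[str, ...] = ("unmasked", "contra_masked", "ipsi_masked")
    seed: int = 0
    peak_mode: Literal["absolute", "gaussian"] = "absolute"
    array: ElectrodeArray = field(default_factory=ElectrodeArray)
    bekesy_start_margin_db: float = 6.0
    max_level_ua: float = 4000.0

    def __post_init__(self) -> None:
        if len(self.probe_places) == 0:
            raise DomainError("probe_places must be non-empty")
        steps = np.diff(np.asarray(self.probe_places))
        if len(steps) and steps.min() < 0.1 - 1e-9:
            raise DomainError("probe grid step must be >= 0.1 electrodes")
        for name, place in self.masker_places:
            if not self.array.contains_place(place):
                raise DomainError(f"masker '{name}' place {place} outside array")

    @property
    def contra_ear(self) -> str:
        return "right" if self.probe_ear == "left" else "left"


def unmasked_threshold(params: ListenerParams, place: float, ear: str) -> float:
    return params.ear(ear).threshold_ua(place)


def mcl(params: ListenerParams, place: float, ear: str) -> float:
    e = params.ear(ear)
    return amplitude_after_db_step(e.threshold_ua(place), e.mcl_headroom_db)


def _masker_scale(params: ListenerParams, masker: PulseTrainSpec) -> float:
    """Linear gain scale of a masker between threshold (0) and MCL (1)."""
    e = params.ear(masker.ear)
    thr_db = ua_to_db(e.threshold_ua(masker.place.place))
    level_db = ua_to_db(masker.amplitude_ua)
    scale = (level_db - thr_db) / e.mcl_headroom_db
    if scale < 0.0:
        logger.warning(
            "masker at place %.2f (%s) below threshold; masking scale clamped to 0",
            masker.place.place,
            masker.ear,
        )
        return 0.0
    return min(scale, 1.0)


def true_masked_threshold(
    params: ListenerParams,
    probe_place: float,
    probe_ear: str,
    masker: Optional[PulseTrainSpec] = None,
) -> float:
    """Ground-truth detection threshold (μA) at a probe place.

    Without a masker this is the unmasked profile. With one, a split-sigma
    Gaussian elevation is added: the apical sigma applies to probe places
    apical of the masking peak, the basal sigma basal of it. The peak sits
    at the masker place (ipsilateral) or masker place + interaural offset
    (contralateral).
    """
    base = unmasked_threshold(params, probe_place, probe_ear)
    if masker is None:
        return base
    m = params.masking
    if masker.ear == probe_ear:
        gain, s_ap, s_ba = m.ipsi_gain_ua, m.ipsi_sigma_apical, m.ipsi_sigma_basal
        peak = masker.place.place
    else:
        gain, s_ap, s_ba = m.contra_gain_ua, m.contra_sigma_apical, m.contra_sigma_basal
        peak = masker.place.place + m.interaural_offset
    sigma = s_ap if probe_place < peak else s_ba
    profile = math.exp(-((probe_place - peak) ** 2) / (2.0 * sigma**2))
    return base + _masker_scale(params, masker) * gain * profile


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def audibility_probability(
    params: ListenerParams,
    level_ua: float,
    probe_place: float,
    probe_ear: str,
    masker: Optional[PulseTrainSpec] = None,
) -> float:
    """P(report audible) for a probe at ``level_ua``."""
    e = params.ear(probe_ear)
    thr_db = ua_to_db(true_masked_threshold(params, probe_place, probe_ear, masker))
    delta = ua_to_db(level_ua) - thr_db
    if math.isinf(e.psychometric_slope):
        core = 1.0 if delta >= 0 else 0.0
    else:
        core = _logistic(e.psychometric_slope * delta)
    return e.guess_rate + (1.0 - e.guess_rate - e.lapse_rate) * core


def respond_audible(
    params: ListenerParams,
    probe: PulseTrainSpec,
    masker: Optional[PulseTrainSpec],
    rng: np.random.Generator,
) -> bool:
    """One Bernoulli audibility report for a fully specified probe."""
    p = audibility_probability(params, probe.amplitude_ua, probe.place.place, probe.ear, masker)
    if p >= 1.0:
        return True
    if p <= 0.0:
        return False
    return bool(rng.random() < p)


def compare_loudness(
    params: ListenerParams,
    a: PulseTrainSpec,
    b: PulseTrainSpec,
    rng: np.random.Generator,
) -> str:
    """Which of two stimuli is louder: returns ``'a'`` or ``'b'``.

    Loudness is monotone in dB level plus the per-ear loudness offset. With
    an infinite choice slope the comparison is deterministic and an exact
    tie goes to ``b`` (the second, conventionally the reference).
    """
    loud_a = ua_to_db(a.amplitude_ua) + params.ear(a.ear).loudness_offset_db
    loud_b = ua_to_db(b.amplitude_ua) + params.ear(b.ear).loudness_offset_db
    delta = loud_a - loud_b
    if math.isinf(params.choice_slope):
        return "a" if delta > 0 else "b"
    return "a" if rng.random() < _logistic(params.choice_slope * delta) else "b"


def audibility_oracle(
    params: ListenerParams,
    probe_place: float,
    probe_ear: str,
    masker: Optional[PulseTrainSpec],
    rng: np.random.Generator,
) -> Callable[[float], bool]:
    """Fast level→audible closure for the tracking engine.

    The detection threshold is fixed by (params, place, masker), so it is
    precomputed once rather than per trial.
    """
    e = params.ear(probe_ear)
    thr_db = ua_to_db(true_masked_threshold(params, probe_place, probe_ear, masker))
    slope, guess, lapse = e.psychometric_slope, e.guess_rate, e.lapse_rate
    deterministic = math.isinf(slope) and guess == 0.0 and lapse == 0.0

    if deterministic:

        def audible(level_ua: float) -> bool:
            return ua_to_db(level_ua) >= thr_db

    else:

        def audible(level_ua: float) -> bool:
            delta = ua_to_db(level_ua) - thr_db
            if math.isinf(slope):
                core = 1.0 if delta >= 0 else 0.0
            else:
                core = _logistic(slope * delta)
            return rng.random() < guess + (1.0 - guess - lapse) * core

    return audible


def loudness_oracle(
    params: ListenerParams,
    reference: PulseTrainSpec,
    comparison_ear: str,
    rng: np.random.Generator,
) -> Callable[[float], bool]:
    """Level→(comparison louder?) closure for the balancing engine."""
    ref_loud = ua_to_db(reference.amplitude_ua) + params.ear(reference.ear).loudness_offset_db
    comp_offset = params.ear(comparison_ear).loudness_offset_db
    slope = params.choice_slope

    def comparison_louder(level_ua: float) -> bool:
        delta = ua_to_db(level_ua) + comp_offset - ref_loud
        if math.isinf(slope):
            return delta > 0  # exact tie goes to the reference
        return rng.random() < _logistic(slope * delta)

    return comparison_louder


def _masker_spec(place: float, ear: str, level_ua: float, array: ElectrodeArray) -> PulseTrainSpec:
    return PulseTrainSpec(
        duration_ms=MASKER_DURATION_MS,
        amplitude_ua=level_ua,
        place=resolve_place(place, array),
        ear=ear,
    )


def _measure_threshold(
    params: ListenerParams,
    place: float,
    ear: str,
    masker: Optional[PulseTrainSpec],
    start_level_ua: float,
    design: ExperimentDesign,
    rng: np.random.Generator,
) -> float:
    cfg = BekesyConfig(start_level_ua=start_level_ua, max_level_ua=design.max_level_ua)
    oracle = audibility_oracle(params, place, ear, masker, rng)
    return run_bekesy_tracking(oracle, cfg).threshold_ua


def generate_experiment_dataset(
    params_per_subject: Sequence[ListenerParams],
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Run the full measurement protocol on simulated listeners.

    Per subject: (1) unmasked thresholds at every probe place via Bekesy
    tracking; (2) contralateral masked thresholds with the masker at each
    design place at MCL; (3) the ipsilateral masker placed at the peak of
    the measured contralateral masking function and loudness-balanced to the
    contralateral masker with the double staircase; (4) ipsilateral masked
    thresholds. Returns the tidy threshold table; fully reproducible from
    (params, design, design.seed).
    """
    if len(params_per_subject) == 0:
        raise DomainError("need at least one subject")
    subject_streams = np.random.SeedSequence(design.seed).spawn(len(params_per_subject))
    rows: List[dict] = []

    for params, stream in zip(params_per_subject, subject_streams):
        rng = np.random.default_rng(stream)
        ear = design.probe_ear

        unmasked_est: Dict[float, float] = {}
        for place in design.probe_places:
            start = amplitude_after_db_step(
                unmasked_threshold(params, place, ear), -design.bekesy_start_margin_db
            )
            est = _measure_threshold(params, place, ear, None, start, design, rng)
            unmasked_est[place] = est
            rows.append(
                _row(params.subject, ear, "unmasked", "none", None, None, place, est)
            )

        for location, masker_place in design.masker_places:
            # Contralateral masker at MCL in the opposite ear.
            contra_level = mcl(params, masker_place, design.contra_ear)
            contra_masker = _masker_spec(
                masker_place, design.contra_ear, contra_level, design.array
            )
            contra_est: Dict[float, float] = {}
            for place in design.probe_places:
                start = amplitude_after_db_step(
                    unmasked_est[place], -design.bekesy_start_margin_db
                )
                est = _measure_threshold(params, place, ear, contra_masker, start, design, rng)
                contra_est[place] = est
                rows.append(
                    _row(
                        params.subject, ear, "contra_masked", location,
                        masker_place, contra_level, place, est,
                    )
                )

            # Ipsilateral masker at the peak of the contralateral function,
            # loudness-balanced against the contralateral masker.
            contra_shift = masking_analysis.ShiftFunction(
                subject=params.subject,
                masker_kind="contralateral",
                masker_location=location,
                probe_places=np.asarray(design.probe_places, dtype=float),
                shifts=np.asarray(
                    [contra_est[p] - unmasked_est[p] for p in design.probe_places]
                ),
            )
            ipsi_place = masking_analysis.locate_ipsi_masker(contra_shift, design.peak_mode)
            ipsi_place = float(np.clip(ipsi_place, 1.0, design.array.n_electrodes))

            predicted = mcl(params, ipsi_place, ear)
            balance_rng = np.random.default_rng(rng.integers(2**31))
            oracle = loudness_oracle(params, contra_masker, ear, balance_rng)
            balanced = run_double_staircase_balance(
                oracle,
                predicted,
                StaircaseConfig(max_level_ua=design.max_level_ua),
            )
            ipsi_masker = _masker_spec(ipsi_place, ear, balanced.level_ua, design.array)

            for place in design.probe_places:
                start = amplitude_after_db_step(
                    unmasked_est[place], -design.bekesy_start_margin_db
                )
                est = _measure_threshold(params, place, ear, ipsi_masker, start, design, rng)
                rows.append(
                    _row(
                        params.subject, ear, "ipsi_masked", location,
                        ipsi_place, balanced.level_ua, place, est,
                    )
                )

    return pd.DataFrame(rows)


def _row(subject, ear, condition, location, masker_place, masker_level, probe_place, threshold):
    return {
        "subject": subject,
        "ear": ear,
        "condition": condition,
        "masker_location": location,
        "masker_place": np.nan if masker_place is None else float(masker_place),
        "masker_level": np.nan if masker_level is None else float(masker_level),
        "probe_place": float(probe_place),
        "threshold": float(threshold),
    }


# ---------------------------------------------------------------------------
# Cohort builders
# ---------------------------------------------------------------------------

def default_cohort_params(
    n_subjects: int = 6,
    seed: int = 0,
    contra_sigma_ratio: float = 0.5,
    contra_gain_ratio: float = 0.6,
    stochastic: bool = True,
) -> List[ListenerParams]:
    """A cohort with sharper, weaker contralateral masking.

    Per-subject parameters are drawn around field-plausible centres:
    ipsilateral spread sigma ~2 electrodes with mild apical/basal asymmetry,
    peak masking gain 60–100 μA, baseline thresholds 150–250 μA with a
    gentle place slope, and an interaural place offset within ±1 electrode.
    The contralateral profile scales the ipsilateral sigma and gain by the
    given ratios.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        ipsi_sigma = rng.uniform(1.6, 2.4)
        asym = rng.uniform(0.85, 1.15)
        ipsi_gain = rng.uniform(60.0, 100.0)
        baseline = rng.uniform(150.0, 250.0)
        slope_ua = rng.uniform(-4.0, 4.0)  # μA per electrode
        offset = rng.uniform(-1.0, 1.0)
        psych_slope = math.inf if not stochastic else 8.0
        lapse = 0.0 if not stochastic else 0.02
        ear_kwargs = dict(
            threshold_baseline_ua=baseline,
            threshold_poly=(slope_ua,),
            psychometric_slope=psych_slope,
            lapse_rate=lapse,
        )
        cohort.append(
            ListenerParams(
                subject=f"S{i + 1:02d}",
                left=EarParams(**ear_kwargs),
                right=EarParams(**ear_kwargs, loudness_offset_db=rng.uniform(-1.0, 1.0)),
                masking=MaskingParams(
                    ipsi_gain_ua=ipsi_gain,
                    ipsi_sigma_apical=ipsi_sigma * asym,
                    ipsi_sigma_basal=ipsi_sigma / asym,
                    contra_gain_ua=contra_gain_ratio * ipsi_gain,
                    contra_sigma_apical=contra_sigma_ratio * ipsi_sigma * asym,
                    contra_sigma_basal=contra_sigma_ratio * ipsi_sigma / asym,
                    interaural_offset=offset,
                ),
                choice_slope=math.inf if not stochastic else 4.0,
            )
        )
    return cohort


def null_cohort_params(n_subjects: int = 6) -> List[ListenerParams]:
    """Symmetric-null cohort: identical ipsi/contra masking, deterministic.

    With equal gains and sigmas, zero interaural offset, flat profiles and
    infinite psychometric/choice slopes, the pipeline's contralateral and
    ipsilateral measurements coincide and both difference measures are 1.
    """
    ear = EarParams(psychometric_slope=math.inf)
    masking = MaskingParams(
        ipsi_gain_ua=80.0,
        ipsi_sigma_apical=2.0,
        ipsi_sigma_basal=2.0,
        contra_gain_ua=80.0,
        contra_sigma_apical=2.0,
        contra_sigma_basal=2.0,
        interaural_offset=0.0,
    )
    return [
        ListenerParams(
            subject=f"S{i + 1:02d}", left=ear, right=ear, masking=masking,
            choice_slope=math.inf,
        )
        for i in range(n_subjects)
    ]


def default_design(seed: int = 0, **overrides) -> ExperimentDesign:
    """The default two-masker (apical 3, middle 9) fine-grid design."""
    return ExperimentDesign(seed=seed, **overrides)
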