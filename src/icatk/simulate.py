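"""Synthetic cohorts and responses for end-to-end testing without clinical data.

The generator emulates the two validation cohorts (combined n = 230: 95
healthy, 80 MCI, 55 mild AD) at the level the analysis pipeline needs:

* **Demographics** per (cohort, diagnosis) group — age, education, sex, MoCA
  and ACE — drawn from truncated normals with the published group means/sds.
* **Responses** via a Rasch-style model with a guessing floor: a participant
  with latent ability ``a`` answers an item of difficulty ``d`` correctly with
  probability ``g + (1 - g) * logistic(a - d)``.  Reaction times of responded
  trials are lognormal around a per-participant location, shifted slightly by
  item difficulty (harder items are slower).  A small timeout rate produces
  no-response trials.
* **Calibration**: per-group ability and RT-location means are solved
  deterministically (Gauss–Hermite quadrature + Brent root finding) so that
  expected group accuracy matches the published accuracy-by-diagnosis values
  and expected group speed matches the value implied by the published group
  ICA-Index means.  The speed equation is inverted in closed form:
  ``RT = 1025 * (0.341 - ln(speed / 100))``.

A separate fixture reproduces the repeated-testing study layout: 12 healthy
participants x 78 sessions = 936 scored tests, with an optional per-session
ability drift (zero by default, the no-practice-effect null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .scoring import DEFAULT_SPEED_CONSTANTS, SpeedConstants
from .session import (
    CATEGORIES,
    MAIN_TRIALS_PER_CATEGORY,
    PRACTICE_BLOCK_SIZE,
    PRACTICE_PASS_THRESHOLD,
    PRACTICE_PER_CATEGORY,
    StimulusItem,
    TrialRecord,
    evaluate_practice_block,
)

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "ResponseModelParams",
    "PracticeStudySpec",
    "GroupCalibration",
    "DIAGNOSES",
    "ACCURACY_TARGETS_PCT",
    "default_cohort_spec",
    "default_params",
    "sample_item_bank",
    "sample_cohort",
    "simulate_session",
    "simulate_study",
    "simulate_practice_study",
    "calibrate_generator",
    "calibrate_group",
    "invert_speed",
    "StudyResult",
]

DIAGNOSES = ("healthy", "mci", "mild_ad")

#: Group mean accuracy targets (percent), averaged over the published
#: below-70 / 70-plus age bands for each diagnosis.
ACCURACY_TARGETS_PCT = {"healthy": 83.25, "mci": 76.7, "mild_ad": 65.2}

#: Between-participant spread of latent ability and log-RT location, per
#: diagnosis; chosen so simulated ICA-Index sds land near the published group
#: sds (~8 / ~11 / ~15).
ABILITY_SD = {"healthy": 0.6, "mci": 0.7, "mild_ad": 0.9}
RT_LOG_SD_BETWEEN = {"healthy": 0.15, "mci": 0.20, "mild_ad": 0.30}

_N_ITEMS = 2 * MAIN_TRIALS_PER_CATEGORY


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one (cohort, diagnosis) group."""

    n: int
    female_frac: float
    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    moca_mean: float
    moca_sd: float
    ace_mean: float
    ace_sd: float
    index_mean: float
    index_sd: float
    accuracy_target_pct: float
    ability_sd: float
    rt_log_sd: float
    age_min: float = 30.0
    age_max: float = 95.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        for name in ("age_sd", "education_sd", "moca_sd", "ace_sd", "index_sd", "ability_sd", "rt_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.female_frac <= 1:
            raise ValueError("female_frac must be in [0, 1]")
        if not 0 < self.accuracy_target_pct <= 100:
            raise ValueError("accuracy_target_pct must be in (0, 100]")

    @property
    def speed_target(self) -> float:
        """Group mean speed implied by the index and accuracy targets."""
        return self.index_mean / self.accuracy_target_pct * 100.0


@dataclass(frozen=True)
class CohortSpec:
    """Per-(cohort, diagnosis) generative parameters for a full study."""

    groups: Mapping[tuple[int, str], GroupSpec]

    def __post_init__(self) -> None:
        for (cohort, diag) in self.groups:
            if diag not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {diag!r}")
            if cohort not in (1, 2):
                raise ValueError(f"cohort must be 1 or 2, got {cohort}")

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.groups.values())


def _group(cohort: int, diag: str, n: int, female_pct: float, age: tuple, edu: tuple,
           moca: tuple, ace: tuple, index: tuple, age_bounds: tuple) -> GroupSpec:
    return GroupSpec(
        n=n,
        female_frac=female_pct / 100.0,
        age_mean=age[0], age_sd=age[1],
        education_mean=edu[0], education_sd=edu[1],
        moca_mean=moca[0], moca_sd=moca[1],
        ace_mean=ace[0], ace_sd=ace[1],
        index_mean=index[0], index_sd=index[1],
        accuracy_target_pct=ACCURACY_TARGETS_PCT[diag],
        ability_sd=ABILITY_SD[diag],
        rt_log_sd=RT_LOG_SD_BETWEEN[diag],
        age_min=age_bounds[0], age_max=age_bounds[1],
    )


def default_cohort_spec() -> CohortSpec:
    """Published demographics and score distributions of the two cohorts."""
    c1, c2 = (30.0, 95.0), (55.0, 90.0)  # recruitment age windows
    groups = {
        (1, "healthy"): _group(1, "healthy", 33, 57.6, (63.6, 6.7), (14.2, 4.7), (25.9, 3.0), (92.1, 6.7), (66.1, 7.7), c1),
        (1, "mci"):     _group(1, "mci",     27, 55.6, (66.0, 7.0), (14.2, 5.7), (23.7, 2.9), (87.3, 7.3), (57.8, 8.1), c1),
        (1, "mild_ad"): _group(1, "mild_ad", 13, 46.2, (69.8, 9.4), (11.2, 4.0), (16.6, 5.8), (68.5, 14.3), (41.6, 14.4), c1),
        (2, "healthy"): _group(2, "healthy", 62, 54.8, (68.5, 7.6), (14.3, 4.2), (28.3, 1.8), (95.7, 3.1), (63.7, 8.7), c2),
        (2, "mci"):     _group(2, "mci",     53, 43.4, (71.5, 7.9), (12.5, 2.7), (23.5, 2.9), (84.1, 6.9), (54.7, 11.9), c2),
        (2, "mild_ad"): _group(2, "mild_ad", 42, 50.0, (71.6, 7.4), (13.3, 3.2), (20.2, 3.0), (76.1, 8.1), (46.9, 15.5), c2),
    }
    return CohortSpec(groups=groups)


@dataclass(frozen=True)
class ResponseModelParams:
    """Parameters of the Rasch-style response model.

    ``guessing_floor`` is the lower asymptote of the correctness curve; it is
    set below the binary-forced-choice chance level of 0.5 so that severely
    impaired simulated participants can fail the above-chance practice gate.
    ``age_ability_corr`` is the (negative) within-group correlation between
    age and latent ability; the published data show it within healthy and MCI
    groups but not within mild AD.
    """

    difficulty_sd: float = 1.0
    guessing_floor: float = 0.35
    rt_log_sd: float = 0.25  # within-session trial-to-trial log-RT sd
    difficulty_rt_slope: float = 0.04  # log-RT shift per unit difficulty
    timeout_rate: float = 0.02
    age_ability_corr: Mapping[str, float] = field(
        default_factory=lambda: {"healthy": -0.4, "mci": -0.4, "mild_ad": 0.0}
    )
    cognition_loading: float = 0.6  # shared latent factor loading for MoCA/ACE
    #: loading of the RT location on the shared cognition factor.  Zero by
    #: default: a nonzero value couples speed to accuracy within groups, which
    #: raises the realized group ICA-Index mean above the product of the
    #: calibrated marginal speed/accuracy targets by the induced covariance.
    rt_cognition_loading: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.guessing_floor <= 0.5:
            raise ValueError("guessing_floor must be in [0, 0.5]")
        if not self.rt_log_sd > 0:
            raise ValueError("rt_log_sd must be positive")
        if not 0 <= self.timeout_rate < 1:
            raise ValueError("timeout_rate must be in [0, 1)")
        if self.difficulty_sd < 0:
            raise ValueError("difficulty_sd must be >= 0")


def default_params() -> ResponseModelParams:
    return ResponseModelParams()


@dataclass(frozen=True)
class PracticeStudySpec:
    """Layout of the repeated-testing (practice-effect) study fixture."""

    n_participants: int = 12
    n_sessions: int = 78
    age_min: float = 26.0
    age_max: float = 73.0
    age_mean: float = 48.2
    age_sd: float = 17.1
    session_effect_slope: float = 0.0  # ability units per additional session

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_sessions <= 0:
            raise ValueError("n_participants and n_sessions must be positive")


@dataclass(frozen=True)
class GroupCalibration:
    """Latent means for one group, solved from its accuracy/speed targets."""

    ability_mean: float
    rt_location_mean: float
    accuracy_target_pct: float
    speed_target: float


# ---------------------------------------------------------------------------
# item bank
# ---------------------------------------------------------------------------

def sample_item_bank(
    params: ResponseModelParams, rng_seed: int, n_items: int = _N_ITEMS
) -> list[StimulusItem]:
    """Draw a fixed bank of items of various difficulty, half per category.

    Difficulties are standardized to exactly zero mean and ``difficulty_sd``
    spread so the realized bank matches the scale the calibration assumes.
    """
    if n_items % 2:
        raise ValueError("n_items must be even (equal split per category)")
    rng = np.random.default_rng(rng_seed)
    d = rng.standard_normal(n_items)
    if params.difficulty_sd > 0 and n_items > 1:
        d = (d - d.mean()) / d.std()
        d = d * params.difficulty_sd
    else:
        d = np.zeros(n_items)
    half = n_items // 2
    items = [
        StimulusItem(item_id=f"animal_{k:03d}", category="animal", difficulty=float(d[k]))
        for k in range(half)
    ]
    items += [
        StimulusItem(item_id=f"nonanimal_{k:03d}", category="non_animal", difficulty=float(d[half + k]))
        for k in range(half)
    ]
    return items


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _norm_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights rescaled for a standard normal."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


def _p_correct(ability, difficulty, params: ResponseModelParams):
    g = params.guessing_floor
    return g + (1.0 - g) * expit(np.asarray(ability) - np.asarray(difficulty))


def invert_speed(
    speed: float, constants: SpeedConstants = DEFAULT_SPEED_CONSTANTS
) -> float:
    """Mean correct RT (ms) implied by a group speed target.

    Inverts ``speed = 100 * exp(-RT/scale + offset)``.  A target at the cap is
    non-unique (any RT at or below the cap boundary); the boundary is
    returned.  Targets above the cap or non-positive are infeasible.
    """
    if speed <= 0 or speed > constants.cap:
        raise ValueError(f"speed target must be in (0, {constants.cap}], got {speed}")
    if speed == constants.cap:
        return constants.cap_rt_ms
    return constants.rt_scale_ms * (constants.offset - math.log(speed / 100.0))


def _difficulty_nodes(
    params: ResponseModelParams, bank: list[StimulusItem] | None
) -> tuple[np.ndarray, np.ndarray]:
    if bank is not None:
        d = np.array([it.difficulty for it in bank])
        return d, np.full(d.size, 1.0 / d.size)
    if params.difficulty_sd == 0:
        return np.zeros(1), np.ones(1)
    d, wd = _norm_nodes(41)
    return d * params.difficulty_sd, wd


def calibrate_group(
    accuracy_target_pct: float,
    speed_target: float,
    ability_sd: float,
    rt_log_sd_between: float,
    params: ResponseModelParams,
    bank: list[StimulusItem] | None = None,
    constants: SpeedConstants = DEFAULT_SPEED_CONSTANTS,
) -> GroupCalibration:
    """Solve one group's latent means against its accuracy and speed targets.

    Expected accuracy and expected speed are computed by quadrature over the
    between-participant latent distributions (and the item difficulties), and
    the two location parameters are found with Brent's method.  Deterministic.
    """
    d, wd = _difficulty_nodes(params, bank)
    z, wz = _norm_nodes(21)

    g = params.guessing_floor
    resp = 1.0 - params.timeout_rate
    lo = 100.0 * resp * g
    if not lo < accuracy_target_pct < 100.0 * resp:
        raise ValueError(
            f"accuracy target {accuracy_target_pct} outside achievable range "
            f"({lo:.1f}, {100.0 * resp:.1f})"
        )

    def acc_gap(mu_a: float) -> float:
        a = mu_a + ability_sd * z
        p = _p_correct(a[:, None], d[None, :], params)
        return 100.0 * resp * float(wz @ (p @ wd)) - accuracy_target_pct

    mu_a = brentq(acc_gap, -12.0, 12.0, xtol=1e-10)

    # implied target RT (sanity check that the speed target is feasible)
    invert_speed(speed_target, constants)

    a = mu_a + ability_sd * z
    p = _p_correct(a[:, None], d[None, :], params)  # (z, d)
    w_rt = np.exp(params.difficulty_rt_slope * d)
    # expected correct-trial RT multiplier per ability node (ratio estimator)
    mult = (p * w_rt[None, :]) @ wd / (p @ wd)  # (z,)
    sigma2 = params.rt_log_sd**2 / 2.0
    w_nodes, ww = _norm_nodes(21)

    def speed_gap(mu_r: float) -> float:
        base = np.exp(mu_r + rt_log_sd_between * w_nodes + sigma2)  # (w,)
        rts = base[None, :] * mult[:, None]  # (z, w)
        spd = np.minimum(
            constants.cap, 100.0 * np.exp(-rts / constants.rt_scale_ms + constants.offset)
        )
        return float(wz @ spd @ ww) - speed_target

    mu_r = brentq(speed_gap, math.log(80.0), math.log(6000.0), xtol=1e-12)
    return GroupCalibration(
        ability_mean=float(mu_a),
        rt_location_mean=float(mu_r),
        accuracy_target_pct=accuracy_target_pct,
        speed_target=speed_target,
    )


def calibrate_generator(
    spec: CohortSpec,
    params: ResponseModelParams | None = None,
    bank: list[StimulusItem] | None = None,
) -> dict[tuple[int, str], GroupCalibration]:
    """Calibrate latent means for every group in a cohort spec."""
    params = params or default_params()
    out = {}
    for key, g in spec.groups.items():
        out[key] = calibrate_group(
            g.accuracy_target_pct, g.speed_target, g.ability_sd, g.rt_log_sd, params, bank
        )
    return out


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _truncated_normal(rng, n, mean, sd, lo, hi):
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_cohort(
    spec: CohortSpec,
    rng_seed: int,
    params: ResponseModelParams | None = None,
    bank: list[StimulusItem] | None = None,
) -> pd.DataFrame:
    """Draw participant profiles for every group in the spec.

    Latent ability and RT location are centred on the calibrated group means;
    a shared latent cognition factor couples ability, RT, MoCA and ACE so
    convergent-validity analyses see positive correlations, and age enters
    ability with the configured within-group correlation.
    """
    params = params or default_params()
    cal = calibrate_generator(spec, params, bank)
    rng = np.random.default_rng(rng_seed)
    frames = []
    for (cohort, diag), g in spec.groups.items():
        n = g.n
        if n == 0:
            continue
        c = cal[(cohort, diag)]
        age = _truncated_normal(rng, n, g.age_mean, g.age_sd, g.age_min, g.age_max)
        edu = _truncated_normal(rng, n, g.education_mean, g.education_sd, 0.0, 30.0)
        sex = np.where(rng.random(n) < g.female_frac, "female", "male")
        u = rng.standard_normal(n)  # shared latent cognition factor
        e_ab, e_rt, e_moca, e_ace = (rng.standard_normal(n) for _ in range(4))

        rho = abs(params.age_ability_corr.get(diag, 0.0))
        lu = params.cognition_loading
        resid = max(0.0, 1.0 - rho**2 - lu**2)
        z_age = (age - g.age_mean) / g.age_sd if g.age_sd > 0 else np.zeros(n)
        z_ability = -rho * z_age + lu * u + math.sqrt(resid) * e_ab
        ability = c.ability_mean + g.ability_sd * z_ability

        l_rt = params.rt_cognition_loading
        z_rt = l_rt * u + math.sqrt(max(0.0, 1.0 - l_rt**2)) * e_rt
        rt_location = c.rt_location_mean + g.rt_log_sd * z_rt

        moca = np.clip(np.round(g.moca_mean + g.moca_sd * (lu * u + math.sqrt(1 - lu**2) * e_moca)), 0, 30)
        ace = np.clip(np.round(g.ace_mean + g.ace_sd * (lu * u + math.sqrt(1 - lu**2) * e_ace)), 0, 100)

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": [f"c{cohort}-{diag}-{i:03d}" for i in range(n)],
                    "cohort": cohort,
                    "diagnosis": diag,
                    "age": age,
                    "education_years": edu,
                    "sex": sex,
                    "moca": moca.astype(int),
                    "ace": ace.astype(int),
                    "ability": ability,
                    "rt_location": rt_location,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "cohort", "diagnosis", "age", "education_years",
                     "sex", "moca", "ace", "ability", "rt_location"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# response simulation
# ---------------------------------------------------------------------------

def _simulate_trials(ability, rt_location, difficulties, params, rng):
    """Vectorized trial outcomes.  Returns (correct, responded, rt) arrays."""
    difficulties = np.asarray(difficulties, dtype=float)
    p = _p_correct(ability, difficulties, params)
    shape = np.broadcast_shapes(np.shape(p), difficulties.shape)
    responded = rng.random(shape) >= params.timeout_rate
    correct = (rng.random(shape) < p) & responded
    log_rt = rng.normal(
        np.broadcast_to(rt_location, shape) + params.difficulty_rt_slope * difficulties,
        params.rt_log_sd,
    )
    rt = np.where(responded, np.exp(log_rt), np.nan)
    return correct, responded, rt


def _records_from_arrays(items, correct, responded, rt, phase, start_index) -> list[TrialRecord]:
    other = {"animal": "non_animal", "non_animal": "animal"}
    records = []
    for k, item in enumerate(items):
        if not responded[k]:
            response, rt_k = "none", None
        elif correct[k]:
            response, rt_k = item.category, float(rt[k])
        else:
            response, rt_k = other[item.category], float(rt[k])
        records.append(
            TrialRecord(
                item_id=item.item_id,
                category=item.category,
                response=response,
                correct=bool(correct[k]),
                rt_ms=rt_k,
                phase=phase,
                trial_index=start_index + k,
            )
        )
    return records


def _practice_items(params, rng, attempt: int) -> list[StimulusItem]:
    d = rng.standard_normal(PRACTICE_BLOCK_SIZE) * params.difficulty_sd
    items = []
    for k in range(PRACTICE_BLOCK_SIZE):
        cat = CATEGORIES[0] if k < PRACTICE_PER_CATEGORY else CATEGORIES[1]
        items.append(
            StimulusItem(item_id=f"practice_a{attempt}_{k:02d}", category=cat, difficulty=float(d[k]))
        )
    return items


def simulate_session(
    profile,
    bank: list[StimulusItem],
    params: ResponseModelParams | None = None,
    rng_seed: int | np.random.Generator = 0,
    max_practice_attempts: int = 8,
) -> list[TrialRecord]:
    """Simulate one full session (gated practice, then 100 main trials).

    ``profile`` is any mapping with ``ability`` and ``rt_location``.  Practice
    blocks are drawn fresh per attempt and gated by the above-chance rule;
    after ``max_practice_attempts`` the participant proceeds regardless, so a
    session always produces a main block.
    """
    params = params or default_params()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ability = float(profile["ability"])
    rt_location = float(profile["rt_location"])

    records: list[TrialRecord] = []
    attempts = 0
    trial_index = 0
    while attempts < max_practice_attempts:
        items = _practice_items(params, rng, attempts + 1)
        d = [it.difficulty for it in items]
        correct, responded, rt = _simulate_trials(ability, rt_location, d, params, rng)
        block = _records_from_arrays(items, correct, responded, rt, "practice", trial_index)
        records.extend(block)
        trial_index += len(block)
        decision = evaluate_practice_block(block, attempts_so_far=attempts)
        attempts = decision.attempts_used
        if decision.outcome == "proceed":
            break

    order = rng.permutation(len(bank))
    items = [bank[i] for i in order]
    d = [it.difficulty for it in items]
    correct, responded, rt = _simulate_trials(ability, rt_location, d, params, rng)
    records.extend(_records_from_arrays(items, correct, responded, rt, "main", trial_index))
    return records


@dataclass
class StudyResult:
    """A simulated study: participants with session scores, plus the bank."""

    participants: pd.DataFrame
    bank: list[StimulusItem]
    logs: dict[str, list[TrialRecord]] | None = None


def _score_arrays(correct, rt, constants=DEFAULT_SPEED_CONSTANTS):
    """Accuracy / mean-correct-RT / speed / index from (n, items) outcome arrays."""
    n_items = correct.shape[-1]
    acc = 100.0 * correct.sum(axis=-1) / n_items
    rt_sum = np.where(correct, rt, 0.0).sum(axis=-1)
    n_corr = correct.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rt = np.where(n_corr > 0, rt_sum / np.maximum(n_corr, 1), np.nan)
        spd = np.minimum(
            constants.cap,
            100.0 * np.exp(-mean_rt / constants.rt_scale_ms + constants.offset),
        )
    idx = spd * acc / 100.0
    return acc, mean_rt, spd, idx


def simulate_study(
    spec: CohortSpec | None = None,
    params: ResponseModelParams | None = None,
    rng_seed: int = 0,
    return_logs: bool = False,
    max_practice_attempts: int = 8,
) -> StudyResult:
    """Simulate a full study: cohort, one scored session per participant.

    The returned participant table carries demographics, latent parameters,
    practice attempts used, and the session scores (accuracy, mean correct RT,
    speed, ICA Index).  With ``return_logs=True`` full per-trial records are
    kept for every participant.
    """
    spec = spec or default_cohort_spec()
    params = params or default_params()
    root = np.random.default_rng(rng_seed)
    bank_seed = int(root.integers(2**31))
    bank = sample_item_bank(params, bank_seed)
    cohort = sample_cohort(spec, int(root.integers(2**31)), params, bank)
    n = len(cohort)
    if n == 0:
        cohort = cohort.assign(
            practice_attempts=pd.Series(dtype=int),
            accuracy_pct=pd.Series(dtype=float),
            mean_correct_rt_ms=pd.Series(dtype=float),
            speed=pd.Series(dtype=float),
            ica_index=pd.Series(dtype=float),
        )
        return StudyResult(participants=cohort, bank=bank, logs={} if return_logs else None)

    rng = np.random.default_rng(int(root.integers(2**31)))
    ability = cohort["ability"].to_numpy()[:, None]
    rt_loc = cohort["rt_location"].to_numpy()[:, None]

    # practice gate: simulate the maximum number of blocks up front, then take
    # the first passing block (fresh items each attempt, as in the live test)
    prac_d = rng.standard_normal((n, max_practice_attempts, PRACTICE_BLOCK_SIZE)) * params.difficulty_sd
    p_prac = _p_correct(ability[:, :, None], prac_d, params)
    prac_resp = rng.random(p_prac.shape) >= params.timeout_rate
    prac_correct = (rng.random(p_prac.shape) < p_prac) & prac_resp
    n_correct = prac_correct.sum(axis=-1)  # (n, attempts)
    passed = n_correct >= PRACTICE_PASS_THRESHOLD
    first_pass = np.argmax(passed, axis=1)
    attempts_used = np.where(passed.any(axis=1), first_pass + 1, max_practice_attempts)

    diffs = np.array([it.difficulty for it in bank])
    correct, responded, rt = _simulate_trials(ability, rt_loc, diffs[None, :], params, rng)
    acc, mean_rt, spd, idx = _score_arrays(correct, rt)

    participants = cohort.assign(
        practice_attempts=attempts_used,
        accuracy_pct=acc,
        mean_correct_rt_ms=mean_rt,
        speed=spd,
        ica_index=idx,
    )

    logs = None
    if return_logs:
        logs = {}
        other = {"animal": "non_animal", "non_animal": "animal"}
        for i, pid in enumerate(participants["participant_id"]):
            recs: list[TrialRecord] = []
            t = 0
            for a in range(attempts_used[i]):
                items = [
                    StimulusItem(
                        item_id=f"practice_a{a + 1}_{k:02d}",
                        category=CATEGORIES[0] if k < PRACTICE_PER_CATEGORY else CATEGORIES[1],
                        difficulty=float(prac_d[i, a, k]),
                    )
                    for k in range(PRACTICE_BLOCK_SIZE)
                ]
                rt_a = np.where(prac_resp[i, a], 600.0, np.nan)  # placeholder latency for practice
                recs.extend(
                    _records_from_arrays(items, prac_correct[i, a], prac_resp[i, a], rt_a, "practice", t)
                )
                t += PRACTICE_BLOCK_SIZE
            order = rng.permutation(len(bank))
            items = [bank[j] for j in order]
            recs.extend(
                _records_from_arrays(
                    items, correct[i, order], responded[i, order], rt[i, order], "main", t
                )
            )
            logs[pid] = recs
    return StudyResult(participants=participants, bank=bank, logs=logs)


def simulate_practice_study(
    spec: PracticeStudySpec | None = None,
    rng_seed: int = 0,
    params: ResponseModelParams | None = None,
) -> pd.DataFrame:
    """Simulate the repeated-testing fixture: healthy participants x sessions.

    Every session is a full 100-trial main block scored with the standard
    transforms.  Latent parameters are calibrated to the combined-healthy
    group targets; ``session_effect_slope`` (ability units per session) is
    zero by default, so the expected ICA Index is constant across sessions —
    the null hypothesis a practice-effect ANOVA should fail to reject.
    """
    spec = spec or PracticeStudySpec()
    params = params or default_params()
    root = np.random.default_rng(rng_seed)
    bank = sample_item_bank(params, int(root.integers(2**31)))
    diffs = np.array([it.difficulty for it in bank])

    healthy = default_cohort_spec().groups[(2, "healthy")]
    combined_index_mean = 64.5  # combined healthy group target
    acc_target = ACCURACY_TARGETS_PCT["healthy"]
    cal = calibrate_group(
        acc_target, combined_index_mean / acc_target * 100.0,
        healthy.ability_sd, healthy.rt_log_sd, params, bank,
    )

    rng = np.random.default_rng(int(root.integers(2**31)))
    n, s = spec.n_participants, spec.n_sessions
    age = _truncated_normal(rng, n, spec.age_mean, spec.age_sd, spec.age_min, spec.age_max)
    ability = cal.ability_mean + healthy.ability_sd * rng.standard_normal(n)
    rt_loc = cal.rt_location_mean + healthy.rt_log_sd * rng.standard_normal(n)

    session_idx = np.arange(s)
    ab = ability[:, None, None] + spec.session_effect_slope * session_idx[None, :, None]
    correct, responded, rt = _simulate_trials(
        ab, rt_loc[:, None, None], diffs[None, None, :], params, rng
    )
    acc, mean_rt, spd, idx = _score_arrays(correct, rt)

    return pd.DataFrame(
        {
            "participant_id": np.repeat([f"p{i:02d}" for i in range(n)], s),
            "session_index": np.tile(session_idx + 1, n),
            "age": np.repeat(age, s),
            "accuracy_pct": acc.ravel(),
            "mean_correct_rt_ms": mean_rt.ravel(),
            "speed": spd.ravel(),
            "ica_index": idx.ravel(),
        }
    )
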