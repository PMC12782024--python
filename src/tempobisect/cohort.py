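"""Synthetic responder cohort from a scalar-timing internal-clock model.

Each simulated participant carries an internal clock in the
pacemaker–accumulator tradition: a stimulus of objective duration ``t``
produces a subjective duration

    tau ~ Normal(gain_c * t, (weber_coef_c * gain_c * t)^2)

where ``gain_c`` is a per-condition multiplier on subjective time (arousal
opens the pacemaker gate -> gain > 1 -> durations feel longer; attentional
capture closes it -> gain < 1), and the standard deviation grows
proportionally with the mean — the scalar property of interval timing.
The response is "long" iff tau exceeds a memory-derived criterion, except
on lapse trials (probability ``lapse``), where the response is uniform
over the two alternatives.

The analytic response curve of this model is

    P(long | t) = lapse/2 + (1 - lapse) * Phi((g t - c) / (w g t))

which crosses 0.5 at t = c / g (the model's bisection point) and has
Weber's ratio 2 x / (1 - x^2) with x = w * z_{0.75}; both are inverted in
closed form by :func:`params_from_targets`, so cohorts can be configured
directly in terms of the target bisection point and Weber's ratio of each
group x condition cell.

The default cohort specification encodes the published group x condition
pattern: six groups (healthy controls, typical Alzheimer's disease and the
behavioural, semantic, nonfluent and logopenic frontotemporal-spectrum
syndromes) with their reported mean bisection points and Weber's ratios,
group sizes, valence-rating means and covariate (age, TIV, MMSE)
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import substream
from .design import (
    ALL_CONDITIONS,
    Condition,
    Schedule,
    TrialSpec,
    build_experiment_schedule,
    condition_from_key,
)

Z75 = float(norm.ppf(0.75))  # 0.6744897501960817


class TargetError(ValueError):
    """Raised when (BP*, WR*) targets fall outside the admissible region."""


@dataclass(frozen=True)
class ResponseRecord:
    trial: TrialSpec
    response: str  # "short" | "long"


@dataclass
class ClockParams:
    """Internal-clock parameters of one synthetic responder.

    ``gain`` and ``weber_coef`` are per-condition mappings (condition
    effects enter through the pacemaker/attention gain; the scalar noise
    coefficient sets discrimination sensitivity); ``criterion`` is the
    fixed memory-derived decision boundary in seconds and ``lapse`` the
    probability of a stimulus-independent random response.
    """

    criterion: float
    lapse: float
    gain: dict[Condition, float]
    weber_coef: dict[Condition, float]
    noise_law: str = "normal"  # or "lognormal"

    def __post_init__(self) -> None:
        if not 2.0 < self.criterion < 5.0:
            raise TargetError(f"criterion {self.criterion} outside (2, 5) s")
        if not 0.0 <= self.lapse < 0.5:
            raise TargetError(f"lapse {self.lapse} outside [0, 0.5)")
        for c, g in self.gain.items():
            if g <= 0:
                raise TargetError(f"gain for {c.key} must be positive")
        for c, w in self.weber_coef.items():
            if w <= 0:
                raise TargetError(f"weber_coef for {c.key} must be positive")

    def p_long(self, condition: Condition, t: np.ndarray | float):
        """Analytic P(long | t) of the clock model (lapses included)."""
        g = self.gain[condition]
        w = self.weber_coef[condition]
        t = np.asarray(t, dtype=float)
        if self.noise_law == "normal":
            core = norm.sf(self.criterion, loc=g * t, scale=w * g * t)
        else:  # lognormal: tau = g t exp(sigma Z - sigma^2/2), sigma ~= w
            core = norm.sf(np.log(self.criterion / (g * t)) / w + self.w_half(w))
        return self.lapse / 2.0 + (1.0 - self.lapse) * core

    @staticmethod
    def w_half(w: float) -> float:
        return w / 2.0


def params_from_targets(
    bp_target: float, wr_target: float, lapse: float = 0.0, criterion: float = 3.5
) -> tuple[float, float]:
    """Invert the clock model: (gain, weber_coef) hitting (BP*, WR*) exactly.

    With lapse = 0 the analytic curve crosses 0.5 at c/g, so
    gain = criterion / BP*.  The 25%/75% quantiles satisfy
    t_q = BP* / (1 -+ w z_{0.75}), giving WR = 2x / (1 - x^2) with
    x = w z_{0.75}; solving the quadratic yields
    x = (sqrt(1 + WR*^2) - 1) / WR*.
    """
    if not 2.0 < bp_target < 5.0:
        raise TargetError(f"target bisection point {bp_target} outside (2, 5) s")
    if wr_target <= 0:
        raise TargetError(f"target Weber's ratio {wr_target} must be positive")
    if not 0.0 <= lapse < 0.5:
        raise TargetError(f"lapse {lapse} outside [0, 0.5)")
    gain = criterion / bp_target
    # x = (sqrt(1 + WR^2) - 1) / WR, written stably for small WR
    x = wr_target / (1.0 + np.sqrt(1.0 + wr_target**2))
    if not 0 < x < 1:
        raise TargetError(f"Weber's ratio {wr_target} not reachable (x={x})")
    weber_coef = x / Z75
    return float(gain), float(weber_coef)


def clock_from_targets(
    bp: dict[Condition, float],
    wr: dict[Condition, float],
    lapse: float = 0.0,
    criterion: float = 3.5,
    noise_law: str = "normal",
) -> ClockParams:
    """Build per-condition clock parameters from target (BP, WR) maps."""
    gain, weber = {}, {}
    for cond in bp:
        gain[cond], weber[cond] = params_from_targets(
            bp[cond], wr[cond], lapse, criterion
        )
    return ClockParams(criterion, lapse, gain, weber, noise_law)


def simulate_response(
    params: ClockParams, trial: TrialSpec, rng: np.random.Generator
) -> str:
    """One short/long decision of the clock model on one trial."""
    if params.lapse > 0 and rng.random() < params.lapse:
        return "long" if rng.random() < 0.5 else "short"
    g = params.gain[trial.condition]
    w = params.weber_coef[trial.condition]
    mean = g * trial.duration
    if params.noise_law == "normal":
        tau = rng.normal(mean, w * mean)
    else:
        tau = mean * np.exp(rng.normal(-(w**2) / 2.0, w))
    return "long" if tau > params.criterion else "short"


@dataclass
class ParticipantRecord:
    participant_id: str
    group: str
    age: float
    tiv: float
    mmse: float
    clock: ClockParams
    responses: list[ResponseRecord] = field(default_factory=list)


def simulate_participant(
    participant_id: str,
    group: str,
    clock: ClockParams,
    schedule: Schedule,
    rng: np.random.Generator,
    age: float = np.nan,
    tiv: float = np.nan,
    mmse: float = np.nan,
) -> ParticipantRecord:
    """Run one responder through a schedule; one response per trial."""
    rec = ParticipantRecord(participant_id, group, age, tiv, mmse, clock)
    rec.responses = [
        ResponseRecord(t, simulate_response(clock, t, rng)) for t in schedule.trials
    ]
    return rec


# --- cohort specification -------------------------------------------------

_EU, _EP = "environmental-unpleasant", "environmental-pleasant"
_HU, _HP = "human-unpleasant", "human-pleasant"

#: Reported mean bisection points (s) per group x condition.
GROUP_BP: dict[str, dict[str, float]] = {
    "controls": {_EU: 3.3, _EP: 3.6, _HU: 4.3, _HP: 4.1},
    "AD":       {_EU: 3.1, _EP: 3.3, _HU: 4.5, _HP: 4.4},
    "lvPPA":    {_EU: 3.3, _EP: 3.3, _HU: 4.7, _HP: 4.4},
    "nfvPPA":   {_EU: 2.9, _EP: 3.3, _HU: 4.7, _HP: 4.3},
    "svPPA":    {_EU: 3.4, _EP: 3.3, _HU: 4.3, _HP: 3.9},
    "bvFTD":    {_EU: 3.4, _EP: 3.6, _HU: 4.5, _HP: 4.5},
}

#: Reported mean Weber's ratios per group x condition.
GROUP_WR: dict[str, dict[str, float]] = {
    "controls": {_EU: 0.20, _EP: 0.23, _HU: 0.18, _HP: 0.22},
    "AD":       {_EU: 0.27, _EP: 0.28, _HU: 0.20, _HP: 0.27},
    "lvPPA":    {_EU: 0.25, _EP: 0.25, _HU: 0.24, _HP: 0.24},
    "nfvPPA":   {_EU: 0.22, _EP: 0.28, _HU: 0.21, _HP: 0.27},
    "svPPA":    {_EU: 0.17, _EP: 0.19, _HU: 0.19, _HP: 0.24},
    "bvFTD":    {_EU: 0.29, _EP: 0.31, _HU: 0.21, _HP: 0.26},
}

#: Final analysis-cohort sizes (participants who passed training).
GROUP_N: dict[str, int] = {
    "controls": 24, "AD": 11, "lvPPA": 8, "nfvPPA": 8, "svPPA": 11, "bvFTD": 8,
}

#: Age mean (SD) in years per group.
GROUP_AGE: dict[str, tuple[float, float]] = {
    "controls": (69.4, 6.5), "AD": (71.3, 5.4), "lvPPA": (70.4, 5.4),
    "nfvPPA": (69.4, 5.7), "svPPA": (66.0, 9.3), "bvFTD": (67.9, 7.2),
}

#: MMSE mean (SD) per group (telephone-MMSE scale).
GROUP_MMSE: dict[str, tuple[float, float]] = {
    "controls": (26.0, 1.3), "AD": (18.7, 3.8), "lvPPA": (17.5, 6.2),
    "nfvPPA": (23.4, 2.9), "svPPA": (21.8, 3.9), "bvFTD": (20.9, 5.4),
}

#: Total intracranial volume mean (SD), mL — conventional adult values.
TIV_DIST: tuple[float, float] = (1400.0, 130.0)

#: Reported mean (SD) pleasantness ratings per condition, 0–100 scale.
VALENCE_MEANS: dict[str, float] = {_EU: 26.0, _EP: 74.0, _HU: 25.0, _HP: 68.0}
VALENCE_SDS: dict[str, float] = {_EU: 20.0, _EP: 16.0, _HU: 18.0, _HP: 18.0}


@dataclass
class GroupSpec:
    n: int
    bp: dict[str, float]  # condition key -> target bisection point (s)
    wr: dict[str, float]  # condition key -> target Weber's ratio

    def __post_init__(self) -> None:
        if self.n < 1:
            raise TargetError("group size must be >= 1")
        for v in self.bp.values():
            if not 2.0 < v < 5.0:
                raise TargetError(f"target bisection point {v} outside (2, 5)")
        for v in self.wr.values():
            if v <= 0:
                raise TargetError(f"target Weber's ratio {v} must be positive")


@dataclass
class CohortSpec:
    """Cohort-level generative configuration.

    ``bp_sd`` / ``wr_rel_sd`` set the between-participant spread of
    individual targets around the group means (Normal for BP, multiplicative
    log-normal for WR); ``lapse`` is shared.  All randomness derives from
    ``seed`` via named substreams.
    """

    groups: dict[str, GroupSpec]
    valence_means: dict[str, float] = field(default_factory=lambda: dict(VALENCE_MEANS))
    valence_sds: dict[str, float] = field(default_factory=lambda: dict(VALENCE_SDS))
    seed: int = 0
    bp_sd: float = 0.5
    wr_rel_sd: float = 0.25
    lapse: float = 0.05
    criterion: float = 3.5
    noise_law: str = "normal"
    n_blocks: int = 8


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The published group x condition pattern as a generative cohort."""
    groups = {
        g: GroupSpec(GROUP_N[g], dict(GROUP_BP[g]), dict(GROUP_WR[g]))
        for g in GROUP_BP
    }
    return CohortSpec(groups=groups, seed=seed)


def _draw_targets(
    spec: CohortSpec, group: GroupSpec, rng: np.random.Generator
) -> tuple[dict[Condition, float], dict[Condition, float]]:
    """Individual (BP, WR) targets around the group means.

    The between-participant spread splits evenly into a participant-level
    offset shared across conditions (the source of the random-intercept
    variance the group model estimates) and condition-specific variation;
    WR varies multiplicatively the same way.
    """
    bp_offset = rng.normal(0.0, spec.bp_sd / np.sqrt(2.0))
    wr_offset = rng.normal(0.0, spec.wr_rel_sd / np.sqrt(2.0))
    bp, wr = {}, {}
    for cond in ALL_CONDITIONS:
        mu = group.bp[cond.key]
        # keep individual targets inside the admissible (2, 5) range
        b = float(np.clip(
            mu + bp_offset + rng.normal(0.0, spec.bp_sd / np.sqrt(2.0)), 2.05, 4.95
        ))
        w = float(group.wr[cond.key] * np.exp(
            wr_offset + rng.normal(0.0, spec.wr_rel_sd / np.sqrt(2.0))
        ))
        bp[cond], wr[cond] = b, w
    return bp, wr


def _cognitive_scores(
    bp: dict[Condition, float], wr: dict[Condition, float], rng: np.random.Generator
) -> dict[str, float]:
    """Cognitive scores coupled to the participant's timing parameters.

    Auditory working-memory span is inversely coupled to the mean bisection
    point (duration underestimation goes with lower span) and nonverbal
    executive score inversely to the mean Weber's ratio — the directions the
    behavioural correlation stage is meant to recover.  Noise levels leave
    the couplings moderate (|rho| in the 0.3–0.45 range at cohort size).
    """
    mean_bp = float(np.mean(list(bp.values())))
    mean_wr = float(np.mean(list(wr.values())))
    return {
        "digit_span_forward": float(
            np.clip(5.5 - 1.8 * (mean_bp - 3.9) + rng.normal(0, 1.6), 2, 9)
        ),
        "digit_span_reverse": float(
            np.clip(4.5 - 1.3 * (mean_bp - 3.9) + rng.normal(0, 1.7), 1, 8)
        ),
        "matrices": float(
            np.clip(20.0 - 50.0 * (mean_wr - 0.24) + rng.normal(0, 6.0), 0, 32)
        ),
    }


def _control_task_scores(rng: np.random.Generator) -> dict[str, float]:
    """Questionnaire and control-task scores with no group differences
    (the confound screen should not flag them)."""
    return {
        "mood": float(np.clip(rng.normal(7.0, 2.5), 0, 20)),
        "hearing": float(np.clip(rng.normal(30.0, 10.0), 0, 80)),
        "musical_background": float(np.clip(rng.normal(1.5, 1.3), 0, 4)),
        "training_score": float(np.clip(rng.normal(92.0, 6.5), 0, 100)),
        "tone_duration_score": float(np.clip(rng.normal(96.0, 6.0), 0, 100)),
        "sound_recognition_score": float(np.clip(rng.normal(98.0, 4.0), 0, 100)),
    }


def simulate_cohort(
    spec: CohortSpec | None = None,
    exemplars=None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ParticipantRecord]]:
    """Simulate the full cohort: trial log, covariate table, records.

    Every participant gets their own constrained schedule (block order
    randomized per participant) and responds to all
    ``28 * n_blocks`` experimental trials via their clock parameters.
    Returns ``(trial_log, covariates, records)`` where ``trial_log`` has one
    row per participant x trial and ``covariates`` one row per participant.
    """
    spec = default_cohort_spec() if spec is None else spec
    log_rows, cov_rows, records = [], [], []
    for group_name in spec.groups:
        gspec = spec.groups[group_name]
        for i in range(gspec.n):
            pid = f"{group_name}-{i:02d}"
            prng = substream(spec.seed, f"participant/{pid}")
            bp, wr = _draw_targets(spec, gspec, prng)
            clock = clock_from_targets(
                bp, wr, spec.lapse, spec.criterion, spec.noise_law
            )
            sched = build_experiment_schedule(
                exemplars,
                n_blocks=spec.n_blocks,
                seed=int(prng.integers(2**31 - 1)),
            )
            age = float(prng.normal(*GROUP_AGE.get(group_name, (69.0, 7.0))))
            mmse_mu, mmse_sd = GROUP_MMSE.get(group_name, (24.0, 4.0))
            mmse = float(np.clip(prng.normal(mmse_mu, mmse_sd), 0, 30))
            tiv = float(prng.normal(*TIV_DIST))
            rec = simulate_participant(
                pid, group_name, clock, sched, prng, age=age, tiv=tiv, mmse=mmse
            )
            records.append(rec)
            cov_rows.append(
                {"participant_id": pid, "group": group_name,
                 "age": age, "tiv": tiv, "mmse": mmse,
                 **_cognitive_scores(bp, wr, prng),
                 **_control_task_scores(prng)}
            )
            for j, rr in enumerate(rec.responses):
                log_rows.append(
                    {
                        "participant_id": pid,
                        "group": group_name,
                        "block": rr.trial.block_index,
                        "trial": j,
                        "semantic_category": rr.trial.condition.semantic_category,
                        "valence": rr.trial.condition.valence,
                        "exemplar": rr.trial.exemplar_id,
                        "duration_s": rr.trial.duration,
                        "response": rr.response,
                    }
                )
    return pd.DataFrame(log_rows), pd.DataFrame(cov_rows), records


def simulate_valence_ratings(
    spec: CohortSpec, n_items: int = 36, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-participant pleasantness ratings of ``n_items`` sounds (0–100).

    Items are spread evenly over the four conditions (36 items -> 9 per
    condition, mirroring the rating block of the task); each rating is
    Normal(condition mean, condition SD) truncated to [0, 100].
    """
    if rng is None:
        rng = substream(spec.seed, "ratings")
    per_cond = n_items // len(ALL_CONDITIONS)
    rows = []
    for group_name, gspec in spec.groups.items():
        for i in range(gspec.n):
            pid = f"{group_name}-{i:02d}"
            for cond in ALL_CONDITIONS:
                mu = spec.valence_means[cond.key]
                sd = spec.valence_sds[cond.key]
                vals = np.clip(rng.normal(mu, sd, size=per_cond), 0.0, 100.0)
                for k, v in enumerate(vals):
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group_name,
                            "item": f"{cond.key}-{k:02d}",
                            "semantic_category": cond.semantic_category,
                            "valence": cond.valence,
                            "rating": float(v),
                        }
                    )
    return pd.DataFrame(rows)


#: Right-hemisphere region-of-interest family used in the association stage.
DEFAULT_ROI_FAMILY: tuple[str, ...] = (
    "right_dlpfc",
    "right_insula",
    "right_inferior_parietal",
    "right_sma",
    "right_precuneus",
)

#: Planted region <- condition effects mirroring the reported associations
#: (precuneus <- environmental pleasant, insula <- human unpleasant,
#: inferior parietal / supramarginal <- human pleasant).  Slope signs follow
#: the atrophy convention: the overall signed difference is positive for
#: environmental conditions (negative correlation = atrophy) and negative
#: for human conditions (positive correlation = atrophy).
DEFAULT_ROI_EFFECTS: dict[tuple[str, str], float] = {
    ("right_precuneus", _EP): -0.8,
    ("right_insula", _HU): +0.8,
    ("right_inferior_parietal", _HP): +0.8,
}

ROI_BASELINE = 10.0
ROI_COVARIATE_COEFS = {"age": -0.02, "tiv": 0.003, "mmse": 0.02}


def simulate_roi_volumes(
    covariates: pd.DataFrame,
    deltas: pd.DataFrame,
    effects: dict[tuple[str, str], float] | None = None,
    noise_sd: float = 0.4,
    regions: tuple[str, ...] = DEFAULT_ROI_FAMILY,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Regional grey-matter volumes with planted signed-difference effects.

    ``volume(region, i) = baseline + slope * delta(i, condition) +
    covariate terms + Normal(0, noise_sd)``.  Regions absent from
    ``effects`` are pure null regions.  ``deltas`` is the signed-difference
    table (patients only; columns ``participant_id, condition, delta``) and
    ``covariates`` carries age/tiv/mmse per participant.
    """
    effects = DEFAULT_ROI_EFFECTS if effects is None else effects
    if rng is None:
        rng = substream(seed, "roi-volumes")
    patients = covariates[covariates["group"] != "controls"].copy()
    wide = deltas.pivot(index="participant_id", columns="condition", values="delta")
    rows = []
    for _, p in patients.iterrows():
        pid = p["participant_id"]
        base = {
            "participant_id": pid,
            "group": p["group"],
            "age": p["age"],
            "tiv": p["tiv"],
            "mmse": p["mmse"],
        }
        cov_term = sum(
            coef * p[name] for name, coef in ROI_COVARIATE_COEFS.items()
        )
        for region in regions:
            vol = ROI_BASELINE + cov_term + rng.normal(0.0, noise_sd)
            for (r, cond_key), slope in effects.items():
                if r == region and pid in wide.index and cond_key in wide.columns:
                    vol += slope * wide.loc[pid, cond_key]
            base[region] = vol
        rows.append(dict(base))
    return pd.DataFrame(rows)
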