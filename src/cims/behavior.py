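"""Synthetic behavioral data for McGurk psychophysics designs.

Generates trial tables with the statistical structure that binomial
mixed-model analyses of McGurk prevalence assume: per-participant and
per-stimulus random intercepts on the logit scale, fixed condition and
counterbalancing-group effects, and binomial response counts. Four
canonical experiment designs are provided:

1. Repetition with co-articulation (76 participants, 2 counterbalancing
   groups, 1-rep vs 6-rep McGurk stimuli plus a reference stimulus).
2. Repetition without co-articulation (40 participants, 2 talkers x
   repetition levels {1, 2, 3, 6}).
3. Talker familiarity (60 participants, familiar vs unfamiliar talker,
   counterbalanced).
4. Testing mechanism (160 online vs 60 in-person participants).

Every participant sees each assigned McGurk stimulus 10 times (by
default), interleaved with congruent control syllables presented 3 or 4
times each (randomly determined). Tables can be generated either from a
logit-scale generative model (:func:`simulate_trials`) or directly from
the causal-inference perception model (:func:`simulate_from_cims`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model import CIMSParams, ModalityNoise, StimulusSpec, _simulate_category_counts

__all__ = [
    "TRIAL_COLUMNS",
    "StimulusEntry",
    "ExperimentDesign",
    "GeneratorParams",
    "CIMSHeterogeneity",
    "build_design",
    "default_generator_params",
    "simulate_trials",
    "simulate_from_cims",
    "validate_trial_table",
    "read_trial_table",
    "write_trial_table",
]

#: Fixed CSV schema for trial tables.
TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "stimulus_id",
    "talker_id",
    "condition",
    "n_trials",
    "n_da_tha",
    "n_ba",
    "n_ga",
]


@dataclass(frozen=True)
class StimulusEntry:
    """One stimulus in a design: identity, talker, condition, structure."""

    stimulus_id: str
    talker_id: str
    condition: str
    kind: str = "mcgurk"  # "mcgurk" | "congruent"
    n_repetitions: int = 1
    coarticulated: bool = False
    congruent_token: str | None = None


@dataclass
class ExperimentDesign:
    """Blueprint for one experiment's trial structure.

    ``group_assignments`` maps counterbalancing group -> list of
    (stimulus_id, condition) pairs for the McGurk stimuli that group sees;
    a condition of ``None`` falls back to the stimulus entry's own
    condition (or, for experiment 4, the participant's cohort).
    """

    experiment_id: int
    n_participants: int
    counterbalancing_groups: int
    stimuli: list[StimulusEntry]
    group_assignments: dict[int, list[tuple[str, str | None]]]
    trials_per_mcgurk_stimulus: int = 10
    trials_per_congruent_stimulus: tuple[int, int] = (3, 4)
    cohort_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_mcgurk_stimulus < 1:
            raise ValueError("trials_per_mcgurk_stimulus must be >= 1")
        if any(t < 1 for t in self.trials_per_congruent_stimulus):
            raise ValueError("trials_per_congruent_stimulus must be >= 1")
        if self.cohort_sizes is not None and sum(self.cohort_sizes.values()) != self.n_participants:
            raise ValueError("cohort sizes must sum to n_participants")

    def _entry(self, stimulus_id: str) -> StimulusEntry:
        for e in self.stimuli:
            if e.stimulus_id == stimulus_id:
                return e
        raise KeyError(stimulus_id)

    def participant_group(self, i: int) -> int:
        return i % self.counterbalancing_groups

    def participant_cohort(self, i: int) -> str | None:
        if self.cohort_sizes is None:
            return None
        cum = 0
        for name, size in self.cohort_sizes.items():
            cum += size
            if i < cum:
                return name
        raise IndexError(f"participant index {i} out of range")

    def mcgurk_stimuli_for(self, i: int) -> list[tuple[StimulusEntry, str]]:
        """(entry, resolved condition) pairs for participant ``i``."""
        group = self.participant_group(i)
        cohort = self.participant_cohort(i)
        out = []
        for sid, cond in self.group_assignments[group]:
            entry = self._entry(sid)
            resolved = cond if cond is not None else (cohort or entry.condition)
            out.append((entry, resolved))
        return out

    def congruent_stimuli(self) -> list[StimulusEntry]:
        return [e for e in self.stimuli if e.kind == "congruent"]


def _congruent_entries(talker: str) -> list[StimulusEntry]:
    return [
        StimulusEntry(f"cong_{tok}", talker, "congruent", "congruent", 1, False, tok)
        for tok in ("ba", "da", "ga")
    ]


def build_design(experiment_id: int, overrides: Mapping | None = None) -> ExperimentDesign:
    """Canonical design for one of the four experiments.

    ``overrides`` may adjust ``n_participants``,
    ``trials_per_mcgurk_stimulus``, ``trials_per_congruent_stimulus`` or
    (experiment 4) ``cohort_sizes`` for scaled-down runs; all other
    structure is preserved. An overridden experiment-4 participant count
    without explicit cohort sizes is split in the canonical 160:60 ratio.
    """
    if experiment_id == 1:
        stimuli = [
            StimulusEntry("mcgurk_t1_r1", "t1", "one_rep", "mcgurk", 1, False),
            StimulusEntry("mcgurk_t1_r6", "t1", "six_rep", "mcgurk", 6, True),
            StimulusEntry("mcgurk_t2_r1", "t2", "one_rep", "mcgurk", 1, False),
            StimulusEntry("mcgurk_t2_r6", "t2", "six_rep", "mcgurk", 6, True),
            StimulusEntry("mcgurk_ref", "t3", "control", "mcgurk", 1, False),
        ] + _congruent_entries("t0")
        design = ExperimentDesign(
            experiment_id=1,
            n_participants=76,
            counterbalancing_groups=2,
            stimuli=stimuli,
            group_assignments={
                0: [("mcgurk_t1_r1", None), ("mcgurk_t2_r6", None), ("mcgurk_ref", None)],
                1: [("mcgurk_t2_r1", None), ("mcgurk_t1_r6", None), ("mcgurk_ref", None)],
            },
        )
    elif experiment_id == 2:
        reps_by_talker = {"t1": 1, "t2": 1, "t3": 2, "t4": 2, "t5": 3, "t6": 3, "t7": 6, "t8": 6}
        stimuli = [
            StimulusEntry(f"mcgurk_{t}_r{r}", t, str(r), "mcgurk", r, False)
            for t, r in reps_by_talker.items()
        ] + _congruent_entries("t0")
        design = ExperimentDesign(
            experiment_id=2,
            n_participants=40,
            counterbalancing_groups=1,
            stimuli=stimuli,
            group_assignments={
                0: [(e.stimulus_id, None) for e in stimuli if e.kind == "mcgurk"]
            },
        )
    elif experiment_id == 3:
        stimuli = [
            StimulusEntry("mcgurk_t1", "t1", "familiar", "mcgurk", 1, False),
            StimulusEntry("mcgurk_t2", "t2", "unfamiliar", "mcgurk", 1, False),
        ] + _congruent_entries("t0")
        design = ExperimentDesign(
            experiment_id=3,
            n_participants=60,
            counterbalancing_groups=2,
            stimuli=stimuli,
            group_assignments={
                0: [("mcgurk_t1", "familiar"), ("mcgurk_t2", "unfamiliar")],
                1: [("mcgurk_t1", "unfamiliar"), ("mcgurk_t2", "familiar")],
            },
        )
    elif experiment_id == 4:
        stimuli = [
            StimulusEntry(f"mcgurk_t{k}", f"t{k}", "mcgurk", "mcgurk", 1, False)
            for k in range(1, 9)
        ] + _congruent_entries("t9")
        design = ExperimentDesign(
            experiment_id=4,
            n_participants=220,
            counterbalancing_groups=1,
            stimuli=stimuli,
            group_assignments={
                0: [(e.stimulus_id, None) for e in stimuli if e.kind == "mcgurk"]
            },
            cohort_sizes={"online": 160, "in_person": 60},
        )
    else:
        raise ValueError(f"unknown experiment_id {experiment_id!r}; expected 1-4")

    if overrides:
        allowed = {
            "n_participants",
            "trials_per_mcgurk_stimulus",
            "trials_per_congruent_stimulus",
            "cohort_sizes",
        }
        unknown = set(overrides) - allowed
        if unknown:
            raise ValueError(f"unknown design overrides: {sorted(unknown)}")
        for key, value in overrides.items():
            setattr(design, key, value)
        if design.experiment_id == 4 and "n_participants" in overrides and "cohort_sizes" not in overrides:
            n_online = int(round(design.n_participants * 160 / 220))
            design.cohort_sizes = {
                "online": n_online,
                "in_person": design.n_participants - n_online,
            }
        design.__post_init__()
    return design


# ---------------------------------------------------------------------------
# logit-scale generative model
# ---------------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """Logit-scale generator for binomial McGurk responses.

    The "da/tha" probability for participant i viewing stimulus j is
    expit(intercept + condition effect + repetition_slope * n_reps
    + group_effect * [group 1] + b_i + s_j) with participant intercepts
    b_i ~ N(0, tau_participant^2) and stimulus intercepts
    s_j ~ N(0, tau_stimulus^2). Non-"da/tha" trials are split between
    "ba" and "ga" with a fixed small "ga" share, since visual-only
    responses to McGurk stimuli are rare. Congruent controls are answered
    correctly with fixed high accuracy.
    """

    intercept: float = 0.0
    condition_effects: dict[str, float] = field(default_factory=dict)
    repetition_slope: float = 0.0
    group_effect: float = 0.0
    tau_participant: float = 2.0
    tau_stimulus: float = 0.3
    ga_share: float = 0.05
    congruent_accuracy: float = 0.97
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tau_participant < 0 or self.tau_stimulus < 0:
            raise ValueError("random-intercept standard deviations must be nonnegative")
        if not (0.0 <= self.ga_share <= 1.0):
            raise ValueError("ga_share must lie in [0, 1]")
        if not (0.0 <= self.congruent_accuracy <= 1.0):
            raise ValueError("congruent_accuracy must lie in [0, 1]")


def default_generator_params(experiment_id: int, seed: int | None = None) -> GeneratorParams:
    """Generator calibrated to each experiment's published group means.

    Experiment 1 encodes a repetition-with-co-articulation odds ratio of
    3.1 on a 48% baseline (reference stimulus near 73%); experiments 2-4
    encode null manipulations at their observed overall prevalences.
    """
    if experiment_id == 1:
        return GeneratorParams(
            intercept=float(logit(0.48)),
            condition_effects={"six_rep": float(np.log(3.1)), "control": float(logit(0.73) - logit(0.48))},
            seed=seed,
        )
    if experiment_id == 2:
        return GeneratorParams(intercept=float(logit(0.62)), seed=seed)
    if experiment_id == 3:
        return GeneratorParams(intercept=float(logit(0.69)), seed=seed)
    if experiment_id == 4:
        return GeneratorParams(intercept=float(logit(0.70)), seed=seed)
    raise ValueError(f"unknown experiment_id {experiment_id!r}; expected 1-4")


def _congruent_counts(token: str, n_trials: int, accuracy: float, rng: np.random.Generator) -> dict[str, int]:
    n_correct = int(rng.binomial(n_trials, accuracy))
    n_err = n_trials - n_correct
    others = [c for c in ("ba", "da", "ga") if c != token]
    e0 = int(rng.binomial(n_err, 0.5))
    counts = {c: 0 for c in ("ba", "da", "ga")}
    counts[token] = n_correct
    counts[others[0]] = e0
    counts[others[1]] = n_err - e0
    return counts


def _append_row(rows, pid, group, entry, condition, n_trials, counts):
    rows.append(
        {
            "participant_id": pid,
            "group": group,
            "stimulus_id": entry.stimulus_id,
            "talker_id": entry.talker_id,
            "condition": condition,
            "n_trials": n_trials,
            "n_da_tha": counts["da"],
            "n_ba": counts["ba"],
            "n_ga": counts["ga"],
        }
    )


def simulate_trials(
    design: ExperimentDesign,
    gen: GeneratorParams,
    rng: np.random.Generator | None = None,
    include_congruent: bool = True,
) -> pd.DataFrame:
    """Simulate a trial table from the logit-scale generative model.

    Deterministic given (design, gen, seed): the same seed yields a
    bit-identical table.
    """
    if rng is None:
        rng = np.random.default_rng(gen.seed)
    b = rng.normal(0.0, gen.tau_participant, design.n_participants)
    mcgurk_ids = [e.stimulus_id for e in design.stimuli if e.kind == "mcgurk"]
    s = dict(zip(mcgurk_ids, rng.normal(0.0, gen.tau_stimulus, len(mcgurk_ids))))

    rows: list[dict] = []
    for i in range(design.n_participants):
        pid = f"p{i:03d}"
        group = design.participant_group(i)
        for entry, condition in design.mcgurk_stimuli_for(i):
            eta = (
                gen.intercept
                + gen.condition_effects.get(condition, 0.0)
                + gen.repetition_slope * entry.n_repetitions
                + (gen.group_effect if group == 1 else 0.0)
                + b[i]
                + s[entry.stimulus_id]
            )
            p = float(expit(eta))
            n = design.trials_per_mcgurk_stimulus
            n_da = int(rng.binomial(n, p))
            n_ga = int(rng.binomial(n - n_da, gen.ga_share))
            counts = {"da": n_da, "ga": n_ga, "ba": n - n_da - n_ga}
            _append_row(rows, pid, group, entry, condition, n, counts)
        if include_congruent:
            for entry in design.congruent_stimuli():
                n = int(rng.choice(design.trials_per_congruent_stimulus))
                counts = _congruent_counts(entry.congruent_token, n, gen.congruent_accuracy, rng)
                _append_row(rows, pid, group, entry, "congruent", n, counts)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# generation directly from the causal-inference model
# ---------------------------------------------------------------------------

@dataclass
class CIMSHeterogeneity:
    """Per-participant parameter jitter for model-based data generation.

    ``prior_logit_sd`` jitters the common-cause prior on the logit scale;
    ``noise_scale_sd`` multiplies both encoding covariances by a
    log-normal factor exp(N(0, noise_scale_sd^2)).
    """

    prior_logit_sd: float = 0.0
    noise_scale_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.prior_logit_sd < 0 or self.noise_scale_sd < 0:
            raise ValueError("heterogeneity scales must be nonnegative")


def simulate_from_cims(
    design: ExperimentDesign,
    cims_params: CIMSParams,
    heterogeneity: CIMSHeterogeneity | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a trial table by running the perception model per trial.

    Every trial (McGurk and congruent alike) is one draw from the full
    encode -> integrate -> causal inference -> classify pipeline, with each
    participant's prior and noise jittered according to ``heterogeneity``.
    All McGurk stimuli are auditory "ba" dubbed over visual "ga".
    """
    het = heterogeneity or CIMSHeterogeneity()
    if rng is None:
        rng = np.random.default_rng(seed)

    rows: list[dict] = []
    for i in range(design.n_participants):
        pid = f"p{i:03d}"
        group = design.participant_group(i)
        prior = cims_params.prior_common
        if het.prior_logit_sd > 0 and 0.0 < prior < 1.0:
            prior = float(expit(logit(prior) + rng.normal(0.0, het.prior_logit_sd)))
        scale = 1.0
        if het.noise_scale_sd > 0:
            scale = float(np.exp(rng.normal(0.0, het.noise_scale_sd)))
        params_i = replace(
            cims_params,
            prior_common=prior,
            noise=ModalityNoise(
                cims_params.noise.sigma_A * scale, cims_params.noise.sigma_V * scale
            ),
        )
        for entry, condition in design.mcgurk_stimuli_for(i):
            stim = StimulusSpec("ba", "ga", entry.n_repetitions, entry.coarticulated)
            n = design.trials_per_mcgurk_stimulus
            n_ba, n_da, n_ga = (int(c) for c in _simulate_category_counts(params_i, stim, n, rng))
            _append_row(rows, pid, group, entry, condition, n, {"ba": n_ba, "da": n_da, "ga": n_ga})
        for entry in design.congruent_stimuli():
            stim = StimulusSpec(entry.congruent_token, entry.congruent_token, 1, False)
            n = int(rng.choice(design.trials_per_congruent_stimulus))
            n_ba, n_da, n_ga = (int(c) for c in _simulate_category_counts(params_i, stim, n, rng))
            _append_row(rows, pid, group, entry, "congruent", n, {"ba": n_ba, "da": n_da, "ga": n_ga})
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# trial-table schema and CSV I/O
# ---------------------------------------------------------------------------

def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the fixed trial-table schema; returns a column-ordered copy.

    Checks column presence, nonnegative integer counts, the per-record
    identity n_ba + n_da_tha + n_ga = n_trials, and non-empty condition
    labels.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    out = df[TRIAL_COLUMNS].copy()
    for col in ("n_trials", "n_da_tha", "n_ba", "n_ga"):
        vals = out[col]
        if vals.isna().any():
            raise ValueError(f"column {col!r} contains missing values")
        arr = np.asarray(vals, dtype=float)
        if not np.all(arr == np.round(arr)) or np.any(arr < 0):
            raise ValueError(f"column {col!r} must contain nonnegative integers")
        out[col] = arr.astype(int)
    total = out["n_ba"] + out["n_da_tha"] + out["n_ga"]
    if not (total == out["n_trials"]).all():
        raise ValueError("response counts must sum to n_trials in every record")
    cond = out["condition"].astype(str)
    if cond.isna().any() or (cond.str.strip() == "").any() or (cond == "nan").any():
        raise ValueError("condition labels must be non-empty")
    return out


def write_trial_table(df: pd.DataFrame, path) -> None:
    validate_trial_table(df).to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    return validate_trial_table(pd.read_csv(path))
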