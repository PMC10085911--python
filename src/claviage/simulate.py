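"""Synthetic cohort generator with the statistical structure the analysis assumes.

Emulates a clavicle-staging study without its raw data: ages uniform over
13.0-25.0 years; per subject one latent developmental value
``beta * t(age) + eps`` with standard-normal eps, cut into the six analysis
groups by the true cutpoints; per side an independently jittered copy (a
small probability of crossing into an adjacent group, reproducing the ~80%
left-right stage concordance seen in bilateral staging); within-group
substages drawn with frequencies mirroring the observed mix (substage 2c
absent by default, stage 5 rare); three raters whose recorded stages are the
truth, an adjacent 9-level rank (confusion), or "not evaluable".

Not-evaluable outcomes have two sources: a clavicle-level image artefact
(motion or anatomical shape variant, seen identically by every rater — the
dominant mechanism, ~11% of clavicles split 3% motion / 8% shape) and a
small per-rater idiosyncratic rate.  The generator emits the same subject
and rating tables the staging module reads, so it is a drop-in data source
for the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .staging import GROUPS, NOT_EVALUABLE, STAGES, stage_rank
from .transition import FrozenTransitionModel

#: Default median transition ages (years) between consecutive stage groups
#: 1 -> 2 -> 3a -> 3b -> 3c -> 4/5, chosen to mirror the age structure of
#: published clavicle-staging descriptives (within-stage SD ~1.3-1.5 y).
DEFAULT_TRANSITION_AGES: tuple[float, ...] = (16.0, 17.4, 19.3, 20.9, 22.2)

#: Default slope on the log-age scale; with unit latent SD this puts the
#: within-stage age spread at roughly 1.3-1.5 y around age 19.
DEFAULT_SLOPE: float = 14.0

_SUBSTAGE_CHOICES: dict[int, tuple[tuple[str, ...], tuple[float, ...]]] = {
    1: (("2a", "2b", "2c"), (0.6, 0.4, 0.0)),  # 2c essentially unobserved
    5: (("4", "5"), (0.85, 0.15)),
}


@dataclass
class SimulationParams:
    """Study-condition parameters of the synthetic cohort."""

    n_subjects: int = 338
    age_min: float = 13.0
    age_max: float = 25.0
    true_slope: float = DEFAULT_SLOPE
    transition_ages: tuple[float, ...] = DEFAULT_TRANSITION_AGES
    transform: str = "log"
    #: probability a side's group independently shifts to an adjacent group;
    #: 0.105 gives ~80% identical left-right stages
    side_jitter: float = 0.105
    #: probability a rater records an adjacent 9-level rank instead of truth;
    #: with strictly adjacent-rank errors, 0.40 reproduces the ~13% rate of
    #: clavicles on which all three raters disagree
    rater_confusion: float = 0.40
    #: clavicle-level probability the image is not evaluable (all raters)
    p_not_evaluable: float = 0.11
    #: motion share of not-evaluable outcomes (rest: shape variants)
    motion_share: float = 3.0 / 11.0
    #: per-rater idiosyncratic not-evaluable probability
    rater_ne: float = 0.03
    uniform_ages: bool = True
    seed: int = 20221219

    def __post_init__(self) -> None:
        for p in (self.side_jitter, self.rater_confusion, self.p_not_evaluable,
                  self.motion_share, self.rater_ne):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.true_slope <= 0:
            raise ValueError("true_slope must be positive")
        if np.any(np.diff(self.transition_ages) <= 0):
            raise ValueError("transition ages must be strictly increasing")

    @property
    def true_cutpoints(self) -> np.ndarray:
        t = np.log(self.transition_ages) if self.transform == "log" else np.asarray(
            self.transition_ages, float)
        return self.true_slope * t

    def true_model(self) -> FrozenTransitionModel:
        """The generating model as a prediction-capable frozen model."""
        return FrozenTransitionModel(
            self.true_cutpoints, self.true_slope, transform=self.transform,
            labels=list(GROUPS),
        )


def _t(params: SimulationParams, age: np.ndarray) -> np.ndarray:
    return np.log(age) if params.transform == "log" else age


def _jitter_groups(groups: np.ndarray, p: float, rng: np.random.Generator,
                   n_groups: int) -> np.ndarray:
    """Shift each group +-1 with probability p; reflect inward at the ends."""
    out = groups.copy()
    hit = rng.random(len(groups)) < p
    step = np.where(rng.random(len(groups)) < 0.5, -1, 1)
    shifted = out + step
    shifted = np.where(shifted < 0, 1, shifted)
    shifted = np.where(shifted > n_groups - 1, n_groups - 2, shifted)
    out[hit] = shifted[hit]
    return out


def _group_to_stage(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pick a 9-level stage code for each collapsed group."""
    stages = np.empty(len(groups), dtype=object)
    for g in np.unique(groups):
        sel = groups == g
        if g in _SUBSTAGE_CHOICES:
            codes, probs = _SUBSTAGE_CHOICES[g]
            stages[sel] = rng.choice(codes, size=sel.sum(), p=probs)
        else:
            stages[sel] = {0: "1", 2: "3a", 3: "3b", 4: "3c"}[int(g)]
    return stages


def simulate_cohort(params: SimulationParams | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate subjects with age, adult flag and true left/right stages.

    Returns one row per subject: ``subject_id``, ``age``, ``adult``, and per
    side the collapsed group rank (``group_L``/``group_R``) plus a
    representative 9-level stage code (``stage_L``/``stage_R``).
    Bit-identical under identical seeds.
    """
    params = params or SimulationParams()
    rng = rng or np.random.default_rng(params.seed)
    n = params.n_subjects
    if params.uniform_ages:
        age = rng.uniform(params.age_min, params.age_max, size=n)
    else:  # mildly bell-shaped alternative for age-structure robustness checks
        age = np.clip(
            rng.normal((params.age_min + params.age_max) / 2, 3.3, size=n),
            params.age_min, params.age_max - 1e-9,
        )
    latent = params.true_slope * _t(params, age) + rng.standard_normal(n)
    group = np.searchsorted(params.true_cutpoints, latent)
    n_groups = len(params.true_cutpoints) + 1
    group_l = _jitter_groups(group, params.side_jitter, rng, n_groups)
    group_r = _jitter_groups(group, params.side_jitter, rng, n_groups)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "adult": age >= 18.0,
            "group_L": group_l,
            "group_R": group_r,
            "stage_L": _group_to_stage(group_l, rng),
            "stage_R": _group_to_stage(group_r, rng),
        }
    )


def _noisy_read(stage: str, confusion: float, rng: np.random.Generator) -> str:
    r = stage_rank(stage)
    if rng.random() < confusion:
        step = -1 if rng.random() < 0.5 else 1
        r = r + step
        if r < 0:
            r = 1
        elif r > len(STAGES) - 1:
            r = len(STAGES) - 2
    return STAGES[r]


def simulate_raters(cohort: pd.DataFrame, params: SimulationParams | None = None,
                    rng: np.random.Generator | None = None,
                    raters: tuple[str, ...] = ("R1", "R2", "R3")) -> pd.DataFrame:
    """Emit the three-rater rating table for a simulated cohort.

    Each rater records the clavicle's true 9-level stage, an adjacent rank
    with probability ``rater_confusion``, or ``NE``.  Clavicle-level
    artefacts (probability ``p_not_evaluable``, motion/shape split) make all
    raters record ``NE``; per-rater idiosyncratic ``NE`` adds on top.  The
    last rater is the adjudicator: its ``adjudicated_stage`` column carries
    an independent re-read, consulted only on three-way splits.
    """
    params = params or SimulationParams()
    rng = rng or np.random.default_rng(params.seed + 1)
    rows = []
    for _, sub in cohort.iterrows():
        for side in ("L", "R"):
            true_stage = sub[f"stage_{side}"]
            clavicle_ne = rng.random() < params.p_not_evaluable
            reason = "motion" if rng.random() < params.motion_share else "shape_variant"
            for rater in raters:
                if clavicle_ne or rng.random() < params.rater_ne:
                    stage, excl = NOT_EVALUABLE, reason
                else:
                    stage, excl = _noisy_read(true_stage, params.rater_confusion, rng), ""
                adjudicated = ""
                if rater == raters[-1]:
                    adjudicated = (
                        NOT_EVALUABLE if clavicle_ne
                        else _noisy_read(true_stage, params.rater_confusion, rng)
                    )
                rows.append(
                    {
                        "subject_id": sub["subject_id"],
                        "side": side,
                        "rater_id": rater,
                        "stage": stage,
                        "exclusion_reason": excl,
                        "adjudicated_stage": adjudicated,
                    }
                )
    return pd.DataFrame(rows)


def simulate_study(params: SimulationParams | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: (subjects, ratings, truth) tables.

    ``subjects`` and ``ratings`` have exactly the columns the staging
    module's readers expect; ``truth`` is the cohort table with the true
    stages for calibration checks.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    cohort = simulate_cohort(params, rng)
    ratings = simulate_raters(cohort, params, rng)
    subjects = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"],
            "age_years": cohort["age"],
            "adult": cohort["adult"].astype(int),
        }
    )
    return subjects, ratings, cohort
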