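"""Consensus staging, exclusions, stage collapsing and descriptive statistics.

The medial clavicular epiphysis is staged on the 9-level ordinal scale of
Schmeling (main stages 1-5) refined by Kellinghaus (substages 2a-2c, 3a-3c):

    1 < 2a < 2b < 2c < 3a < 3b < 3c < 4 < 5

Stage 1 is an unossified centre; 2a-2c grade the ossifying epiphysis by its
length relative to the metaphyseal width; 3a-3c grade partial
epiphyseal-metaphyseal fusion; stage 4 is complete fusion with a visible
epiphyseal scar, stage 5 complete fusion without one.  A clavicle whose image
cannot be staged (motion artefact, anatomical shape variant) carries the
distinguished ``NE`` marker with an exclusion reason.

Three blinded raters stage each clavicle; the final stage per side is a
majority vote, with three-way splits resolved by a designated adjudicating
rater's re-evaluated stage.  For modelling, substages are collapsed into six
analysis groups 1, 2, 3a, 3b, 3c, 4/5.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Ordinal stage codes in developmental order; rank = index.
STAGES: tuple[str, ...] = ("1", "2a", "2b", "2c", "3a", "3b", "3c", "4", "5")

#: Marker for a clavicle that could not be staged.
NOT_EVALUABLE: str = "NE"

EXCLUSION_REASONS: tuple[str, ...] = ("motion", "shape_variant")

_RANK: dict[str, int] = {code: i for i, code in enumerate(STAGES)}

#: Collapsed analysis groups in developmental order; rank = index.
GROUPS: tuple[str, ...] = ("1", "2", "3a", "3b", "3c", "4/5")

_GROUP_OF_STAGE: dict[str, str] = {
    "1": "1",
    "2a": "2",
    "2b": "2",
    "2c": "2",
    "3a": "3a",
    "3b": "3b",
    "3c": "3c",
    "4": "4/5",
    "5": "4/5",
}


@dataclass(frozen=True)
class StageGroup:
    """A collapsed analysis group with its ordinal rank (0-5)."""

    label: str
    rank: int

    def __post_init__(self) -> None:
        if self.label not in GROUPS or GROUPS[self.rank] != self.label:
            raise ValueError(f"inconsistent stage group {self.label!r}/{self.rank}")


class StageError(ValueError):
    """An unparseable or out-of-scale stage code."""


def stage_rank(code: str) -> int:
    """Rank (0-8) of a stage code on the 9-level scale."""
    try:
        return _RANK[code]
    except KeyError:
        raise StageError(f"unknown stage code {code!r}; expected one of {STAGES}")


def rank_stage(rank: int) -> str:
    """Stage code for a rank; inverse of :func:`stage_rank`."""
    if not 0 <= rank < len(STAGES):
        raise StageError(f"stage rank {rank} outside 0..{len(STAGES) - 1}")
    return STAGES[rank]


def collapse_stage(stage: str) -> StageGroup:
    """Collapse a 9-level stage into its analysis group.

    Substages 2a/2b/2c merge into group 2 and the terminal stages 4 and 5
    into group 4/5; the map is total and order-preserving.  ``NE`` is not a
    stage and is rejected.
    """
    if stage == NOT_EVALUABLE:
        raise StageError("cannot collapse a not-evaluable clavicle")
    label = _GROUP_OF_STAGE[STAGES[stage_rank(stage)]]
    return StageGroup(label, GROUPS.index(label))


def group_rank(label: str) -> int:
    """Rank (0-5) of a collapsed group label."""
    try:
        return GROUPS.index(label)
    except ValueError:
        raise StageError(f"unknown stage group {label!r}; expected one of {GROUPS}")


# ---------------------------------------------------------------------------
# rating-table ingestion


RATING_COLUMNS = ("subject_id", "side", "rater_id", "stage")


def read_ratings(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a multi-rater rating table.

    One row per (subject, side, rater) with columns ``subject_id``, ``side``
    (L/R), ``rater_id``, ``stage`` (a 9-level code or ``NE``), optional
    ``exclusion_reason`` (required iff stage is ``NE``) and optional
    ``adjudicated_stage`` (consulted only on three-way splits).

    Raises
    ------
    KeyError
        if a required column is missing (configuration error).
    StageError
        naming the offending value and row on an unknown stage code.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"ratings file missing required column(s) {missing}")
    valid = set(STAGES) | {NOT_EVALUABLE}
    for row, value in df["stage"].items():
        if value not in valid:
            raise StageError(f"row {row + 2}: unknown stage code {value!r}")
    if "exclusion_reason" not in df.columns:
        df["exclusion_reason"] = ""
    if "adjudicated_stage" not in df.columns:
        df["adjudicated_stage"] = ""
    bad = df[(df["stage"] == NOT_EVALUABLE) & (~df["exclusion_reason"].isin(EXCLUSION_REASONS))]
    if len(bad):
        raise StageError(
            f"row {bad.index[0] + 2}: not-evaluable rating requires an exclusion "
            f"reason in {EXCLUSION_REASONS}"
        )
    df["side"] = df["side"].str.upper().str[0]
    if not df["side"].isin(["L", "R"]).all():
        raise StageError("side must be L or R")
    return df


def read_subjects(path, delimiter: str = ",") -> pd.DataFrame:
    """Read the subject table: ``subject_id``, ``age_years``, optional ``adult``.

    When ``adult`` is absent it is derived as ``age_years >= 18``.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"subject_id": str})
    missing = [c for c in ("subject_id", "age_years") if c not in df.columns]
    if missing:
        raise KeyError(f"subjects file missing required column(s) {missing}")
    if (df["age_years"] <= 0).any():
        raise ValueError("age_years must be strictly positive")
    if "adult" in df.columns:
        df["adult"] = df["adult"].astype(int).astype(bool)
    else:
        df["adult"] = df["age_years"] >= 18.0
    return df


# ---------------------------------------------------------------------------
# consensus


def consensus_stage(
    ratings: dict[str, str],
    adjudicator: str,
    adjudicated_stage: str | None = None,
) -> str:
    """Resolve one clavicle's consensus stage from its per-rater stages.

    ``ratings`` maps rater_id -> stage code (or ``NE``).  A stage attaining at
    least two of the three votes wins; ``NE`` counts as an ordinary vote
    category, so two not-evaluable votes exclude the clavicle.  When all
    three raters disagree the adjudicating rater's re-evaluated stage
    (``adjudicated_stage``, supplied as data; falls back to the adjudicator's
    own vote) decides.
    """
    if len(ratings) != 3:
        raise ValueError(f"expected ratings from exactly 3 raters, got {len(ratings)}")
    if adjudicator not in ratings:
        raise ValueError(f"adjudicator {adjudicator!r} is not among the raters")
    counts = Counter(ratings.values())
    stage, votes = counts.most_common(1)[0]
    if votes >= 2:
        return stage
    if adjudicated_stage:
        return adjudicated_stage
    return ratings[adjudicator]


def consensus_observations(
    ratings: pd.DataFrame,
    subjects: pd.DataFrame,
    adjudicator: str | None = None,
) -> pd.DataFrame:
    """Resolve consensus per clavicle and join subject ages.

    Returns one row per evaluable clavicle with columns ``subject_id``,
    ``side``, ``stage``, ``group``, ``group_rank``, ``age``, ``adult``.
    Clavicles whose consensus is ``NE`` are excluded (the subject's other
    side may still contribute).
    """
    if adjudicator is None:
        adjudicator = sorted(ratings["rater_id"].unique())[-1]
    ages = subjects.set_index("subject_id")["age_years"]
    adult = subjects.set_index("subject_id")["adult"]
    rows = []
    for (sid, side), grp in ratings.groupby(["subject_id", "side"], sort=True):
        votes = dict(zip(grp["rater_id"], grp["stage"]))
        adj = grp.loc[grp["rater_id"] == adjudicator, "adjudicated_stage"]
        adj_stage = adj.iloc[0] if len(adj) and adj.iloc[0] else None
        stage = consensus_stage(votes, adjudicator, adj_stage)
        if stage == NOT_EVALUABLE:
            continue
        g = collapse_stage(stage)
        rows.append(
            {
                "subject_id": sid,
                "side": side,
                "stage": stage,
                "stage_rank": stage_rank(stage),
                "group": g.label,
                "group_rank": g.rank,
                "age": float(ages[sid]),
                "adult": bool(adult[sid]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "side",
            "stage",
            "stage_rank",
            "group",
            "group_rank",
            "age",
            "adult",
        ],
    )


# ---------------------------------------------------------------------------
# side comparison


def _paired_ranks(observations: pd.DataFrame) -> pd.DataFrame:
    """Subjects with both sides staged, as one row with left/right stage ranks."""
    wide = observations.pivot(index="subject_id", columns="side", values="stage_rank")
    if "L" not in wide.columns or "R" not in wide.columns:
        return pd.DataFrame(columns=["L", "R"])
    return wide.dropna(subset=["L", "R"]).astype(int)


def side_concordance(observations: pd.DataFrame) -> dict[str, int]:
    """Partition paired subjects by absolute left/right rank difference.

    Differences are counted on the full 9-level scale.  Returns counts
    ``{"same", "diff_one", "diff_two_plus"}`` summing to the number of
    subjects with both sides staged.
    """
    pairs = _paired_ranks(observations)
    diff = (pairs["L"] - pairs["R"]).abs()
    return {
        "same": int((diff == 0).sum()),
        "diff_one": int((diff == 1).sum()),
        "diff_two_plus": int((diff >= 2).sum()),
    }


def paired_side_test(
    observations: pd.DataFrame, zero_method: str = "wilcox"
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test of left vs right stage ranks.

    Tests for a systematic developmental advance of one side.  Zero
    differences are dropped by default (classic Wilcoxon); with ~80% of
    subjects showing identical stages this choice matters, so ``zero_method``
    is exposed (``"pratt"`` keeps zeros in the ranking).

    Returns ``(statistic, p_value)``; with no nonzero difference the test is
    degenerate and ``(nan, nan)`` is returned.
    """
    pairs = _paired_ranks(observations)
    diff = pairs["L"] - pairs["R"]
    if len(diff) == 0 or (diff == 0).all():
        return (float("nan"), float("nan"))
    res = stats.wilcoxon(
        pairs["L"], pairs["R"], zero_method=zero_method, alternative="two-sided"
    )
    return (float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# descriptives


def descriptive_table(
    observations: pd.DataFrame,
    by: str = "stage",
    quantile_method: str = "linear",
    decimals: int | None = 2,
) -> pd.DataFrame:
    """Per-(stage, side) descriptive statistics of chronological age in years.

    Mean, SD (n-1 denominator), min, lower quartile, median, upper quartile
    and max per group.  Quartiles use linear interpolation between order
    statistics by default (numpy's ``linear`` method; configurable via
    ``quantile_method``).  Single-member groups report SD as missing.
    """
    rows = []
    order = STAGES if by == "stage" else GROUPS
    for (label, side), grp in observations.groupby([by, "side"], sort=False):
        a = grp["age"].to_numpy(float)
        q1, med, q3 = np.quantile(a, [0.25, 0.5, 0.75], method=quantile_method)
        rows.append(
            {
                by: label,
                "side": side,
                "n": len(a),
                "mean": a.mean(),
                "sd": a.std(ddof=1) if len(a) > 1 else np.nan,
                "min": a.min(),
                "lq": q1,
                "median": med,
                "uq": q3,
                "max": a.max(),
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=[by, "side"], key=lambda s: s.map(lambda v: order.index(v)) if s.name == by else s
    ).reset_index(drop=True)
    if decimals is not None:
        for c in ("mean", "sd", "min", "lq", "median", "uq", "max"):
            out[c] = out[c].round(decimals)
    return out
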