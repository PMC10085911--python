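"""Cross-validation and test-set validation of the transition model.

Seven constellations mirror the standard bilateral design: 10-fold
cross-validation of the right, left, merged ("whole") and half-set-max/min
datasets, plus the two cross-side train/test splits.  Half set max/min carry,
per subject, the more/less advanced of the two clavicle stages; the whole
set stacks both sides (two rows per subject, sharing a fold).  Only subjects
with both sides staged enter any constellation.

Per fold the model is refit on the training part and each test clavicle's
age is predicted by the MLA of its stage group; terminal groups substitute
the training fold's minimum/maximum age (fold-local, avoiding leakage).
Errors are pooled across folds before computing MAE and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .transition import CumulativeProbitTA

CONSTELLATIONS: tuple[str, ...] = (
    "right_cv",
    "left_cv",
    "whole_cv",
    "right_train_left_test",
    "left_train_right_test",
    "halfmax_cv",
    "halfmin_cv",
)


@dataclass(frozen=True)
class ValidationReport:
    constellation: str
    mae: float
    rmse: float
    n_test: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.n_test and self.rmse < self.mae - 1e-12:
            raise ValueError("rmse must be >= mae")


def _paired(observations: pd.DataFrame) -> pd.DataFrame:
    """Restrict to subjects with both sides staged."""
    counts = observations.groupby("subject_id")["side"].nunique()
    keep = counts[counts == 2].index
    return observations[observations["subject_id"].isin(keep)].copy()


def _half_set(paired: pd.DataFrame, which: str) -> pd.DataFrame:
    idx = paired.groupby("subject_id")["group_rank"]
    take = idx.idxmax() if which == "max" else idx.idxmin()
    return paired.loc[take.values].copy()


def build_constellation(
    observations: pd.DataFrame, name: str
) -> tuple[pd.DataFrame, pd.DataFrame | None, int | None]:
    """Train/test datasets and fold count for a named constellation.

    Returns ``(train, test, folds)``: CV constellations return the single
    dataset with ``test=None`` and ``folds=10``; cross-side splits return
    disjoint train/test with ``folds=None``.
    """
    paired = _paired(observations)
    left = paired[paired["side"] == "L"]
    right = paired[paired["side"] == "R"]
    if name == "right_cv":
        return right, None, 10
    if name == "left_cv":
        return left, None, 10
    if name == "whole_cv":
        return paired, None, 10
    if name == "right_train_left_test":
        return right, left, None
    if name == "left_train_right_test":
        return left, right, None
    if name == "halfmax_cv":
        return _half_set(paired, "max"), None, 10
    if name == "halfmin_cv":
        return _half_set(paired, "min"), None, 10
    raise ValueError(f"unknown constellation {name!r}; expected one of {CONSTELLATIONS}")


# ---------------------------------------------------------------------------
# prediction plumbing


def _mla_by_group(results, train: pd.DataFrame, step: float = 0.01) -> dict[int, float]:
    """MLA per fitted group level, with fold-local terminal substitution."""
    lo, hi = float(train["age"].min()), float(train["age"].max())
    out = {}
    for idx, level in enumerate(results.model.levels):
        pred = results.predict_age(idx, lo, hi, step=step)
        out[int(level)] = pred.mla
    return out


def _predict_errors(train: pd.DataFrame, test: pd.DataFrame, transform: str
                    ) -> tuple[np.ndarray, int]:
    """Fit on train, predict test MLAs; returns (errors, n_skipped)."""
    model = CumulativeProbitTA.from_dataframe(train, transform=transform)
    results = model.fit()
    mla = _mla_by_group(results, train)
    known = test["group_rank"].isin(mla.keys())
    n_skipped = int((~known).sum())
    sub = test[known]
    pred = sub["group_rank"].map(mla).to_numpy(float)
    return sub["age"].to_numpy(float) - pred, n_skipped


def _report(name: str, errors: np.ndarray, n_skipped: int) -> ValidationReport:
    if len(errors) == 0:
        raise ValueError("empty test set")
    mae = float(np.abs(errors).mean())
    rmse = float(np.sqrt((errors**2).mean()))
    return ValidationReport(name, mae, rmse, len(errors), n_skipped)


def _subject_folds(dataset: pd.DataFrame, k: int, seed: int) -> dict[str, int]:
    """Subject-level fold assignment, stratified by stage group where possible.

    Both rows of a subject (whole-set case) share a fold.  Stratification
    labels with fewer members than folds are merged into the adjacent rank
    so every training fold sees every common group; if stratification is
    still impossible a plain shuffled split is used.
    """
    per_subject = dataset.groupby("subject_id")["group_rank"].max()
    subjects = per_subject.index.to_numpy()
    labels = per_subject.to_numpy(int).copy()
    for _ in range(len(np.unique(labels))):
        vals, counts = np.unique(labels, return_counts=True)
        rare = vals[counts < k]
        if len(rare) == 0:
            break
        v = rare[0]
        others = vals[vals != v]
        if len(others) == 0:
            break
        labels[labels == v] = others[np.argmin(np.abs(others - v))]
    try:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(subjects, labels)
        folds = {}
        for f, (_, test_idx) in enumerate(splits):
            for i in test_idx:
                folds[subjects[i]] = f
        return folds
    except ValueError:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return {
            subjects[i]: f
            for f, (_, test_idx) in enumerate(splitter.split(subjects))
            for i in test_idx
        }


def cross_validate(dataset: pd.DataFrame, k: int = 10, seed: int = 20221219,
                   transform: str = "log", name: str = "cv") -> ValidationReport:
    """k-fold cross-validation with subject-level folds and pooled errors."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if dataset["subject_id"].nunique() < k:
        raise ValueError("dataset smaller than the number of folds")
    folds = _subject_folds(dataset, k, seed)
    fold_of = dataset["subject_id"].map(folds)
    all_errors, skipped = [], 0
    for f in range(k):
        train = dataset[fold_of != f]
        test = dataset[fold_of == f]
        if len(test) == 0:
            continue
        errors, n_skip = _predict_errors(train, test, transform)
        all_errors.append(errors)
        skipped += n_skip
    return _report(name, np.concatenate(all_errors), skipped)


def train_test(train: pd.DataFrame, test: pd.DataFrame, transform: str = "log",
               name: str = "train_test") -> ValidationReport:
    """Single fit on ``train`` evaluated on ``test`` with the same metrics."""
    if len(test) == 0:
        raise ValueError("empty test set")
    errors, n_skip = _predict_errors(train, test, transform)
    return _report(name, errors, n_skip)


def run_constellations(observations: pd.DataFrame, k: int = 10,
                       seed: int = 20221219, transform: str = "log",
                       names: tuple[str, ...] = CONSTELLATIONS) -> pd.DataFrame:
    """Validation report table over the named constellations (report layout)."""
    rows = []
    for name in names:
        train, test, folds = build_constellation(observations, name)
        if folds is not None:
            rep = cross_validate(train, k=folds if k == 10 else k, seed=seed,
                                 transform=transform, name=name)
        else:
            rep = train_test(train, test, transform=transform, name=name)
        rows.append(
            {
                "constellation": rep.constellation,
                "mae": round(rep.mae, 2),
                "rmse": round(rep.rmse, 2),
                "n_test": rep.n_test,
                "n_skipped": rep.n_skipped,
            }
        )
    return pd.DataFrame(rows)
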