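"""Normed-likelihood age prediction from a fitted transition model.

For a clavicle observed in stage group j, the age likelihood is
L_j(a) = P(group j | age a) under the fitted cumulative probit.  Divided by
its maximum over the age grid it becomes the *normed likelihood curve*, whose
peak (the maximum-likelihood age, MLA) is the point prediction and whose
superlevel set above

    c(level) = exp(-chi2_{1, level} / 2)

forms the level-% prediction interval (Wilks inversion of the likelihood
ratio; c(0.95) = 0.1465).  The lowest and highest stage groups have no
interior likelihood peak — their curves are monotone over any realistic age
range — so their point predictions are set to the sample minimum and maximum
age respectively, and terminal interval bounds are clipped to the sample
bounds rather than extrapolated.

Minor/adult classification uses the point prediction: adult iff MLA >= 18.0
(the boundary age itself counts as adult).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def normed_threshold(level: float) -> float:
    """Normed-likelihood cutoff for a given prediction-interval level.

    exp(-q/2) with q the ``level`` quantile of chi-square(1); 0.95 -> 0.1465.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    return float(np.exp(-stats.chi2.ppf(level, df=1) / 2.0))


@dataclass
class LikelihoodCurve:
    """Per-stage normed likelihood over a regular age grid (max = 1)."""

    group_index: int
    ages: np.ndarray
    normed: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, float)
        self.normed = np.asarray(self.normed, float)
        if self.ages.shape != self.normed.shape or self.ages.ndim != 1:
            raise ValueError("ages and normed must be equal-length 1-d arrays")


@dataclass
class AgePrediction:
    """Point prediction (MLA) with prediction interval for one stage group."""

    group_index: int
    mla: float
    pi_low: float
    pi_high: float
    terminal: bool


def likelihood_curve(model, group_index: int, age_min: float, age_max: float,
                     step: float = 0.01) -> LikelihoodCurve:
    """Evaluate P(group | age) on a regular grid and norm to a unit maximum.

    ``model`` is any object with ``stage_probability(group_index, ages)``
    (a fitted or frozen transition model).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    # exact endpoints so terminal-stage bounds land on the sample limits
    n_steps = max(1, round((age_max - age_min) / step))
    ages = np.linspace(age_min, age_max, n_steps + 1)
    lik = model.stage_probability(group_index, ages)
    peak = lik.max()
    if peak <= 0:
        raise ValueError("stage has zero probability over the whole age range")
    return LikelihoodCurve(group_index, ages, lik / peak)


def point_prediction(curve: LikelihoodCurve, sample_age_min: float,
                     sample_age_max: float, n_groups: int) -> tuple[float, bool]:
    """MLA for interior groups; sample min/max substitution for terminal ones."""
    if curve.group_index == 0:
        return float(sample_age_min), True
    if curve.group_index == n_groups - 1:
        return float(sample_age_max), True
    return float(curve.ages[int(np.argmax(curve.normed))]), False


def prediction_interval(curve: LikelihoodCurve, level: float = 0.95
                        ) -> tuple[float, float]:
    """Smallest and largest ages with normed likelihood >= the level cutoff.

    Crossings are refined by linear interpolation between grid points; the
    bounds are clipped to the grid range (the sample age range for curves
    built on it), implementing the terminal-stage convention.
    """
    c = normed_threshold(level)
    above = curve.normed >= c
    idx = np.flatnonzero(above)
    if len(idx) == 0:  # cannot happen: max = 1 > c
        raise RuntimeError("threshold above curve maximum")
    lo_i, hi_i = idx[0], idx[-1]
    ages, f = curve.ages, curve.normed
    if lo_i > 0:
        a0, a1 = ages[lo_i - 1], ages[lo_i]
        f0, f1 = f[lo_i - 1], f[lo_i]
        lo = a0 + (c - f0) / (f1 - f0) * (a1 - a0)
    else:
        lo = ages[0]
    if hi_i < len(ages) - 1:
        a0, a1 = ages[hi_i], ages[hi_i + 1]
        f0, f1 = f[hi_i], f[hi_i + 1]
        hi = a0 + (c - f0) / (f1 - f0) * (a1 - a0)
    else:
        hi = ages[-1]
    return float(lo), float(hi)


def predict_age(curve: LikelihoodCurve, sample_age_min: float,
                sample_age_max: float, n_groups: int, level: float = 0.95
                ) -> AgePrediction:
    """Combine point prediction and prediction interval for one group."""
    mla, terminal = point_prediction(curve, sample_age_min, sample_age_max, n_groups)
    lo, hi = prediction_interval(curve, level)
    lo = max(lo, sample_age_min)
    hi = min(hi, sample_age_max)
    return AgePrediction(curve.group_index, mla, lo, hi, terminal)


def classify_adult(prediction: AgePrediction) -> str:
    """Minor/adult call from the point prediction: adult iff MLA >= 18.0 y."""
    return "adult" if prediction.mla >= 18.0 else "minor"


def classification_metrics(predicted_adult, true_adult) -> dict[str, float | None]:
    """Accuracy, specificity and sensitivity of the minor/adult call, in %.

    Accuracy: correctly classified individuals; specificity: correctly
    classified minors; sensitivity: correctly classified adults.  A
    component whose denominator is empty is reported as None rather than 0.
    """
    pred = np.asarray(predicted_adult, bool)
    true = np.asarray(true_adult, bool)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth must align")
    n = len(true)
    n_adult = int(true.sum())
    n_minor = n - n_adult
    acc = 100.0 * float((pred == true).sum()) / n if n else None
    spec = 100.0 * float((~pred[~true]).sum()) / n_minor if n_minor else None
    sens = 100.0 * float(pred[true].sum()) / n_adult if n_adult else None
    return {"accuracy": acc, "specificity": spec, "sensitivity": sens}


def plot_likelihood_curves(model, sample_age_min: float, sample_age_max: float,
                           level: float = 0.95, step: float = 0.01, path=None):
    """Normed likelihood curves per stage group with the interval cutoff line.

    Mirrors the standard presentation: one curve per group, a horizontal
    line at the normed cutoff (0.1465 for 95%), a dashed vertical line at
    age 18, and solid vertical lines at the interior point predictions.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for j in range(model.J):
        curve = likelihood_curve(model, j, sample_age_min, sample_age_max, step)
        ax.plot(curve.ages, curve.normed, label=model.labels[j])
        mla, terminal = point_prediction(curve, sample_age_min, sample_age_max, model.J)
        if not terminal:
            ax.axvline(mla, color="grey", lw=0.8)
    ax.axhline(normed_threshold(level), color="black", lw=1)
    ax.axvline(18.0, color="black", ls="--", lw=1)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("normed likelihood")
    ax.legend(title="stage group", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
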