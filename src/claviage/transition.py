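"""Cumulative-probit transition analysis of ossification stage on age.

Transition analysis relates an ordinal developmental stage to age through a
latent-variable model and then inverts it into age-given-stage statements,
avoiding the age-mimicry bias of naive per-stage descriptive statistics.

The model: with stage groups j = 1..J and a monotone age transform t
(log-age by default, the convention of the transition-analysis literature),

    P(group <= j | age) = Phi(tau_j - beta * t(age)),

with ordered cutpoints tau_1 < ... < tau_{J-1} on a unit-variance latent
scale and a single positive slope beta (common latent sigma).  The age at
which the transition j -> j+1 is median occurs where the latent mean crosses
tau_j, i.e. at t^{-1}(tau_j / beta).

Estimation is maximum likelihood.  The optimiser works on the unconstrained
parameterisation (tau_1, log of the cutpoint gaps, log beta), which enforces
cutpoint ordering and slope positivity without constrained optimisation.

Fit diagnostics: a Lagrange-multiplier (score) test of the common-slope
restriction against cutpoint-specific slopes (chi-square, J-2 df), and the
Cragg-Uhler pseudo-R^2 against the intercept-only model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from . import inference

_TRANSFORMS = {
    "log": (np.log, np.exp),
    "identity": (lambda a: np.asarray(a, float), lambda t: np.asarray(t, float)),
}


def _interval_prob(u_hi: np.ndarray, u_lo: np.ndarray) -> np.ndarray:
    """Phi(u_hi) - Phi(u_lo) for u_hi >= u_lo, stable in both tails."""
    flip = (u_hi + u_lo) > 0
    a = np.where(flip, -u_lo, u_hi)
    b = np.where(flip, -u_hi, u_lo)
    return np.clip(special.ndtr(a) - special.ndtr(b), 1e-300, 1.0)


class ConvergenceWarning(UserWarning):
    pass


class CumulativeProbitTA:
    """Cumulative probit model of stage group on (transformed) age.

    Parameters
    ----------
    group_rank : array-like of int
        Ordinal stage-group codes; re-indexed internally to 0..J-1 over the
        levels present.
    age : array-like of float
        Chronological ages in decimal years; strictly positive when
        ``transform="log"``.
    transform : {"log", "identity"}
        Age transform t applied before the linear predictor.
    labels : sequence of str, optional
        Display labels aligned with the sorted distinct group codes.
    """

    def __init__(self, group_rank, age, transform: str = "log", labels=None):
        group_rank = np.asarray(group_rank, dtype=int)
        age = np.asarray(age, dtype=float)
        if group_rank.shape != age.shape or group_rank.ndim != 1:
            raise ValueError("group_rank and age must be equal-length 1-d arrays")
        if transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {transform!r}")
        if transform == "log" and np.any(age <= 0):
            raise ValueError("ages must be strictly positive under the log transform")
        self.levels = np.unique(group_rank)
        if len(self.levels) < 2:
            raise ValueError("need at least 2 distinct stage groups")
        self.y = np.searchsorted(self.levels, group_rank)
        self.age = age
        self.transform = transform
        self.t = _TRANSFORMS[transform][0](age)
        self.J = len(self.levels)
        self.n = len(age)
        if labels is not None:
            labels = list(labels)
            if len(labels) != self.J:
                raise ValueError("labels must match the number of distinct groups")
        self.labels = labels or [str(v) for v in self.levels]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        group_col: str = "group_rank",
        age_col: str = "age",
        transform: str = "log",
        label_col: str | None = "group",
    ) -> "CumulativeProbitTA":
        """Build the model from a consensus-observation table."""
        labels = None
        if label_col is not None and label_col in data.columns:
            labels = (
                data[[group_col, label_col]]
                .drop_duplicates()
                .sort_values(group_col)[label_col]
                .tolist()
            )
        return cls(data[group_col], data[age_col], transform=transform, labels=labels)

    # -- parameterisation: theta = (tau_1, log gaps..., log beta) ------------

    def _unpack(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        gaps = np.exp(theta[1 : self.J - 1])
        tau = theta[0] + np.concatenate([[0.0], np.cumsum(gaps)])
        return tau, float(np.exp(theta[-1]))

    def _pack(self, tau: np.ndarray, beta: float) -> np.ndarray:
        return np.concatenate([[tau[0]], np.log(np.diff(tau)), [np.log(beta)]])

    def _cut_args(self, tau: np.ndarray, beta: float):
        ext = np.concatenate([[-np.inf], tau, [np.inf]])
        u_hi = ext[self.y + 1] - beta * self.t
        u_lo = ext[self.y] - beta * self.t
        return u_hi, u_lo

    def loglike(self, theta: np.ndarray) -> float:
        tau, beta = self._unpack(theta)
        u_hi, u_lo = self._cut_args(tau, beta)
        return float(np.log(_interval_prob(u_hi, u_lo)).sum())

    def score(self, theta: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood in theta."""
        tau, beta = self._unpack(theta)
        u_hi, u_lo = self._cut_args(tau, beta)
        p = _interval_prob(u_hi, u_lo)
        phi_hi = np.where(np.isfinite(u_hi), stats.norm.pdf(u_hi), 0.0)
        phi_lo = np.where(np.isfinite(u_lo), stats.norm.pdf(u_lo), 0.0)
        # dl/dtau_j : + phi(u_hi)/p where y==j, - phi(u_lo)/p where y==j+1
        d_tau = np.zeros(self.J - 1)
        hi_term = phi_hi / p
        lo_term = phi_lo / p
        for j in range(self.J - 1):
            d_tau[j] = hi_term[self.y == j].sum() - lo_term[self.y == j + 1].sum()
        d_beta = float((self.t * (lo_term - hi_term)).sum())
        # chain rule to (tau_1, log gaps, log beta)
        g = np.empty(self.J)
        g[0] = d_tau.sum()
        gaps = np.exp(theta[1 : self.J - 1])
        for k in range(1, self.J - 1):
            g[k] = d_tau[k:].sum() * gaps[k - 1]
        g[-1] = d_beta * beta
        return g

    def _newton_polish(self, theta: np.ndarray, gtol: float,
                       max_iter: int = 20) -> tuple[np.ndarray, float]:
        """Newton steps (numerical Hessian of the analytic score) to drive the
        gradient max-norm below tolerance; keeps the best iterate seen."""
        x = theta.copy()
        g = self.score(x)
        best = (x, float(np.abs(g).max()), self.loglike(x))
        for _ in range(max_iter):
            if best[1] <= gtol:
                break
            hess = numdiff.approx_fprime(x, self.score, centered=True)
            hess = (hess + hess.T) / 2.0
            try:
                step = np.linalg.solve(hess, g)
            except np.linalg.LinAlgError:
                break
            cand = x - step
            if not np.all(np.isfinite(cand)):
                break
            ll = self.loglike(cand)
            if ll < best[2] - 1e-6:  # diverging Newton step; halve once
                cand = x - 0.5 * step
                ll = self.loglike(cand)
                if ll < best[2] - 1e-6:
                    break
            x = cand
            g = self.score(x)
            gn = float(np.abs(g).max())
            if gn < best[1]:
                best = (x, gn, ll)
        return best[0], best[1]

    def _start_params(self) -> np.ndarray:
        freq = np.bincount(self.y, minlength=self.J) / self.n
        cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
        beta0 = 1.0
        tau0 = stats.norm.ppf(cum) + beta0 * self.t.mean()
        tau0 = np.maximum.accumulate(tau0 + 1e-6 * np.arange(self.J - 1))
        tau0 += np.arange(self.J - 1) * 1e-3  # strictly increasing
        return self._pack(tau0, beta0)

    def fit(
        self,
        start_params: np.ndarray | None = None,
        gtol: float = 1e-6,
        max_restarts: int = 3,
    ) -> "TransitionResults":
        """Maximise the likelihood; deterministic given data and start values.

        Convergence requires gradient max-norm <= ``gtol``; up to
        ``max_restarts`` deterministic perturbed restarts are attempted
        before the fit is flagged.  A parameter-magnitude guard flags
        complete separation (runaway slope or cutpoint gaps) as a warning
        rather than failing silently.
        """
        theta0 = self._start_params() if start_params is None else np.asarray(start_params)
        rng = np.random.default_rng(12345)
        best = None
        for attempt in range(max_restarts + 1):
            res = optimize.minimize(
                lambda th: -self.loglike(th),
                theta0 if attempt == 0 else theta0 + rng.normal(0, 0.1, size=theta0.shape),
                jac=lambda th: -self.score(th),
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
            )
            x, gnorm = self._newton_polish(res.x, gtol)
            fun = -self.loglike(x)
            if best is None or fun < best[1]:
                best = (x, fun, gnorm)
            if gnorm <= gtol:
                best = (x, fun, gnorm)
                break
        x, fun, gnorm = best
        converged = gnorm <= gtol
        tau, beta = self._unpack(x)
        flagged = bool(beta > 1e3 or np.any(np.diff(tau) > 50) or np.abs(tau).max() > 1e4)
        if not converged:
            warnings.warn(
                f"gradient max-norm {gnorm:.2e} above tolerance {gtol:.0e}",
                ConvergenceWarning,
            )
        if flagged:
            warnings.warn(
                "parameter magnitudes suggest complete separation; "
                "estimates are unreliable",
                ConvergenceWarning,
            )
        return TransitionResults(
            model=self,
            theta=x,
            cutpoints=tau,
            slope=beta,
            loglik=float(-fun),
            converged=converged,
            separation_flag=flagged,
            grad_norm=gnorm,
        )

    # -- intercept-only reference --------------------------------------------

    def loglike_null(self) -> float:
        """Log-likelihood of the intercept-only (multinomial) model."""
        freq = np.bincount(self.y, minlength=self.J)
        nz = freq[freq > 0]
        return float((nz * np.log(nz / self.n)).sum())


@dataclass
class FitDiagnostics:
    """Score test of the common-slope restriction plus Cragg-Uhler R^2."""

    lm_statistic: float
    lm_df: int
    lm_p: float
    pseudo_r2: float


class TransitionResults:
    """Fitted cumulative-probit transition model.

    Carries the ordered cutpoints, the slope on the transformed-age scale,
    the log-likelihood, and convergence flags; exposes transition ages,
    stage probabilities over age, fit diagnostics, normed-likelihood age
    prediction (via :mod:`claviage.inference`) and a text ``summary()``.
    """

    def __init__(self, model, theta, cutpoints, slope, loglik, converged,
                 separation_flag, grad_norm):
        self.model = model
        self.theta = theta
        self.cutpoints = cutpoints
        self.slope = slope
        self.loglik = loglik
        self.converged = converged
        self.separation_flag = separation_flag
        self.grad_norm = grad_norm
        self.n = model.n
        self.J = model.J
        self.transform = model.transform
        self.labels = model.labels

    # -- core quantities -----------------------------------------------------

    def transition_ages(self) -> np.ndarray:
        """Ages (years) at which each stage-group transition is median.

        t^{-1}(tau_j / beta); strictly increasing in j.
        """
        inv = _TRANSFORMS[self.transform][1]
        return inv(self.cutpoints / self.slope)

    def predict_proba(self, ages) -> np.ndarray:
        """P(group j | age) for each age; rows sum to 1."""
        t = _TRANSFORMS[self.transform][0](np.asarray(ages, float))
        ext = np.concatenate([[-np.inf], self.cutpoints, [np.inf]])
        cum = special.ndtr(ext[None, :] - self.slope * t[:, None])
        return np.diff(cum, axis=1)

    def stage_probability(self, group_index: int, ages) -> np.ndarray:
        """P(group | age) for one group (0-based index into the fitted levels)."""
        return self.predict_proba(ages)[:, group_index]

    # -- diagnostics ---------------------------------------------------------

    def _full_loglike_and_score(self, psi: np.ndarray):
        """Alternative model with cutpoint-specific slopes.

        psi = (tau_1..tau_{J-1}, beta_1..beta_{J-1});
        P(y = j) = Phi(tau_j - beta_j t) - Phi(tau_{j-1} - beta_{j-1} t).
        """
        m = self.model
        J = self.J
        tau = psi[: J - 1]
        betas = psi[J - 1 :]
        ext_tau = np.concatenate([[-np.inf], tau, [np.inf]])
        ext_beta = np.concatenate([[1.0], betas, [1.0]])  # unused at +-inf cuts
        u_hi = ext_tau[m.y + 1] - ext_beta[m.y + 1] * m.t
        u_lo = ext_tau[m.y] - ext_beta[m.y] * m.t
        p = _interval_prob(u_hi, u_lo)
        ll = float(np.log(p).sum())
        phi_hi = np.where(np.isfinite(u_hi), stats.norm.pdf(u_hi), 0.0) / p
        phi_lo = np.where(np.isfinite(u_lo), stats.norm.pdf(u_lo), 0.0) / p
        grad = np.zeros(2 * (J - 1))
        for j in range(J - 1):
            sel_hi = m.y == j       # cut j is this category's upper bound
            sel_lo = m.y == j + 1   # and the next category's lower bound
            grad[j] = phi_hi[sel_hi].sum() - phi_lo[sel_lo].sum()
            grad[J - 1 + j] = -(m.t[sel_hi] * phi_hi[sel_hi]).sum() + (
                m.t[sel_lo] * phi_lo[sel_lo]
            ).sum()
        return ll, grad

    def lm_test(self) -> tuple[float, int, float]:
        """Lagrange-multiplier (score) test of the common-slope restriction.

        The score and observed information of the cutpoint-specific-slope
        alternative are evaluated at the restricted MLE; the statistic is
        asymptotically chi-square with J-2 degrees of freedom under the
        restriction.  Returns ``(statistic, df, p)``; an (effectively)
        singular information matrix yields ``(nan, df, nan)`` (untestable).
        """
        df = self.J - 2
        if df < 1:
            return (float("nan"), df, float("nan"))
        psi_hat = np.concatenate([self.cutpoints, np.full(self.J - 1, self.slope)])
        _, score = self._full_loglike_and_score(psi_hat)
        hess = numdiff.approx_fprime(
            psi_hat, lambda p: self._full_loglike_and_score(p)[1], centered=True
        )
        info = -(hess + hess.T) / 2.0
        try:
            sol = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return (float("nan"), df, float("nan"))
        if np.linalg.cond(info) > 1e12:
            return (float("nan"), df, float("nan"))
        lm = float(score @ sol)
        lm = max(lm, 0.0)
        return (lm, df, float(stats.chi2.sf(lm, df)))

    def pseudo_r2(self) -> float:
        """Cragg-Uhler pseudo-R^2 against the intercept-only model.

        [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)] with L the likelihoods.
        """
        ll0 = self.model.loglike_null()
        ll1 = self.loglik
        if ll1 < ll0 - 1e-8:
            raise RuntimeError("fitted likelihood below intercept-only likelihood")
        n = self.n
        num = 1.0 - np.exp(2.0 / n * (ll0 - max(ll1, ll0)))
        den = 1.0 - np.exp(2.0 / n * ll0)
        return float(num / den)

    def diagnostics(self) -> FitDiagnostics:
        lm, df, p = self.lm_test()
        return FitDiagnostics(lm, df, p, self.pseudo_r2())

    # -- prediction (delegates to the inference layer) -----------------------

    def likelihood_curve(self, group_index, age_min, age_max, step=0.01):
        """Normed likelihood curve for one stage group; see inference module."""
        return inference.likelihood_curve(self, group_index, age_min, age_max, step)

    def predict_age(self, group_index, sample_age_min, sample_age_max, level=0.95,
                    step=0.01):
        """MLA point prediction with prediction interval for one stage group."""
        curve = self.likelihood_curve(group_index, sample_age_min, sample_age_max, step)
        return inference.predict_age(curve, sample_age_min, sample_age_max,
                                     n_groups=self.J, level=level)

    def prediction_table(self, sample_age_min, sample_age_max, level=0.95,
                         counts=None) -> pd.DataFrame:
        """Per-group MLA and prediction-interval table (report layout)."""
        rows = []
        for j in range(self.J):
            pred = self.predict_age(j, sample_age_min, sample_age_max, level)
            rows.append(
                {
                    "group": self.labels[j],
                    "mla": None if pred.terminal else round(pred.mla, 2),
                    "pi_low": round(pred.pi_low, 2),
                    "pi_high": round(pred.pi_high, 2),
                    "n": None if counts is None else int(counts[j]),
                }
            )
        return pd.DataFrame(rows)

    # -- reporting / persistence --------------------------------------------

    def summary(self) -> str:
        ages = self.transition_ages()
        lines = [
            "Cumulative Probit Transition Analysis",
            "=" * 55,
            f"n observations      {self.n:>10d}",
            f"stage groups (J)    {self.J:>10d}",
            f"age transform       {self.transform:>10s}",
            f"log-likelihood      {self.loglik:>12.3f}",
            f"slope (beta)        {self.slope:>12.4f}",
            f"converged           {str(self.converged):>10s}",
            "-" * 55,
            f"{'transition':<18}{'cutpoint':>12}{'age (y)':>12}",
        ]
        for j in range(self.J - 1):
            name = f"{self.labels[j]} -> {self.labels[j + 1]}"
            lines.append(f"{name:<18}{self.cutpoints[j]:>12.3f}{ages[j]:>12.2f}")
        lines.append("=" * 55)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "transform": self.transform,
            "cutpoints": [float(v) for v in self.cutpoints],
            "slope": float(self.slope),
            "loglik": float(self.loglik),
            "n": int(self.n),
            "J": int(self.J),
            "labels": list(self.labels),
            "levels": [int(v) for v in self.model.levels],
            "converged": bool(self.converged),
        }

    def save(self, path) -> None:
        """Dump the fitted model as JSON, sufficient to reload and predict."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def load(path) -> "FrozenTransitionModel":
        with open(path) as fh:
            return FrozenTransitionModel(**json.load(fh))


class FrozenTransitionModel:
    """A reloaded (or directly specified) transition model for prediction only.

    Shares the prediction surface of :class:`TransitionResults` without the
    fitting machinery — also the vehicle for simulating from known truth.
    """

    def __init__(self, cutpoints, slope, transform="log", labels=None, J=None,
                 loglik=None, n=None, levels=None, converged=True):
        self.cutpoints = np.asarray(cutpoints, float)
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        if slope <= 0:
            raise ValueError("slope must be strictly positive")
        self.slope = float(slope)
        self.transform = transform
        self.J = len(self.cutpoints) + 1
        self.labels = labels or [str(j) for j in range(self.J)]
        self.loglik = loglik
        self.n = n

    transition_ages = TransitionResults.transition_ages
    predict_proba = TransitionResults.predict_proba
    stage_probability = TransitionResults.stage_probability
    likelihood_curve = TransitionResults.likelihood_curve
    predict_age = TransitionResults.predict_age
    prediction_table = TransitionResults.prediction_table
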